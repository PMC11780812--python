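"""Clinical-outcome machinery: platinum response, Kaplan–Meier, log-rank, Cox PH.

Endpoints follow the usual ovarian-cancer conventions: progression-free
survival (PFS) runs from completion of primary treatment to recurrence or
censoring; overall survival (OS) runs from diagnosis to death or censoring.
Platinum sensitivity is recurrence strictly beyond six months after primary
treatment; recurrence at or before six months is resistance, and patients
without recurrence are assessable only once followed for six months.

Kaplan–Meier curves and the two-group log-rank test are computed with
lifelines.  The Cox proportional-hazards fit maximizes the partial
likelihood directly (Newton–Raphson, Efron tie handling by default, Breslow
available) and reports Wald confidence intervals and p-values on the
log-hazard scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .errors import ConvergenceError, ValidationError

__all__ = [
    "CohortRecord",
    "SurvivalFit",
    "KmCurve",
    "read_clinical_table",
    "classify_platinum_response",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "PLATINUM_BOUNDARY_MONTHS",
]

#: Months separating platinum-sensitive from platinum-resistant recurrence.
PLATINUM_BOUNDARY_MONTHS = 6.0

CLINICAL_COLUMNS = [
    "PatientID",
    "HRD_status",
    "Resection",
    "PFS_months",
    "PFS_event",
    "OS_months",
    "OS_event",
    "Months_to_recurrence",
    "Followup_after_primary_months",
]


@dataclass(frozen=True)
class CohortRecord:
    """One patient's HRD status, surgery result and follow-up."""

    patient_id: str
    hrd_status: str  # positive | negative
    resection: str  # R0 | R1 | R2
    pfs_months: float
    pfs_event: int  # 1 recurrence/progression, 0 censored
    os_months: float
    os_event: int  # 1 death, 0 censored
    months_to_recurrence: Optional[float]
    followup_after_primary_months: float

    def __post_init__(self) -> None:
        if self.hrd_status not in {"positive", "negative"}:
            raise ValidationError(f"patient {self.patient_id!r}: bad HRD status {self.hrd_status!r}")
        if self.resection not in {"R0", "R1", "R2"}:
            raise ValidationError(f"patient {self.patient_id!r}: bad resection {self.resection!r}")
        for name in ("pfs_months", "os_months", "followup_after_primary_months"):
            if getattr(self, name) < 0:
                raise ValidationError(f"patient {self.patient_id!r}: negative {name}")
        if self.months_to_recurrence is not None and self.months_to_recurrence < 0:
            raise ValidationError(f"patient {self.patient_id!r}: negative months_to_recurrence")
        for name in ("pfs_event", "os_event"):
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"patient {self.patient_id!r}: {name} must be 0 or 1")


@dataclass(frozen=True)
class SurvivalFit:
    """One fitted Cox term: hazard ratio with Wald 95% CI and p-value."""

    term: str
    coef: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    ties_method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValidationError(
                f"term {self.term!r}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket HR {self.hazard_ratio}"
            )


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate: right-continuous step function and median."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    median: Optional[float]

    def at(self, t: float) -> float:
        """S(t): survival just after time t (right-continuous)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


# ---------------------------------------------------------------------------
# Clinical table I/O
# ---------------------------------------------------------------------------

def read_clinical_table(path: Union[str, Path]) -> list[CohortRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table {path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        raw_rec = row["Months_to_recurrence"]
        absent = pd.isna(raw_rec) or str(raw_rec).strip() in {"", "NA", "NaN", "."}
        try:
            records.append(
                CohortRecord(
                    patient_id=str(row["PatientID"]).strip(),
                    hrd_status=str(row["HRD_status"]).strip().lower(),
                    resection=str(row["Resection"]).strip().upper(),
                    pfs_months=float(row["PFS_months"]),
                    pfs_event=int(row["PFS_event"]),
                    os_months=float(row["OS_months"]),
                    os_event=int(row["OS_event"]),
                    months_to_recurrence=None if absent else float(raw_rec),
                    followup_after_primary_months=float(row["Followup_after_primary_months"]),
                )
            )
        except (ValueError, TypeError):
            raise ValidationError(f"clinical table {path}, row {idx + 2}: malformed field") from None
        except ValidationError as exc:
            raise ValidationError(f"clinical table {path}, row {idx + 2}: {exc}") from None
    return records


def write_clinical_table(records: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "PatientID": r.patient_id,
                "HRD_status": r.hrd_status,
                "Resection": r.resection,
                "PFS_months": r.pfs_months,
                "PFS_event": r.pfs_event,
                "OS_months": r.os_months,
                "OS_event": r.os_event,
                "Months_to_recurrence": "" if r.months_to_recurrence is None else r.months_to_recurrence,
                "Followup_after_primary_months": r.followup_after_primary_months,
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Platinum response
# ---------------------------------------------------------------------------

def classify_platinum_response(
    record: CohortRecord, boundary_months: float = PLATINUM_BOUNDARY_MONTHS
) -> str:
    """Sensitive / resistant / not_assessable under the six-month rule.

    Recurrence strictly beyond the boundary is sensitive; recurrence at or
    before it ("within") is resistant.  Without recurrence, follow-up of at
    least the boundary is sensitive, shorter follow-up is not assessable.
    """
    if record.months_to_recurrence is not None:
        return "sensitive" if record.months_to_recurrence > boundary_months else "resistant"
    if record.followup_after_primary_months >= boundary_months:
        return "sensitive"
    return "not_assessable"


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

def _check_surv_inputs(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape or t.size == 0:
        raise ValidationError("times and events must be equal-length non-empty 1-D vectors")
    if np.any(t < 0):
        raise ValidationError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event indicators must be 0 or 1")
    return t, e.astype(int)


def km_curve(times: Sequence[float], events: Sequence[int]) -> KmCurve:
    """Product-limit survival estimate with the standard median convention.

    The median is the smallest observed time with S(t) <= 0.5 and is absent
    (None) when the curve never reaches 0.5.
    """
    t, e = _check_surv_inputs(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = sorted(set(t[e == 1]))
    surv = tuple(float(kmf.predict(ti)) for ti in event_times)
    median = float(kmf.median_survival_time_)
    return KmCurve(
        times=tuple(float(ti) for ti in event_times),
        survival=surv,
        median=None if math.isinf(median) else median,
    )


def logrank_test(
    times: Sequence[float], events: Sequence[int], group: Sequence
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value)."""
    t, e = _check_surv_inputs(times, events)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValidationError("group labels must match times in length")
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    mask = g == labels[0]
    if e.sum() == 0:
        warnings.warn("no events in either group; log-rank p = 1", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(t[mask], t[~mask], event_observed_A=e[mask], event_observed_B=e[~mask])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _partial_lik_derivs(
    X: np.ndarray, t: np.ndarray, e: np.ndarray, beta: np.ndarray, ties_method: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Efron or Breslow handling of tied event times; subjects are grouped by
    distinct event time, with risk sums accumulated from the largest time
    downward.
    """
    n, p = X.shape
    order = np.argsort(-t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    eta = Xs @ beta
    w = np.exp(eta)

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        for k in range(i, j):  # everyone at this time enters the risk set
            s0 += w[k]
            s1 += w[k] * Xs[k]
            s2 += w[k] * np.outer(Xs[k], Xs[k])
        deaths = [k for k in range(i, j) if es[k] == 1]
        d = len(deaths)
        if d > 0:
            xd = Xs[deaths]
            wd = w[deaths]
            loglik += float(eta[deaths].sum())
            grad += xd.sum(axis=0)
            d0 = wd.sum()
            d1 = (wd[:, None] * xd).sum(axis=0)
            d2 = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
            for l in range(d):
                frac = l / d if ties_method == "efron" else 0.0
                r0 = s0 - frac * d0
                r1 = s1 - frac * d1
                r2 = s2 - frac * d2
                loglik -= math.log(r0)
                mu = r1 / r0
                grad -= mu
                hess -= r2 / r0 - np.outer(mu, mu)
        i = j
    return loglik, grad, hess


def _check_separation(beta: np.ndarray, scale: np.ndarray) -> None:
    # a log-hazard shift beyond 15 on the covariate's own scale (HR > e^15)
    # only arises when the partial likelihood has no interior maximum
    if np.any(np.abs(beta * scale) > 15):
        raise ConvergenceError(
            "coefficients diverging: complete separation suspected; "
            "consider a penalized fit (not implemented)"
        )


def _prepare_design(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        labels = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = [f"x{i}" for i in range(X.shape[1])]
    return X, labels


def cox_fit(
    design,
    times: Sequence[float],
    events: Sequence[int],
    ties_method: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[SurvivalFit]:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    ``design`` is an (n, p) array or DataFrame of covariates (no intercept;
    a constant column is a precondition error).  Iterates until the gradient
    norm falls below ``tol``; failure within ``max_iter`` iterations, or a
    diverging coefficient (complete separation), raises
    :class:`ConvergenceError`.
    """
    if ties_method not in {"efron", "breslow"}:
        raise ValidationError(f"unknown ties method {ties_method!r}")
    t, e = _check_surv_inputs(times, events)
    X, labels = _prepare_design(design)
    if X.shape[0] != t.size:
        raise ValidationError("design rows must match times in length")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"covariate {labels[j]!r} is constant across subjects")
    n_events = int(e.sum())
    if n_events < X.shape[1]:
        raise ValidationError(
            f"need at least as many events ({n_events}) as covariates ({X.shape[1]})"
        )

    scale = np.abs(X).max(axis=0)
    beta = np.zeros(X.shape[1])
    for iteration in range(1, max_iter + 1):
        loglik, grad, hess = _partial_lik_derivs(X, t, e, beta, ties_method)
        if float(np.linalg.norm(grad)) < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                f"singular information matrix at iteration {iteration} "
                f"(beta={beta.tolist()}); the design may be collinear"
            ) from None
        # step-halving keeps the partial likelihood non-decreasing
        # (tolerance scaled to |loglik| so float noise cannot stall the ascent)
        slack = 1e-9 * max(1.0, abs(loglik))
        for _ in range(30):
            candidate = beta + step
            new_loglik, _, _ = _partial_lik_derivs(X, t, e, candidate, ties_method)
            if new_loglik >= loglik - slack:
                break
            step = step / 2
        beta = beta + step
        _check_separation(beta, scale)
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(|grad|={float(np.linalg.norm(grad)):.3g}, beta={beta.tolist()})"
        )

    _check_separation(beta, scale)
    _, _, hess = _partial_lik_derivs(X, t, e, beta, ties_method)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z975 = float(sps.norm.ppf(0.975))
    fits = []
    for j, label in enumerate(labels):
        b, s = float(beta[j]), float(se[j])
        z = b / s
        fits.append(
            SurvivalFit(
                term=label,
                coef=b,
                se=s,
                hazard_ratio=math.exp(b),
                ci_low=math.exp(b - z975 * s),
                ci_high=math.exp(b + z975 * s),
                p=float(2 * sps.norm.sf(abs(z))),
                ties_method=ties_method,
            )
        )
    return fits


def cox_score_test(
    design, times: Sequence[float], events: Sequence[int], ties_method: str = "efron"
) -> tuple[float, float]:
    """Score test of beta = 0: U(0)' I(0)^-1 U(0), chi-square with p df.

    With a single binary covariate and no tied event times this statistic
    coincides with the log-rank chi-square.
    """
    t, e = _check_surv_inputs(times, events)
    X, _ = _prepare_design(design)
    _, grad, hess = _partial_lik_derivs(X, t, e, np.zeros(X.shape[1]), ties_method)
    stat = float(grad @ np.linalg.solve(-hess, grad))
    return stat, float(sps.chi2.sf(stat, df=X.shape[1]))
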