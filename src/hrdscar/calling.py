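"""Deleterious-variant filtering, cross-assay calibration, and the HRD call.

A specimen is HRD-positive under a two-condition rule: (1) a deleterious
(pathogenic or likely-pathogenic) BRCA1/2 variant is present, or (2) the
genomic-scar sum reaches a threshold on the test's own scale.  The threshold
is transferred from a reference assay's cutoff (GIS >= 42) by ordinary least
squares of test score on reference score: evaluating the fitted line at the
reference cutoff gives the test-scale threshold (>= 50 in the cohort that
motivated these defaults).

Variant classifications are taken as given (guideline-based labels from
upstream annotation); variants of uncertain significance are never
deleterious.  Non-BRCA DNA-damage-repair genes are tracked for reporting but
never trigger a positive call on their own.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "CLASSIFICATIONS",
    "DELETERIOUS_CLASSES",
    "VariantRecord",
    "GenePanel",
    "CalibrationModel",
    "HrdCall",
    "DeleteriousHits",
    "read_variant_table",
    "filter_deleterious",
    "fit_calibration",
    "call_hrd",
    "DEFAULT_THRESHOLD",
    "DEFAULT_REFERENCE_CUTOFF",
]

CLASSIFICATIONS = frozenset(
    {"pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign"}
)
DELETERIOUS_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})

#: Test-scale positivity threshold and the reference-assay cutoff it mirrors.
DEFAULT_THRESHOLD = 50.0
DEFAULT_REFERENCE_CUTOFF = 42.0


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant with a guideline classification."""

    sample_id: str
    gene: str
    variant: str
    classification: str

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}, gene {self.gene!r}: unknown classification "
                f"{self.classification!r} (expected one of {sorted(CLASSIFICATIONS)})"
            )


def _norm_gene(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GenePanel:
    """BRCA genes and the wider DNA-damage-repair panel (BRCA ⊆ DDR)."""

    brca_genes: frozenset[str] = frozenset({"BRCA1", "BRCA2"})
    ddr_genes: frozenset[str] = frozenset(
        {
            "ATM",
            "BRCA1",
            "BRCA2",
            "BRIP1",
            "CHEK2",
            "FANCG",
            "MLH1",
            "MSH2",
            "MSH6",
            "PALB2",
            "RAD51C",
            "RAD51D",
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "brca_genes", frozenset(map(_norm_gene, self.brca_genes)))
        object.__setattr__(self, "ddr_genes", frozenset(map(_norm_gene, self.ddr_genes)))
        if not self.brca_genes <= self.ddr_genes:
            raise ValidationError(
                f"BRCA genes {sorted(self.brca_genes - self.ddr_genes)} missing from DDR panel"
            )


@dataclass(frozen=True)
class DeleteriousHits:
    """Per-sample deleterious variants: full-panel view plus the BRCA-only flag."""

    hits: Mapping[str, tuple[VariantRecord, ...]]
    brca_flags: Mapping[str, bool]

    def brca_positive(self, sample_id: str) -> bool:
        return self.brca_flags.get(sample_id, False)


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line test = intercept + slope * reference, with the derived threshold."""

    intercept: float
    slope: float
    reference_cutoff: float
    derived_threshold: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("calibration slope is zero")
        if not math.isfinite(self.derived_threshold):
            raise ValidationError("derived threshold is not finite")

    @property
    def calling_threshold(self) -> int:
        """The integer threshold used for calling: raw value rounded up."""
        return math.ceil(self.derived_threshold - 1e-9)


@dataclass(frozen=True)
class HrdCall:
    """One sample's HRD status with the basis of the decision."""

    sample_id: str
    score: int
    threshold: float
    brca_deleterious: bool
    status: str  # positive | negative
    basis: str  # score | brca_variant | both | none

    def __post_init__(self) -> None:
        expected = "positive" if (self.score >= self.threshold or self.brca_deleterious) else "negative"
        if self.status != expected:
            raise ValidationError(
                f"sample {self.sample_id!r}: status {self.status!r} inconsistent with "
                f"score {self.score} vs threshold {self.threshold} and "
                f"brca_deleterious={self.brca_deleterious}"
            )


# ---------------------------------------------------------------------------
# Variant I/O and filtering
# ---------------------------------------------------------------------------

def read_variant_table(path: Union[str, Path]) -> list[VariantRecord]:
    """Read a variant TSV (SampleID, Gene, Variant, Classification)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["SampleID", "Gene", "Variant", "Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table {path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                VariantRecord(
                    sample_id=str(row["SampleID"]).strip(),
                    gene=str(row["Gene"]).strip(),
                    variant=str(row["Variant"]),
                    classification=str(row["Classification"]).strip(),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"variant table {path}, row {idx + 2}: {exc}") from None
    return records


def filter_deleterious(
    variants: Iterable[VariantRecord], panel: GenePanel = GenePanel()
) -> DeleteriousHits:
    """Retain pathogenic/likely-pathogenic variants in the DDR panel.

    VUS and (likely) benign records are never retained.  Per sample, the
    BRCA flag is true when any retained gene is in ``panel.brca_genes``
    (matched case-insensitively after trimming).
    """
    hits: dict[str, list[VariantRecord]] = {}
    flags: dict[str, bool] = {}
    for rec in variants:
        gene = _norm_gene(rec.gene)
        if rec.classification not in DELETERIOUS_CLASSES or gene not in panel.ddr_genes:
            continue
        hits.setdefault(rec.sample_id, []).append(rec)
        flags[rec.sample_id] = flags.get(rec.sample_id, False) or gene in panel.brca_genes
    return DeleteriousHits(
        hits={s: tuple(v) for s, v in hits.items()},
        brca_flags=flags,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def fit_calibration(
    paired_scores: Sequence[tuple[float, float]],
    reference_cutoff: float = DEFAULT_REFERENCE_CUTOFF,
) -> CalibrationModel:
    """Transfer the reference assay's cutoff onto the test scale by OLS.

    ``paired_scores`` are (test_score, reference_score) pairs.  The test
    score is regressed on the reference score and the fitted line evaluated
    at ``reference_cutoff``; the raw value is stored in
    ``derived_threshold`` and ``calling_threshold`` rounds it up to the next
    integer (scores are integer counts and the positivity rule is >=).
    """
    pairs = [(float(t), float(r)) for t, r in paired_scores]
    if len(pairs) < 3:
        raise ValidationError(f"calibration needs >= 3 score pairs, got {len(pairs)}")
    test = [t for t, _ in pairs]
    ref = [r for _, r in pairs]
    if len(set(ref)) == 1:
        raise ValidationError("reference scores are constant: regression design is degenerate")
    if len(set(test)) == 1:
        raise ValidationError("test scores are constant: calibration is uninformative")
    fit = stats.linregress(ref, test)
    derived = fit.intercept + fit.slope * reference_cutoff
    return CalibrationModel(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        reference_cutoff=float(reference_cutoff),
        derived_threshold=float(derived),
        n_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_hrd(
    scores: Mapping[str, int],
    brca_flags: Mapping[str, bool],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[HrdCall]:
    """Apply the two-condition positivity rule to every scored sample.

    ``scores`` maps sample id to the scar sum; ``brca_flags`` maps sample id
    to the deleterious-BRCA indicator (samples absent from ``brca_flags``
    count as variant-free).  Samples flagged in ``brca_flags`` but not
    scored are reported with a warning, never silently dropped.
    """
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    unscored = sorted(set(brca_flags) - set(scores))
    if unscored:
        warnings.warn(
            f"samples with variant records but no scar score (not called): {unscored}",
            stacklevel=2,
        )
    calls = []
    for sample_id in scores:
        score = int(scores[sample_id])
        brca = bool(brca_flags.get(sample_id, False))
        by_score = score >= threshold
        if by_score and brca:
            basis = "both"
        elif by_score:
            basis = "score"
        elif brca:
            basis = "brca_variant"
        else:
            basis = "none"
        calls.append(
            HrdCall(
                sample_id=sample_id,
                score=score,
                threshold=threshold,
                brca_deleterious=brca,
                status="positive" if (by_score or brca) else "negative",
                basis=basis,
            )
        )
    return calls
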