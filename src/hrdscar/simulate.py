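"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the study's data types:

* :func:`simulate_scarred_profile` — an allele-specific copy-number profile
  built from a diploid (1,1) background with planted LOH regions, telomeric
  allelic imbalances and large-scale-transition junctions.  Events are
  placed with wide clearances (unsegmented buffer gaps wider than the LST
  gap limit, and background blocks keeping events > 15 Mb from each other,
  chromosome ends and centromeres) so no planted event interacts with
  another's filter: scar scoring must recover the planted counts exactly.
* :func:`simulate_paired_scores` — paired (test, reference) assay scores on
  a linear model with Gaussian noise, reference scores uniform on [0, 90]
  (the span of observed score ranges on both assays).
* :func:`simulate_cohort` — a two-group exponential survival cohort with a
  chosen hazard ratio for HRD-positive patients, independent exponential
  censoring, and platinum-response fields derived through the six-month rule.

All randomness flows from one ``numpy`` generator seeded per call; equal
seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import GenomeModel, Segment, SegmentProfile
from .survival import CohortRecord, classify_platinum_response

__all__ = [
    "PlantedTruth",
    "simulate_scarred_profile",
    "simulate_paired_scores",
    "simulate_cohort",
    "add_split_noise",
    "add_fragment_noise",
]

MB = 1_000_000

# Placement clearances (bp).  BUFFER_GAP exceeds the 3 Mb LST gap limit so a
# planted block never forms a breakpoint with its background; SPACER_BG plus
# two buffer gaps exceeds the 15 Mb LOH length so events stay independent.
BUFFER_GAP = 4 * MB
SPACER_BG = 12 * MB
LEAD_BG = 16 * MB

DIPLOID = (1, 1)
LOH_STATE = (1, 0)
TAI_STATE = (2, 1)
LST_STATES = ((2, 2), (3, 3))
FRAGMENT_STATE = (4, 4)


@dataclass(frozen=True)
class PlantedTruth:
    """The events a simulated profile contains, with their coordinates."""

    k_loh: int
    k_tai: int
    k_lst: int
    event_coordinates: tuple[tuple[str, str, str, int, int], ...]  # kind, chrom, arm, start, end

    @property
    def hrd_sum(self) -> int:
        return self.k_loh + self.k_tai + self.k_lst


def _segment(chrom: str, start: int, end: int, state: tuple[int, int]) -> Segment:
    major, minor = state
    return Segment(
        chrom=chrom, start=start, end=end,
        total_cn=major + minor, major_cn=major, minor_cn=minor,
    )


# ---------------------------------------------------------------------------
# Planted-scar profiles
# ---------------------------------------------------------------------------

def simulate_scarred_profile(
    genome: GenomeModel,
    k_loh: int = 3,
    k_tai: int = 2,
    k_lst: int = 4,
    seed: int = 0,
    split_noise: int = 0,
    fragment_noise: int = 0,
    sample_id: str = "sim",
) -> tuple[SegmentProfile, PlantedTruth]:
    """Plant ``k_loh``/``k_tai``/``k_lst`` clean scar events on a diploid genome.

    LOH regions are interior (1,0) runs spanning 16-25 Mb; TAI events are
    terminal (2,1) segments of 5-8 Mb confined to one arm; LST events are
    abutting (2,2)|(3,3) junctions with both sides 12-14 Mb.  ``split_noise``
    state-preserving random splits per chromosome and ``fragment_noise``
    sub-3 Mb interstitial (4,4) fragments may be layered on top; neither
    changes any scar score.  Raises :class:`ValidationError` when the
    requested events cannot be packed with the required clearances.
    """
    if min(k_loh, k_tai, k_lst) < 0:
        raise ValidationError("planted event counts must be >= 0")
    rng = np.random.default_rng(seed)

    arms: list[dict] = []
    for info in genome.chromosomes:
        arms.append(
            {"chrom": info.name, "arm": "p", "len": info.centromere_start,
             "tai": None, "interior": [], "used": LEAD_BG}
        )
        arms.append(
            {"chrom": info.name, "arm": "q", "len": info.length - info.centromere_end + 1,
             "tai": None, "interior": [], "used": LEAD_BG}
        )

    def _place_tai(span: int) -> None:
        # a TAI block replaces the leading background at the telomere
        delta = span + BUFFER_GAP + SPACER_BG - LEAD_BG
        candidates = [
            a for a in arms
            if a["tai"] is None and a["used"] + delta + BUFFER_GAP <= a["len"]
        ]
        if not candidates:
            raise ValidationError("infeasible packing: no free arm telomere for a TAI event")
        a = candidates[rng.integers(len(candidates))]
        a["tai"] = span
        a["used"] += delta

    def _place_interior(block: tuple) -> None:
        _, pieces = block
        span = sum(s for _, s in pieces)
        need = BUFFER_GAP + span + BUFFER_GAP + SPACER_BG
        candidates = [a for a in arms if a["used"] + need + BUFFER_GAP <= a["len"]]
        if not candidates:
            raise ValidationError("infeasible packing: no arm can hold another interior event")
        a = candidates[rng.integers(len(candidates))]
        a["interior"].append(block)
        a["used"] += need

    for _ in range(k_tai):
        _place_tai(int(rng.uniform(5 * MB, 8 * MB)))
    interior_events = [("LOH", [(LOH_STATE, int(rng.uniform(16 * MB, 25 * MB)))]) for _ in range(k_loh)]
    interior_events += [
        ("LST", [(LST_STATES[0], int(rng.uniform(12 * MB, 14 * MB))),
                 (LST_STATES[1], int(rng.uniform(12 * MB, 14 * MB)))])
        for _ in range(k_lst)
    ]
    order = rng.permutation(len(interior_events))
    for idx in order:
        _place_interior(interior_events[idx])

    segments: list[Segment] = []
    events: list[tuple[str, str, str, int, int]] = []
    for a in arms:
        chrom, arm, arm_len = a["chrom"], a["arm"], a["len"]
        info = genome[chrom]

        def to_coords(off: int, length: int) -> tuple[int, int]:
            # offsets measured from the telomere inward
            if arm == "p":
                return 1 + off, off + length
            return info.length - off - length + 1, info.length - off

        blocks: list[tuple] = []  # ("seg", state, length, tag) | ("gap", length) | ("bg", length)
        if a["tai"] is not None:
            blocks += [("seg", TAI_STATE, a["tai"], "TAI"), ("gap", BUFFER_GAP), ("bg", SPACER_BG)]
        elif a["interior"]:
            blocks += [("bg", LEAD_BG)]
        else:
            # event-free arm: one diploid segment covering it entirely
            segments.append(_segment(chrom, *to_coords(0, arm_len), DIPLOID))
            continue
        for kind, pieces in a["interior"]:
            blocks.append(("gap", BUFFER_GAP))
            for piece_idx, (state, length) in enumerate(pieces):
                blocks.append(("seg", state, length, f"{kind}:{piece_idx}"))
            blocks += [("gap", BUFFER_GAP), ("bg", SPACER_BG)]
        used = sum(b[2] if b[0] == "seg" else b[1] for b in blocks)
        if used > arm_len:
            raise ValidationError("infeasible packing: arm overflow")  # pragma: no cover
        # stretch the innermost background to the centromere boundary
        blocks[-1] = ("bg", blocks[-1][1] + (arm_len - used))

        off = 0
        arm_segs: list[tuple[Segment, Optional[str]]] = []
        for b in blocks:
            if b[0] == "gap":
                off += b[1]
                continue
            if b[0] == "bg":
                start, end = to_coords(off, b[1])
                arm_segs.append((_segment(chrom, start, end, DIPLOID), None))
                off += b[1]
            else:
                _, state, length, tag = b
                start, end = to_coords(off, length)
                arm_segs.append((_segment(chrom, start, end, state), tag))
                off += length

        for seg, tag in arm_segs:
            segments.append(seg)
            if tag == "TAI":
                events.append(("TAI", chrom, arm, seg.start, seg.end))
            elif tag == "LOH:0":
                events.append(("LOH", chrom, arm, seg.start, seg.end))
        # LST junction coordinates: recovered from planted-pair adjacency
        ordered = sorted((seg for seg, _ in arm_segs), key=lambda s: s.start)
        tags = {id(seg): tag for seg, tag in arm_segs}
        for s1, s2 in zip(ordered, ordered[1:]):
            t1, t2 = tags[id(s1)], tags[id(s2)]
            if {t1, t2} == {"LST:0", "LST:1"} and s2.start == s1.end + 1:
                events.append(("LST", chrom, arm, s1.end, s2.start))

    segments.sort(key=lambda s: (genome.chrom_order(s.chrom), s.start))
    profile = SegmentProfile(sample_id=sample_id, ploidy=2.0, segments=tuple(segments))
    profile.validate(genome)

    if split_noise:
        profile = add_split_noise(profile, rng, per_chrom=split_noise)
    if fragment_noise:
        profile = add_fragment_noise(profile, rng, count=fragment_noise)
    profile.validate(genome)

    truth = PlantedTruth(
        k_loh=k_loh, k_tai=k_tai, k_lst=k_lst, event_coordinates=tuple(events)
    )
    return profile, truth


def add_split_noise(
    profile: SegmentProfile, rng: np.random.Generator, per_chrom: int = 1
) -> SegmentProfile:
    """Split random segments at random points, preserving every state.

    Normalization re-merges the pieces, so all scar scores are unchanged.
    """
    segs = list(profile.segments)
    for chrom in profile.chroms:
        for _ in range(per_chrom):
            idx = [i for i, s in enumerate(segs) if s.chrom == chrom and s.span >= 2]
            if not idx:
                continue
            i = idx[rng.integers(len(idx))]
            s = segs[i]
            cut = int(rng.integers(s.start, s.end))  # cut in [start, end-1]
            segs[i : i + 1] = [replace(s, end=cut), replace(s, start=cut + 1)]
    return replace(profile, segments=tuple(segs))


def add_fragment_noise(
    profile: SegmentProfile, rng: np.random.Generator, count: int = 1
) -> SegmentProfile:
    """Insert sub-3 Mb (4,4) fragments at eligible zero-gap junctions.

    Eligible junctions have both flanks >= 12 Mb with a retained minor
    allele, so fragment insertion never shortens an LST flank below 10 Mb
    and never interrupts an LOH run; LST smoothing removes the fragment and
    either re-joins same-state flanks or leaves a sub-3 Mb gap, so scar
    scores are unchanged.
    """
    segs = list(profile.segments)
    for _ in range(count):
        junctions = [
            i
            for i, (a, b) in enumerate(zip(segs, segs[1:]))
            if a.chrom == b.chrom
            and b.start == a.end + 1
            and a.span >= 12 * MB
            and b.span >= 12 * MB
            and a.minor_cn > 0
            and b.minor_cn > 0
            and a.state != FRAGMENT_STATE
            and b.state != FRAGMENT_STATE
        ]
        if not junctions:
            break
        i = junctions[rng.integers(len(junctions))]
        a, b = segs[i], segs[i + 1]
        f1 = int(rng.integers(200_000, 1_200_000))
        f2 = int(rng.integers(200_000, 1_200_000))
        fragment = _segment(a.chrom, a.end - f1 + 1, b.start + f2 - 1, FRAGMENT_STATE)
        segs[i : i + 2] = [replace(a, end=a.end - f1), fragment, replace(b, start=b.start + f2)]
    return replace(profile, segments=tuple(segs))


# ---------------------------------------------------------------------------
# Paired assay scores
# ---------------------------------------------------------------------------

def simulate_paired_scores(
    n: int = 40,
    alpha: float = 8.0,
    beta: float = 1.0,
    sigma: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired scores: reference ~ U[0, 90]; test = alpha + beta*ref + N(0, sigma).

    Both scores are rounded to integers (assay scores are integer counts)
    and floored at 0.  Returns a DataFrame with columns SampleID, TestScore,
    ReferenceScore.
    """
    if n < 3:
        raise ValidationError(f"need n >= 3 score pairs, got {n}")
    if beta == 0:
        raise ValidationError("beta must be nonzero")
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    reference = np.round(rng.uniform(0, 90, size=n)).astype(int)
    test = alpha + beta * reference + rng.normal(0.0, sigma, size=n)
    test = np.maximum(np.round(test).astype(int), 0)
    return pd.DataFrame(
        {
            "SampleID": [f"S{i + 1:03d}" for i in range(n)],
            "TestScore": test,
            "ReferenceScore": reference,
        }
    )


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n: int = 40,
    prevalence_hrd: float = 0.775,
    hr: float = 0.33,
    baseline_hazard: float = 0.15,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> list[CohortRecord]:
    """Two-group exponential cohort with proportional hazards.

    HRD status is Bernoulli(``prevalence_hrd``); progression times are
    exponential with hazard ``baseline_hazard`` (HRD-negative) or
    ``baseline_hazard * hr`` (HRD-positive).  Independent exponential
    censoring is tuned so the marginal censoring fraction is approximately
    ``censor_rate`` (exactly none when 0).  Death times add an exponential
    post-progression stage.  Platinum-response inputs (recurrence time,
    follow-up) come directly from the simulated histories.
    """
    if not 0 <= prevalence_hrd <= 1:
        raise ValidationError("prevalence_hrd must be in [0, 1]")
    if not 0 <= censor_rate < 1:
        raise ValidationError("censor_rate must be in [0, 1)")
    if hr <= 0 or baseline_hazard <= 0:
        raise ValidationError("hr and baseline_hazard must be > 0")
    rng = np.random.default_rng(seed)

    hrd = rng.random(n) < prevalence_hrd
    hazard = np.where(hrd, baseline_hazard * hr, baseline_hazard)
    t_prog = rng.exponential(1.0 / hazard)
    mean_hazard = baseline_hazard * (1 - prevalence_hrd + prevalence_hrd * hr)
    if censor_rate > 0:
        c_hazard = mean_hazard * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / c_hazard, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_death = t_prog + rng.exponential(1.0 / (baseline_hazard / 2), size=n)

    records = []
    for i in range(n):
        event = t_prog[i] <= t_cens[i]
        pfs = float(min(t_prog[i], t_cens[i]))
        death = t_death[i] <= t_cens[i]
        os_m = float(min(t_death[i], t_cens[i]))
        resection = "R0" if rng.random() < 0.325 else "R1"
        records.append(
            CohortRecord(
                patient_id=f"P{i + 1:04d}",
                hrd_status="positive" if hrd[i] else "negative",
                resection=resection,
                pfs_months=pfs,
                pfs_event=int(event),
                os_months=os_m,
                os_event=int(death),
                months_to_recurrence=float(t_prog[i]) if event else None,
                followup_after_primary_months=pfs,
            )
        )
    return records
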