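"""Independent brute-force oracles used to cross-check the scar engine and stats.

Everything here is written from the definitions, not from the package's
algorithms: maximal runs are listed explicitly and filtered one condition at
a time; the LST smoother enumerates every deletion order to its fixed
point(s); the Fisher p sums hypergeometric terms from math.comb.
"""

from __future__ import annotations

from dataclasses import replace
from math import comb

import numpy as np

from hrdscar.genome import GenomeModel, Segment, SegmentProfile


def _runs(segs, pred):
    """All maximal runs (as lists of segments) of consecutive pred-true segments."""
    runs, cur = [], []
    for s in segs:
        if pred(s):
            cur.append(s)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def oracle_loh(profile: SegmentProfile, genome: GenomeModel, params) -> int:
    count = 0
    for chrom in {s.chrom for s in profile.segments}:
        segs = sorted((s for s in profile.segments if s.chrom == chrom), key=lambda s: s.start)
        for run in _runs(segs, lambda s: s.minor_cn == 0 and s.total_cn >= 1):
            span = run[-1].end - run[0].start + 1
            if span <= params.loh_min_len:
                continue
            covers_all = run[0].start == segs[0].start and run[-1].end == segs[-1].end
            if params.exclude_whole_chromosome_loh and covers_all:
                continue
            count += 1
    return count


def oracle_tai(profile: SegmentProfile, genome: GenomeModel, params) -> int:
    count = 0
    for chrom in {s.chrom for s in profile.segments}:
        info = genome[chrom]
        segs = sorted((s for s in profile.segments if s.chrom == chrom), key=lambda s: s.start)
        outermost_p = segs[0].start if segs[0].start <= info.centromere_start else None
        outermost_q = segs[-1].end if segs[-1].end >= info.centromere_end else None
        for run in _runs(segs, lambda s: s.major_cn != s.minor_cn):
            start, end = run[0].start, run[-1].end
            if start <= info.centromere_start and end >= info.centromere_end:
                continue  # crosses the centromere
            if end - start + 1 <= params.tai_min_len:
                continue
            if start == segs[0].start and end == segs[-1].end:
                continue  # covers the whole segmented extent
            reaches_p = outermost_p is not None and start == outermost_p
            reaches_q = outermost_q is not None and end == outermost_q
            if reaches_p or reaches_q:
                count += 1
    return count


def _arm_split(segs, info):
    """Independent arm partition: clip to [1, cen_start] and [cen_end, length]."""
    p, q = [], []
    for s in segs:
        if s.start <= info.centromere_start:
            p.append(replace(s, end=min(s.end, info.centromere_start)))
        if s.end >= info.centromere_end:
            q.append(replace(s, start=max(s.start, info.centromere_end)))
    return p, q


def smooth_fixed_points(segs, min_span, _memo=None):
    """Every fixed point reachable by deleting sub-min_span segments in any order."""
    if _memo is None:
        _memo = {}
    key = tuple(segs)
    if key in _memo:
        return _memo[key]
    small = [i for i, s in enumerate(segs) if s.span < min_span]
    if not small:
        result = {key}
    else:
        result = set()
        for i in small:
            nxt = list(segs[:i]) + list(segs[i + 1 :])
            if 0 < i < len(nxt) and nxt[i - 1].state == nxt[i].state:
                nxt[i - 1 : i + 1] = [replace(nxt[i - 1], end=nxt[i].end)]
            result |= smooth_fixed_points(tuple(nxt), min_span, _memo)
    _memo[key] = result
    return result


def oracle_lst(profile: SegmentProfile, genome: GenomeModel, params) -> set[int]:
    """Set of LST counts over every reachable smoothing fixed point.

    A singleton set certifies confluence of the smoothing for this input.
    """

    def breakpoints(segs):
        n = 0
        for a, b in zip(segs, segs[1:]):
            if (
                a.state != b.state
                and a.span >= params.lst_min_seg
                and b.span >= params.lst_min_seg
                and b.start - a.end - 1 <= params.lst_max_gap_and_smooth
            ):
                n += 1
        return n

    units = []
    for chrom in {s.chrom for s in profile.segments}:
        segs = sorted((s for s in profile.segments if s.chrom == chrom), key=lambda s: s.start)
        if params.lst_per_arm:
            units.extend(_arm_split(segs, genome[chrom]))
        else:
            units.append(segs)
    per_unit = []
    for unit in units:
        fps = smooth_fixed_points(tuple(unit), params.lst_max_gap_and_smooth)
        per_unit.append({breakpoints(list(fp)) for fp in fps})
    totals = {0}
    for counts in per_unit:
        totals = {t + c for t in totals for c in counts}
    return totals


# ---------------------------------------------------------------------------
# Random profiles for engine-vs-oracle equivalence
# ---------------------------------------------------------------------------

def random_profile(genome: GenomeModel, rng: np.random.Generator, max_segs: int = 12) -> SegmentProfile:
    """A random (possibly unnormalized) profile with <= max_segs segments/chromosome."""
    segments = []
    for info in genome.chromosomes:
        n = int(rng.integers(0, max_segs + 1))
        if n == 0:
            continue
        cuts = np.sort(rng.choice(np.arange(1, info.length, 500_000), size=2 * n, replace=False))
        for k in range(n):
            start, end = int(cuts[2 * k]), int(cuts[2 * k + 1] - 1)
            if end < start:
                continue
            major = int(rng.integers(0, 4))
            minor = int(rng.integers(0, major + 1))
            segments.append(
                Segment(chrom=info.name, start=start, end=end,
                        total_cn=major + minor, major_cn=major, minor_cn=minor)
            )
    return SegmentProfile(sample_id="rand", ploidy=2.0, segments=tuple(segments))


# ---------------------------------------------------------------------------
# Fisher exact by full enumeration
# ---------------------------------------------------------------------------

def oracle_fisher_two_sided(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7):
    """(p, total_probability): minimum-likelihood two-sided p and the sanity sum."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1))
    p = sum(px for x in range(lo, hi + 1) if (px := prob(x)) <= p_obs * (1 + rel_tol))
    return min(p, 1.0), total
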