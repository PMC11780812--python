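"""Genome metadata and allele-specific copy-number segment tables.

The segment-table dialect is the one consumed downstream of allele-specific
segmentation (one row per segment, tab-separated, header exactly)::

    SampleID  Chromosome  Start_position  End_position  total_cn  A_cn  B_cn  ploidy

Coordinates are 1-based and inclusive at both ends, the common convention of
seg-table dialects.  On read, the two allele columns are reoriented so that
``major_cn >= minor_cn``: the scar statistics depend only on the unordered
allele pair, so orientation carries no information.

Genome models carry per-chromosome lengths and centromere intervals; the
centromere is what defines chromosome arms for the telomeric-imbalance and
large-scale-transition logic.  Two models ship with the package:
``"GRCh38-autosomes"`` (the 22 autosomes; the default) and ``"toy"`` (three
100 Mb chromosomes with centromeres at 45-55 Mb, for tests and examples).
``"GRCh38-autosomes+X"`` adds chromosome X for cohorts where it is wanted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .errors import ValidationError

__all__ = [
    "ChromosomeInfo",
    "GenomeModel",
    "Segment",
    "SegmentProfile",
    "load_genome",
    "read_segment_table",
    "write_segment_table",
    "normalize_profile",
    "BUILTIN_GENOMES",
]

SEGMENT_COLUMNS = [
    "SampleID",
    "Chromosome",
    "Start_position",
    "End_position",
    "total_cn",
    "A_cn",
    "B_cn",
    "ploidy",
]

GENOME_COLUMNS = ["chrom", "length", "centromere_start", "centromere_end"]

BUILTIN_GENOMES = ("GRCh38-autosomes", "GRCh38-autosomes+X", "toy")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeInfo:
    """One chromosome: total length and centromere interval (bp, 1-based)."""

    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValidationError(
                f"chromosome {self.name!r}: need "
                f"0 < centromere_start ({self.centromere_start}) < "
                f"centromere_end ({self.centromere_end}) < length ({self.length})"
            )


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes with centromere annotations."""

    name: str
    chromosomes: tuple[ChromosomeInfo, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"genome {self.name!r}: duplicate chromosome names {dup}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def __getitem__(self, chrom: str) -> ChromosomeInfo:
        for c in self.chromosomes:
            if c.name == chrom:
                return c
        raise KeyError(chrom)

    def chrom_order(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)

    def harmonize_chrom(self, raw: str) -> str:
        """Map ``"1"``/``"chr1"`` style names onto this genome's convention.

        Raises :class:`ValidationError` for names unknown under either style.
        """
        raw = raw.strip()
        for candidate in (raw, f"chr{raw}", raw.removeprefix("chr")):
            if candidate in self:
                return candidate
        raise ValidationError(
            f"chromosome {raw!r} not present in genome {self.name!r}"
        )


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment (1-based inclusive coords)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"need major_cn >= minor_cn >= 0, got ({self.major_cn}, {self.minor_cn})"
            )
        if self.total_cn != self.major_cn + self.minor_cn:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"total_cn ({self.total_cn}) != major_cn + minor_cn "
                f"({self.major_cn} + {self.minor_cn})"
            )

    @property
    def span(self) -> int:
        """Length in bp (inclusive coordinates)."""
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        """The (major, minor) allele state that scar logic compares."""
        return (self.major_cn, self.minor_cn)

    @property
    def is_ai(self) -> bool:
        """Allelic imbalance: unequal parental contributions."""
        return self.major_cn != self.minor_cn

    @property
    def is_loh(self) -> bool:
        """Loss of heterozygosity with retained material."""
        return self.minor_cn == 0 and self.total_cn >= 1


@dataclass(frozen=True)
class SegmentProfile:
    """One sample's ordered, non-overlapping segments plus ploidy metadata."""

    sample_id: str
    ploidy: float
    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def validate(self, genome: GenomeModel) -> "SegmentProfile":
        """Check ordering, non-overlap and genome consistency; return self."""
        prev: Segment | None = None
        for seg in self.segments:
            if seg.chrom not in genome:
                raise ValidationError(
                    f"sample {self.sample_id!r}: chromosome {seg.chrom!r} "
                    f"not in genome {genome.name!r}"
                )
            if seg.end > genome[seg.chrom].length:
                raise ValidationError(
                    f"sample {self.sample_id!r}: segment {seg.chrom}:{seg.start}-{seg.end} "
                    f"extends beyond chromosome length {genome[seg.chrom].length}"
                )
            if prev is not None:
                key_prev = (genome.chrom_order(prev.chrom), prev.start)
                key_cur = (genome.chrom_order(seg.chrom), seg.start)
                if key_cur < key_prev:
                    raise ValidationError(
                        f"sample {self.sample_id!r}: segments not sorted at "
                        f"{seg.chrom}:{seg.start}"
                    )
                if prev.chrom == seg.chrom and seg.start <= prev.end:
                    raise ValidationError(
                        f"sample {self.sample_id!r}: overlapping segments on {seg.chrom}: "
                        f"{prev.start}-{prev.end} and {seg.start}-{seg.end}"
                    )
            prev = seg
        return self

    def chrom_segments(self, chrom: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.chrom == chrom)

    @property
    def chroms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.chrom)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Genome loading
# ---------------------------------------------------------------------------

def _toy_genome() -> GenomeModel:
    mb = 1_000_000
    return GenomeModel(
        name="toy",
        chromosomes=tuple(
            ChromosomeInfo(f"chr{i}", 100 * mb, 45 * mb, 55 * mb) for i in (1, 2, 3)
        ),
    )


def _read_genome_table(text_source, name: str) -> GenomeModel:
    df = pd.read_csv(text_source, sep="\t", dtype=str)
    missing = [c for c in GENOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"genome table {name!r}: missing columns {missing}")
    chroms = []
    for idx, row in df.iterrows():
        try:
            chroms.append(
                ChromosomeInfo(
                    name=str(row["chrom"]).strip(),
                    length=int(row["length"]),
                    centromere_start=int(row["centromere_start"]),
                    centromere_end=int(row["centromere_end"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"genome table {name!r}, row {idx + 2}: non-integer coordinate ({exc})"
            ) from None
    return GenomeModel(name=name, chromosomes=tuple(chroms))


def load_genome(source: Union[str, Path] = "GRCh38-autosomes") -> GenomeModel:
    """Load a built-in genome model or a 4-column metadata TSV.

    Parameters
    ----------
    source
        ``"GRCh38-autosomes"`` (default), ``"GRCh38-autosomes+X"``, ``"toy"``,
        or a path to a TSV with columns ``chrom, length, centromere_start,
        centromere_end``.
    """
    if isinstance(source, str) and source in BUILTIN_GENOMES:
        if source == "toy":
            return _toy_genome()
        fname = {
            "GRCh38-autosomes": "grch38_autosomes.tsv",
            "GRCh38-autosomes+X": "grch38_autosomes_x.tsv",
        }[source]
        ref = importlib.resources.files("hrdscar.data").joinpath(fname)
        with ref.open("r") as fh:
            return _read_genome_table(fh, source)
    path = Path(source)
    if not path.exists():
        raise ValidationError(
            f"unknown genome {str(source)!r}: not a built-in "
            f"({', '.join(BUILTIN_GENOMES)}) and no such file"
        )
    return _read_genome_table(path, path.stem)


# ---------------------------------------------------------------------------
# Segment table I/O
# ---------------------------------------------------------------------------

def read_segment_table(path: Union[str, Path], genome: GenomeModel) -> list[SegmentProfile]:
    """Read a segment TSV into one validated :class:`SegmentProfile` per sample.

    Rows are sorted by (chromosome, start) in the genome's chromosome order;
    allele columns are reoriented so major >= minor; chromosome names are
    harmonized onto the genome's convention ("1" and "chr1" both accepted).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"segment table {path}: missing columns {missing}")

    rows: list[tuple[str, Segment, float, int]] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based file line, header on line 1
        sample = str(row["SampleID"]).strip()
        chrom = genome.harmonize_chrom(str(row["Chromosome"]))
        try:
            start = int(row["Start_position"])
            end = int(row["End_position"])
            total = int(row["total_cn"])
            a_cn = int(row["A_cn"])
            b_cn = int(row["B_cn"])
        except (ValueError, TypeError):
            raise ValidationError(
                f"segment table {path}, row {line} (sample {sample!r}): "
                f"non-integer coordinate or copy number"
            ) from None
        try:
            ploidy = float(row["ploidy"])
        except (ValueError, TypeError):
            raise ValidationError(
                f"segment table {path}, row {line} (sample {sample!r}): "
                f"non-numeric ploidy {row['ploidy']!r}"
            ) from None
        try:
            seg = Segment(
                chrom=chrom,
                start=start,
                end=end,
                total_cn=total,
                major_cn=max(a_cn, b_cn),
                minor_cn=min(a_cn, b_cn),
            )
        except ValidationError as exc:
            raise ValidationError(f"segment table {path}, row {line}: {exc}") from None
        rows.append((sample, seg, ploidy, line))

    profiles: list[SegmentProfile] = []
    for sample in dict.fromkeys(s for s, *_ in rows):  # preserve file order
        sample_rows = [(seg, ploidy, line) for s, seg, ploidy, line in rows if s == sample]
        ploidies = {p for _, p, _ in sample_rows}
        if len(ploidies) > 1:
            raise ValidationError(
                f"segment table {path}, sample {sample!r}: inconsistent ploidy values "
                f"{sorted(ploidies)}"
            )
        sample_rows.sort(key=lambda t: (genome.chrom_order(t[0].chrom), t[0].start))
        for (a, _, la), (b, _, lb) in zip(sample_rows, sample_rows[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValidationError(
                    f"segment table {path}, sample {sample!r}: overlapping segments "
                    f"on {a.chrom} (rows {la} and {lb}: "
                    f"{a.start}-{a.end} overlaps {b.start}-{b.end})"
                )
        profile = SegmentProfile(
            sample_id=sample,
            ploidy=sample_rows[0][1],
            segments=tuple(seg for seg, _, _ in sample_rows),
        )
        profiles.append(profile.validate(genome))
    return profiles


def write_segment_table(profiles: Iterable[SegmentProfile], path: Union[str, Path]) -> None:
    """Write profiles in the exact input dialect (round-trips with the reader)."""
    records = []
    for p in profiles:
        for seg in p.segments:
            records.append(
                {
                    "SampleID": p.sample_id,
                    "Chromosome": seg.chrom,
                    "Start_position": seg.start,
                    "End_position": seg.end,
                    "total_cn": seg.total_cn,
                    "A_cn": seg.major_cn,
                    "B_cn": seg.minor_cn,
                    "ploidy": p.ploidy,
                }
            )
    df = pd.DataFrame.from_records(records, columns=SEGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_profile(profile: SegmentProfile, gap_tolerance: int = 0) -> SegmentProfile:
    """Merge same-state neighbours separated by at most ``gap_tolerance`` bp.

    Adjacent segments on the same chromosome with identical (major, minor)
    state whose inter-segment gap is <= ``gap_tolerance`` become one segment
    spanning from the first start to the last end.  With the default
    ``gap_tolerance=0`` only abutting segments merge.  Idempotent.
    """
    merged: list[Segment] = []
    for seg in profile.segments:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chrom == seg.chrom
            and prev.state == seg.state
            and seg.start - prev.end - 1 <= gap_tolerance
        ):
            merged[-1] = replace(prev, end=max(prev.end, seg.end))
        else:
            merged.append(seg)
    return replace(profile, segments=tuple(merged))
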