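"""Genomic-interval data model and region selection.

All coordinates are 0-based, half-open (BED convention). The module houses
the shared interval type, BED/TSV input and output, the selection of
variable regulatory regions from per-tumor histone-mark peak sets, and the
tiling of regions into overlapping activity windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "PeakCollection",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "merge_intervals",
    "select_variable_regions",
    "tile_windows",
    "overlaps",
]

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 2500
BODY_EXCLUSION = 5000
DOMAIN_HALFWIDTH = 1_000_000


class BedParseError(ValueError):
    """Raised for malformed BED input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Invariants: ``0 <= start < end`` (zero-length intervals are forbidden).
    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def distance_to(self, pos: int) -> int:
        """Distance from a point to this interval; 0 when the point is inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene anchor with derived regulatory windows.

    The promoter spans 1500 bp upstream to 2500 bp downstream of the TSS in
    transcription orientation (4000 bp). ``body_excl5k`` is the gene body
    with the first 5 kb downstream of the TSS removed (``None`` for short
    genes). ``domain`` is the +/-1 Mb analysis window around the TSS within
    which methylation-expression associations are sought.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.body_end <= self.body_start:
            raise ValueError(f"{self.gene_id}: empty gene body")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS")

    @property
    def promoter(self) -> GenomicInterval:
        if self.strand == "+":
            start = self.tss - PROMOTER_UPSTREAM
            end = self.tss + PROMOTER_DOWNSTREAM
        else:
            start = self.tss - PROMOTER_DOWNSTREAM
            end = self.tss + PROMOTER_UPSTREAM
        return GenomicInterval(self.chrom, max(0, start), end, self.strand)

    @property
    def body_excl5k(self) -> GenomicInterval | None:
        if self.strand == "+":
            start = max(self.body_start, self.tss + BODY_EXCLUSION)
            end = self.body_end
        else:
            start = self.body_start
            end = min(self.body_end, self.tss - BODY_EXCLUSION)
        if end <= start:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand)

    def domain(
        self, halfwidth: int = DOMAIN_HALFWIDTH, chrom_size: int | None = None
    ) -> GenomicInterval:
        start = max(0, self.tss - halfwidth)
        end = self.tss + halfwidth
        if chrom_size is not None:
            end = min(end, chrom_size)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def contains_in_domain(self, chrom: str, pos: int, halfwidth: int = DOMAIN_HALFWIDTH) -> bool:
        return chrom == self.chrom and abs(pos - self.tss) <= halfwidth


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, overlapping/abutting runs merged per chromosome."""
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class PeakCollection:
    """Per-sample peak interval sets for one histone mark.

    Intervals within a sample are merged on construction so each base is
    covered at most once per sample.
    """

    mark: str
    samples: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = {s: merge_intervals(ivs) for s, ivs in self.samples.items()}

    @classmethod
    def from_bed_files(cls, mark: str, paths: dict[str, str | Path]) -> "PeakCollection":
        return cls(mark, {sample: read_bed(p) for sample, p in paths.items()})

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.samples)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into validated, sorted intervals.

    Malformed lines raise :class:`BedParseError` naming the line number.
    Header-ish lines (``track``, ``browser``, ``#``) and blank lines are
    skipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (BED6 when any interval is stranded)."""
    stranded = any(iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if stranded:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a TSV gene annotation table.

    Required header columns: gene_id, chrom, strand, tss, body_start, body_end.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "strand", "tss", "body_start", "body_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gene-table columns {missing}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tss=int(r.tss),
            body_start=int(r.body_start),
            body_end=int(r.body_end),
        )
        for r in df.itertuples(index=False)
    ]


def select_variable_regions(
    h3k4me1: PeakCollection,
    h3k27ac: PeakCollection,
    min_frac: float = 0.25,
) -> list[GenomicInterval]:
    """Select variable regulatory regions across a tumor cohort.

    A base belongs to a variable region when (a) H3K4me1 covers it in every
    sample and (b) the fraction of samples carrying H3K27ac over it lies in
    ``[min_frac, 1 - min_frac]`` -- chromatin that is consistently poised
    but variably active. Selection is computed at base-pair resolution by
    coverage counting and the passing bases are merged into maximal
    intervals.
    """
    if not 0 < min_frac <= 0.5:
        raise ValueError("min_frac must be in (0, 0.5]")
    if set(h3k4me1.samples) != set(h3k27ac.samples):
        raise ValueError("H3K4me1 and H3K27ac collections must share the sample universe")
    n = len(h3k4me1.samples)
    if n == 0:
        return []
    if n == 1:
        warnings.warn(
            "variable-region selection with a single sample is necessarily empty "
            "(H3K27ac fraction is 0 or 1)",
            stacklevel=2,
        )
        return []

    chroms = {iv.chrom for ivs in h3k4me1.samples.values() for iv in ivs}
    eps = 1e-9
    selected: list[GenomicInterval] = []
    for chrom in sorted(chroms):
        events: dict[int, list[int]] = {}  # pos -> [d_k4, d_k27]
        for coll, idx in ((h3k4me1, 0), (h3k27ac, 1)):
            for ivs in coll.samples.values():
                for iv in ivs:
                    if iv.chrom != chrom:
                        continue
                    events.setdefault(iv.start, [0, 0])[idx] += 1
                    events.setdefault(iv.end, [0, 0])[idx] -= 1
        positions = sorted(events)
        k4 = k27 = 0
        run_start: int | None = None
        for i, pos in enumerate(positions):
            k4 += events[pos][0]
            k27 += events[pos][1]
            seg_end = positions[i + 1] if i + 1 < len(positions) else None
            frac = k27 / n
            passing = (
                seg_end is not None
                and k4 == n
                and frac >= min_frac - eps
                and frac <= 1 - min_frac + eps
            )
            if passing and run_start is None:
                run_start = pos
            elif not passing and run_start is not None:
                selected.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
        if run_start is not None:  # pragma: no cover - coverage ends at last event
            selected.append(GenomicInterval(chrom, run_start, positions[-1]))
    return selected


def tile_windows(
    regions: Sequence[GenomicInterval], size: int = 500, step: int = 250
) -> list[GenomicInterval]:
    """Tile each region with overlapping windows (default 500 bp, 50% overlap).

    Windows start at the region start and advance by ``step``; the final
    window is clipped to the region end. A region shorter than ``size``
    yields a single clipped window.
    """
    if size <= 0 or step <= 0 or step > size:
        raise ValueError("require size > 0 and 0 < step <= size")
    windows: list[GenomicInterval] = []
    for region in sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.end)):
        s = region.start
        while True:
            if s + size >= region.end:
                windows.append(GenomicInterval(region.chrom, s, region.end))
                break
            windows.append(GenomicInterval(region.chrom, s, s + size))
            s += step
    return windows
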