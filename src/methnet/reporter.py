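"""Transcriptional activity scoring of bidirectional reporter libraries.

Candidate regulatory DNA segments drive self-transcription in a reporter
vector; activity is read out as the ratio of RNA to DNA reads. The
transcriptional activity score of an element j is

    TAS_j = log2( (RNA_j / DNA_j) / (RNA_total / DNA_total) )

so positive scores mark enhancers and negative scores silencers relative to
the library-wide baseline. Scores are aggregated in 500-bp half-overlapping
windows, tested by a 2x2 Pearson chi-square against the library totals, and
corrected by Benjamini-Hochberg. Comparing matched unmethylated/methylated
runs classifies elements into methylation-response groups:

    I   enhancer weakened (or switched to silencer) by methylation
    II  enhancer strengthened by methylation
    III silencer strengthened by methylation
    IV  silencer weakened (or switched to enhancer) by methylation
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

__all__ = [
    "SegmentCount",
    "compute_tas",
    "chi_square_window",
    "bh_adjust",
    "score_windows",
    "call_elements",
    "classify_methylation_response",
    "read_segment_counts",
]

CONDITIONS = ("unmethylated", "methylated")


@dataclass(frozen=True)
class SegmentCount:
    """DNA/RNA read counts of one captured segment in one assay condition."""

    interval: GenomicInterval
    condition: str
    dna_reads: int
    rna_reads: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.dna_reads < 0 or self.rna_reads < 0:
            raise ValueError("read counts must be non-negative")


def compute_tas(rna_j: float, dna_j: float, rna_total: float, dna_total: float) -> float:
    """Transcriptional activity score: local RNA/DNA ratio over the global one, log2.

    All four counts must be positive; a zero anywhere leaves the score
    undefined and raises.
    """
    if min(rna_j, dna_j, rna_total, dna_total) <= 0:
        raise ValueError("TAS undefined: all counts must be > 0")
    return math.log2((rna_j / dna_j) / (rna_total / dna_total))


def chi_square_window(
    rna_j: int,
    dna_j: int,
    rna_total: int,
    dna_total: int,
    correction: bool = False,
) -> float:
    """Pearson chi-square p-value (1 df) of a window's RNA:DNA split vs the rest.

    The 2x2 table is [[rna_j, dna_j], [rna_total - rna_j, dna_total - dna_j]].
    No continuity correction by default (counts are large); returns NaN when
    any expected cell is zero.
    """
    if rna_j > rna_total or dna_j > dna_total:
        raise ValueError("window counts exceed totals")
    table = np.array(
        [[rna_j, dna_j], [rna_total - rna_j, dna_total - dna_j]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        return float("nan")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaN entries are passed through and excluded from the family.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def read_segment_counts(path) -> list[SegmentCount]:
    """Read segment counts from TSV (chrom, start, end, condition, dna_reads, rna_reads)."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "condition", "dna_reads", "rna_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        SegmentCount(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            str(r.condition),
            int(r.dna_reads),
            int(r.rna_reads),
        )
        for r in df.itertuples(index=False)
    ]


def score_windows(
    segments: list[SegmentCount],
    windows: list[GenomicInterval],
    condition: str,
    correction: bool = False,
) -> pd.DataFrame:
    """Aggregate segment counts into windows and score activity.

    Segments of the requested condition with at least one RNA read and one
    DNA read are retained; library totals are the sums over all retained
    segments. Each window receives the full counts of every overlapping
    segment (a segment spanning two windows contributes to both). Windows
    with zero aggregated DNA or RNA are flagged unscored. q-values are BH
    over all scored windows of this run.

    Returns a DataFrame with columns chrom, start, end, condition,
    dna_reads, rna_reads, n_segments, tas, p, q, scored.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    retained = [
        s
        for s in segments
        if s.condition == condition and s.rna_reads >= 1 and s.dna_reads >= 1
    ]
    if not retained:
        warnings.warn(f"no retained segments for condition {condition!r}", stacklevel=2)
    rna_total = sum(s.rna_reads for s in retained)
    dna_total = sum(s.dna_reads for s in retained)

    # per-chromosome arrays sorted by start for windowed lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {s.interval.chrom for s in retained}:
        segs = sorted(
            (s for s in retained if s.interval.chrom == chrom),
            key=lambda s: (s.interval.start, s.interval.end),
        )
        by_chrom[chrom] = (
            np.array([s.interval.start for s in segs]),
            np.array([s.interval.end for s in segs]),
            np.array([s.dna_reads for s in segs]),
            np.array([s.rna_reads for s in segs]),
        )

    rows = []
    for w in windows:
        dna = rna = nseg = 0
        if w.chrom in by_chrom:
            starts, ends, dnas, rnas = by_chrom[w.chrom]
            max_len = int((ends - starts).max()) if len(starts) else 0
            lo = int(np.searchsorted(starts, w.start - max_len, side="left"))
            hi = int(np.searchsorted(starts, w.end, side="left"))
            for i in range(lo, hi):
                if ends[i] > w.start:  # starts[i] < w.end by construction
                    dna += int(dnas[i])
                    rna += int(rnas[i])
                    nseg += 1
        scored = dna > 0 and rna > 0 and rna_total > 0 and dna_total > 0
        tas = compute_tas(rna, dna, rna_total, dna_total) if scored else np.nan
        p = (
            chi_square_window(rna, dna, rna_total, dna_total, correction=correction)
            if scored
            else np.nan
        )
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "condition": condition,
                "dna_reads": dna,
                "rna_reads": rna,
                "n_segments": nseg,
                "tas": tas,
                "p": p,
                "scored": scored,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def call_elements(
    windows_unmeth: pd.DataFrame,
    q_max: float = 0.05,
    min_rna: int = 100,
) -> pd.DataFrame:
    """Call significant regulatory elements from unmethylated-condition windows.

    An element is a scored window with q < ``q_max`` and at least ``min_rna``
    aggregated RNA reads; its class follows the TAS sign (enhancer > 0,
    silencer < 0; exact zero is excluded).
    """
    df = windows_unmeth
    keep = (
        df["scored"]
        & (df["q"] < q_max)
        & (df["rna_reads"] >= min_rna)
        & (df["tas"] != 0)
    )
    out = df.loc[keep, ["chrom", "start", "end", "dna_reads", "rna_reads", "tas", "p", "q"]]
    out = out.rename(columns={"tas": "tas_unmeth"}).reset_index(drop=True)
    out["cls"] = np.where(out["tas_unmeth"] > 0, "enhancer", "silencer")
    return out


def classify_methylation_response(
    elements: pd.DataFrame,
    windows_meth: pd.DataFrame,
    fold: float = 1.5,
) -> pd.DataFrame:
    """Attach methylation-response groups I-IV to called elements.

    An element is methylation-sensitive when its activity changes by at
    least ``fold`` between conditions, i.e. |TAS_meth - TAS_unmeth| >=
    log2(fold). Sensitive enhancers weakened by methylation are group I,
    strengthened group II; sensitive silencers strengthened are group III,
    weakened group IV. Insensitive elements, and elements whose window is
    unscored in the methylated condition, stay 'unclassified'.
    """
    meth = windows_meth.loc[
        windows_meth["scored"], ["chrom", "start", "end", "tas"]
    ].rename(columns={"tas": "tas_meth"})
    out = elements.merge(meth, on=["chrom", "start", "end"], how="left")
    out["delta"] = out["tas_meth"] - out["tas_unmeth"]
    threshold = math.log2(fold)
    out["sensitive"] = out["delta"].abs() >= threshold
    out["sensitive"] = out["sensitive"].fillna(False)
    out["meth_missing"] = out["tas_meth"].isna()

    group = np.full(len(out), "unclassified", dtype=object)
    sens = out["sensitive"].to_numpy(dtype=bool)
    enh = (out["cls"] == "enhancer").to_numpy()
    delta = out["delta"].to_numpy()
    with np.errstate(invalid="ignore"):  # NaN delta stays unclassified
        group[sens & enh & (delta < 0)] = "I"
        group[sens & enh & (delta > 0)] = "II"
        group[sens & ~enh & (delta < 0)] = "III"
        group[sens & ~enh & (delta > 0)] = "IV"
    out["group"] = group
    return out
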