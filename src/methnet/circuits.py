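"""Inference of methylation-expression cis-regulatory circuits.

A circuit is a statistically significant monotone association between the
methylation level (beta value) of one CpG site and the expression of one
gene across a tumor cohort, evaluated within the gene's +/-1 Mb domain by
Spearman rank correlation with Benjamini-Hochberg FDR control. Circuits
must additionally clear an effect-size floor (rho^2 > 0.3). Downstream
filters flag -- but never delete -- circuits that likely reflect blood
contamination (methylation tracking the pan-leukocyte marker PTPRC),
secondary effects through another gene's promoter or gene body, or a
mismatch with the reporter-assay methylation-response class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneAnnotation
from .reporter import bh_adjust

__all__ = [
    "MethylationMatrix",
    "spearman",
    "map_circuits",
    "blood_filter",
    "secondary_filter",
    "canonical_filter",
    "update_retained",
    "cnv_block_association",
]

FILTER_FLAGS = ("blood_filtered", "secondary_filtered", "canonical_mismatch")


@dataclass
class MethylationMatrix:
    """CpG site annotation plus a sites x samples beta-value matrix.

    ``sites`` is indexed by site_id with columns chrom and pos; ``beta``
    shares the same index, one column per sample, values in [0, 1] with
    NaN for missing observations.
    """

    sites: pd.DataFrame
    beta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.beta.index):
            raise ValueError("sites and beta must share the site_id index")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @classmethod
    def from_tsv(cls, path) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t")
        for col in ("site_id", "chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        df = df.set_index("site_id")
        sites = df[["chrom", "pos"]].copy()
        beta = df.drop(columns=["chrom", "pos"]).astype(float)
        return cls(sites, beta)

    def to_tsv(self, path) -> None:
        out = pd.concat([self.sites, self.beta], axis=1)
        out.index.name = "site_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def spearman(x, y, min_obs: int = 8) -> tuple[float, float, int]:
    """Spearman rank correlation on pairwise-complete observations.

    Average ranks for ties; p-value from the t-approximation on n - 2 df.
    Returns (rho, p, n_obs); rho and p are NaN when fewer than ``min_obs``
    complete pairs remain or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < min_obs:
        return float("nan"), float("nan"), n
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p), n


def map_circuits(
    meth: MethylationMatrix,
    expr: pd.DataFrame,
    genes: list[GeneAnnotation],
    halfwidth: int = 1_000_000,
    q_max: float = 0.05,
    r2_min: float = 0.3,
    min_obs: int = 8,
    min_shared_samples: int = 12,
    bh_family: str = "global",
) -> pd.DataFrame:
    """Test every gene x in-domain site pair and call circuits.

    For each gene, every CpG site within ``halfwidth`` of its TSS is tested
    by Spearman correlation between site methylation and gene expression
    across the shared samples; sites with fewer than ``min_obs`` non-missing
    values are skipped. q-values are BH over all tested pairs (``bh_family=
    'global'``) or within each gene (``'per_gene'``). A circuit is retained
    when q < ``q_max``, rho^2 > ``r2_min`` and no downstream filter has
    flagged it.

    Returns a circuit table with one row per tested pair; filter flag
    columns are initialised to False so the unfiltered table remains
    recoverable after filtering (flags only ever accumulate).
    """
    shared = [s for s in meth.samples if s in expr.columns]
    if len(shared) < min_shared_samples:
        raise ValueError(
            f"only {len(shared)} shared samples; need >= {min_shared_samples}"
        )
    beta = meth.beta[shared]
    eligible = beta.notna().sum(axis=1) >= min_obs

    rows = []
    for gene in genes:
        if gene.gene_id not in expr.index:
            continue
        y = expr.loc[gene.gene_id, shared].to_numpy(dtype=float)
        in_domain = (
            (meth.sites["chrom"] == gene.chrom)
            & ((meth.sites["pos"] - gene.tss).abs() <= halfwidth)
            & eligible
        )
        site_ids = meth.sites.index[in_domain]
        for site_id in site_ids:
            x = beta.loc[site_id].to_numpy(dtype=float)
            rho, p, n = spearman(x, y, min_obs=min_obs)
            if np.isnan(rho):
                continue
            pos = int(meth.sites.at[site_id, "pos"])
            dist = pos - gene.tss
            if gene.strand == "-":
                dist = -dist
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "site_id": site_id,
                    "chrom": gene.chrom,
                    "pos": pos,
                    "tss_distance": dist,
                    "n_obs": n,
                    "rho": rho,
                    "r2": rho * rho,
                    "sign": "positive" if rho > 0 else "negative",
                    "p": p,
                }
            )
    circuits = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "site_id",
            "chrom",
            "pos",
            "tss_distance",
            "n_obs",
            "rho",
            "r2",
            "sign",
            "p",
        ],
    )
    if len(circuits):
        if bh_family == "global":
            circuits["q"] = bh_adjust(circuits["p"].to_numpy())
        elif bh_family == "per_gene":
            circuits["q"] = circuits.groupby("gene_id")["p"].transform(
                lambda s: bh_adjust(s.to_numpy())
            )
        else:
            raise ValueError(f"unknown bh_family {bh_family!r}")
    else:
        circuits["q"] = pd.Series(dtype=float)
    circuits["stat_ok"] = (circuits["q"] < q_max) & (circuits["r2"] > r2_min)
    for flag in FILTER_FLAGS:
        circuits[flag] = False
    return update_retained(circuits)


def update_retained(circuits: pd.DataFrame) -> pd.DataFrame:
    """Recompute the retained flag: significant, strong, and unflagged."""
    flagged = np.zeros(len(circuits), dtype=bool)
    for flag in FILTER_FLAGS:
        flagged |= circuits[flag].to_numpy(dtype=bool)
    circuits["retained"] = circuits["stat_ok"].to_numpy(dtype=bool) & ~flagged
    return circuits


def blood_filter(
    circuits: pd.DataFrame,
    meth: MethylationMatrix,
    ptprc_expression: pd.Series | None,
    r2_max: float = 0.1,
    min_obs: int = 8,
) -> pd.DataFrame:
    """Flag circuits whose site methylation tracks PTPRC (CD45) expression.

    Sites correlating with the pan-leukocyte marker beyond rho^2 >
    ``r2_max`` are likely reporting blood contamination of the tumor biopsy
    rather than tumor-cell regulation. Flags are additive; nothing is
    deleted. When PTPRC expression is unavailable the filter is skipped
    with a warning.
    """
    if ptprc_expression is None:
        warnings.warn(
            "PTPRC expression unavailable: blood-contamination filter skipped",
            stacklevel=2,
        )
        return circuits
    samples = [s for s in meth.samples if s in ptprc_expression.index]
    y = ptprc_expression[samples].to_numpy(dtype=float)
    flag_site: dict[str, bool] = {}
    for site_id in circuits["site_id"].unique():
        x = meth.beta.loc[site_id, samples].to_numpy(dtype=float)
        rho, _, _ = spearman(x, y, min_obs=min_obs)
        flag_site[site_id] = bool(not np.isnan(rho) and rho * rho > r2_max)
    circuits["blood_filtered"] = (
        circuits["blood_filtered"].to_numpy(dtype=bool)
        | circuits["site_id"].map(flag_site).fillna(False).to_numpy(dtype=bool)
    )
    return update_retained(circuits)


def secondary_filter(
    circuits: pd.DataFrame,
    genes: list[GeneAnnotation],
    expr: pd.DataFrame,
    r2_max: float = 0.1,
    min_obs: int = 8,
    strict: bool = False,
) -> pd.DataFrame:
    """Flag circuits that may reflect secondary effects through another gene.

    If a circuit's site lies in another gene H's promoter or gene body
    (excluding the first 5 kb downstream of H's TSS) and the expression of
    the circuit's gene correlates with H's expression beyond rho^2 >
    ``r2_max``, the association may be indirect and is flagged. With
    ``strict=True`` the expression-correlation condition is dropped and any
    such site is flagged outright.
    """
    by_id = {g.gene_id: g for g in genes}
    flags = np.zeros(len(circuits), dtype=bool)
    for i, row in enumerate(circuits.itertuples(index=False)):
        for other in genes:
            if other.gene_id == row.gene_id or other.chrom != row.chrom:
                continue
            regions = [other.promoter, other.body_excl5k]
            inside = any(
                r is not None and r.start <= row.pos < r.end for r in regions
            )
            if not inside:
                continue
            if strict:
                flags[i] = True
                break
            if row.gene_id not in expr.index or other.gene_id not in expr.index:
                continue
            rho, _, _ = spearman(
                expr.loc[row.gene_id].to_numpy(dtype=float),
                expr.loc[other.gene_id].to_numpy(dtype=float),
                min_obs=min_obs,
            )
            if not np.isnan(rho) and rho * rho > r2_max:
                flags[i] = True
                break
    circuits["secondary_filtered"] = (
        circuits["secondary_filtered"].to_numpy(dtype=bool) | flags
    )
    del by_id
    return update_retained(circuits)


def canonical_filter(
    circuits: pd.DataFrame,
    elements: pd.DataFrame,
    max_dist: int = 500,
    canonical_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flag circuits that contradict the reporter-assay methylation response.

    Each circuit's site is matched to the nearest called element within
    ``max_dist`` bp. A negative circuit (expression falls as methylation
    rises) canonically corresponds to a methylation-weakened enhancer
    (group I); a positive circuit to a methylation-weakened silencer
    (group IV). When the matched element is methylation-sensitive but its
    group differs from the canonical expectation, the circuit is flagged.
    Unmatched sites and insensitive elements are left untouched.
    """
    if canonical_map is None:
        canonical_map = {"negative": "I", "positive": "IV"}
    flags = np.zeros(len(circuits), dtype=bool)
    if len(elements):
        el_by_chrom = {
            chrom: sub.reset_index(drop=True)
            for chrom, sub in elements.groupby("chrom")
        }
        for i, row in enumerate(circuits.itertuples(index=False)):
            sub = el_by_chrom.get(row.chrom)
            if sub is None:
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            dists = np.where(
                row.pos < starts,
                starts - row.pos,
                np.where(row.pos >= ends, row.pos - ends + 1, 0),
            )
            j = int(np.argmin(dists))
            if dists[j] > max_dist:
                continue
            el = sub.iloc[j]
            if not bool(el.get("sensitive", False)):
                continue
            if el["group"] != canonical_map[row.sign]:
                flags[i] = True
    circuits["canonical_mismatch"] = (
        circuits["canonical_mismatch"].to_numpy(dtype=bool) | flags
    )
    return update_retained(circuits)


def cnv_block_association(
    tcn: pd.DataFrame,
    expr: pd.DataFrame,
    genes: list[GeneAnnotation],
    halfwidth: int = 1_000_000,
    min_n: int = 6,
) -> pd.DataFrame:
    """Associate total copy number of sliding blocks with gene expression.

    ``tcn`` carries one row per pre-computed block (columns chrom, start,
    end, then one column per sample holding total copy number, NaN when
    unavailable). For every gene, blocks overlapping its TSS domain are
    tested by Pearson and Spearman correlation against the gene's
    expression over samples with available copy number; blocks with fewer
    than ``min_n`` such samples, or constant copy number, are skipped.
    p-values are BH-adjusted over all tested (block, gene) pairs, one
    family per correlation type.
    """
    sample_cols = [c for c in tcn.columns if c not in ("chrom", "start", "end")]
    rows = []
    for gene in genes:
        if gene.gene_id not in expr.index:
            continue
        dom = gene.domain(halfwidth)
        sel = (
            (tcn["chrom"] == dom.chrom)
            & (tcn["start"] < dom.end)
            & (tcn["end"] > dom.start)
        )
        y_all = expr.loc[gene.gene_id]
        for blk in tcn.loc[sel].itertuples(index=False):
            x = np.array([getattr(blk, s) for s in sample_cols], dtype=float)
            y = y_all[sample_cols].to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < min_n:
                continue
            xs, ys = x[mask], y[mask]
            if np.all(xs == xs[0]) or np.all(ys == ys[0]):
                continue
            pear_r, pear_p = stats.pearsonr(xs, ys)
            spear_r, spear_p = stats.spearmanr(xs, ys)
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "chrom": blk.chrom,
                    "start": int(blk.start),
                    "end": int(blk.end),
                    "n_obs": int(mask.sum()),
                    "pearson_r": float(pear_r),
                    "pearson_p": float(pear_p),
                    "spearman_rho": float(spear_r),
                    "spearman_p": float(spear_p),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "start",
            "end",
            "n_obs",
            "pearson_r",
            "pearson_p",
            "spearman_rho",
            "spearman_p",
        ],
    )
    if len(out):
        out["pearson_q"] = bh_adjust(out["pearson_p"].to_numpy())
        out["spearman_q"] = bh_adjust(out["spearman_p"].to_numpy())
    else:
        out["pearson_q"] = pd.Series(dtype=float)
        out["spearman_q"] = pd.Series(dtype=float)
    return out
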