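"""Clustering of gene-associated methylation sites into regulatory units.

A regulatory unit is a genomic cluster of a gene's retained circuit sites
that all carry the same association sign (all positive or all negative).
Units are built by a greedy left-to-right merge: a site joins the open
cluster when it shares the sign and lies within ``max_gap`` bp of the
previous member; an intervening retained site of opposite sign closes the
cluster. Clusters below ``min_sites`` members are emitted as singletons
flagged ``sub_unit`` and excluded from unit statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circuits import MethylationMatrix, spearman

__all__ = ["build_units", "build_units_all", "unit_stats", "correlation_map"]


def build_units(
    circuits_of_gene: pd.DataFrame,
    max_gap: int = 1000,
    min_sites: int = 2,
) -> pd.DataFrame:
    """Cluster one gene's retained circuits into same-sign units.

    Returns one row per cluster (or per flagged singleton) with columns
    gene_id, unit_id, sign, chrom, start, end, size_bp, n_sites, sites,
    is_unit. ``size_bp`` is the genomic distance from the first to the
    last member site (1 for singletons).
    """
    df = circuits_of_gene.loc[circuits_of_gene["retained"]].sort_values(
        ["chrom", "pos", "site_id"]
    )
    clusters: list[list[tuple]] = []
    current: list[tuple] = []

    def close() -> None:
        if current:
            clusters.append(list(current))
            current.clear()

    prev_chrom = prev_pos = prev_sign = None
    for row in df.itertuples(index=False):
        if current and (
            row.chrom != prev_chrom
            or row.sign != prev_sign
            or row.pos - prev_pos > max_gap
        ):
            close()
        current.append((row.site_id, row.chrom, int(row.pos), row.sign))
        prev_chrom, prev_pos, prev_sign = row.chrom, int(row.pos), row.sign
    close()

    gene_id = (
        str(circuits_of_gene["gene_id"].iloc[0]) if len(circuits_of_gene) else ""
    )
    rows = []
    counter = 0
    for cluster in clusters:
        if len(cluster) >= min_sites:
            emitted = [cluster]
        else:  # split undersized clusters into flagged singletons
            emitted = [[member] for member in cluster]
        for grp in emitted:
            positions = [m[2] for m in grp]
            first, last = min(positions), max(positions)
            rows.append(
                {
                    "gene_id": gene_id,
                    "unit_id": f"{gene_id}:u{counter}",
                    "sign": grp[0][3],
                    "chrom": grp[0][1],
                    "start": first,
                    "end": last if last > first else first + 1,
                    "size_bp": (last - first) if last > first else 1,
                    "n_sites": len(grp),
                    "sites": tuple(m[0] for m in grp),
                    "is_unit": len(grp) >= min_sites,
                }
            )
            counter += 1
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "unit_id",
            "sign",
            "chrom",
            "start",
            "end",
            "size_bp",
            "n_sites",
            "sites",
            "is_unit",
        ],
    )


def build_units_all(
    circuits: pd.DataFrame, max_gap: int = 1000, min_sites: int = 2
) -> pd.DataFrame:
    """Build units for every gene in a circuit table."""
    parts = [
        build_units(sub, max_gap=max_gap, min_sites=min_sites)
        for _, sub in circuits.groupby("gene_id", sort=True)
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return build_units(circuits.iloc[0:0], max_gap, min_sites)
    return pd.concat(parts, ignore_index=True)


def unit_stats(units: pd.DataFrame, circuits: pd.DataFrame | None = None) -> dict:
    """Summary statistics over built units.

    Reports unit-size and site-count means over multi-site units, the same
    means with flagged singletons included, and per-gene unit/circuit
    counts split by sign.
    """
    real = units.loc[units["is_unit"]]
    per_gene = units.groupby("gene_id")
    stats: dict = {
        "n_units": int(len(real)),
        "n_sub_units": int((~units["is_unit"]).sum()),
        "mean_size_bp": float(real["size_bp"].mean()) if len(real) else float("nan"),
        "mean_sites_per_unit": float(real["n_sites"].mean()) if len(real) else float("nan"),
        "mean_size_bp_incl_singletons": float(units["size_bp"].mean())
        if len(units)
        else float("nan"),
        "mean_sites_incl_singletons": float(units["n_sites"].mean())
        if len(units)
        else float("nan"),
    }
    gene_rows = []
    for gene_id, sub in per_gene:
        sub_real = sub.loc[sub["is_unit"]]
        gene_rows.append(
            {
                "gene_id": gene_id,
                "n_units": int(len(sub_real)),
                "n_units_positive": int((sub_real["sign"] == "positive").sum()),
                "n_units_negative": int((sub_real["sign"] == "negative").sum()),
            }
        )
    gene_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "n_units", "n_units_positive", "n_units_negative"]
    )
    if circuits is not None and len(circuits):
        counts = (
            circuits.loc[circuits["retained"]]
            .groupby("gene_id")
            .agg(
                n_circuits=("site_id", "size"),
                n_circuits_positive=("sign", lambda s: int((s == "positive").sum())),
                n_circuits_negative=("sign", lambda s: int((s == "negative").sum())),
            )
            .reset_index()
        )
        gene_df = gene_df.merge(counts, on="gene_id", how="outer").fillna(0)
    stats["per_gene"] = gene_df
    stats["mean_units_per_gene"] = (
        float(gene_df["n_units"].mean()) if len(gene_df) else float("nan")
    )
    return stats


def correlation_map(
    site_ids,
    meth: MethylationMatrix,
    min_obs: int = 8,
) -> pd.DataFrame:
    """Pairwise methylation-methylation Spearman correlation matrix.

    Computed on pairwise-complete observations; pairs with fewer than
    ``min_obs`` shared observations get NaN (rendered as no-correlation).
    The diagonal is exactly 1 and the matrix is symmetric.
    """
    site_ids = list(site_ids)
    n = len(site_ids)
    mat = np.full((n, n), np.nan)
    vals = meth.beta.loc[site_ids].to_numpy(dtype=float)
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            rho, _, _ = spearman(vals[i], vals[j], min_obs=min_obs)
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=site_ids, columns=site_ids)
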