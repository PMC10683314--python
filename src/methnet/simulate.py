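"""Synthetic cohorts and reporter libraries with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a tumor cohort (default 24 samples) in which each gene owns a small set
  of positive and negative regulatory units; per sample, each unit has a
  latent activity drawn Uniform(0, 1); the member CpG sites report that
  activity plus site-level noise (clipped to [0, 1]); gene expression is a
  baseline plus the signed, weighted sum of unit activities plus Gaussian
  noise on the log2 scale; background null sites are independent;
* a reporter library in which windows carry planted activities in the
  unmethylated and methylated conditions, DNA counts are negative-binomial
  and RNA counts Poisson conditional on DNA scaled by 2^activity; the
  default activity plan is depth-balanced so the library-wide RNA:DNA
  ratio matches the baseline and planted scores are recovered on their
  own scale;
* per-sample histone-peak sets with a known subset of variable regions.

Every draw flows from a single seed through spawned child generators, so
identical (config, seed) reproduce byte-identical fixture bundles. Ground
truth records each planted circuit's population Spearman correlation
(``rho_true``), estimated on an independent large reference cohort drawn
with the same structural parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import MethylationMatrix
from .intervals import GeneAnnotation, GenomicInterval, PeakCollection, write_bed
from .reporter import SegmentCount

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_reporter_library",
    "simulate_peak_sets",
    "write_fixture_bundle",
]

# (unmethylated, methylated) planted activities per response group
GROUP_ACTIVITIES = {
    "I": (1.0, 0.0),
    "II": (1.0, 2.0),
    "III": (-1.0, -2.0),
    "IV": (-1.0, 0.0),
    "null": (0.0, 0.0),
}
# depth-balanced group mix: sum(frac * 2^a) = 1 in both conditions, so the
# library-wide ratio equals the baseline and planted scores are absolute
GROUP_FRACTIONS = {"I": 0.2, "II": 0.1, "III": 0.4, "IV": 0.2, "null": 0.1}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort, reporter library, and peak sets.

    Cohort defaults mirror the analysis conditions: 24 tumors; on average
    1.1 positive and 1.4 negative units per gene; around 4.9 sites per
    unit spread over ~900 bp; site-level beta noise sd 0.05; 5% missing
    methylation calls; expression noise sd 0.25 log2 units.
    """

    seed: int = 0
    n_samples: int = 24
    n_genes: int = 8
    # unit plan: count = base + Bernoulli(extra_prob)
    base_pos_units: int = 1
    base_neg_units: int = 1
    extra_pos_unit_prob: float = 0.1
    extra_neg_unit_prob: float = 0.4
    sites_per_unit_min: int = 2
    sites_per_unit_lambda: float = 2.9  # count = min + Poisson(lambda)
    unit_span_bp: int = 900
    unit_gap_bp: int = 20_000
    unit_weight_range: tuple[float, float] = (0.8, 1.6)
    unit_coupling: float = 0.0  # 1.0 -> opposite-sign units perfectly anticorrelated
    site_sd: float = 0.05
    expr_sd: float = 0.25
    missing_rate: float = 0.05
    n_null_sites_per_gene: int = 15
    baseline_range: tuple[float, float] = (6.0, 10.0)
    gene_spacing_bp: int = 2_200_000
    n_reference_samples: int = 20_000  # for rho_true estimation
    # reporter plan
    n_windows: int = 300
    window_bp: int = 500
    window_gap_bp: int = 1000
    segments_per_window: int = 3
    dna_depth_mean: float = 500.0
    dna_dispersion: float = 10.0
    baseline_ratio: float = 1.0
    group_fractions: dict = field(default_factory=lambda: dict(GROUP_FRACTIONS))
    # peak plan
    n_peak_regions: int = 40
    peak_region_bp: int = 2000
    min_frac: float = 0.25

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    circuits: pd.DataFrame = field(default_factory=pd.DataFrame)
    units: pd.DataFrame = field(default_factory=pd.DataFrame)
    coefficients: pd.DataFrame = field(default_factory=pd.DataFrame)
    elements: pd.DataFrame = field(default_factory=pd.DataFrame)
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: getattr(self, name).to_dict(orient="records")
            for name in ("circuits", "units", "coefficients", "elements", "regions")
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")


def _unit_activities(rng, n, sign: int, coupling: float, z: np.ndarray) -> np.ndarray:
    indep = rng.uniform(0.0, 1.0, n)
    if coupling <= 0:
        return indep
    shared = z if sign > 0 else 1.0 - z
    return coupling * shared + (1.0 - coupling) * indep


def _plan_genes(cfg: SimulationConfig, rng) -> list[dict]:
    """Draw the per-gene unit architecture (counts, sites, weights, layout)."""
    plans = []
    for g in range(cfg.n_genes):
        tss = 1_500_000 + g * cfg.gene_spacing_bp
        n_pos = cfg.base_pos_units + int(rng.random() < cfg.extra_pos_unit_prob)
        n_neg = cfg.base_neg_units + int(rng.random() < cfg.extra_neg_unit_prob)
        units = []
        signs = [1] * n_pos + [-1] * n_neg
        for u, sign in enumerate(signs):
            n_sites = cfg.sites_per_unit_min + int(rng.poisson(cfg.sites_per_unit_lambda))
            weight = float(rng.uniform(*cfg.unit_weight_range))
            unit_start = tss + 30_000 + u * cfg.unit_gap_bp
            if n_sites == 1:
                positions = [unit_start]
            else:
                step = cfg.unit_span_bp / (n_sites - 1)
                positions = [int(round(unit_start + i * step)) for i in range(n_sites)]
            units.append(
                {"sign": sign, "weight": weight, "positions": positions}
            )
        null_positions = [
            tss - 800_000 + j * 2_000 for j in range(cfg.n_null_sites_per_gene)
        ]
        plans.append(
            {
                "gene_id": f"G{g:03d}",
                "tss": tss,
                "baseline": float(rng.uniform(*cfg.baseline_range)),
                "units": units,
                "null_positions": null_positions,
            }
        )
    return plans


def _draw_gene_data(cfg: SimulationConfig, plan: dict, n: int, rng):
    """Draw (site betas dict, expression vector) for one gene on n samples."""
    z = rng.uniform(0.0, 1.0, n)
    expr = np.full(n, plan["baseline"], dtype=float)
    betas: dict[int, np.ndarray] = {}
    for unit in plan["units"]:
        m = _unit_activities(rng, n, unit["sign"], cfg.unit_coupling, z)
        expr += unit["sign"] * unit["weight"] * m
        for pos in unit["positions"]:
            betas[pos] = np.clip(m + rng.normal(0.0, cfg.site_sd, n), 0.0, 1.0)
    for pos in plan["null_positions"]:
        betas[pos] = rng.uniform(0.0, 1.0, n)
    expr += rng.normal(0.0, cfg.expr_sd, n)
    return betas, expr


def _spearman_fast(x: np.ndarray, y_rank: np.ndarray) -> float:
    from scipy.stats import rankdata

    xr = rankdata(x)
    xc = xr - xr.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float((xc @ yc) / denom) if denom > 0 else float("nan")


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, list[GeneAnnotation], GroundTruth]:
    """Generate a cohort with planted circuits, units, and model coefficients.

    Returns the methylation matrix (with missingness applied), the
    expression matrix (genes x samples, log2 scale), gene annotations, and
    the ground truth. ``rho_true`` per planted circuit is the Spearman
    correlation measured on a large independent reference draw of the same
    gene, so it reflects the population association implied by the noise
    and weight settings rather than the finite cohort.
    """
    ss = np.random.SeedSequence(config.seed)
    plan_rng, data_rng, miss_rng, ref_rng = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    plans = _plan_genes(config, plan_rng)
    samples = [f"T{t:02d}" for t in range(config.n_samples)]

    genes: list[GeneAnnotation] = []
    site_rows, beta_rows = [], []
    expr_rows = {}
    truth_circuits, truth_units, truth_coefs = [], [], []
    for plan in plans:
        gene_id = plan["gene_id"]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom="chrS",
                strand="+",
                tss=plan["tss"],
                body_start=plan["tss"],
                body_end=plan["tss"] + 20_000,
            )
        )
        betas, expr = _draw_gene_data(config, plan, config.n_samples, data_rng)
        # independent large draw for population rho per planted site
        ref_betas, ref_expr = _draw_gene_data(
            config, plan, config.n_reference_samples, ref_rng
        )
        from scipy.stats import rankdata

        ref_expr_rank = rankdata(ref_expr)
        expr_rows[gene_id] = expr
        truth_coefs.append(
            {
                "gene_id": gene_id,
                "baseline": plan["baseline"],
                "unit_weights": [u["sign"] * u["weight"] for u in plan["units"]],
            }
        )
        for u_idx, unit in enumerate(plan["units"]):
            unit_id = f"{gene_id}:unit{u_idx}"
            truth_units.append(
                {
                    "gene_id": gene_id,
                    "unit_id": unit_id,
                    "sign": "positive" if unit["sign"] > 0 else "negative",
                    "weight": unit["sign"] * unit["weight"],
                    "positions": list(unit["positions"]),
                }
            )
            for pos in unit["positions"]:
                site_id = f"{gene_id}_s{pos}"
                site_rows.append({"site_id": site_id, "chrom": "chrS", "pos": pos})
                beta_rows.append(betas[pos])
                truth_circuits.append(
                    {
                        "gene_id": gene_id,
                        "site_id": site_id,
                        "pos": pos,
                        "unit_id": unit_id,
                        "sign": "positive" if unit["sign"] > 0 else "negative",
                        "rho_true": _spearman_fast(ref_betas[pos], ref_expr_rank),
                    }
                )
        for pos in plan["null_positions"]:
            site_id = f"{gene_id}_n{pos}"
            site_rows.append({"site_id": site_id, "chrom": "chrS", "pos": pos})
            beta_rows.append(betas[pos])

    sites = pd.DataFrame(site_rows).set_index("site_id")
    beta = pd.DataFrame(
        np.vstack(beta_rows), index=sites.index, columns=samples
    )
    if config.missing_rate > 0:
        mask = miss_rng.random(beta.shape) < config.missing_rate
        beta = beta.mask(mask)
    meth = MethylationMatrix(sites, beta)
    expr = pd.DataFrame(expr_rows, index=samples).T
    expr.index.name = "gene_id"
    truth = GroundTruth(
        circuits=pd.DataFrame(truth_circuits),
        units=pd.DataFrame(truth_units),
        coefficients=pd.DataFrame(truth_coefs),
    )
    return meth, expr, genes, truth


def simulate_reporter_library(
    config: SimulationConfig,
) -> tuple[list[SegmentCount], list[GenomicInterval], GroundTruth]:
    """Generate reporter segment counts for both assay conditions.

    Each planted window occupies its own region (regions are separated by
    more than a window, so tiling yields exactly one window per region and
    planted effects do not bleed across windows). Windows are assigned to
    methylation-response groups by the configured fractions; per window
    and condition, segment DNA counts are negative binomial and RNA counts
    Poisson with mean DNA * baseline_ratio * 2^activity.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_windows
    groups = []
    for grp, frac in config.group_fractions.items():
        groups.extend([grp] * int(round(frac * n)))
    groups = groups[:n]
    while len(groups) < n:
        groups.append("null")
    groups = list(rng.permutation(np.array(groups, dtype=object)))

    pitch = config.window_bp + config.window_gap_bp
    regions, segments, truth_rows = [], [], []
    for w, grp in enumerate(groups):
        a_u, a_m = GROUP_ACTIVITIES[grp]
        start = w * pitch
        end = start + config.window_bp
        region = GenomicInterval("chrR", start, end)
        regions.append(region)
        for cond, a in (("unmethylated", a_u), ("methylated", a_m)):
            mu = config.dna_depth_mean / config.segments_per_window
            k = config.dna_dispersion
            for _ in range(config.segments_per_window):
                seg_start = int(rng.integers(start, end - 50))
                seg_end = int(rng.integers(seg_start + 50, end + 1))
                dna = int(rng.negative_binomial(k, k / (k + mu)))
                rna = (
                    int(rng.poisson(dna * config.baseline_ratio * (2.0 ** a)))
                    if dna > 0
                    else 0
                )
                segments.append(
                    SegmentCount(
                        GenomicInterval("chrR", seg_start, seg_end), cond, dna, rna
                    )
                )
        if a_u > 0:
            cls = "enhancer"
        elif a_u < 0:
            cls = "silencer"
        else:
            cls = "null"
        truth_rows.append(
            {
                "chrom": "chrR",
                "start": start,
                "end": end,
                "group": grp,
                "cls": cls,
                "tas_unmeth": a_u,
                "tas_meth": a_m,
                "delta": a_m - a_u,
            }
        )
    truth = GroundTruth(elements=pd.DataFrame(truth_rows))
    return segments, regions, truth


def simulate_peak_sets(
    config: SimulationConfig,
) -> tuple[PeakCollection, PeakCollection, GroundTruth]:
    """Generate per-sample H3K4me1/H3K27ac peak sets with known variable regions.

    All regions carry H3K4me1 in every sample except a planted subset that
    lacks it in one sample; H3K27ac presence counts sweep the full range
    so regions fall on both sides of the variability band.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_samples
    samples = [f"T{t:02d}" for t in range(n)]
    k4: dict[str, list[GenomicInterval]] = {s: [] for s in samples}
    k27: dict[str, list[GenomicInterval]] = {s: [] for s in samples}
    truth_rows = []
    for r in range(config.n_peak_regions):
        start = r * config.peak_region_bp * 5
        end = start + config.peak_region_bp
        region = GenomicInterval("chrP", start, end)
        drop_k4 = r % 10 == 9  # every tenth region misses H3K4me1 in one sample
        k4_samples = samples[1:] if drop_k4 else samples
        for s in k4_samples:
            k4[s].append(region)
        n_ac = int(rng.integers(0, n + 1))
        ac_samples = list(rng.choice(samples, size=n_ac, replace=False))
        for s in ac_samples:
            k27[s].append(region)
        frac = n_ac / n
        selected = (
            not drop_k4
            and config.min_frac - 1e-9 <= frac <= 1 - config.min_frac + 1e-9
        )
        truth_rows.append(
            {
                "chrom": "chrP",
                "start": start,
                "end": end,
                "k27_fraction": frac,
                "k4_all": not drop_k4,
                "selected": selected,
            }
        )
    return (
        PeakCollection("H3K4me1", k4),
        PeakCollection("H3K27ac", k27),
        GroundTruth(regions=pd.DataFrame(truth_rows)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(config: SimulationConfig, directory: str | Path) -> dict:
    """Simulate everything and write a standard-format fixture bundle.

    Writes the methylation/expression/gene tables, reporter segment counts
    and regions, per-sample peak BEDs, ground-truth JSONs and the config;
    returns a manifest (also written as manifest.json) listing every file
    with row counts and SHA-256 checksums. Re-running with the same config
    and seed reproduces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meth, expr, genes, cohort_truth = simulate_cohort(config)
    segments, regions, reporter_truth = simulate_reporter_library(config)
    k4, k27, peak_truth = simulate_peak_sets(config)

    meth.to_tsv(directory / "meth.tsv")
    expr.to_csv(directory / "expr.tsv", sep="\t", float_format="%.10g")
    gene_df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "body_start": g.body_start,
                "body_end": g.body_end,
            }
            for g in genes
        ]
    )
    gene_df.to_csv(directory / "genes.tsv", sep="\t", index=False)
    seg_df = pd.DataFrame(
        [
            {
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "condition": s.condition,
                "dna_reads": s.dna_reads,
                "rna_reads": s.rna_reads,
            }
            for s in segments
        ]
    )
    seg_df.to_csv(directory / "segments.tsv", sep="\t", index=False)
    write_bed(regions, directory / "regions.bed")
    peak_dir = directory / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for mark, coll in (("h3k4me1", k4), ("h3k27ac", k27)):
        for sample, ivs in sorted(coll.samples.items()):
            write_bed(ivs, peak_dir / f"{mark}_{sample}.bed")
    cohort_truth.to_json(directory / "ground_truth_cohort.json")
    reporter_truth.to_json(directory / "ground_truth_reporter.json")
    peak_truth.to_json(directory / "ground_truth_peaks.json")
    with open(directory / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {}
    for path in sorted(directory.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            rel = str(path.relative_to(directory))
            n_rows = sum(1 for _ in open(path)) if path.suffix in (".tsv", ".bed") else None
            manifest[rel] = {"sha256": _sha256(path), "rows": n_rows}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
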