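"""End-to-end pipeline orchestration with reproducible run manifests.

Stage order: regions -> tas -> circuits -> units -> models -> validate.
Each stage consumes either the previous stage's in-memory product or a
file supplied in the run configuration, so runs can start mid-pipeline
from precomputed inputs. Every run writes per-stage TSV/BED outputs, a
parameter echo, and a manifest with SHA-256 checksums of all products;
identical configuration and seed reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import circuits as circ
from . import models as mdl
from . import reporter as rep
from . import units as un
from .intervals import PeakCollection, read_bed, read_gene_table, select_variable_regions, tile_windows, write_bed

logger = logging.getLogger("methnet.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("regions", "tas", "circuits", "units", "models", "validate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths, thresholds, and seed for a pipeline run.

    Threshold defaults are the analysis defaults throughout the package:
    500/250 bp windows, q < 0.05 with >= 100 RNA reads for element calls,
    1.5-fold methylation sensitivity, +/-1 Mb gene domains, >= 8 observed
    samples per site, rho^2 > 0.3 circuits with rho^2 > 0.1 contamination
    and secondary filters, 1000-bp unit gap, <= 4-site models with >= 12
    jointly complete samples, 2-fold prediction success and 20-of-24
    verification scaling.
    """

    out_dir: str = "methnet_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs (any may be None; stages lacking inputs are skipped)
    meth: str | None = None
    expr: str | None = None
    genes: str | None = None
    segments: str | None = None
    regions: str | None = None
    peaks_dir: str | None = None
    elements: str | None = None
    # thresholds
    window_size: int = 500
    window_step: int = 250
    min_frac: float = 0.25
    q_elements: float = 0.05
    min_rna: int = 100
    fold: float = 1.5
    halfwidth: int = 1_000_000
    q_circuits: float = 0.05
    r2_min: float = 0.3
    r2_blood: float = 0.1
    r2_secondary: float = 0.1
    min_obs: int = 8
    max_gap: int = 1000
    min_sites: int = 2
    max_k: int = 4
    min_complete: int = 12
    q_model: float = 0.05
    canonical_max_dist: int = 500
    canonical_map: dict = field(
        default_factory=lambda: {"negative": "I", "positive": "IV"}
    )
    run_lasso: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _load_peaks(peaks_dir: str) -> tuple[PeakCollection, PeakCollection]:
    peak_dir = Path(peaks_dir)
    colls = {}
    for mark in ("h3k4me1", "h3k27ac"):
        files = sorted(peak_dir.glob(f"{mark}_*.bed"))
        if not files:
            raise PipelineError(f"regions: no {mark}_*.bed files under {peak_dir}")
        colls[mark] = PeakCollection(
            mark, {f.stem.removeprefix(f"{mark}_"): read_bed(f) for f in files}
        )
    return colls["h3k4me1"], colls["h3k27ac"]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True))

    products: dict[str, object] = {}
    meth = circ.MethylationMatrix.from_tsv(config.meth) if config.meth else None
    expr = (
        pd.read_csv(config.expr, sep="\t", index_col=0) if config.expr else None
    )
    genes = read_gene_table(config.genes) if config.genes else None

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    try:
        if stage_enabled("regions") and config.peaks_dir:
            k4, k27 = _load_peaks(config.peaks_dir)
            regions = select_variable_regions(k4, k27, min_frac=config.min_frac)
            write_bed(regions, out / "regions.bed")
            products["regions"] = regions
            logger.info("regions: %d variable regions", len(regions))
        if config.regions:  # an explicit regions file overrides the stage product
            products["regions"] = read_bed(config.regions)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"regions: {exc}") from exc

    try:
        if stage_enabled("tas") and config.segments and "regions" in products:
            segments = rep.read_segment_counts(config.segments)
            windows = tile_windows(
                products["regions"], size=config.window_size, step=config.window_step
            )
            win_u = rep.score_windows(segments, windows, "unmethylated")
            win_m = rep.score_windows(segments, windows, "methylated")
            elements = rep.call_elements(
                win_u, q_max=config.q_elements, min_rna=config.min_rna
            )
            elements = rep.classify_methylation_response(
                elements, win_m, fold=config.fold
            )
            _write_df(win_u, out / "windows_unmethylated.tsv")
            _write_df(win_m, out / "windows_methylated.tsv")
            _write_df(elements, out / "elements.tsv")
            products["elements"] = elements
            logger.info("tas: %d elements called", len(elements))
        elif config.elements:
            products["elements"] = pd.read_csv(config.elements, sep="\t")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"tas: {exc}") from exc

    try:
        if (
            stage_enabled("circuits")
            and meth is not None
            and expr is not None
            and genes is not None
        ):
            circuits = circ.map_circuits(
                meth,
                expr,
                genes,
                halfwidth=config.halfwidth,
                q_max=config.q_circuits,
                r2_min=config.r2_min,
                min_obs=config.min_obs,
            )
            ptprc = expr.loc["PTPRC"] if "PTPRC" in expr.index else None
            circuits = circ.blood_filter(
                circuits, meth, ptprc, r2_max=config.r2_blood, min_obs=config.min_obs
            )
            circuits = circ.secondary_filter(
                circuits, genes, expr, r2_max=config.r2_secondary, min_obs=config.min_obs
            )
            if "elements" in products:
                circuits = circ.canonical_filter(
                    circuits,
                    products["elements"],
                    max_dist=config.canonical_max_dist,
                    canonical_map=config.canonical_map,
                )
            _write_df(circuits, out / "circuits.tsv")
            products["circuits"] = circuits
            logger.info(
                "circuits: %d tested, %d retained",
                len(circuits),
                int(circuits["retained"].sum()),
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"circuits: {exc}") from exc

    try:
        if stage_enabled("units") and "circuits" in products:
            units = un.build_units_all(
                products["circuits"], max_gap=config.max_gap, min_sites=config.min_sites
            )
            units_out = units.copy()
            units_out["sites"] = units_out["sites"].map(lambda t: ",".join(t))
            _write_df(units_out, out / "units.tsv")
            stats = un.unit_stats(units, products["circuits"])
            per_gene = stats.pop("per_gene")
            _write_df(per_gene, out / "unit_stats_per_gene.tsv")
            with open(out / "unit_stats.json", "w") as fh:
                json.dump(stats, fh, indent=1, sort_keys=True, default=float)
                fh.write("\n")
            products["units"] = units
            logger.info("units: %d units built", int(units["is_unit"].sum()))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"units: {exc}") from exc

    try:
        if (
            stage_enabled("models")
            and "circuits" in products
            and meth is not None
            and expr is not None
        ):
            rows = []
            for gene in genes:
                best = mdl.best_model_for_gene(
                    gene,
                    products["circuits"],
                    meth,
                    expr,
                    max_k=config.max_k,
                    min_complete=config.min_complete,
                    q_max=config.q_model,
                )
                for model in filter(None, [best]):
                    rows.append(_model_row(model))
                if config.run_lasso:
                    sub = products["circuits"]
                    cand = list(
                        sub.loc[
                            (sub["gene_id"] == gene.gene_id) & sub["retained"]
                        ].sort_values(["pos", "site_id"])["site_id"]
                    )
                    las = mdl.lasso_model(
                        gene.gene_id,
                        cand,
                        meth,
                        expr.loc[gene.gene_id] if gene.gene_id in expr.index else None,
                        seed=config.seed,
                        min_complete=config.min_complete,
                    ) if cand and gene.gene_id in expr.index else None
                    if las is not None:
                        rows.append(_model_row(las))
            models_df = pd.DataFrame(
                rows,
                columns=[
                    "gene_id",
                    "method",
                    "site_ids",
                    "intercept",
                    "coefs",
                    "n_complete",
                    "r_model",
                    "p_model",
                    "q_model",
                    "synergic",
                ],
            )
            _write_df(models_df, out / "models.tsv")
            products["models"] = models_df
            logger.info("models: %d fitted", len(models_df))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"models: {exc}") from exc

    try:
        if (
            stage_enabled("validate")
            and meth is not None
            and expr is not None
            and genes is not None
        ):
            predictions, report = mdl.loo_validate(
                meth,
                expr,
                genes,
                halfwidth=config.halfwidth,
                q_max_circuit=config.q_circuits,
                r2_min=config.r2_min,
                min_obs=config.min_obs,
                max_k=config.max_k,
                min_complete=config.min_complete,
                q_max_model=config.q_model,
                elements=products.get("elements"),
                canonical_max_dist=config.canonical_max_dist,
            )
            _write_df(predictions, out / "predictions.tsv")
            _write_df(report, out / "cv_report.tsv")
            modeled = predictions.loc[predictions["had_model"]]
            irregular = predictions.loc[predictions["irregular"] & predictions["had_model"]]
            summary = {
                "n_genes": int(report.shape[0]),
                "n_verified": int(report["verified"].sum()),
                "success_rate": float(modeled["success"].mean())
                if len(modeled)
                else float("nan"),
                "irregular_cases": int(len(irregular)),
                "irregular_accuracy": float(irregular["success"].mean())
                if len(irregular)
                else float("nan"),
            }
            with open(out / "cv_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
                fh.write("\n")
            logger.info("validate: %s", summary)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"validate: {exc}") from exc

    manifest = {"config": config.to_dict(), "outputs": {}}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _model_row(model: mdl.GeneModel) -> dict:
    return {
        "gene_id": model.gene_id,
        "method": model.method,
        "site_ids": ",".join(model.site_ids),
        "intercept": model.intercept,
        "coefs": ",".join(f"{c:.10g}" for c in model.coefs),
        "n_complete": model.n_complete,
        "r_model": model.r_model,
        "p_model": model.p_model,
        "q_model": model.q_model,
        "synergic": model.synergic,
    }
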