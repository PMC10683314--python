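"""Methylation-based combinatorial models of gene expression.

For each gene, every combination of one to four of its retained circuit
sites is fitted by ordinary least squares of log2 expression on the sites'
beta values over jointly complete samples. Model significance is the
overall F-test of the fit, BH-corrected over the gene's candidate models;
among significant models the one with the highest model correlation wins,
smaller models breaking ties. A winning model is synergic when its squared
model correlation exceeds every member site's single-site squared Pearson
correlation on the same samples. A LASSO alternative with no site-count
cap is provided, and a leave-one-out protocol re-derives circuits and
models on each 23-sample training cohort and scores the held-out tumor:
a prediction within 2-fold (|log2 error| <= 1, boundary inclusive) is a
success; a gene is verified when it succeeds in at least ceil(20/24 * N)
of the N rounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import fdtrc
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .circuits import MethylationMatrix, map_circuits
from .intervals import GeneAnnotation
from .reporter import bh_adjust

__all__ = [
    "GeneModel",
    "enumerate_site_sets",
    "fit_linear_model",
    "select_best_model",
    "lasso_model",
    "prediction_success",
    "loo_validate",
]

SUCCESS_LOG2_ERROR = 1.0  # "within 2-fold" on the log2 scale, inclusive
VERIFY_NUM, VERIFY_DEN = 20, 24  # verified when succeeding in >= 20/24 of rounds


@dataclass
class GeneModel:
    """A fitted linear model of one gene's expression on <=4 site betas."""

    gene_id: str
    site_ids: tuple[str, ...]
    intercept: float
    coefs: np.ndarray
    coef_se: np.ndarray
    n_complete: int
    r_model: float
    p_model: float
    q_model: float = float("nan")
    max_single_r2: float = float("nan")
    synergic: bool = False
    method: str = "exhaustive"
    rank_ok: bool = True
    extras: dict = field(default_factory=dict)

    @property
    def r2(self) -> float:
        return self.r_model * self.r_model

    def predict(self, x: np.ndarray) -> float:
        return float(self.intercept + np.dot(self.coefs, x))


def enumerate_site_sets(
    candidate_sites: list[str],
    meth: MethylationMatrix,
    max_k: int = 4,
    min_complete: int = 12,
    sample_mask: np.ndarray | None = None,
) -> list[tuple[str, ...]]:
    """All site subsets of size 1..max_k with jointly complete data.

    A subset qualifies when its member sites (optionally restricted by
    ``sample_mask``, e.g. samples with expression available) are jointly
    non-missing in at least ``min_complete`` samples. Enumeration order is
    deterministic: by size, then by position of the sites in
    ``candidate_sites``.
    """
    if not candidate_sites:
        warnings.warn("no candidate sites to enumerate", stacklevel=2)
        return []
    masks = {}
    for sid in candidate_sites:
        m = meth.beta.loc[sid].notna().to_numpy()
        if sample_mask is not None:
            m = m & sample_mask
        masks[sid] = m
    out: list[tuple[str, ...]] = []
    for k in range(1, max_k + 1):
        for combo in combinations(candidate_sites, k):
            joint = masks[combo[0]].copy()
            for sid in combo[1:]:
                joint &= masks[sid]
            if int(joint.sum()) >= min_complete:
                out.append(combo)
    if not out:
        warnings.warn("no site set meets the joint-completeness floor", stacklevel=2)
    return out


def fit_linear_model(
    site_ids,
    meth: MethylationMatrix,
    expr_gene: pd.Series,
    gene_id: str = "",
    min_complete: int = 12,
) -> GeneModel:
    """OLS of gene expression on the given sites' betas, complete cases only.

    ``r_model`` is the Pearson correlation of fitted versus observed;
    ``p_model`` the overall F-test against the intercept-only model.
    Rank-deficient designs are returned with ``rank_ok=False`` and are
    rejected from model selection. Also records the best single-site
    squared Pearson correlation among the members, evaluated on the same
    complete-case samples, which anchors the synergy call.
    """
    site_ids = tuple(site_ids)
    X_full = meth.beta.loc[list(site_ids)].to_numpy(dtype=float).T
    y_full = expr_gene[meth.beta.columns].to_numpy(dtype=float)
    return _fit_ols_arrays(site_ids, X_full, y_full, gene_id, min_complete)


def _fit_ols_arrays(
    site_ids: tuple[str, ...],
    X_full: np.ndarray,
    y_full: np.ndarray,
    gene_id: str,
    min_complete: int,
) -> GeneModel:
    k = len(site_ids)
    mask = ~(np.isnan(X_full).any(axis=1) | np.isnan(y_full))
    n = int(mask.sum())
    if n < min_complete:
        raise ValueError(f"only {n} complete samples; need >= {min_complete}")
    X, y = X_full[mask], y_full[mask]
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    model = GeneModel(
        gene_id=gene_id,
        site_ids=site_ids,
        intercept=float(coef[0]),
        coefs=coef[1:].copy(),
        coef_se=np.full(k, np.nan),
        n_complete=n,
        r_model=float("nan"),
        p_model=float("nan"),
    )
    if rank < k + 1 or n <= k + 1:
        model.rank_ok = False
        return model
    fitted = design @ coef
    resid = y - fitted
    sse = float(resid @ resid)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        model.rank_ok = False
        return model
    sigma2 = sse / (n - k - 1)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    model.coef_se = np.sqrt(np.diag(cov)[1:])
    # for OLS with an intercept, Pearson(fitted, observed) equals the
    # multiple correlation sqrt(1 - SSE/SST)
    r2 = max(0.0, 1.0 - sse / sst)
    model.r_model = math.sqrt(min(r2, 1.0))
    if sse <= 1e-14 * sst:
        model.p_model = 0.0
    else:
        f_stat = ((sst - sse) / k) / (sse / (n - k - 1))
        model.p_model = float(fdtrc(k, n - k - 1, f_stat))
    xc = X - X.mean(axis=0)
    xvar = np.einsum("ij,ij->j", xc, xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        singles = np.where(xvar > 0, (xc.T @ yc) ** 2 / (xvar * sst), 0.0)
    model.max_single_r2 = float(singles.max())
    return model


def select_best_model(
    gene_id: str,
    models: list[GeneModel],
    q_max: float = 0.05,
) -> GeneModel | None:
    """Pick the gene's best model among its significant candidates.

    Candidate p-values are BH-corrected within the gene; among models with
    q < ``q_max`` the highest squared model correlation wins, ties broken
    by fewer sites then lexicographic site order. The winner's synergy
    flag is set when its r^2 strictly exceeds the best member single-site
    r^2. Returns None when no model is significant.
    """
    valid = [m for m in models if m.rank_ok and np.isfinite(m.p_model)]
    if not valid:
        return None
    qs = bh_adjust([m.p_model for m in valid])
    for m, q in zip(valid, qs):
        m.q_model = float(q)
    significant = [m for m in valid if m.q_model < q_max]
    if not significant:
        return None
    best = min(significant, key=lambda m: (-m.r2, len(m.site_ids), m.site_ids))
    best.synergic = bool(best.r2 > best.max_single_r2)
    best.gene_id = gene_id
    return best


def lasso_model(
    gene_id: str,
    candidate_sites: list[str],
    meth: MethylationMatrix,
    expr_gene: pd.Series,
    seed: int = 0,
    min_complete: int = 12,
    n_folds: int = 10,
) -> GeneModel | None:
    """L1-penalised model over all candidate sites (no size cap).

    Predictors are standardised internally; the penalty is chosen by
    k-fold cross-validation (default 10, reduced when fewer complete
    samples are available) with a fixed seed, using the one-standard-error
    rule: the strongest penalty whose cross-validated error is within one
    standard error of the minimum. At cohort-scale sample sizes the
    minimum-MSE penalty retains many spurious sites; the 1-SE rule is the
    standard parsimony convention. Sites with nonzero coefficients
    constitute the model; full shrinkage returns None.
    """
    if not candidate_sites:
        return None
    X_full = meth.beta.loc[list(candidate_sites)].to_numpy(dtype=float).T
    y_full = expr_gene[meth.beta.columns].to_numpy(dtype=float)
    mask = ~(np.isnan(X_full).any(axis=1) | np.isnan(y_full))
    n = int(mask.sum())
    if n < min_complete:
        return None
    X, y = X_full[mask], y_full[mask]
    scale = X.std(axis=0, ddof=0)
    keep = scale > 0
    if not keep.any():
        return None
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / scale[keep]
    cv = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    lasso = LassoCV(cv=cv, random_state=seed, alphas=50, max_iter=20_000, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso.fit(Xs, y)
        # 1-SE rule on the CV error path (alphas_ are descending)
        mse_mean = lasso.mse_path_.mean(axis=1)
        mse_se = lasso.mse_path_.std(axis=1, ddof=1) / np.sqrt(
            lasso.mse_path_.shape[1]
        )
        i_min = int(np.argmin(mse_mean))
        ceiling = mse_mean[i_min] + mse_se[i_min]
        eligible = np.flatnonzero(mse_mean <= ceiling)
        alpha_1se = float(lasso.alphas_[eligible.min()])
        from sklearn.linear_model import Lasso

        final = Lasso(alpha=alpha_1se, max_iter=20_000, tol=1e-6)
        final.fit(Xs, y)
    coefs_std = final.coef_
    if np.all(coefs_std == 0):
        return None
    kept_sites = [s for s, k_ in zip(candidate_sites, keep) if k_]
    sel = coefs_std != 0
    site_ids = tuple(s for s, nz in zip(kept_sites, sel) if nz)
    coefs = coefs_std[sel] / scale[keep][sel]
    means = X[:, keep].mean(axis=0)[sel]
    intercept = float(final.intercept_ - np.dot(coefs, means))
    fitted = intercept + X[:, keep][:, sel] @ coefs
    r = float(np.corrcoef(fitted, y)[0, 1]) if np.std(fitted) > 0 else 0.0
    return GeneModel(
        gene_id=gene_id,
        site_ids=site_ids,
        intercept=intercept,
        coefs=coefs,
        coef_se=np.full(len(site_ids), np.nan),
        n_complete=n,
        r_model=r,
        p_model=float("nan"),
        method="lasso",
        extras={"alpha": alpha_1se, "alpha_min_mse": float(lasso.alpha_)},
    )


def prediction_success(abs_log2_error: float) -> bool:
    """Success rule: prediction within 2-fold of the observation, inclusive."""
    return abs_log2_error <= SUCCESS_LOG2_ERROR


def best_model_for_gene(
    gene: GeneAnnotation,
    circuits: pd.DataFrame,
    meth: MethylationMatrix,
    expr: pd.DataFrame,
    max_k: int = 4,
    min_complete: int = 12,
    q_max: float = 0.05,
) -> GeneModel | None:
    """Fit and select the best exhaustive model for one gene."""
    sub = circuits.loc[
        (circuits["gene_id"] == gene.gene_id) & circuits["retained"]
    ].sort_values(["pos", "site_id"])
    candidates = list(sub["site_id"])
    if not candidates or gene.gene_id not in expr.index:
        return None
    expr_gene = expr.loc[gene.gene_id]
    sample_mask = expr_gene[meth.beta.columns].notna().to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sets = enumerate_site_sets(
            candidates, meth, max_k=max_k, min_complete=min_complete,
            sample_mask=sample_mask,
        )
    # extract arrays once: the exhaustive search fits thousands of models
    beta_mat = meth.beta.loc[candidates].to_numpy(dtype=float)
    y_full = expr_gene[meth.beta.columns].to_numpy(dtype=float)
    col = {s: i for i, s in enumerate(candidates)}
    models = []
    for combo in sets:
        X_full = beta_mat[[col[s] for s in combo]].T
        try:
            models.append(
                _fit_ols_arrays(combo, X_full, y_full, gene.gene_id, min_complete)
            )
        except ValueError:
            continue
    return select_best_model(gene.gene_id, models, q_max=q_max)


def loo_validate(
    meth: MethylationMatrix,
    expr: pd.DataFrame,
    genes: list[GeneAnnotation],
    halfwidth: int = 1_000_000,
    q_max_circuit: float = 0.05,
    r2_min: float = 0.3,
    min_obs: int = 8,
    max_k: int = 4,
    min_complete: int = 12,
    q_max_model: float = 0.05,
    elements: pd.DataFrame | None = None,
    canonical_max_dist: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out validation of the circuit-to-model pipeline.

    For each held-out sample the whole inference chain -- circuit mapping,
    optional canonical filtering against reporter elements, exhaustive
    model search -- is re-run on the remaining samples, and the selected
    model predicts the held-out tumor's expression of each modeled gene.
    The held-out observation never informs training. A round with no
    model, or with missing methylation at the model's sites in the
    held-out sample, counts as a failure for that gene.

    Returns (predictions, report): one prediction row per gene x round,
    and one report row per gene with the verification call and
    irregular-expression bookkeeping (irregular: the held-out observation
    deviates from the gene's cohort mean by more than one cohort SD).
    """
    from .circuits import canonical_filter

    samples = list(meth.beta.columns)
    n_rounds = len(samples)
    threshold_rounds = math.ceil(VERIFY_NUM / VERIFY_DEN * n_rounds)
    gene_mean = expr.mean(axis=1)
    gene_sd = expr.std(axis=1, ddof=1)

    pred_rows = []
    for held_out in samples:
        train = [s for s in samples if s != held_out]
        meth_train = MethylationMatrix(meth.sites, meth.beta[train])
        expr_train = expr[train]
        min_shared = min(min_complete, len(train))
        circuits = map_circuits(
            meth_train,
            expr_train,
            genes,
            halfwidth=halfwidth,
            q_max=q_max_circuit,
            r2_min=r2_min,
            min_obs=min_obs,
            min_shared_samples=min_shared,
        )
        if elements is not None:
            circuits = canonical_filter(
                circuits, elements, max_dist=canonical_max_dist
            )
        for gene in genes:
            if gene.gene_id not in expr.index:
                continue
            observed = float(expr.at[gene.gene_id, held_out])
            model = best_model_for_gene(
                gene,
                circuits,
                meth_train,
                expr_train,
                max_k=max_k,
                min_complete=min_complete,
                q_max=q_max_model,
            )
            predicted = np.nan
            if model is not None:
                x = meth.beta.loc[list(model.site_ids), held_out].to_numpy(dtype=float)
                if not np.isnan(x).any():
                    predicted = model.predict(x)
            err = abs(predicted - observed) if np.isfinite(predicted) else np.nan
            success = bool(np.isfinite(err) and prediction_success(err))
            sd = float(gene_sd[gene.gene_id])
            irregular = bool(
                sd > 0 and abs(observed - float(gene_mean[gene.gene_id])) > sd
            )
            pred_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "left_out_sample": held_out,
                    "predicted": predicted,
                    "observed": observed,
                    "abs_log2_error": err,
                    "success": success,
                    "irregular": irregular,
                    "had_model": model is not None,
                }
            )
    predictions = pd.DataFrame(pred_rows)

    report_rows = []
    for gene_id, sub in predictions.groupby("gene_id", sort=True):
        succeeded = int(sub["success"].sum())
        modeled = int(sub["had_model"].sum())
        irr = sub.loc[sub["irregular"]]
        report_rows.append(
            {
                "gene_id": gene_id,
                "rounds_run": n_rounds,
                "rounds_with_model": modeled,
                "rounds_succeeded": succeeded,
                "verified": succeeded >= threshold_rounds,
                "irregular_cases": int(len(irr)),
                "irregular_successes": int(irr["success"].sum()),
            }
        )
    report = pd.DataFrame(
        report_rows,
        columns=[
            "gene_id",
            "rounds_run",
            "rounds_with_model",
            "rounds_succeeded",
            "verified",
            "irregular_cases",
            "irregular_successes",
        ],
    )
    return predictions, report
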