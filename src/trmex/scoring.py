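"""Per-cell module scoring with binned control genes, and downstream ratios.

The module score of a gene set in a cell is the mean normalized expression
of the set genes minus the mean of a seeded random draw of control genes,
where each set gene contributes controls from its own average-expression bin
(so the control distribution matches the set's expression profile). Up and
down scores are combined by averaging the up score with the sign-reversed
down score. Subset abundance comparisons use the per-sample log2 TEX/TRM
ratio, which can be regressed on tumor mutational burden.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .de import GeneSignature

__all__ = [
    "normalize_cells",
    "module_score",
    "combined_score",
    "signature_scores",
    "subset_log_ratio",
    "ratio_tmb_regression",
]


def normalize_cells(
    cells: ad.AnnData, target_sum: float = 1e4, base: float = 2.0
) -> pd.DataFrame:
    """Library-size normalize raw counts and log-transform (cells × genes)."""
    X = cells.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    lib = X.sum(axis=1)
    lib[lib == 0] = 1.0
    norm = X / lib[:, None] * target_sum
    return pd.DataFrame(
        np.log1p(norm) / np.log(base), index=cells.obs_names,
        columns=cells.var_names,
    )


def module_score(
    expr: pd.DataFrame,
    gene_set: list[str] | set[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    Candidate control genes (all genes outside the set) are binned into
    ``n_bins`` groups by their average expression over all cells; for each
    set gene, up to ``n_ctrl`` controls are drawn (seeded) from the bin
    matching that gene's average expression. The score is the mean
    expression of the set genes minus the mean expression of the pooled
    controls. Set genes absent from the matrix are dropped with a warning.
    """
    gene_set = sorted(set(gene_set))
    present = [g for g in gene_set if g in expr.columns]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} gene(s) absent from the matrix: {missing[:5]}")
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")

    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=0)
    # candidate controls exclude the set itself; bin them by average
    # expression (rank-based cut so bins are evenly filled even with ties)
    cand = avg.drop(index=present)
    if cand.empty:
        raise ValueError("no genes left to serve as controls")
    n_bins_eff = min(n_bins, len(cand))
    ranks = cand.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins_eff, labels=False)
    bin_members = {b: cand.index[bins == b] for b in np.unique(bins)}
    # quantile edges of the candidate averages locate each set gene's bin
    edges = np.quantile(cand, np.linspace(0, 1, n_bins_eff + 1))[1:-1]

    ctrl_genes: list[str] = []
    for g in present:
        pool = bin_members[int(np.searchsorted(edges, avg[g], side="right"))]
        take = min(n_ctrl, len(pool))
        ctrl_genes.extend(rng.choice(pool, size=take, replace=False))
    ctrl_mean = expr.loc[:, ctrl_genes].mean(axis=1)
    set_mean = expr.loc[:, present].mean(axis=1)
    return (set_mean - ctrl_mean).rename("module_score")


def combined_score(
    up: pd.Series, down: pd.Series | None = None
) -> pd.Series:
    """Average of the up score and the sign-reversed down score.

    With no down set the up score passes through unchanged.
    """
    if down is None:
        return up.rename("combined_score")
    if len(up) != len(down) or not up.index.equals(down.index):
        raise ValueError("up and down scores must align on the same cells")
    return ((up + (-down)) / 2.0).rename("combined_score")


def signature_scores(
    expr: pd.DataFrame,
    signature: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Up, down and combined module scores of a signature for every cell."""
    up = module_score(expr, signature.up_genes, n_bins, n_ctrl, seed)
    if signature.down_genes:
        down = module_score(expr, signature.down_genes, n_bins, n_ctrl, seed)
        comb = combined_score(up, down)
    else:
        down = pd.Series(np.nan, index=expr.index)
        comb = combined_score(up)
    return pd.DataFrame(
        {"up_score": up, "down_score": down, "combined": comb}
    )


def subset_log_ratio(
    labels: pd.Series,
    samples: pd.Series,
    numerator: str = "TEX",
    denominator: str = "TRM",
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-sample log2 ratio of cells in two subsets (e.g. TEX over TRM).

    ``labels`` holds the per-cell subset assignment and ``samples`` the
    per-cell sample (e.g. cancer or donor) id; both align on cells. Samples
    with zero cells in both subsets are excluded with a warning.
    """
    if not labels.index.equals(samples.index):
        raise ValueError("labels and samples must align on the same cells")
    out = {}
    for s, idx in samples.groupby(samples, observed=True).groups.items():
        sub = labels.loc[idx]
        n_num = int((sub == numerator).sum())
        n_den = int((sub == denominator).sum())
        if n_num == 0 and n_den == 0:
            warnings.warn(f"sample {s!r} has no {numerator} or {denominator} cells")
            continue
        out[s] = np.log2((n_num + pseudocount) / (n_den + pseudocount))
    return pd.Series(out, name=f"log2_{numerator}_{denominator}")


def ratio_tmb_regression(
    ratios: pd.Series, tmb: pd.Series
) -> dict[str, float]:
    """OLS of per-cancer log2 subset ratios on median tumor mutational burden.

    Returns slope, intercept, r2 and the two-sided p value for the slope
    departing from zero. Requires at least three paired observations with
    variance in the predictor.
    """
    shared = ratios.index.intersection(tmb.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired observations")
    x = tmb.loc[shared].to_numpy(dtype=float)
    y = ratios.loc[shared].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p_slope": float(res.pvalue),
        "n": int(len(shared)),
    }
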