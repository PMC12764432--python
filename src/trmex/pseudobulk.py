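"""Pseudobulk construction, filtering, scaling and unwanted-variation removal.

The workflow mirrors standard bulk-style processing of single-cell data:
donor × cluster cells are summed into pseudobulk samples, small samples and
uninformative genes are dropped, counts are put on a log2 scale (optionally
as TMM-scaled counts-per-million), and unwanted variation is estimated from
technical replicates restricted to negative-control genes (RUV-III) and
removed. For batched bulk cohorts without replicates, pseudo-replicates of
pseudo-samples (PRPS) are constructed from ranked relative-log-expression
tiers so the same replicate-based correction applies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PseudobulkSet",
    "ReplicateDesign",
    "PRPSDesign",
    "aggregate_pseudobulk",
    "filter_genes",
    "log_transform",
    "tmm_factors",
    "compute_rle",
    "ruv3_correct",
    "build_prps",
    "prps_replicate_design",
]

DEFAULT_REMOVED_PREFIXES = ("HLA", "TRA", "TRB", "TRG", "TRD")


@dataclass
class PseudobulkSet:
    """Samples × genes integer count matrix with per-sample metadata.

    ``sample_meta`` rows align with ``counts`` rows and carry at least the
    grouping keys used at aggregation, a ``group`` column (replicate group /
    biological condition) and ``n_cells``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.sample_meta.index):
            raise ValueError("counts and sample_meta must share the sample index")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class ReplicateDesign:
    """Replicate membership and negative controls for RUV-III.

    ``membership`` is a samples × groups indicator matrix (exactly one 1 per
    row). ``control_genes`` are genes assumed free of the biology of interest;
    ``k`` is the number of unwanted factors to estimate and remove
    (``k = 0`` means no correction).
    """

    membership: pd.DataFrame
    control_genes: set[str]
    k: int

    def __post_init__(self) -> None:
        rs = self.membership.sum(axis=1)
        if not np.all(rs == 1):
            bad = self.membership.index[rs != 1].tolist()
            raise ValueError(f"samples must belong to exactly one group: {bad}")
        if self.k < 0:
            raise ValueError("k must be >= 0")

    @classmethod
    def from_groups(
        cls, groups: pd.Series, control_genes: set[str], k: int
    ) -> "ReplicateDesign":
        m = pd.get_dummies(groups).astype(float)
        return cls(membership=m, control_genes=set(control_genes), k=k)


@dataclass
class PRPSDesign:
    """Pseudo-replicates of pseudo-samples for batched cohorts.

    ``tiers`` assigns each real sample a ``(batch, tier)`` pair; tiers are the
    bottom/middle/top thirds of the within-batch ranking by median relative
    log expression. ``pseudo_samples`` holds the gene-wise means (each over
    exactly five real samples) and ``pseudo_meta`` their batch / tier /
    subtype labels and members.
    """

    tiers: pd.DataFrame
    pseudo_samples: pd.DataFrame
    pseudo_meta: pd.DataFrame
    seed: int
    members: dict[str, list[str]] = field(default_factory=dict)


def aggregate_pseudobulk(
    cells: ad.AnnData,
    group_by: Sequence[str] = ("donor", "subset"),
    min_cells: int = 20,
    *,
    group_key: str | None = None,
) -> PseudobulkSet:
    """Sum raw counts gene-wise over each combination of ``group_by`` keys.

    Combinations with fewer than ``min_cells`` cells are removed (a sample
    with exactly ``min_cells`` cells is retained). ``group_key`` names the
    metadata column defining the replicate group of each pseudobulk sample;
    it defaults to the last ``group_by`` key (samples from the same cluster
    are treated as replicates of one group).
    """
    for key in group_by:
        if key not in cells.obs.columns:
            raise KeyError(f"cell metadata lacks required key {key!r}")
    group_key = group_key or group_by[-1]

    X = cells.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X)
    df = pd.DataFrame(X, index=cells.obs_names, columns=cells.var_names)

    keys = [cells.obs[k].astype(str) for k in group_by]
    grouped = df.groupby(list(keys), sort=True, observed=True)

    rows, meta_rows, dropped = [], [], []
    for name, sub in grouped:
        name = name if isinstance(name, tuple) else (name,)
        n = len(sub)
        sample_id = "|".join(str(v) for v in name)
        if n < min_cells:
            dropped.append((sample_id, n))
            continue
        rows.append(pd.Series(sub.sum(axis=0), name=sample_id))
        meta_rows.append(dict(zip(group_by, name), n_cells=n))
    if dropped:
        logger.info(
            "aggregate_pseudobulk: dropped %d sample(s) with < %d cells: %s",
            len(dropped), min_cells, dropped,
        )
    if not rows:
        raise ValueError(
            f"no pseudobulk sample has >= {min_cells} cells; nothing survives "
            "the minimum-cell filter"
        )
    counts = pd.DataFrame(rows).astype(np.int64)
    meta = pd.DataFrame(meta_rows, index=counts.index)
    meta["group"] = meta[group_key].astype(str)
    return PseudobulkSet(counts=counts, sample_meta=meta)


def filter_genes(
    pb: PseudobulkSet,
    removed_prefixes: Sequence[str] = DEFAULT_REMOVED_PREFIXES,
    min_count: int = 5,
    min_samples: int = 2,
) -> PseudobulkSet:
    """Drop receptor/HLA genes by identifier prefix and lowly expressed genes.

    A gene is kept iff, in at least one replicate group, it has a count
    strictly above ``min_count`` in at least ``min_samples`` samples (the
    breast rule is ``(>5, >=2)``, the liver rule ``(>3, >=4)``). Prefix
    matching is case-insensitive.
    """
    prefixes = tuple(p.upper() for p in removed_prefixes)
    names = pb.counts.columns
    keep_prefix = ~names.str.upper().str.startswith(prefixes) if prefixes else \
        np.ones(len(names), dtype=bool)

    groups = pb.sample_meta["group"]
    passed = np.zeros(len(names), dtype=bool)
    for _, idx in groups.groupby(groups, observed=True).groups.items():
        sub = pb.counts.loc[idx]
        passed |= ((sub > min_count).sum(axis=0) >= min_samples).to_numpy()

    keep = keep_prefix & passed
    if not keep.any():
        raise ValueError(
            "all genes removed by the prefix/low-count filter "
            f"(prefixes={prefixes}, rule: count > {min_count} in >= "
            f"{min_samples} samples of some group)"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_genes: removed %d of %d genes", n_drop, len(names))
    return PseudobulkSet(
        counts=pb.counts.loc[:, keep].copy(), sample_meta=pb.sample_meta.copy()
    )


def log_transform(
    counts: PseudobulkSet | pd.DataFrame,
    prior_count: float = 0.5,
    as_cpm: bool = False,
    scaling: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """log2-transform counts with a prior count, optionally as scaled CPM.

    With ``as_cpm`` the counts are first converted to counts-per-million
    using the effective library size (library size × TMM scaling factor when
    ``scaling`` is given), then ``log2(cpm + prior_count)``.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    mat = counts.counts if isinstance(counts, PseudobulkSet) else counts
    if (np.asarray(mat) < 0).any():
        raise ValueError("counts must be non-negative")
    if as_cpm:
        lib = mat.sum(axis=1).astype(float)
        if scaling is not None:
            lib = lib * np.asarray(scaling, dtype=float)
        mat = mat.div(lib, axis=0) * 1e6
    return np.log2(mat + prior_count)


def _quantile75(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=1)
    return np.array(
        [np.quantile(counts[i] / lib[i], 0.75) for i in range(counts.shape[0])]
    )


def tmm_factors(
    counts: PseudobulkSet | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (Robinson–Oshlack).

    M (log2 ratio) and A (average log2 abundance) are computed on
    library-size-normalized counts against a reference sample (the one whose
    75th-percentile fraction is closest to the mean). Genes in the upper or
    lower ``trim_m`` tail of M or ``trim_a`` tail of A are trimmed and the
    remaining M values averaged with precision weights. Factors are
    normalized to geometric mean 1.
    """
    mat = counts.counts if isinstance(counts, PseudobulkSet) else counts
    arr = np.asarray(mat, dtype=float)
    index = mat.index if isinstance(mat, pd.DataFrame) else pd.RangeIndex(len(arr))
    lib = arr.sum(axis=1)
    if (lib == 0).any():
        bad = list(index[lib == 0])
        raise ValueError(f"sample(s) with all-zero counts: {bad}")

    q75 = _quantile75(arr)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    yr, nr = arr[ref], lib[ref]

    factors = np.ones(arr.shape[0])
    for i in range(arr.shape[0]):
        if i == ref:
            continue
        y, n = arr[i], lib[i]
        ok = (y > 0) & (yr > 0)
        if not ok.any():
            continue
        p, pr = y[ok] / n, yr[ok] / nr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        # precision weights: delta-method variance of M
        w = (n - y[ok]) / (n * y[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        if np.allclose(m, 0):
            continue
        n_ok = ok.sum()
        lo_m, hi_m = np.floor(n_ok * trim_m) + 1, n_ok + 1 - (np.floor(n_ok * trim_m) + 1)
        lo_a, hi_a = np.floor(n_ok * trim_a) + 1, n_ok + 1 - (np.floor(n_ok * trim_a) + 1)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            factors[i] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=index, name="tmm_factor")


def compute_rle(log_expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Relative log expression: deviation from the gene-wise median profile.

    Returns the RLE matrix and the per-sample RLE medians used for ranking
    samples in normalization diagnostics and PRPS construction.
    """
    if log_expr.shape[0] == 1:
        warnings.warn("compute_rle on a single sample returns all zeros")
    med = log_expr.median(axis=0)
    rle = log_expr.sub(med, axis=1)
    return rle, rle.median(axis=1)


def ruv3_correct(
    log_expr: pd.DataFrame,
    design: ReplicateDesign,
    *,
    return_w: bool = False,
):
    """Estimate and remove unwanted variation from replicate residuals (RUV-III).

    Algebra: with replicate membership M, compute the residual
    ``R = Y - M (M'M)^{-1} M' Y`` (replicate-group means removed), take the
    left singular vectors of R, project Y onto the leading ones to get the
    full loading matrix alpha, then solve for sample scores W using only the
    negative-control gene columns and subtract ``W @ alpha``. Biology shared
    by replicates lives in the group means and is untouched; variation that
    differs within replicate groups and shows on control genes is removed.

    With ``k = 0`` the input is returned unchanged. ``return_w`` additionally
    returns the estimated sample scores W (samples × k) for use as model
    covariates downstream.
    """
    M = design.membership.loc[log_expr.index].to_numpy(dtype=float)
    Y = log_expr.to_numpy(dtype=float)
    m, n_groups = M.shape
    ctl = [g for g in design.control_genes if g in log_expr.columns]
    if design.k == 0:
        W = np.zeros((m, 0))
        out = log_expr.copy()
        return (out, W) if return_w else out
    if not ctl:
        raise ValueError("no control genes present in the matrix")
    max_k = m - n_groups
    if design.k > max_k:
        raise ValueError(
            f"k={design.k} not estimable: at most {max_k} unwanted factors with "
            f"{m} samples in {n_groups} replicate groups"
        )
    if design.k > len(ctl):
        raise ValueError(f"k={design.k} exceeds the {len(ctl)} control genes")

    ctl_idx = log_expr.columns.get_indexer(ctl)
    proj = M @ np.linalg.solve(M.T @ M, M.T @ Y)
    resid = Y - proj
    U, _s, _vt = np.linalg.svd(resid, full_matrices=False)
    kmax = min(max_k, len(ctl))
    fullalpha = U[:, :kmax].T @ Y
    alpha = fullalpha[: design.k]
    ac = alpha[:, ctl_idx]
    W = Y[:, ctl_idx] @ ac.T @ np.linalg.inv(ac @ ac.T)
    corrected = pd.DataFrame(
        Y - W @ alpha, index=log_expr.index, columns=log_expr.columns
    )
    return (corrected, W) if return_w else corrected


def _tier_sizes(n: int) -> tuple[int, int, int]:
    # bottom/middle/top thirds; remainder goes to the bottom of the ranking
    base, rem = divmod(n, 3)
    return base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base


def build_prps(
    expr: pd.DataFrame,
    sample_meta: pd.DataFrame,
    seed: int = 0,
) -> PRPSDesign:
    """Construct pseudo-replicates of pseudo-samples from a batched cohort.

    Within each platform batch, samples are ranked by their median relative
    log expression and split into bottom/middle/top tiers. For each molecular
    subtype within each tier: 5–10 samples → one pseudo-sample averaging five
    randomly selected members (seeded); more than 10 → two pseudo-samples
    averaging the bottom five and top five ranked members; fewer than 5 →
    none. Pseudo-samples of the same subtype later serve as replicate groups
    for RUV-III.
    """
    if "batch" not in sample_meta.columns or "subtype" not in sample_meta.columns:
        raise KeyError("sample_meta must carry 'batch' and 'subtype' columns")
    missing = sample_meta.index[sample_meta["subtype"].isna()]
    if len(missing):
        raise ValueError(f"sample(s) missing a subtype label: {list(missing)}")

    rng = np.random.default_rng(seed)
    tier_rows, pseudo_rows, pseudo_meta, members = [], [], [], {}

    for batch, bidx in sample_meta.groupby("batch", observed=True).groups.items():
        sub = expr.loc[bidx]
        _rle, med = compute_rle(sub)
        order = med.sort_values(kind="mergesort").index  # ascending, stable
        n1, n2, _n3 = _tier_sizes(len(order))
        tiers = {}
        for rank, s in enumerate(order):
            tier = "bottom" if rank < n1 else ("middle" if rank < n1 + n2 else "top")
            tiers[s] = tier
            tier_rows.append({"sample": s, "batch": batch, "tier": tier,
                              "rle_median": med[s], "rank": rank})
        tier_ser = pd.Series(tiers)
        for (tier, subtype), gidx in sample_meta.loc[bidx].groupby(
            [tier_ser.loc[bidx], "subtype"], observed=True
        ).groups.items():
            ranked = [s for s in order if s in set(gidx)]
            n = len(ranked)
            if n < 5:
                continue
            if n <= 10:
                chosen = sorted(rng.choice(ranked, size=5, replace=False))
                groups = [("r", chosen)]
            else:
                groups = [("lo", ranked[:5]), ("hi", ranked[-5:])]
            for tag, sel in groups:
                pid = f"PS|{batch}|{tier}|{subtype}|{tag}"
                pseudo_rows.append(pd.Series(expr.loc[sel].mean(axis=0), name=pid))
                pseudo_meta.append(
                    {"pseudo_sample": pid, "batch": batch, "tier": tier,
                     "subtype": subtype}
                )
                members[pid] = list(sel)

    tiers_df = pd.DataFrame(tier_rows).set_index("sample")
    pseudo = pd.DataFrame(pseudo_rows) if pseudo_rows else \
        pd.DataFrame(columns=expr.columns)
    meta = pd.DataFrame(pseudo_meta).set_index("pseudo_sample") if pseudo_meta \
        else pd.DataFrame(columns=["batch", "tier", "subtype"])
    return PRPSDesign(tiers=tiers_df, pseudo_samples=pseudo, pseudo_meta=meta,
                      seed=seed, members=members)


def prps_replicate_design(
    expr: pd.DataFrame,
    prps: PRPSDesign,
    control_genes: set[str] | None = None,
    k: int = 1,
) -> tuple[pd.DataFrame, ReplicateDesign]:
    """Stack real samples with PRPS pseudo-samples and build the RUV design.

    Pseudo-samples of the same subtype form replicate groups; every real
    sample is its own singleton group, so the correction is driven entirely
    by the pseudo-replicates. ``control_genes`` defaults to all genes (the
    PRPS convention for cohort normalization).
    """
    stacked = pd.concat([expr, prps.pseudo_samples], axis=0)
    groups = pd.Series(
        [f"real|{s}" for s in expr.index]
        + [f"prps|{t}" for t in prps.pseudo_meta["subtype"]],
        index=stacked.index,
    )
    ctl = set(expr.columns) if control_genes is None else set(control_genes)
    return stacked, ReplicateDesign.from_groups(groups, ctl, k)
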