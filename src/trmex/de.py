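"""Gene-wise negative-binomial GLM differential expression and signatures.

Pseudobulk counts are modeled per gene as NB with a log link,
``log mu = X beta + offset`` where X holds one coefficient per replicate
group plus any unwanted-variation covariates W, and the offset is the log
effective library size (library size × TMM factor). Contrasts — e.g. the
target group against the average of all other groups — are tested by a
likelihood-ratio test: the model is refit under the linear constraint
``c' beta = 0`` via null-space reparameterization of the design, and twice
the log-likelihood difference is referred to chi-square(1). P values are
Benjamini–Hochberg adjusted; a gene is DE when the adjusted p is below
``de_alpha``.

Dispersions use the mean–dispersion form ``Var = mu + phi mu**2`` and are
estimated per gene by Cox–Reid adjusted profile likelihood, then shrunk
toward the trimmed mean of all estimates (weight 0.25) to stabilize genes
with few replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .pseudobulk import PseudobulkSet, tmm_factors

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "nb_loglik",
    "effective_offsets",
    "average_contrast",
    "estimate_dispersions",
    "test_contrast",
    "derive_signature",
]

_MIN_PHI = 1e-8


@dataclass
class GeneSignature:
    """Named up/down gene lists with provenance of the deriving contrasts."""

    name: str
    up_genes: list[str]
    down_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"up and down sets overlap: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB log-likelihood with Var = mu + phi mu**2; phi = 0 is Poisson."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    if phi < _MIN_PHI:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + y * np.log(phi * mu / (1.0 + phi * mu))
            - r * np.log1p(phi * mu)
        )
    )


def effective_offsets(
    pb: PseudobulkSet, use_tmm: bool = True
) -> pd.Series:
    """Log effective library sizes (library size × TMM factor) as GLM offsets."""
    lib = pb.library_sizes.astype(float)
    if use_tmm:
        lib = lib * tmm_factors(pb)
    return np.log(lib)


def average_contrast(
    groups_order: Sequence[str], target: str, exclude: Sequence[str] = ()
) -> np.ndarray:
    """Contrast of ``target`` against the average of all other groups.

    ``exclude`` names groups left out of the average (e.g. a CD103− resident
    cluster excluded from the liver contrasts); coefficients sum to zero.
    """
    groups_order = list(groups_order)
    if target not in groups_order:
        raise ValueError(f"target group {target!r} not among {groups_order}")
    others = [g for g in groups_order if g != target and g not in exclude]
    if not others:
        raise ValueError("no groups left to average against")
    c = np.zeros(len(groups_order))
    c[groups_order.index(target)] = 1.0
    for g in others:
        c[groups_order.index(g)] = -1.0 / len(others)
    return c


def _fit_gene(y, X, offset, phi, start=None):
    """One statsmodels GLM fit; returns (beta, mu, ll, converged)."""
    fam = sm.families.NegativeBinomial(alpha=phi) if phi >= _MIN_PHI \
        else sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit(
                maxiter=100, tol=1e-10, start_params=start
            )
            beta = np.asarray(res.params, dtype=float)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            return None, None, -np.inf, False
    mu = np.exp(X @ beta + offset)
    return beta, mu, nb_loglik(y, mu, phi), converged


def _design(groups: pd.Series, W: np.ndarray | None):
    levels = sorted(groups.unique())
    G = len(levels)
    X = pd.get_dummies(groups).loc[:, levels].to_numpy(dtype=float)
    if W is not None and np.size(W):
        W = np.asarray(W, dtype=float)
        X = np.hstack([X, W])
    return X, levels, G


def estimate_dispersions(
    pb: PseudobulkSet,
    covariates: np.ndarray | None = None,
    *,
    offsets: pd.Series | None = None,
    shrink_weight: float = 0.25,
    max_phi: float = 20.0,
) -> pd.Series:
    """Per-gene NB dispersion by Cox–Reid adjusted profile likelihood.

    Fitted means come from a Poisson fit of the group + covariate design
    (the mean model is nearly free of phi); the profile likelihood in phi is
    then maximized with the Cox–Reid adjustment ``-0.5 log det(X' W X)``
    penalizing the degrees of freedom spent on the mean. Estimates are shrunk
    toward the trimmed mean of all per-gene estimates with weight
    ``shrink_weight``. All-zero genes get NaN and are excluded downstream.
    """
    groups = pb.sample_meta["group"]
    X, _levels, G = _design(groups, covariates)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"{X.shape[0]} samples cannot identify {X.shape[1]} coefficients"
        )
    off = (effective_offsets(pb) if offsets is None else offsets).to_numpy(float)

    counts = pb.counts.to_numpy(dtype=float)
    phis = np.full(counts.shape[1], np.nan)
    for j in range(counts.shape[1]):
        y = counts[:, j]
        if y.sum() == 0:
            continue
        _beta, mu, _ll, ok = _fit_gene(y, X, off, 0.0)
        if not ok or mu is None:
            continue

        def neg_apl(log_phi, y=y, mu=mu):
            phi = np.exp(log_phi)
            w = mu / (1.0 + phi * mu)
            _sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            return -(nb_loglik(y, mu, phi) - 0.5 * logdet)

        res = optimize.minimize_scalar(
            neg_apl, bounds=(np.log(1e-6), np.log(max_phi)), method="bounded",
            options={"xatol": 1e-4},
        )
        phi_hat = float(np.exp(res.x))
        phis[j] = 0.0 if phi_hat < 2e-6 else phi_hat

    out = pd.Series(phis, index=pb.counts.columns, name="dispersion")
    finite = out.dropna()
    if len(finite) and shrink_weight > 0:
        center = float(stats.trim_mean(finite, 0.1))
        out[finite.index] = (1 - shrink_weight) * finite + shrink_weight * center
    return out


def test_contrast(
    pb: PseudobulkSet,
    groups: pd.Series | None = None,
    W: np.ndarray | None = None,
    contrast: np.ndarray | Sequence[float] | None = None,
    de_alpha: float = 0.05,
    *,
    dispersions: pd.Series | None = None,
    offsets: pd.Series | None = None,
    target: str | None = None,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Likelihood-ratio test of a group contrast for every gene.

    ``contrast`` is a coefficient vector over the sorted group levels and
    must sum to zero; alternatively pass ``target`` (and optionally
    ``exclude``) to build the target-vs-average-of-others contrast. Returns a
    DataFrame indexed by gene with columns ``log2fc`` (contrast applied to
    the fitted group coefficients, in log2 units), ``lr_stat``, ``p``,
    ``p_adj`` (Benjamini–Hochberg) and ``de`` (``p_adj < de_alpha``), plus a
    ``converged`` flag; non-converged NB fits fall back to Poisson.
    """
    if not 0 < de_alpha < 1:
        raise ValueError("de_alpha must be in (0, 1)")
    groups = pb.sample_meta["group"] if groups is None else groups
    X, levels, G = _design(groups, W)
    if contrast is None:
        if target is None:
            raise ValueError("provide either a contrast vector or a target group")
        contrast = average_contrast(levels, target, exclude)
    c = np.zeros(X.shape[1])
    c[:G] = np.asarray(contrast, dtype=float)
    if abs(c[:G].sum()) > 1e-10:
        raise ValueError("contrast coefficients must sum to 0")

    B = linalg.null_space(c[None, :])  # X_null = X @ B spans {c'beta = 0}
    X0 = X @ B
    off = (effective_offsets(pb) if offsets is None else offsets).to_numpy(float)
    if dispersions is None:
        dispersions = estimate_dispersions(pb, W, offsets=pd.Series(off, index=pb.counts.index))

    counts = pb.counts.to_numpy(dtype=float)
    genes = pb.counts.columns
    rows = []
    n_nonconv = n_zero = 0
    for j, g in enumerate(genes):
        y = counts[:, j]
        phi = dispersions.get(g, np.nan)
        if y.sum() == 0 or not np.isfinite(phi):
            n_zero += 1
            continue
        beta, mu, ll1, ok1 = _fit_gene(y, X, off, phi)
        if not ok1:
            phi = 0.0
            beta, mu, ll1, ok1 = _fit_gene(y, X, off, phi)
            n_nonconv += 1
            if not ok1:
                continue
        start0 = None if beta is None else linalg.lstsq(B, beta)[0]
        b0, mu0, ll0, ok0 = _fit_gene(y, X0, off, phi, start=start0)
        if not ok0 or b0 is None:
            b0, mu0, ll0, ok0 = _fit_gene(y, X0, off, phi)
            if not ok0:
                continue
        lr = max(2.0 * (ll1 - ll0), 0.0)
        rows.append(
            {
                "gene": g,
                "log2fc": float(c @ beta) / np.log(2.0),
                "lr_stat": lr,
                "p": float(stats.chi2.sf(lr, df=1)),
                "converged": ok1 and ok0,
            }
        )
    if n_zero:
        logger.info("test_contrast: skipped %d all-zero/unestimable genes", n_zero)
    if n_nonconv:
        logger.info("test_contrast: %d NB fits fell back to Poisson", n_nonconv)
    if not rows:
        raise ValueError("no gene could be tested")

    res = pd.DataFrame(rows).set_index("gene")
    res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
    res["de"] = res["p_adj"] < de_alpha
    return res[["log2fc", "lr_stat", "p", "p_adj", "de", "converged"]]


def derive_signature(
    stage1: pd.DataFrame,
    stage2: pd.DataFrame,
    de_alpha: float = 0.05,
    *,
    name: str = "signature",
    mode: str = "intersection",
) -> GeneSignature:
    """Two-stage signature: subset-vs-rest then head-to-head DE, sign-concordant.

    ``stage1`` is the contrast of the subset against the average of the other
    groups, ``stage2`` the direct contrast between the two subsets being
    deconvoluted (e.g. TRM vs TEX). Under the default ``intersection`` mode a
    gene enters ``up_genes`` iff it is up-DE in both stages (and ``down``
    analogously); ``union`` keeps genes DE in either stage provided signs
    never conflict; ``stage2_only`` ignores stage 1.
    """
    shared = stage1.index.intersection(stage2.index)
    if shared.empty:
        raise ValueError("stage1 and stage2 share no genes")
    s1, s2 = stage1.loc[shared], stage2.loc[shared]

    de1_up = s1["de"] & (s1["log2fc"] > 0)
    de1_dn = s1["de"] & (s1["log2fc"] < 0)
    de2_up = s2["de"] & (s2["log2fc"] > 0)
    de2_dn = s2["de"] & (s2["log2fc"] < 0)
    if mode == "intersection":
        up, dn = de1_up & de2_up, de1_dn & de2_dn
    elif mode == "union":
        up = (de1_up | de2_up) & ~(de1_dn | de2_dn)
        dn = (de1_dn | de2_dn) & ~(de1_up | de2_up)
    elif mode == "stage2_only":
        up, dn = de2_up, de2_dn
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sig = GeneSignature(
        name=name,
        up_genes=sorted(shared[up]),
        down_genes=sorted(shared[dn]),
        provenance={
            "mode": mode,
            "de_alpha": de_alpha,
            "n_genes_stage1": int(len(stage1)),
            "n_genes_stage2": int(len(stage2)),
        },
    )
    if not sig.up_genes and not sig.down_genes:
        warnings.warn(f"signature {name!r} is empty: no gene passed both stages")
    return sig
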