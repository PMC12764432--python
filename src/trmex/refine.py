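"""Cross-dataset signature refinement and running-sum gene-set enrichment.

Two signatures of the same phenotype derived in different tumor types (e.g.
breast and liver TRM) are merged into a "pancancer" signature by a
concordance rule on the two differential-expression tables: a gene survives
if it is DE in both datasets with the same sign, or DE in one with a
same-sign log2 fold change of magnitude above a threshold in the other.

Enrichment of a gene set in a ranked list (typically genes ranked by log2FC)
uses the weighted Kolmogorov–Smirnov running-sum statistic with a
gene-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import GeneSignature

__all__ = ["EnrichmentResult", "refine_pancancer_signature", "gsea_running_sum"]


@dataclass
class EnrichmentResult:
    """Enrichment score in [-1, 1], permutation p value and leading edge."""

    es: float
    p_perm: float
    leading_edge: list[str]
    n_permutations: int


def _refine_direction(
    genes: set[str],
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    sign: int,
    fc_threshold: float,
) -> list[str]:
    kept = []
    for g in sorted(genes):
        in_a, in_b = g in de_a.index, g in de_b.index
        if not (in_a and in_b):
            warnings.warn(f"gene {g!r} lacks a log2FC in one dataset; skipped")
            continue
        fa, fb = de_a.loc[g, "log2fc"], de_b.loc[g, "log2fc"]
        da = bool(de_a.loc[g, "de"]) and sign * fa > 0
        db = bool(de_b.loc[g, "de"]) and sign * fb > 0
        if da and db:
            kept.append(g)
        elif da and sign * fb > fc_threshold:
            kept.append(g)
        elif db and sign * fa > fc_threshold:
            kept.append(g)
    return kept


def refine_pancancer_signature(
    sig_a: GeneSignature,
    de_a: pd.DataFrame,
    sig_b: GeneSignature,
    de_b: pd.DataFrame,
    fc_threshold: float = 0.5,
    *,
    name: str | None = None,
) -> GeneSignature:
    """Merge two same-phenotype signatures by cross-dataset concordance.

    Candidate up genes are the union of the two up lists (down analogously);
    a candidate is kept iff it is (a) concordantly DE in both datasets or
    (b) DE in one with a same-sign |log2FC| strictly above ``fc_threshold``
    in the other. Symmetric in the two inputs.
    """
    up = _refine_direction(
        set(sig_a.up_genes) | set(sig_b.up_genes), de_a, de_b, +1, fc_threshold
    )
    down = _refine_direction(
        set(sig_a.down_genes) | set(sig_b.down_genes), de_a, de_b, -1, fc_threshold
    )
    return GeneSignature(
        name=name or f"{sig_a.name}+{sig_b.name}_refined",
        up_genes=up,
        down_genes=down,
        provenance={
            "rule": "concordant-DE or DE-with-concordant-FC",
            "fc_threshold": fc_threshold,
            "inputs": [sig_a.name, sig_b.name],
        },
    )


def _running_sum(order_scores: np.ndarray, hit: np.ndarray, p: float) -> np.ndarray:
    """Per-position increments of the weighted KS running sum."""
    n = len(order_scores)
    nh = int(hit.sum())
    w = np.abs(order_scores) ** p if p != 0 else np.ones(n)
    inc = np.where(hit, w, 0.0)
    denom = inc.sum()
    if denom == 0:  # all hit scores exactly zero: fall back to equal weights
        inc = hit.astype(float)
        denom = nh
    inc = inc / denom
    inc[~hit] = -1.0 / (n - nh)
    return np.cumsum(inc)


def gsea_running_sum(
    ranking: pd.Series,
    gene_set: list[str] | set[str],
    weight_exponent: float = 1.0,
    n_permutations: int = 999,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted running-sum enrichment of ``gene_set`` in a ranked list.

    ``ranking`` maps gene id to score (e.g. log2FC); genes are ordered by
    decreasing score with ties broken by gene id. The enrichment score ES is
    the signed maximum deviation of the running sum (set members step up by
    |score|^weight_exponent, normalized; non-members step down by
    1/(N - n_set)). The p value counts gene-label permutations whose |ES|
    reaches the observed one, with the +1 pseudo-count convention. The
    leading edge is the set members at or before the extremum (after it for
    negative ES).
    """
    ranking = ranking.sort_index().sort_values(ascending=False, kind="mergesort")
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no overlap with the ranking")
    if nh == len(genes):
        raise ValueError("gene set equals the whole ranking; ES is degenerate")

    run = _running_sum(scores, hit, weight_exponent)
    i_ext = int(np.argmax(np.abs(run)))
    es = float(run[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]

    rng = np.random.default_rng(seed)
    n = len(genes)
    n_ge = 0
    chunk = max(1, min(n_permutations, int(2e6 // max(n, 1))))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        # b random membership vectors of nh hits each
        pos = np.argsort(rng.random((b, n)), axis=1)[:, :nh]
        hits = np.zeros((b, n), dtype=bool)
        np.put_along_axis(hits, pos, True, axis=1)
        if weight_exponent != 0:
            w = np.abs(scores)[None, :] ** weight_exponent
            inc = np.where(hits, w, 0.0)
        else:
            inc = hits.astype(float)
        denom = inc.sum(axis=1, keepdims=True)
        denom[denom == 0] = nh
        inc = inc / denom
        inc[~hits] = -1.0 / (n - nh)
        runs = np.cumsum(inc, axis=1)
        es_perm = np.take_along_axis(
            runs, np.argmax(np.abs(runs), axis=1)[:, None], axis=1
        )[:, 0]
        n_ge += int(np.sum(np.abs(es_perm) >= abs(es)))
        done += b
    p_perm = (1.0 + n_ge) / (1.0 + n_permutations)
    return EnrichmentResult(
        es=es, p_perm=float(p_perm), leading_edge=leading,
        n_permutations=n_permutations,
    )
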