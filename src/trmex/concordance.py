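"""Cross-study log2 fold-change concordance and Fisher's exact test.

Fold-change estimates for the same contrast from independent studies (e.g.
tissue-residency contrasts from skin, gut and liver pooled against an
exhaustion contrast) are compared by cross-classifying the signs of each
gene's log2FC in the two studies into a 2×2 table and testing association
with Fisher's exact test. The two-sided p value follows the
point-probability convention: the sum of hypergeometric probabilities of
all tables (with the observed margins) no more probable than the observed
one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

logger = logging.getLogger(__name__)

__all__ = ["ContingencyTable2x2", "pooled_log2fc", "fisher_exact_2x2",
           "concordance_fisher"]


@dataclass
class ContingencyTable2x2:
    """Sign-concordance counts: rows = sign in study A, columns = study B.

    ``a`` = up/up, ``b`` = up/down, ``c`` = down/up, ``d`` = down/down.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def pooled_log2fc(tables: list[pd.DataFrame]) -> pd.Series:
    """Gene-wise mean log2FC over the tables in which the gene appears."""
    if not tables:
        raise ValueError("at least one differential result is required")
    stacked = pd.concat([t["log2fc"] for t in tables], axis=1)
    return stacked.mean(axis=1, skipna=True).dropna().rename("log2fc")


def fisher_exact_2x2(
    table: ContingencyTable2x2, rel_tol: float = 1e-10
) -> tuple[float, float]:
    """Two-sided Fisher exact p and conditional odds ratio for a 2×2 table.

    The p value sums hypergeometric point probabilities over all tables with
    the observed margins whose probability does not exceed the observed
    table's (a relative tolerance absorbs floating-point ties). The odds
    ratio is the conditional maximum-likelihood estimate.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    if n == 0:
        raise ValueError("empty contingency table")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    p = min(p, 1.0)
    orat = float(_conditional_or(table.as_array()).statistic)
    return p, orat


def concordance_fisher(
    fc_a: pd.Series,
    fc_b: pd.Series,
    gene_subset: list[str] | set[str] | None = None,
) -> tuple[ContingencyTable2x2, float, float]:
    """Cross-classify log2FC signs of two studies and test association.

    Genes with a log2FC of exactly zero in either study have no sign and are
    excluded (counted in the log). ``gene_subset`` restricts the comparison,
    e.g. to a published core residency signature. Returns the 2×2 table, the
    conditional odds ratio and the two-sided Fisher exact p value.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(sorted(set(gene_subset))))
    if shared.empty:
        raise ValueError("no genes shared between the two studies (after subset)")
    x, y = fc_a.loc[shared], fc_b.loc[shared]
    nonzero = (x != 0) & (y != 0)
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("concordance_fisher: %d gene(s) with zero log2FC excluded",
                    n_dropped)
    x, y = x[nonzero], y[nonzero]
    table = ContingencyTable2x2(
        a=int(((x > 0) & (y > 0)).sum()),
        b=int(((x > 0) & (y < 0)).sum()),
        c=int(((x < 0) & (y > 0)).sum()),
        d=int(((x < 0) & (y < 0)).sum()),
    )
    p, orat = fisher_exact_2x2(table)
    return table, orat, p
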