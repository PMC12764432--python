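"""TCR clonotype construction, overlap statistics and viral annotation.

A clonotype is the joined alpha and beta CDR3 nucleotide sequence of a cell.
Contigs are reduced to one per chain per cell by the highest UMI count;
cells annotated with more than one distinct beta chain are excluded as
doublets before that retention step. Clone sizes are donor-scoped (public
clonotypes across donors are not assumed). Overlap between subsets is
summarized by shared-clone counts at minimum-cell cutoffs and by the Jaccard
dissimilarity (1 − Jaccard index) of expanded-clone sets. Putative
virus-specific clones are called by the minimum Levenshtein distance of
their CDR3 amino-acid sequences to a reference table of published
virus-specific TCRs, restricted to references whose HLA allele the donor
carries; the default threshold flags distances strictly below 1, i.e. exact
matches only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClonotypeTable",
    "build_clonotypes",
    "expanded_clones",
    "jaccard_dissimilarity",
    "shared_clonotype_counts",
    "annotate_viral",
    "clone_composition",
]

_CHAINS = {"TRA", "TRB"}
_CELL_COLUMNS = [
    "cell_id", "clonotype_key", "cdr3a_nt", "cdr3b_nt", "cdr3a_aa",
    "cdr3b_aa", "subset", "tissue", "donor",
]


@dataclass
class ClonotypeTable:
    """Per-cell clonotype assignments with subset/tissue/donor labels.

    ``cells`` has one row per cell with the columns in ``_CELL_COLUMNS``.
    Clone sizes are computed within donor (see :meth:`clone_sizes`).
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"clonotype table lacks columns: {missing}")

    def __len__(self) -> int:
        return len(self.cells)

    def clone_sizes(self, scope: str = "donor") -> pd.Series:
        """Cells per clonotype; keys are (donor, clonotype_key) when donor-scoped."""
        if scope == "donor":
            return self.cells.groupby(
                ["donor", "clonotype_key"], observed=True
            ).size()
        if scope == "global":
            return self.cells.groupby("clonotype_key", observed=True).size()
        raise ValueError(f"unknown scope {scope!r}")

    def to_contigs(self, seed: int = 0) -> pd.DataFrame:
        """Emit a contig table (one TRA and one TRB row per cell)."""
        rng = np.random.default_rng(seed)
        rows = []
        for r in self.cells.itertuples():
            for chain, nt, aa in (
                ("TRA", r.cdr3a_nt, r.cdr3a_aa),
                ("TRB", r.cdr3b_nt, r.cdr3b_aa),
            ):
                rows.append(
                    {"cell_id": r.cell_id, "chain": chain, "cdr3_nt": nt,
                     "cdr3_aa": aa, "umis": int(rng.integers(1, 20))}
                )
        return pd.DataFrame(rows)


def build_clonotypes(
    contigs: pd.DataFrame, cell_meta: pd.DataFrame
) -> ClonotypeTable:
    """Collapse contigs to one clonotype per cell and attach cell metadata.

    Cells annotated with more than one distinct beta-chain CDR3 are excluded
    as doublets before any retention; then, per cell per chain, the contig
    with the highest UMI count is kept (ties broken by CDR3 nt, ascending).
    Cells lacking either chain are dropped. ``cell_meta`` is indexed by cell
    id and carries ``subset``, ``tissue`` and ``donor``.
    """
    required = {"cell_id", "chain", "cdr3_nt", "cdr3_aa", "umis"}
    if not required.issubset(contigs.columns):
        raise ValueError(f"contig table lacks columns: {required - set(contigs.columns)}")
    bad = contigs.loc[~contigs["chain"].isin(_CHAINS)]
    if len(bad):
        raise ValueError(
            f"unknown chain label(s) in contig rows: {bad.index.tolist()[:5]}"
        )

    # doublet rule first, on raw annotations
    n_beta = (
        contigs[contigs["chain"] == "TRB"]
        .groupby("cell_id")["cdr3_nt"].nunique()
    )
    doublets = set(n_beta.index[n_beta > 1])
    if doublets:
        logger.info("build_clonotypes: excluded %d doublet cell(s)", len(doublets))
    keep = contigs[~contigs["cell_id"].isin(doublets)]

    # highest-UMI contig per cell per chain
    best = (
        keep.sort_values(["cell_id", "chain", "umis", "cdr3_nt"],
                         ascending=[True, True, False, True])
        .drop_duplicates(["cell_id", "chain"], keep="first")
    )
    if best.empty:
        return ClonotypeTable(pd.DataFrame(columns=_CELL_COLUMNS))
    wide = best.pivot(index="cell_id", columns="chain",
                      values=["cdr3_nt", "cdr3_aa"])
    wide = wide.reindex(
        columns=pd.MultiIndex.from_product([["cdr3_nt", "cdr3_aa"],
                                            ["TRA", "TRB"]])
    )
    has_both = wide.notna().all(axis=1)
    wide = wide.loc[has_both]

    rows = pd.DataFrame(
        {
            "cell_id": wide.index,
            "cdr3a_nt": wide[("cdr3_nt", "TRA")].to_numpy(),
            "cdr3b_nt": wide[("cdr3_nt", "TRB")].to_numpy(),
            "cdr3a_aa": wide[("cdr3_aa", "TRA")].to_numpy(),
            "cdr3b_aa": wide[("cdr3_aa", "TRB")].to_numpy(),
        }
    )
    rows["clonotype_key"] = rows["cdr3a_nt"] + "_" + rows["cdr3b_nt"]
    meta = cell_meta.reindex(rows["cell_id"])
    for col in ("subset", "tissue", "donor"):
        rows[col] = meta[col].to_numpy() if col in meta.columns else "NA"
    return ClonotypeTable(rows.reset_index(drop=True)[_CELL_COLUMNS])


def expanded_clones(
    ct: ClonotypeTable, min_cells: int = 2, scope: str = "donor"
):
    """Clonotypes found in ``min_cells`` or more cells (default: two or more)."""
    sizes = ct.clone_sizes(scope=scope)
    return set(sizes.index[sizes >= min_cells])


def jaccard_dissimilarity(set_a, set_b) -> float:
    """1 − |A∩B| / |A∪B| between two clonotype-key sets."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("both clonotype sets are empty; dissimilarity undefined")
    return 1.0 - len(a & b) / len(union)


def shared_clonotype_counts(
    ct: ClonotypeTable,
    subsets: Sequence[str],
    min_overlap_cells: int = 1,
) -> dict[tuple[str, ...], int]:
    """Exclusive (UpSet-style) shared-clone counts per subset combination.

    A clonotype belongs to the combination of exactly those subsets in which
    it has at least ``min_overlap_cells`` cells; the count of clonotypes is
    reported for every non-empty combination.
    """
    unknown = set(ct.cells["subset"]) - set(subsets)
    if unknown:
        raise ValueError(f"unknown subset label(s): {sorted(unknown)}")
    per = ct.cells.groupby(
        ["donor", "clonotype_key", "subset"], observed=True
    ).size().unstack(fill_value=0)
    out: dict[tuple[str, ...], int] = {}
    for _, row in per.iterrows():
        combo = tuple(s for s in subsets if row.get(s, 0) >= min_overlap_cells)
        if combo:
            out[combo] = out.get(combo, 0) + 1
    return out


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def annotate_viral(
    ct: ClonotypeTable,
    refs: pd.DataFrame,
    donor_hla: Mapping[str, Sequence[str]],
    max_distance: float = 1.0,
    *,
    inclusive: bool = False,
    chain_combine: str = "max",
) -> pd.DataFrame:
    """Edit-distance annotation of clones against virus-specific references.

    For each (donor, clonotype), candidate references are restricted to
    entries whose HLA allele the donor carries; the per-entry distance is the
    Levenshtein distance of the CDR3 amino-acid sequences, combining the two
    chains by ``max`` (both must match closely; ``sum`` and ``min``
    configurable), single-chain references using that chain alone. The clone
    distance is the minimum over candidates; the viral flag is
    ``distance < max_distance`` (or ``<=`` with ``inclusive``), so the
    default 1.0 admits exact matches only. Clones of donors without an HLA
    record are skipped with a warning.

    Returns one row per (donor, clonotype_key) with columns ``min_distance``,
    ``species`` (of the nearest reference) and ``viral``.
    """
    if chain_combine not in {"max", "sum", "min"}:
        raise ValueError(f"unknown chain_combine {chain_combine!r}")
    combine = {"max": max, "sum": lambda a, b: a + b, "min": min}[chain_combine]

    clones = ct.cells.drop_duplicates(["donor", "clonotype_key"])[
        ["donor", "clonotype_key", "cdr3a_aa", "cdr3b_aa"]
    ]
    rows = []
    for r in clones.itertuples():
        if r.donor not in donor_hla:
            warnings.warn(f"donor {r.donor!r} has no HLA record; clone skipped")
            continue
        alleles = set(donor_hla[r.donor])
        best, species = np.inf, None
        for ref in refs.itertuples():
            if ref.hla not in alleles:
                continue
            da = _edit_distance(r.cdr3a_aa, ref.cdr3a_aa) \
                if isinstance(ref.cdr3a_aa, str) and ref.cdr3a_aa else None
            db = _edit_distance(r.cdr3b_aa, ref.cdr3b_aa) \
                if isinstance(ref.cdr3b_aa, str) and ref.cdr3b_aa else None
            if da is None and db is None:
                continue
            d = combine(da, db) if da is not None and db is not None \
                else (da if da is not None else db)
            if d < best:
                best, species = d, ref.species
        viral = bool(best <= max_distance if inclusive else best < max_distance)
        rows.append(
            {"donor": r.donor, "clonotype_key": r.clonotype_key,
             "min_distance": best, "species": species if viral else None,
             "viral": viral}
        )
    return pd.DataFrame(
        rows, columns=["donor", "clonotype_key", "min_distance", "species",
                       "viral"],
    )


def clone_composition(
    ct: ClonotypeTable,
    top_n: int = 100,
    *,
    row_scaled: bool = True,
    scope: str = "donor",
) -> pd.DataFrame:
    """Subset composition of the top expanded clones.

    The ``top_n`` largest expanded clones (size >= 2; ties broken by
    lexicographically smaller key) are selected; each row gives the clone's
    cell distribution over subsets, as percentages summing to 100 when
    ``row_scaled``.
    """
    sizes = ct.clone_sizes(scope=scope)
    sizes = sizes[sizes >= 2]
    if len(sizes) < top_n:
        logger.info(
            "clone_composition: only %d expanded clones (< top_n=%d)",
            len(sizes), top_n,
        )
    order = sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    keys = [k for k, _ in order]

    if scope == "donor":
        grouped = ct.cells.groupby(
            ["donor", "clonotype_key", "subset"], observed=True
        ).size().unstack(fill_value=0)
    else:
        grouped = ct.cells.groupby(
            ["clonotype_key", "subset"], observed=True
        ).size().unstack(fill_value=0)
    comp = grouped.loc[keys].astype(float)
    if row_scaled:
        comp = comp.div(comp.sum(axis=1), axis=0) * 100.0
    return comp
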