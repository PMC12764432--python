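"""Synthetic single-cell, bulk and TCR data with planted ground truth.

Every generator here emulates the statistical structure of the real assays the
downstream stages consume — donor/batch effects, subset-specific differential
expression with negative-binomial noise, clone-size-skewed paired-chain TCR
repertoires with planted virus-specific clones — so the whole pipeline can be
exercised and scored against a known :class:`SyntheticTruth` without any
external download.

Counts follow the mean–dispersion NB parameterization ``Var = mu + phi*mu**2``
(``phi = 0`` collapses to Poisson), matching the count model used for
differential expression. Library sizes are lognormal (sigma 0.3) so that
between-sample scaling factors are nontrivial but bounded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTruth",
    "simulate_cells",
    "simulate_repertoire",
    "simulate_bulk_batches",
]

# sense-strand codons excluding stop codons, with the standard translation
_CODON_TO_AA = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
_CODONS = sorted(_CODON_TO_AA)
_AA_ALPHABET = sorted(set(_CODON_TO_AA.values()))
_AA_TO_CODON = {aa: min(c for c, a in _CODON_TO_AA.items() if a == aa)
                for aa in _AA_ALPHABET}

_HLA_POOL = ("A*01:01", "A*02:01", "B*07:02", "B*08:01", "B*35:01")
_SPECIES_POOL = ("CMV", "EBV", "InfluenzaA")


def translate_cdr3(nt: str) -> str:
    """Translate an in-frame CDR3 nucleotide string with the standard table."""
    if len(nt) % 3:
        raise ValueError(f"CDR3 nt length {len(nt)} is not a multiple of 3")
    return "".join(_CODON_TO_AA[nt[i:i + 3]] for i in range(0, len(nt), 3))


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    ``planted_up_genes`` / ``planted_down_genes`` map each subset label to the
    gene ids whose mean was shifted up / down in that subset.
    ``planted_log2fc`` maps each subset to a ``{gene: signed log2 effect}``
    dict. ``control_genes`` are guaranteed non-DE in every subset (they may
    still carry donor or batch effects — that is what normalization removes).
    ``viral_clonotypes`` holds ``(donor, clonotype_key)`` pairs planted as
    exact (edit distance 0) copies of reference CDR3s;
    ``near_viral_clonotypes`` the distance-1 mutants.
    """

    seed: int
    planted_up_genes: dict[str, set[str]] = field(default_factory=dict)
    planted_down_genes: dict[str, set[str]] = field(default_factory=dict)
    planted_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    donor_effects: pd.DataFrame | None = None
    control_genes: set[str] = field(default_factory=set)
    viral_clonotypes: set[tuple[str, str]] = field(default_factory=set)
    near_viral_clonotypes: set[tuple[str, str]] = field(default_factory=set)
    subset_labels: pd.Series | None = None
    batch_labels: pd.Series | None = None
    batch_shifts: dict[str, float] = field(default_factory=dict)
    clone_home_subset: dict[str, str] = field(default_factory=dict)


def _plant_gene_sets(
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    subsets: Sequence[str],
    n_de: int,
    n_controls: int,
    effect: float,
) -> tuple[dict, dict, dict, set]:
    """Reserve disjoint up/down sets per subset plus a control set."""
    need = 2 * n_de * len(subsets) + n_controls
    if need > len(gene_ids):
        raise ValueError(
            f"n_genes={len(gene_ids)} too small for {need} planted + control genes"
        )
    chosen = rng.choice(len(gene_ids), size=need, replace=False)
    it = iter(chosen)
    up, down, lfc = {}, {}, {}
    for s in subsets:
        up[s] = {gene_ids[next(it)] for _ in range(n_de)}
        down[s] = {gene_ids[next(it)] for _ in range(n_de)}
        lfc[s] = {g: effect for g in up[s]}
        lfc[s].update({g: -effect for g in down[s]})
    controls = {gene_ids[i] for i in itertools.islice(it, n_controls)}
    return up, down, lfc, controls


def simulate_cells(
    n_donors: int = 4,
    n_cells_per_donor: int = 300,
    subsets: Sequence[str] = ("TRM", "TEX", "TEM", "TCM", "TN"),
    n_genes: int = 2000,
    effect_log2fc: float = 1.0,
    dispersion: float = 0.4,
    seed: int = 0,
    *,
    n_tissues: int = 1,
    n_de_per_subset: int = 40,
    n_control_genes: int = 200,
    donor_sd: float = 0.15,
    mean_library_size: float = 3000.0,
    library_sigma: float = 0.3,
    plant_seed: int | None = None,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate a single-cell count matrix with planted subset DE genes.

    Cells are split evenly over ``n_tissues`` tissue sites and ``subsets``
    within each donor. Gene baseline abundances are lognormal; each subset's
    planted up/down genes are shifted by ``±effect_log2fc`` (log2 units); each
    donor adds an independent N(0, donor_sd) log2 shift per gene (the unwanted
    variation the replicate-based normalization stage removes). Counts are NB
    with ``Var = mu + dispersion*mu**2``.

    ``plant_seed`` seeds the choice of planted/control gene sets separately
    from the noise, so two datasets simulated with different ``seed`` but a
    common ``plant_seed`` share the same planted biology — the situation
    cross-dataset signature refinement assumes.

    Returns an :class:`anndata.AnnData` (cells × genes, raw counts, obs
    columns ``donor``/``tissue``/``subset``) and the :class:`SyntheticTruth`.
    """
    if n_donors < 1 or n_cells_per_donor < 1 or n_genes < 1:
        raise ValueError("n_donors, n_cells_per_donor and n_genes must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not subsets:
        raise ValueError("at least one subset label is required")

    rng = np.random.default_rng(seed)
    plant_rng = rng if plant_seed is None else np.random.default_rng(plant_seed)
    gene_ids = [f"GENE{i:05d}" for i in range(n_genes)]
    donors = [f"D{d + 1}" for d in range(n_donors)]
    tissues = [f"T{t + 1}" for t in range(n_tissues)]

    up, down, lfc, controls = _plant_gene_sets(
        plant_rng, gene_ids, subsets, n_de_per_subset, n_control_genes,
        effect_log2fc,
    )

    # baseline relative abundance per gene (sums to 1)
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    base /= base.sum()

    # donor x gene additive log2 shifts
    donor_eff = rng.normal(0.0, donor_sd, size=(n_donors, n_genes))

    # per-subset multiplicative effect vectors
    subset_mult = {}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for s in subsets:
        mult = np.ones(n_genes)
        for g, e in lfc[s].items():
            mult[gene_index[g]] = 2.0 ** e
        subset_mult[s] = mult

    # even assignment of cells to tissue x subset blocks within each donor
    blocks = [(t, s) for t in tissues for s in subsets]
    obs_rows = []
    for d in donors:
        for i in range(n_cells_per_donor):
            t, s = blocks[i % len(blocks)]
            obs_rows.append((d, t, s))
    obs = pd.DataFrame(obs_rows, columns=["donor", "tissue", "subset"])
    obs.index = [f"CELL{i:06d}" for i in range(len(obs))]

    lib = rng.lognormal(np.log(mean_library_size), library_sigma, size=len(obs))

    donor_idx = obs["donor"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    mu = base[None, :] * (2.0 ** donor_eff)[donor_idx, :]
    mult_mat = np.stack([subset_mult[s] for s in obs["subset"]])
    mu = mu * mult_mat * lib[:, None]

    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    adata = ad.AnnData(
        X=counts.astype(np.int32),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    truth = SyntheticTruth(
        seed=seed,
        planted_up_genes=up,
        planted_down_genes=down,
        planted_log2fc=lfc,
        donor_effects=pd.DataFrame(donor_eff, index=donors, columns=gene_ids),
        control_genes=controls,
        subset_labels=obs["subset"].copy(),
    )
    return adata, truth


def _random_cdr3_nt(rng: np.random.Generator) -> str:
    n_codons = int(rng.integers(10, 17))  # nt length 30..48
    return "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons))


def _reverse_translate(aa: str) -> str:
    return "".join(_AA_TO_CODON[a] for a in aa)


def _mutate_one_aa(rng: np.random.Generator, aa: str) -> str:
    pos = int(rng.integers(0, len(aa)))
    repl = [a for a in _AA_ALPHABET if a != aa[pos]]
    return aa[:pos] + repl[int(rng.integers(0, len(repl)))] + aa[pos + 1:]


def simulate_repertoire(
    n_cells_per_subset: Mapping[str, int],
    clone_size_alpha: float = 2.0,
    n_viral_refs: int = 30,
    viral_fraction: float = 0.1,
    seed: int = 0,
    *,
    n_donors: int = 4,
    subset_bias: float = 0.8,
    n_tissues: int = 1,
):
    """Simulate a paired-chain TCR repertoire with planted viral clones.

    Clone sizes are Zipf-distributed with exponent ``clone_size_alpha``; each
    clone lives in one donor (no public clonotypes) and has a "home" subset it
    preferentially occupies (probability ``subset_bias``), emulating the
    preferential adoption of one phenotype per clone. A ``viral_fraction`` of
    clones is planted from a reference CDR3 table: half as exact copies of a
    reference alpha/beta pair (edit distance 0) and half with one amino-acid
    substitution in the beta chain (edit distance 1), so the behavior of the
    annotation threshold at the 0/1 boundary is directly testable. Donors of
    planted clones carry the reference's HLA allele.

    Returns ``(clonotype_table, reference_table, truth)``; import
    :class:`trmex.tcr.ClonotypeTable` holds per-cell rows, and
    ``reference_table`` is a DataFrame with columns
    ``cdr3a_aa, cdr3b_aa, hla, species``.
    """
    from .tcr import ClonotypeTable  # local import to avoid a cycle

    if not 0.0 <= viral_fraction <= 1.0:
        raise ValueError("viral_fraction must be in [0, 1]")
    if clone_size_alpha <= 1.0:
        raise ValueError("clone_size_alpha must be > 1 for a proper power law")
    if not n_cells_per_subset:
        raise ValueError("n_cells_per_subset must name at least one subset")

    rng = np.random.default_rng(seed)
    subsets = list(n_cells_per_subset)
    total_cells = int(sum(n_cells_per_subset.values()))
    if total_cells < 1:
        raise ValueError("total cell count must be positive")

    donors = [f"D{d + 1}" for d in range(n_donors)]
    donor_hla = {
        d: sorted(rng.choice(_HLA_POOL, size=2, replace=False)) for d in donors
    }

    # reference table of published virus-specific CDR3 pairs
    refs = pd.DataFrame(
        {
            "cdr3a_aa": [
                translate_cdr3(_random_cdr3_nt(rng)) for _ in range(n_viral_refs)
            ],
            "cdr3b_aa": [
                translate_cdr3(_random_cdr3_nt(rng)) for _ in range(n_viral_refs)
            ],
            "hla": [
                _HLA_POOL[int(rng.integers(0, len(_HLA_POOL)))]
                for _ in range(n_viral_refs)
            ],
            "species": [
                _SPECIES_POOL[int(rng.integers(0, len(_SPECIES_POOL)))]
                for _ in range(n_viral_refs)
            ],
        }
    )

    # clone sizes: truncated Zipf, accumulated to cover the requested cells
    sizes: list[int] = []
    while sum(sizes) < total_cells:
        s = int(rng.zipf(clone_size_alpha))
        sizes.append(min(s, 50))
    sizes[-1] -= sum(sizes) - total_cells
    if sizes[-1] == 0:
        sizes.pop()
    n_clones = len(sizes)

    # per-clone identity
    weights = np.array([n_cells_per_subset[s] for s in subsets], dtype=float)
    weights /= weights.sum()
    home = rng.choice(len(subsets), size=n_clones, p=weights)
    clone_donor = [donors[int(i)] for i in rng.integers(0, n_donors, n_clones)]

    n_viral = int(round(viral_fraction * n_clones))
    viral_clone_idx = rng.choice(n_clones, size=n_viral, replace=False)
    exact_idx = set(viral_clone_idx[: (n_viral + 1) // 2].tolist())
    mutant_idx = set(viral_clone_idx[(n_viral + 1) // 2:].tolist())

    clone_rows = []
    for ci in range(n_clones):
        if ci in exact_idx or ci in mutant_idx:
            ref = refs.iloc[int(rng.integers(0, n_viral_refs))]
            a_aa, b_aa = ref["cdr3a_aa"], ref["cdr3b_aa"]
            if ci in mutant_idx:
                b_aa = _mutate_one_aa(rng, b_aa)
            a_nt, b_nt = _reverse_translate(a_aa), _reverse_translate(b_aa)
            # the planted clone's donor must carry the reference HLA
            d = clone_donor[ci]
            if ref["hla"] not in donor_hla[d]:
                donor_hla[d] = sorted(donor_hla[d] + [ref["hla"]])
        else:
            a_nt, b_nt = _random_cdr3_nt(rng), _random_cdr3_nt(rng)
            a_aa, b_aa = translate_cdr3(a_nt), translate_cdr3(b_nt)
        clone_rows.append((a_nt, b_nt, a_aa, b_aa))

    # fill subset slots: home subset while available, else any remaining
    slots = {s: int(n_cells_per_subset[s]) for s in subsets}
    cells = []
    cid = 0
    tissues = [f"T{t + 1}" for t in range(n_tissues)]
    for ci, size in enumerate(sizes):
        a_nt, b_nt, a_aa, b_aa = clone_rows[ci]
        key = f"{a_nt}_{b_nt}"
        for _ in range(size):
            want = subsets[int(home[ci])]
            if slots.get(want, 0) <= 0 or rng.random() > subset_bias:
                avail = [s for s in subsets if slots[s] > 0]
                if not avail:
                    break
                want = avail[int(rng.integers(0, len(avail)))]
            slots[want] -= 1
            cells.append(
                {
                    "cell_id": f"TCELL{cid:06d}",
                    "clonotype_key": key,
                    "cdr3a_nt": a_nt,
                    "cdr3b_nt": b_nt,
                    "cdr3a_aa": a_aa,
                    "cdr3b_aa": b_aa,
                    "subset": want,
                    "tissue": tissues[int(rng.integers(0, n_tissues))],
                    "donor": clone_donor[ci],
                }
            )
            cid += 1

    table = ClonotypeTable(pd.DataFrame(cells))
    truth = SyntheticTruth(
        seed=seed,
        viral_clonotypes={
            (clone_donor[ci], f"{clone_rows[ci][0]}_{clone_rows[ci][1]}")
            for ci in exact_idx
        },
        near_viral_clonotypes={
            (clone_donor[ci], f"{clone_rows[ci][0]}_{clone_rows[ci][1]}")
            for ci in mutant_idx
        },
        clone_home_subset={
            f"{clone_rows[ci][0]}_{clone_rows[ci][1]}": subsets[int(home[ci])]
            for ci in range(n_clones)
        },
    )
    truth.donor_hla = donor_hla  # type: ignore[attr-defined]
    return table, refs, truth


def simulate_bulk_batches(
    n_samples: int = 60,
    n_batches: int = 3,
    subtype_labels: Sequence[str] = ("LumA", "LumB", "Her2", "Basal"),
    batch_shift: float = 2.0,
    seed: int = 0,
    *,
    n_genes: int = 1000,
    subtype_effect: float = 1.0,
    n_de_per_subtype: int = 30,
    n_control_genes: int = 200,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a log2-scale bulk expression cohort with additive batch shifts.

    Batch ``B{j}`` adds ``j * batch_shift`` (log2 units) to every gene of its
    samples, mimicking platform batches in microarray cohorts. Each sample
    carries one molecular subtype label; ``n_de_per_subtype`` planted genes per
    subtype are shifted by ``+subtype_effect`` (the biology that normalization
    must preserve). Gaussian noise sd ``noise_sd``.

    Returns ``(expr, sample_meta, truth)`` with ``expr`` samples × genes.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if n_samples < n_batches:
        raise ValueError("n_samples must be >= n_batches")

    rng = np.random.default_rng(seed)
    gene_ids = [f"GENE{i:05d}" for i in range(n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    batches = [f"B{j + 1}" for j in range(n_batches)]

    up, _down, lfc, controls = _plant_gene_sets(
        rng, gene_ids, list(subtype_labels), n_de_per_subtype, n_control_genes,
        subtype_effect,
    )
    # bulk plants are one-directional: keep only the up sets
    for s in subtype_labels:
        lfc[s] = {g: e for g, e in lfc[s].items() if e > 0}

    meta = pd.DataFrame(
        {
            "batch": [batches[i % n_batches] for i in range(n_samples)],
            "subtype": [
                subtype_labels[int(i)]
                for i in rng.integers(0, len(subtype_labels), n_samples)
            ],
        },
        index=samples,
    )

    base = rng.normal(6.0, 2.0, size=n_genes)
    expr = np.tile(base, (n_samples, 1))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    shifts = {b: j * batch_shift for j, b in enumerate(batches)}
    for i, s in enumerate(samples):
        expr[i] += shifts[meta.loc[s, "batch"]]
        for g in up[meta.loc[s, "subtype"]]:
            expr[i, gene_index[g]] += subtype_effect
    expr += rng.normal(0.0, noise_sd, size=expr.shape)

    truth = SyntheticTruth(
        seed=seed,
        planted_up_genes=up,
        planted_log2fc=lfc,
        control_genes=controls,
        batch_labels=meta["batch"].copy(),
        batch_shifts=shifts,
    )
    return pd.DataFrame(expr, index=samples, columns=gene_ids), meta, truth
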