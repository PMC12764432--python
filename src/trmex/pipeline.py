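"""Configuration-driven orchestration of the deconvolution analysis.

``run_pipeline`` executes the stages in order — pseudobulk → filters →
normalization → differential expression → signatures → scoring → TCR —
skipping stages whose inputs are absent, and writes a manifest listing every
output file with a content hash. ``run_synthetic_demo`` generates two
synthetic datasets with shared planted biology plus a repertoire, runs the
full analysis including cross-dataset refinement, enrichment and
concordance, and scores the recovered signatures and viral calls against
the planted truth.

All randomness derives from one root seed split per stage, so a fixed seed
yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import concordance as conc
from . import de, io, pseudobulk as pbk, refine, scoring, simulate, tcr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_synthetic_demo", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic sub-seed (< 2**31) for a named pipeline stage."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # inputs
    mtx_dir: Optional[str] = None
    contig_tsv: Optional[str] = None
    reference_tsv: Optional[str] = None
    donor_hla_json: Optional[str] = None
    control_gene_file: Optional[str] = None
    # parameters
    group_by: list[str] = Field(default=["donor", "tissue", "subset"])
    group_key: str = "subset"
    min_cells: int = Field(default=20, ge=1)
    gene_min_count: int = Field(default=5, ge=0)
    gene_min_samples: int = Field(default=2, ge=1)
    prior_count: float = Field(default=0.5, gt=0)
    k: int = Field(default=1, ge=0)
    de_alpha: float = Field(default=0.05, gt=0, lt=1)
    fc_threshold: float = Field(default=0.5, ge=0)
    n_bins: int = Field(default=24, ge=2)
    n_ctrl: int = Field(default=100, ge=1)
    min_overlap: int = Field(default=1, ge=1)
    viral_threshold: float = Field(default=1.0, gt=0)
    viral_inclusive: bool = False
    target_subset: str = "TRM"
    versus_subset: str = "TEX"
    seed: int = Field(default=0, ge=0)
    # output
    outdir: str = "trmex_run"

    @field_validator("group_by")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("group_by must name at least one metadata key")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, files: Sequence[Path], **info) -> None:
        self.stages[stage] = {
            "outputs": {str(f.relative_to(self.outdir)): _sha256(f) for f in files},
            **info,
        }

    def skip(self, stage: str, reason: str) -> None:
        self.stages[stage] = {"skipped": True, "reason": reason}

    def write(self) -> Path:
        return io.write_json({"stages": self.stages}, self.outdir / "manifest.json")


def _derive_both_signatures(
    pb: pbk.PseudobulkSet,
    cfg: RunConfig,
    W: np.ndarray | None,
    name_prefix: str,
) -> tuple[dict[str, de.GeneSignature], dict[str, pd.DataFrame]]:
    """Stage-1 (subset vs rest) and stage-2 (head-to-head) DE for both subsets."""
    offsets = de.effective_offsets(pb)
    disp = de.estimate_dispersions(pb, W, offsets=offsets)
    results, sigs = {}, {}
    for subset, other in (
        (cfg.target_subset, cfg.versus_subset),
        (cfg.versus_subset, cfg.target_subset),
    ):
        stage1 = de.test_contrast(
            pb, W=W, target=subset, de_alpha=cfg.de_alpha,
            dispersions=disp, offsets=offsets,
        )
        stage2 = de.test_contrast(
            pb, W=W, de_alpha=cfg.de_alpha, dispersions=disp, offsets=offsets,
            contrast=_pairwise_contrast(pb, subset, other),
        )
        results[f"{subset}_stage1"] = stage1
        results[f"{subset}_stage2"] = stage2
        sigs[subset] = de.derive_signature(
            stage1, stage2, cfg.de_alpha, name=f"{name_prefix}_{subset}"
        )
    return sigs, results


def _pairwise_contrast(pb: pbk.PseudobulkSet, a: str, b: str) -> np.ndarray:
    levels = sorted(pb.sample_meta["group"].unique())
    c = np.zeros(len(levels))
    c[levels.index(a)], c[levels.index(b)] = 1.0, -1.0
    return c


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages on on-disk inputs; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    io.write_json(config.model_dump(), outdir / "resolved_config.json")

    cells = None
    if config.mtx_dir:
        cells = io.read_mtx_dir(config.mtx_dir)

    sigs = None
    if cells is not None:
        pb = pbk.aggregate_pseudobulk(
            cells, group_by=config.group_by, min_cells=config.min_cells,
            group_key=config.group_key,
        )
        pb = pbk.filter_genes(
            pb, min_count=config.gene_min_count,
            min_samples=config.gene_min_samples,
        )
        f1 = io.write_tsv(pb.counts, outdir / "pseudobulk_counts.tsv")
        f2 = io.write_tsv(pb.sample_meta, outdir / "pseudobulk_meta.tsv")
        manifest.record("pseudobulk", [f1, f2], n_samples=len(pb.counts))

        factors = pbk.tmm_factors(pb)
        log_expr = pbk.log_transform(
            pb, prior_count=config.prior_count, as_cpm=True, scaling=factors
        )
        rle, rle_med = pbk.compute_rle(log_expr)
        f3 = io.write_tsv(rle, outdir / "rle.tsv")
        W = None
        if config.k > 0:
            if config.control_gene_file:
                ctl = set(
                    Path(config.control_gene_file).read_text().split()
                )
            else:
                ctl = set(pb.counts.columns)
            design = pbk.ReplicateDesign.from_groups(
                pb.sample_meta["group"], ctl, config.k
            )
            corrected, W = pbk.ruv3_correct(log_expr, design, return_w=True)
            f4 = io.write_tsv(
                pd.DataFrame(W, index=pb.counts.index,
                             columns=[f"W{i+1}" for i in range(W.shape[1])]),
                outdir / "ruv_w.tsv",
            )
            manifest.record("normalize", [f3, f4], k=config.k)
        else:
            manifest.record("normalize", [f3], k=0)

        sigs, results = _derive_both_signatures(pb, config, W, "run")
        files = []
        for key, table in results.items():
            files.append(io.write_tsv(table, outdir / f"de_{key}.tsv"))
        files.append(io.write_gmt(list(sigs.values()), outdir / "signatures.gmt"))
        manifest.record(
            "signatures", files,
            sizes={s: len(sig) for s, sig in sigs.items()},
        )

        norm = scoring.normalize_cells(cells)
        score_files = []
        for subset, sig in sigs.items():
            if len(sig) == 0:
                continue
            sc = scoring.signature_scores(
                norm, sig, config.n_bins, config.n_ctrl,
                stage_seed(config.seed, f"score_{subset}"),
            )
            score_files.append(io.write_tsv(sc, outdir / f"scores_{subset}.tsv"))
        if score_files:
            manifest.record("scoring", score_files)
        else:
            manifest.skip("scoring", "all signatures empty")
    else:
        for st in ("pseudobulk", "normalize", "signatures", "scoring"):
            manifest.skip(st, "no MTX input configured")

    if config.contig_tsv:
        contigs = pd.read_csv(config.contig_tsv, sep="\t")
        meta = cells.obs if cells is not None else pd.DataFrame()
        ct = tcr.build_clonotypes(contigs, meta)
        files = [io.write_tsv(ct.cells, outdir / "clonotypes.tsv", index=False)]
        subsets = sorted(ct.cells["subset"].unique())
        exp = tcr.expanded_clones(ct)
        present = ct.cells.groupby(
            ["donor", "clonotype_key", "subset"], observed=True
        ).size()
        by_subset = {
            s: {k[:2] for k in present[present > 0].index if k[2] == s} & exp
            for s in subsets
        }
        overlap = {
            "jaccard_dissimilarity": {
                f"{a}|{b}": tcr.jaccard_dissimilarity(by_subset[a], by_subset[b])
                for i, a in enumerate(subsets) for b in subsets[i + 1:]
                if by_subset[a] | by_subset[b]
            },
            "shared_counts": {
                str(cut): {
                    "+".join(k): v
                    for k, v in tcr.shared_clonotype_counts(ct, subsets, cut).items()
                }
                for cut in (1, 2, 3)
            },
        }
        files.append(io.write_json(overlap, outdir / "tcr_overlap.json"))
        if config.reference_tsv and config.donor_hla_json:
            refs = pd.read_csv(config.reference_tsv, sep="\t")
            import json as _json

            hla = _json.loads(Path(config.donor_hla_json).read_text())
            ann = tcr.annotate_viral(
                ct, refs, hla, config.viral_threshold,
                inclusive=config.viral_inclusive,
            )
            files.append(io.write_tsv(ann, outdir / "viral_annotation.tsv",
                                      index=False))
        manifest.record("tcr", files, n_cells=len(ct))
    else:
        manifest.skip("tcr", "no contig input configured")

    manifest.write()
    return {"stages": manifest.stages, "outdir": str(outdir)}


# ---------------------------------------------------------------------------
# synthetic end-to-end demo


_SCALES = {
    "small": dict(n_genes=600, n_cells_per_donor=220, n_de_per_subset=20,
                  n_control_genes=80, rep_cells=400),
    "default": dict(n_genes=1500, n_cells_per_donor=300, n_de_per_subset=40,
                    n_control_genes=150, rep_cells=1200),
}


def _two_stage_truth(
    truth: simulate.SyntheticTruth, target: str, versus: str,
    subsets: Sequence[str],
) -> set[str]:
    """Genes that truly satisfy the two-stage rule for ``target`` vs ``versus``.

    From the planted per-subset effects: a gene qualifies iff its true
    stage-1 contrast (target minus the mean of the other subsets) and true
    stage-2 contrast (target minus ``versus``) are nonzero with equal sign.
    A gene planted only in ``versus`` therefore qualifies with reversed
    sign, while genes planted in bystander subsets do not (their stage-2
    contrast is zero).
    """
    genes = set()
    for s in subsets:
        genes |= set(truth.planted_log2fc.get(s, {}))
    others = [s for s in subsets if s != target]
    out = set()
    for g in genes:
        eff = {s: truth.planted_log2fc.get(s, {}).get(g, 0.0) for s in subsets}
        s1 = eff[target] - np.mean([eff[s] for s in others])
        s2 = eff[target] - eff[versus]
        if s1 * s2 > 0:
            out.add(g)
    return out


def _precision_recall(found: set, truth: set) -> tuple[float, float]:
    tp = len(found & truth)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall


def run_synthetic_demo(
    seed: int = 0, scale: str = "default", outdir: str | Path = "trmex_demo"
) -> dict:
    """Generate synthetic data, run the full analysis, score against truth.

    Two single-cell datasets with shared planted biology stand in for the
    breast and liver cohorts; their two-stage signatures are refined into a
    pancancer signature; module scores, enrichment, TCR overlap/viral calls
    and cross-dataset concordance are computed; and a recovery report
    (precision, recall, effect-size bias, AUC) is written alongside a
    manifest of content-hashed outputs.
    """
    from sklearn.metrics import roc_auc_score

    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}")
    p = _SCALES[scale]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    cfg = RunConfig(seed=seed, outdir=str(outdir))
    subsets = ("TRM", "TEX", "TEM", "TCM", "TN")

    plant = stage_seed(seed, "plant")
    cells_a, truth_a = simulate.simulate_cells(
        n_donors=4, n_cells_per_donor=p["n_cells_per_donor"], subsets=subsets,
        n_genes=p["n_genes"], effect_log2fc=1.0, dispersion=0.3,
        seed=stage_seed(seed, "cells_a"), n_tissues=2,
        n_de_per_subset=p["n_de_per_subset"],
        n_control_genes=p["n_control_genes"], plant_seed=plant,
    )
    cells_b, truth_b = simulate.simulate_cells(
        n_donors=4, n_cells_per_donor=p["n_cells_per_donor"], subsets=subsets,
        n_genes=p["n_genes"], effect_log2fc=1.0, dispersion=0.3,
        seed=stage_seed(seed, "cells_b"), n_tissues=2,
        n_de_per_subset=p["n_de_per_subset"],
        n_control_genes=p["n_control_genes"], plant_seed=plant,
    )
    io.write_mtx_dir(cells_a, outdir / "dataset_a")
    manifest.record("simulate", sorted((outdir / "dataset_a").glob("*")),
                    n_cells=cells_a.n_obs, n_genes=cells_a.n_vars)

    report: dict = {"seed": seed, "scale": scale}
    sig_by_ds, de_by_ds = {}, {}
    for tag, cells, truth in (("a", cells_a, truth_a), ("b", cells_b, truth_b)):
        pb = pbk.aggregate_pseudobulk(cells, group_by=("donor", "tissue", "subset"))
        pb = pbk.filter_genes(pb)
        log_expr = pbk.log_transform(pb, as_cpm=True,
                                     scaling=pbk.tmm_factors(pb))
        ctl = truth.control_genes & set(pb.counts.columns)
        design = pbk.ReplicateDesign.from_groups(pb.sample_meta["group"], ctl, k=1)
        _corr, W = pbk.ruv3_correct(log_expr, design, return_w=True)
        sigs, results = _derive_both_signatures(pb, cfg, W, f"demo_{tag}")
        sig_by_ds[tag], de_by_ds[tag] = sigs, results

    files = [
        io.write_gmt(
            [sig_by_ds["a"]["TRM"], sig_by_ds["a"]["TEX"],
             sig_by_ds["b"]["TRM"], sig_by_ds["b"]["TEX"]],
            outdir / "signatures.gmt",
        )
    ]
    for tag in ("a", "b"):
        for key, tab in de_by_ds[tag].items():
            files.append(io.write_tsv(tab, outdir / f"de_{tag}_{key}.tsv"))
    manifest.record("signatures", files)

    truth_up = truth_a.planted_up_genes["TRM"]
    truth_dn = truth_a.planted_down_genes["TRM"]
    rule_truth = _two_stage_truth(truth_a, "TRM", "TEX", subsets)
    found = set(sig_by_ds["a"]["TRM"].up_genes) | set(sig_by_ds["a"]["TRM"].down_genes)
    _prec, rec = _precision_recall(found, truth_up | truth_dn)
    prec_rule, _ = _precision_recall(found, rule_truth)
    s1 = de_by_ds["a"]["TRM_stage1"]
    planted_in = [g for g in truth_up if g in s1.index]
    report["signature"] = {
        "recall_planted_trm": rec,
        "empirical_fdr": 1.0 - prec_rule if np.isfinite(prec_rule) else float("nan"),
        "log2fc_bias_up": float(s1.loc[planted_in, "log2fc"].mean() - 1.0),
        "n_genes": len(found),
    }

    refined = refine.refine_pancancer_signature(
        sig_by_ds["a"]["TRM"], de_by_ds["a"]["TRM_stage2"],
        sig_by_ds["b"]["TRM"], de_by_ds["b"]["TRM_stage2"],
        fc_threshold=cfg.fc_threshold, name="pancancer_TRM",
    )
    files = [io.write_gmt([refined], outdir / "pancancer_signature.gmt")]
    manifest.record("refinement", files, n_genes=len(refined))
    found_r = set(refined.up_genes) | set(refined.down_genes)
    prec_r, _ = _precision_recall(found_r, rule_truth)
    _, rec_r = _precision_recall(found_r, truth_up | truth_dn)
    report["refined_signature"] = {
        "precision_vs_rule": prec_r, "recall_planted_trm": rec_r,
        "n_genes": len(found_r),
    }

    enr = refine.gsea_running_sum(
        de_by_ds["b"]["TRM_stage2"]["log2fc"],
        sig_by_ds["a"]["TRM"].up_genes or sorted(truth_up),
        n_permutations=499, seed=stage_seed(seed, "gsea"),
    )
    report["enrichment"] = {"es": enr.es, "p_perm": enr.p_perm,
                            "n_leading_edge": len(enr.leading_edge)}

    norm = scoring.normalize_cells(cells_a)
    score_sig = sig_by_ds["a"]["TRM"] if len(sig_by_ds["a"]["TRM"]) else \
        de.GeneSignature("planted_TRM", sorted(truth_up), sorted(truth_dn))
    sc = scoring.signature_scores(
        norm, score_sig, cfg.n_bins, cfg.n_ctrl, stage_seed(seed, "score")
    )
    labels = cells_a.obs["subset"]
    mask = labels.isin(["TRM", "TEX"])
    auc = roc_auc_score((labels[mask] == "TRM").astype(int),
                        sc.loc[mask.to_numpy(), "combined"])
    files = [io.write_tsv(sc, outdir / "scores_TRM.tsv")]
    manifest.record("scoring", files)
    report["module_score"] = {"auc_trm_vs_tex": float(auc)}

    samples = cells_a.obs["donor"].astype(str) + "|" + cells_a.obs["tissue"].astype(str)
    ratios = scoring.subset_log_ratio(labels, samples)
    report["subset_ratio"] = {
        "mean_log2_tex_trm": float(ratios.mean()),
        "n_samples": int(len(ratios)),
    }

    rep, refs, truth_r = simulate.simulate_repertoire(
        {"TRM": p["rep_cells"], "TEX": p["rep_cells"], "TEM": p["rep_cells"] // 2},
        viral_fraction=0.1, seed=stage_seed(seed, "repertoire"),
    )
    exp = tcr.expanded_clones(rep)
    by_subset = {
        s: {k for k in exp
            if truth_r.clone_home_subset.get(k[1]) == s}
        for s in ("TRM", "TEX", "TEM")
    }
    jac = tcr.jaccard_dissimilarity(by_subset["TRM"], by_subset["TEX"]) \
        if by_subset["TRM"] | by_subset["TEX"] else float("nan")
    shared = {
        str(cut): {"+".join(k): v for k, v in
                   tcr.shared_clonotype_counts(rep, ("TRM", "TEX", "TEM"), cut).items()}
        for cut in (1, 2, 3)
    }
    ann = tcr.annotate_viral(rep, refs, truth_r.donor_hla)
    called = {
        (r.donor, r.clonotype_key) for r in ann.itertuples() if r.viral
    }
    vprec, vrec = _precision_recall(called, truth_r.viral_clonotypes)
    comp = tcr.clone_composition(rep, top_n=100)
    files = [
        io.write_tsv(rep.cells, outdir / "repertoire.tsv", index=False),
        io.write_tsv(ann, outdir / "viral_annotation.tsv", index=False),
        io.write_tsv(comp, outdir / "clone_composition.tsv"),
        io.write_json(shared, outdir / "shared_clonotypes.json"),
    ]
    manifest.record("tcr", files, n_expanded=len(exp))
    report["tcr"] = {
        "jaccard_dissimilarity_trm_tex": jac,
        "viral_precision": vprec,
        "viral_recall": vrec,
        "n_viral_called": len(called),
    }

    table, orat, pval = conc.concordance_fisher(
        de_by_ds["a"]["TRM_stage1"]["log2fc"],
        de_by_ds["b"]["TRM_stage1"]["log2fc"],
        gene_subset=truth_up | truth_dn,
    )
    report["concordance"] = {
        "table": table.as_array().tolist(),
        "odds_ratio": orat if np.isfinite(orat) else None,
        "p": pval,
    }
    files = [io.write_json(report["concordance"], outdir / "concordance.json")]
    manifest.record("concordance", files)

    io.write_json(report, outdir / "recovery_report.json")
    manifest.record("report", [outdir / "recovery_report.json"])
    manifest.write()
    report["outdir"] = str(outdir)
    return report
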