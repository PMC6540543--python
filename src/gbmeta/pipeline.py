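"""End-to-end orchestration: simulate -> per-study DE -> meta-combine ->
DEG selection cascade -> downstream validation.

A single :class:`PipelineConfig` (plus its seed) determines every output
byte.  The stage cascade mirrors a multi-cohort biomarker screen: a
training and a validation GBM-vs-NG cohort analysed by both meta-analysis
routes at a stringent FDR, intersected with direction agreement, then
filtered for GBM specificity against GBM-vs-A and GBM-vs-OD cohorts at a
conventional FDR, and finally validated by survival, ROC and
over-representation statistics.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import combine, downstream, selection, study_de
from .io import GeneSetCollection, filter_low_signal_consensus, write_annotations
from .simulate import SimulationConfig, SyntheticTruth, generate_multistudy, generate_survival_cohort

COHORTS = ("training", "validation", "gbm_vs_a", "gbm_vs_od")
COHORT_CONTROL = {
    "training": "NG",
    "validation": "NG",
    "gbm_vs_a": "A",
    "gbm_vs_od": "OD",
}


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults are the desk-scale demo.

    Cohort sizes follow the screen's structure: the larger GBM-vs-NG cohort
    trains, the smaller validates, and two subtype cohorts test
    GBM-specificity.  ``stringent_fdr`` guards the GBM-vs-NG selections on
    both meta-analysis routes; ``subtype_fdr`` (conventional 0.05) guards
    the subtype comparisons.
    """

    # simulation
    n_genes: int = 2000
    samples_per_class: int = 15
    n_training: int = 6
    n_validation: int = 4
    n_gbm_vs_a: int = 4
    n_gbm_vs_od: int = 4
    n_pan_glioma_degs: int = 60
    n_gbm_specific_degs: int = 80
    frac_down: float = 0.25
    effect_mean: float = 1.5
    effect_heterogeneity: float = 0.2
    residual_sd: float = 1.0
    study_baseline_sd: float = 0.3
    gene_dropout: float = 0.0
    # QC filter
    mean_filter_q: float = 0.10
    sd_filter_q: float = 0.10
    # per-study DE
    B: int = 200
    s0: str | float = "auto"
    # meta-combination
    B_aw: int = 1000
    rop_r: int | None = None
    fisher_reference: str = "chi2"
    # selection thresholds
    stringent_fdr: float = 0.01
    subtype_fdr: float = 0.05
    selection_method: str = "fisher"
    # survival / downstream
    n_patients: int = 400
    baseline_hazard: float = 0.02
    log_hazard_ratio: float = 0.5
    censor_rate: float = 0.01
    ora_fdr: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _cohort_sim_config(cfg: PipelineConfig, cohort: str, seed: int) -> SimulationConfig:
    n = {
        "training": cfg.n_training,
        "validation": cfg.n_validation,
        "gbm_vs_a": cfg.n_gbm_vs_a,
        "gbm_vs_od": cfg.n_gbm_vs_od,
    }[cohort]
    spc = {"GBM": cfg.samples_per_class, COHORT_CONTROL[cohort]: cfg.samples_per_class}
    return SimulationConfig(
        n_studies=n,
        n_genes=cfg.n_genes,
        samples_per_class=spc,
        n_pan_glioma_degs=cfg.n_pan_glioma_degs,
        n_gbm_specific_degs=cfg.n_gbm_specific_degs,
        frac_down=cfg.frac_down,
        effect_mean=cfg.effect_mean,
        effect_heterogeneity=cfg.effect_heterogeneity,
        residual_sd=cfg.residual_sd,
        study_baseline_sd=cfg.study_baseline_sd,
        gene_dropout=cfg.gene_dropout,
        seed=seed,
        gene_seed=cfg.seed,
    )


def simulate_cohorts(cfg: PipelineConfig):
    """Simulate the four comparison cohorts with one shared truth ledger.

    The planted-gene identities are a function of (n_genes, planted counts)
    only, so the same genes carry signal in every cohort; realized
    per-study effects differ between cohorts (fresh heterogeneity draws).
    """
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(len(COHORTS))]
    cohorts: dict = {}
    truth: SyntheticTruth | None = None
    for cohort, seed in zip(COHORTS, seeds):
        sim = _cohort_sim_config(cfg, cohort, seed)
        studies, ann, t = generate_multistudy(sim, study_prefix=f"{cohort[:2].upper()}")
        cohorts[cohort] = {"studies": studies, "annotations": ann}
        if truth is None:
            truth = t
    assert truth is not None
    return cohorts, truth


def _derive_seeds(base_seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence([base_seed, stream])
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def run_cohort_de(
    cfg: PipelineConfig, cohort: str, studies: list, ann: pd.DataFrame, seeds: list
) -> dict:
    """QC-filter the cohort and compute each study's DE table."""
    control = COHORT_CONTROL[cohort]
    filtered = filter_low_signal_consensus(studies, cfg.mean_filter_q, cfg.sd_filter_q)
    results = {}
    for study, seed in zip(filtered, seeds):
        contrast = study_de.from_annotations(ann, study.study_id, "GBM", control)
        results[study.study_id] = study_de.run_study_de(
            study, contrast, B=cfg.B, seed=seed, s0=cfg.s0
        )
    return results


def _dual_selection(meta: pd.DataFrame, cfg: PipelineConfig, comparison: str):
    p_set = selection.select_significant(
        meta, cfg.selection_method, cfg.stringent_fdr, comparison=comparison
    )
    es_set = selection.select_significant(
        meta, "rem", cfg.stringent_fdr, comparison=comparison
    )
    return p_set, es_set, selection.dual_method_overlap(p_set, es_set)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage, write tables under ``outdir``, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()}, "stages": {}}

    cohorts, truth = simulate_cohorts(cfg)
    truth.to_tsv(outdir / "truth_ledger.tsv")

    metas: dict = {}
    for i, cohort in enumerate(COHORTS):
        studies = cohorts[cohort]["studies"]
        ann = cohorts[cohort]["annotations"]
        write_annotations(ann, outdir / f"annotations_{cohort}.tsv")
        de_seeds = _derive_seeds(cfg.seed, len(studies), stream=100 + i)
        results = run_cohort_de(cfg, cohort, studies, ann, de_seeds)
        meta = combine.meta_table(
            results,
            rop_r=cfg.rop_r,
            B_aw=cfg.B_aw,
            fisher_reference=cfg.fisher_reference,
            seed=_derive_seeds(cfg.seed, 1, stream=200 + i)[0],
        )
        meta.to_csv(outdir / f"meta_{cohort}.tsv", sep="\t", index_label="gene")
        metas[cohort] = meta
        report["stages"][cohort] = {
            "n_studies": len(studies),
            "universe": int(len(meta)),
        }

    # GBM-vs-NG: stringent dual-method selection in training and validation
    p_tr, es_tr, dual_tr = _dual_selection(metas["training"], cfg, "GBM_vs_NG_training")
    p_va, es_va, dual_va = _dual_selection(metas["validation"], cfg, "GBM_vs_NG_validation")
    confirmed = selection.train_validate(dual_tr, dual_va)

    # Subtype comparisons at the conventional FDR (p-combination route)
    set_a = selection.select_significant(
        metas["gbm_vs_a"], cfg.selection_method, cfg.subtype_fdr, comparison="GBM_vs_A"
    )
    set_od = selection.select_significant(
        metas["gbm_vs_od"], cfg.selection_method, cfg.subtype_fdr, comparison="GBM_vs_OD"
    )
    final = selection.specificity_filter(confirmed, set_a, set_od)

    cascade = {
        "training_pcomb": len(p_tr),
        "training_rem": len(es_tr),
        "training_overlap": len(dual_tr),
        "validation_pcomb": len(p_va),
        "validation_rem": len(es_va),
        "validation_overlap": len(dual_va),
        "train_validate": confirmed.counts(),
        "gbm_vs_a": len(set_a),
        "gbm_vs_od": len(set_od),
        "gbm_specific": final.counts(),
    }
    report["stages"]["cascade"] = cascade
    report["venn"] = {
        "dual_training": selection.venn_counts(
            {"pcomb": p_tr, "rem": es_tr}
        ),
        "specificity": selection.venn_counts(
            {"GBM_vs_NG": confirmed, "GBM_vs_A": set_a, "GBM_vs_OD": set_od}
        ),
    }
    for name, s in (
        ("deg_training_overlap", dual_tr),
        ("deg_train_validate", confirmed),
        ("deg_gbm_specific", final),
    ):
        s.to_frame().to_csv(outdir / f"{name}.tsv", sep="\t")

    # truth scoring (only meaningful on synthetic data)
    planted_gbm = set(truth.planted(("gbm_up", "gbm_down")))
    planted_pan = set(truth.planted(("pan_glioma",)))
    members = set(final.members)
    report["truth"] = {
        "planted_gbm_specific": len(planted_gbm),
        "recovered_gbm_specific": len(members & planted_gbm),
        "recall": (len(members & planted_gbm) / len(planted_gbm)) if planted_gbm else None,
        "non_planted_members": len(members - planted_gbm),
        "pan_glioma_leaked": len(members & planted_pan),
    }

    # detection competency of the four combination methods (training cohort)
    grid = [1e-10, 1e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05]
    comp = combine.detection_competency(metas["training"], grid)
    comp.to_csv(outdir / "detection_competency.tsv", sep="\t", index_label="method")
    report["detection_competency"] = {
        m: {f"{t:g}": int(c) for t, c in row.items()} for m, row in comp.iterrows()
    }

    # downstream validation on a representative selected gene
    report["downstream"] = _downstream_stage(cfg, metas, final, truth, cohorts, outdir)

    # report.json must be a pure function of config + seed; timings go to the log
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    with open(outdir / "log.txt", "w") as fh:
        fh.write(f"pipeline completed in {time.perf_counter() - t0:.1f} s\n")
        fh.write(f"seed: {cfg.seed}\n")
    return report


def _downstream_stage(
    cfg: PipelineConfig,
    metas: dict,
    final: selection.DEGSet,
    truth: SyntheticTruth,
    cohorts: dict,
    outdir: Path,
) -> dict:
    out: dict = {}
    meta_tr = metas["training"]
    if len(final) == 0:
        return {"note": "final DEG set empty; no downstream statistics"}

    # pick the most significant up-regulated final gene (falling back to any)
    ranked = meta_tr.loc[[g for g in final.members if g in meta_tr.index]]
    ranked = ranked.sort_values(f"{cfg.selection_method}_q")
    top_gene = ranked.index[0]
    out["top_gene"] = str(top_gene)
    out["top_gene_direction"] = final.members[top_gene]

    # survival: expression of the biomarker across a simulated glioma cohort
    surv_seeds = _derive_seeds(cfg.seed, 2, stream=900)
    rng = np.random.default_rng(surv_seeds[0])
    expr = rng.normal(0.0, 1.0, size=cfg.n_patients)
    surv = generate_survival_cohort(
        expr,
        baseline_hazard=cfg.baseline_hazard,
        log_hazard_ratio=cfg.log_hazard_ratio,
        censor_rate=cfg.censor_rate,
        seed=surv_seeds[1],
    )
    # flag a small better-prognosis subgroup for the sensitivity re-run
    surv["exclude_flag"] = rng.random(cfg.n_patients) < 0.1
    res_all = downstream.survival_analysis(surv, apply_exclusions=False)
    res_excl = downstream.survival_analysis(surv, apply_exclusions=True)
    out["survival"] = {
        "all_patients": {k: res_all[k] for k in ("n_low", "n_high", "chi2", "p")},
        "flag_excluded": {k: res_excl[k] for k in ("n_low", "n_high", "chi2", "p")},
    }
    res_all["km_low"].to_csv(outdir / "km_low.tsv", sep="\t", index=False)
    res_all["km_high"].to_csv(outdir / "km_high.tsv", sep="\t", index=False)

    # ROC: diagnostic separation GBM vs NG for the top gene, pooled across
    # validation studies after per-study centering (removes platform shift)
    scores, labels = [], []
    ann = cohorts["validation"]["annotations"]
    for study in cohorts["validation"]["studies"]:
        if top_gene not in study.values.index:
            continue
        row = study.values.loc[top_gene]
        centered = row - row.mean()
        for sid, val in centered.items():
            scores.append(val)
            labels.append(ann.loc[ann["sample_id"] == sid, "class"].iloc[0])
    roc = downstream.roc_auc(np.array(scores), np.array(labels), positive_label="GBM")
    out["roc"] = {"auc": roc.auc, "n": len(scores)}
    roc.curve.to_csv(outdir / "roc_top_gene.tsv", sep="\t", index=False)

    # ORA of the final set against truth-derived gene sets
    background = list(meta_tr.index)
    bg = set(background)
    collection = GeneSetCollection(
        sets={
            "PLANTED_GBM_SPECIFIC": set(truth.planted(("gbm_up", "gbm_down"))) & bg,
            "PLANTED_PAN_GLIOMA": set(truth.planted(("pan_glioma",))) & bg,
            "RANDOM_CONTROL": set(list(bg)[:: max(1, len(bg) // 50)]),
        },
        descriptions={
            "PLANTED_GBM_SPECIFIC": "genes simulated as GBM-specific",
            "PLANTED_PAN_GLIOMA": "genes simulated as pan-glioma",
            "RANDOM_CONTROL": "arbitrary background slice",
        },
    )
    ora = downstream.hypergeometric_ora(set(final.members) & bg, collection, bg)
    ora.to_csv(outdir / "ora_final_set.tsv", sep="\t")
    out["ora"] = {
        name: {"overlap": int(r["overlap"]), "q": float(r["q"])}
        for name, r in ora.iterrows()
    }
    return out
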