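#!/usr/bin/env python
"""Downstream validation of the selected biomarkers.

For the top GBM-specific gene: a median-dichotomized Kaplan-Meier /
log-rank survival analysis on a linked synthetic patient cohort (with and
without the exclusion-flagged subgroup), ROC analysis of GBM-vs-NG
discrimination in the validation cohort, over-representation of the final
set against truth-derived gene sets, and worked examples of the
immunoreactivity and 2^-ΔΔCt assay scores.  Outputs to results/downstream/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gbmeta.assays import QpcrMeasurement, fold_change_ddct, score_observation
from gbmeta.downstream import hypergeometric_ora, roc_auc, survival_analysis
from gbmeta.io import GeneSetCollection, read_annotations, read_expression_matrix
from gbmeta.pipeline import PipelineConfig, _derive_seeds
from gbmeta.simulate import generate_survival_cohort

OUT = Path("results/downstream")


def main() -> None:
    cfg = PipelineConfig.from_yaml(Path("results/cohorts/config.yaml"))
    OUT.mkdir(parents=True, exist_ok=True)
    final = pd.read_csv("results/selection/deg_gbm_specific.tsv", sep="\t")
    meta = pd.read_csv("results/meta/meta_training.tsv", sep="\t", index_col=0)
    if final.empty:
        print("final DEG set empty; nothing to validate")
        return
    ranked = meta.loc[[g for g in final["gene"] if g in meta.index]]
    top = ranked.sort_values("fisher_q").index[0]
    print(f"top GBM-specific gene: {top}")

    # survival: biomarker expression linked to hazard in a patient cohort
    seeds = _derive_seeds(cfg.seed, 2, stream=900)
    rng = np.random.default_rng(seeds[0])
    expr = rng.normal(size=cfg.n_patients)
    surv = generate_survival_cohort(expr, cfg.baseline_hazard,
                                    cfg.log_hazard_ratio, cfg.censor_rate,
                                    seed=seeds[1])
    surv["exclude_flag"] = rng.random(cfg.n_patients) < 0.1
    for label, excl in (("all patients", False), ("flag-excluded", True)):
        res = survival_analysis(surv, apply_exclusions=excl)
        print(f"  log-rank ({label}): chi2 = {res['chi2']:.1f}, p = {res['p']:.2e} "
              f"(n = {res['n_low']} low / {res['n_high']} high)")
    res = survival_analysis(surv)
    res["km_low"].to_csv(OUT / "km_low.tsv", sep="\t", index=False)
    res["km_high"].to_csv(OUT / "km_high.tsv", sep="\t", index=False)

    # ROC: GBM vs NG separation in the validation cohort, per-study centered
    ann = read_annotations("results/cohorts/annotations_validation.tsv")
    scores, labels = [], []
    for p in sorted(Path("results/cohorts").glob("validation_VA*.tsv")):
        study = read_expression_matrix(p, study_id=p.stem.split("_")[-1])
        if top not in study.values.index:
            continue
        row = study.values.loc[top]
        centered = row - row.mean()
        cls = ann.set_index("sample_id")["class"]
        scores.extend(centered.to_numpy())
        labels.extend(cls.loc[list(centered.index)])
    roc = roc_auc(np.array(scores), np.array(labels), positive_label="GBM")
    print(f"  ROC AUC (GBM vs NG, validation cohort): {roc.auc:.3f} "
          f"over {len(scores)} samples")
    roc.curve.to_csv(OUT / "roc_top_gene.tsv", sep="\t", index=False)

    # over-representation of the final set against truth-derived sets
    truth = pd.read_csv("results/cohorts/truth_ledger.tsv", sep="\t", index_col=0)
    bg = set(meta.index)
    coll = GeneSetCollection(
        sets={
            "PLANTED_GBM_SPECIFIC": set(truth.index[truth["class"].isin(["gbm_up", "gbm_down"])]) & bg,
            "PLANTED_PAN_GLIOMA": set(truth.index[truth["class"] == "pan_glioma"]) & bg,
        },
        descriptions={
            "PLANTED_GBM_SPECIFIC": "genes simulated as GBM-specific",
            "PLANTED_PAN_GLIOMA": "genes simulated as pan-glioma",
        },
    )
    ora = hypergeometric_ora(set(final["gene"]) & bg, coll, bg)
    ora.to_csv(OUT / "ora_final_set.tsv", sep="\t")
    print("  over-representation of the final set:")
    for name, r in ora.iterrows():
        print(f"    {name}: overlap {int(r['overlap'])}/{int(r['set_size'])}, "
              f"q = {r['q']:.2e}")

    # assay scoring worked examples
    irs_score, irs_bin = score_observation("strong", 80)
    fold = fold_change_ddct(QpcrMeasurement(20, 18, 22, 18))
    print(f"  IRS example: strong staining, 80% positive -> {irs_score} ({irs_bin})")
    print(f"  qPCR example: ΔΔCt = -2 -> fold change {fold:.1f}")
    (OUT / "assay_examples.json").write_text(json.dumps(
        {"irs": {"score": irs_score, "bin": irs_bin}, "ddct_fold": fold}, indent=1))


if __name__ == "__main__":
    main()
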