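#!/usr/bin/env python
"""The biomarker intersection cascade.

Applies the stringent dual-method (Fisher + random-effects) selection to the
training and validation GBM-vs-NG meta tables, confirms genes across both,
and keeps those also differential versus astrocytoma and oligodendroglioma —
the GBM-specific set.  Scores the outcome against the simulation truth
ledger and writes DEG tables plus a Venn summary to results/selection/.
"""

import json
from pathlib import Path

import pandas as pd

from gbmeta.pipeline import PipelineConfig, _dual_selection
from gbmeta.selection import select_significant, specificity_filter, train_validate, venn_counts

META = Path("results/meta")
OUT = Path("results/selection")


def main() -> None:
    cfg = PipelineConfig.from_yaml(Path("results/cohorts/config.yaml"))
    OUT.mkdir(parents=True, exist_ok=True)
    metas = {
        c: pd.read_csv(META / f"meta_{c}.tsv", sep="\t", index_col=0)
        for c in ("training", "validation", "gbm_vs_a", "gbm_vs_od")
    }
    p_tr, es_tr, dual_tr = _dual_selection(metas["training"], cfg, "GBM_vs_NG_training")
    p_va, es_va, dual_va = _dual_selection(metas["validation"], cfg, "GBM_vs_NG_validation")
    confirmed = train_validate(dual_tr, dual_va)
    set_a = select_significant(metas["gbm_vs_a"], cfg.selection_method,
                               cfg.subtype_fdr, comparison="GBM_vs_A")
    set_od = select_significant(metas["gbm_vs_od"], cfg.selection_method,
                                cfg.subtype_fdr, comparison="GBM_vs_OD")
    final = specificity_filter(confirmed, set_a, set_od)

    print(f"training: {len(p_tr)} p-combination / {len(es_tr)} effect-size "
          f"DEGs -> {len(dual_tr)} dual-method overlap")
    print(f"validation: {len(p_va)} / {len(es_va)} -> {len(dual_va)} overlap")
    c = confirmed.counts()
    print(f"train∩validate: {c['total']} DEGs ({c['up']} up, {c['down']} down)")
    f = final.counts()
    print(f"GBM-specific after subtype filter: {f['total']} "
          f"({f['up']} up, {f['down']} down)")

    truth = pd.read_csv("results/cohorts/truth_ledger.tsv", sep="\t", index_col=0)
    planted = set(truth.index[truth["class"].isin(["gbm_up", "gbm_down"])])
    pan = set(truth.index[truth["class"] == "pan_glioma"])
    members = set(final.members)
    print(f"truth: recovered {len(members & planted)}/{len(planted)} planted "
          f"GBM-specific genes; {len(members - planted)} non-planted; "
          f"{len(members & pan)} pan-glioma leaked")

    for name, s in (("dual_training", dual_tr), ("dual_validation", dual_va),
                    ("train_validate", confirmed), ("gbm_specific", final)):
        s.to_frame().to_csv(OUT / f"deg_{name}.tsv", sep="\t")
    venn = {
        "dual_training": venn_counts({"pcomb": p_tr, "rem": es_tr}),
        "specificity": venn_counts(
            {"GBM_vs_NG": confirmed, "GBM_vs_A": set_a, "GBM_vs_OD": set_od}
        ),
    }
    (OUT / "venn.json").write_text(json.dumps(venn, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
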