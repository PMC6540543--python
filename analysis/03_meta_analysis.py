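#!/usr/bin/env python
"""Cross-study meta-analysis of every cohort.

Combines the per-study one-sided p-values with Fisher / maxP / roP / AW and
pools Hedges' g with the DerSimonian-Laird random-effects model, applying
BH-FDR per method.  Writes one meta table per cohort and the
detection-competency curves of the four combination methods to results/meta/.
"""

from pathlib import Path

import pandas as pd

from gbmeta.combine import detection_competency, meta_table
from gbmeta.pipeline import COHORTS, PipelineConfig, _derive_seeds

IN = Path("results/de")
OUT = Path("results/meta")


def main() -> None:
    cfg = PipelineConfig.from_yaml(Path("results/cohorts/config.yaml"))
    OUT.mkdir(parents=True, exist_ok=True)
    for i, cohort in enumerate(COHORTS):
        results = {
            p.stem.split("_")[-1]: pd.read_csv(p, sep="\t", index_col=0)
            for p in sorted(IN.glob(f"{cohort}_*.tsv"))
        }
        meta = meta_table(
            results,
            rop_r=cfg.rop_r,
            B_aw=cfg.B_aw,
            fisher_reference=cfg.fisher_reference,
            seed=_derive_seeds(cfg.seed, 1, stream=200 + i)[0],
        )
        meta.to_csv(OUT / f"meta_{cohort}.tsv", sep="\t", index_label="gene")
        n_sig = (meta["fisher_q"] < cfg.stringent_fdr).sum()
        print(f"{cohort}: {len(meta)} genes combined over {len(results)} studies; "
              f"{n_sig} pass Fisher FDR<{cfg.stringent_fdr:g}")
    comp = detection_competency(
        pd.read_csv(OUT / "meta_training.tsv", sep="\t", index_col=0),
        [1e-10, 1e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05],
    )
    comp.to_csv(OUT / "detection_competency.tsv", sep="\t", index_label="method")
    print("detection competency (training cohort):")
    print(comp.to_string())


if __name__ == "__main__":
    main()
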