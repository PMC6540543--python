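#!/usr/bin/env python
"""Per-study differential expression for every cohort.

Reads the simulated studies back from results/cohorts/ (exercising the TSV
round trip), applies the cohort-consensus 10% mean/SD low-signal filter,
and computes each study's moderated-t, permutation p-values and Hedges' g
for the GBM-vs-control contrast.  Tables go to results/de/.
"""

from pathlib import Path

from gbmeta.io import read_annotations, read_expression_matrix
from gbmeta.pipeline import COHORTS, PipelineConfig, _derive_seeds, run_cohort_de

IN = Path("results/cohorts")
OUT = Path("results/de")


def main() -> None:
    cfg = PipelineConfig.from_yaml(IN / "config.yaml")
    OUT.mkdir(parents=True, exist_ok=True)
    for i, cohort in enumerate(COHORTS):
        ann = read_annotations(IN / f"annotations_{cohort}.tsv")
        studies = [
            read_expression_matrix(p, study_id=p.stem.split("_")[-1])
            for p in sorted(IN.glob(f"{cohort}_*.tsv"))
            if not p.name.startswith("annotations")
        ]
        seeds = _derive_seeds(cfg.seed, len(studies), stream=100 + i)
        results = run_cohort_de(cfg, cohort, studies, ann, seeds)
        for study_id, table in results.items():
            table.to_csv(OUT / f"{cohort}_{study_id}.tsv", sep="\t")
        universe = len(next(iter(results.values())))
        print(f"{cohort}: {len(results)} studies analysed, "
              f"{universe} genes after QC filter")


if __name__ == "__main__":
    main()
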