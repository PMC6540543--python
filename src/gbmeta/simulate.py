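"""Synthetic multi-study expression cohorts with planted glioma signal.

The generator emulates the structure of a collection of independently
normalized microarray studies of glioma: each study has its own gene-wise
baseline shift (a platform/batch effect), samples from up to four histology
classes (GBM, A, OD, NG), Gaussian residual noise on the log2 scale, and a
set of planted differentially expressed genes whose true per-study effects
are drawn around a common mean with between-study heterogeneity.  Planted
genes come in two flavours mirroring the biology of interest:

* ``pan_glioma`` genes shift GBM, A and OD equally relative to NG — they are
  differential in every glioma subtype and must be filtered out by a
  GBM-specificity analysis;
* ``gbm_up`` / ``gbm_down`` genes shift only the GBM class — the biomarkers
  a GBM-vs-everything cascade should recover.

Every simulated gene is recorded in a truth ledger so that end-to-end
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionStudy

CLASSES = ("GBM", "A", "OD", "NG")
GLIOMA_CLASSES = ("GBM", "A", "OD")

# Global log2-intensity baseline distribution (location/spread of gene-wise
# mean expression on an RMA-like scale).
_BASELINE_MEAN = 7.0
_BASELINE_SD = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated multi-study cohort.

    Parameters
    ----------
    n_studies:
        Number of studies generated for this comparison set.
    n_genes:
        Genes per study before any per-study dropout.
    samples_per_class:
        Mapping class label -> samples per study.  Classes with count 0 are
        simply absent from the study.
    n_pan_glioma_degs, n_gbm_specific_degs:
        Planted differential genes of each flavour.
    frac_down:
        Fraction of each planted flavour whose mean effect is negative
        (down in the affected classes).
    effect_mean:
        Mean true effect ``delta`` in log2 units.
    effect_heterogeneity:
        Between-study SD ``tau`` of the true effect (log2 units).
    residual_sd:
        Within-class residual SD ``sigma`` (log2 units).
    study_baseline_sd:
        SD of the gene-wise per-study baseline shift (log2 units).
    gene_dropout:
        Fraction of genes dropped at random per study (emulates platform
        coverage differences; exercises the gene-intersection rule).
    heavy_tails:
        If True, residual noise is Student-t with 5 df scaled to
        ``residual_sd``; default Gaussian.
    """

    n_studies: int
    n_genes: int
    samples_per_class: dict = field(
        default_factory=lambda: {"GBM": 15, "A": 15, "OD": 15, "NG": 15}
    )
    n_pan_glioma_degs: int = 0
    n_gbm_specific_degs: int = 0
    frac_down: float = 0.25
    effect_mean: float = 1.5
    effect_heterogeneity: float = 0.2
    residual_sd: float = 1.0
    study_baseline_sd: float = 0.3
    gene_dropout: float = 0.0
    heavy_tails: bool = False
    seed: int = 0
    # Gene-level quantities (baselines) are drawn from gene_seed so that
    # several cohorts over the same genes can share them; defaults to seed.
    gene_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_genes < 1:
            raise ValueError("n_studies and n_genes must be positive")
        if min(self.samples_per_class.values(), default=-1) < 0:
            raise ValueError("negative sample count")
        if self.n_pan_glioma_degs < 0 or self.n_gbm_specific_degs < 0:
            raise ValueError("planted gene counts must be >= 0")
        if self.n_pan_glioma_degs + self.n_gbm_specific_degs > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.effect_heterogeneity < 0:
            raise ValueError("effect_heterogeneity must be >= 0")
        if not 0 <= self.gene_dropout < 1:
            raise ValueError("gene_dropout must be in [0, 1)")
        if not 0 <= self.frac_down <= 1:
            raise ValueError("frac_down must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ledger of planted signal: per-gene class and realized per-study effects.

    ``genes`` is a DataFrame indexed by gene symbol with columns ``class``
    (null / pan_glioma / gbm_up / gbm_down) and ``direction`` (up/down/none).
    ``effects`` is a genes x studies DataFrame of realized true effects in
    log2 units (0 for null genes everywhere).
    """

    genes: pd.DataFrame
    effects: pd.DataFrame

    def planted(self, kinds: tuple[str, ...]) -> list[str]:
        mask = self.genes["class"].isin(kinds)
        return list(self.genes.index[mask])

    def to_tsv(self, path) -> None:
        out = self.genes.join(self.effects)
        out.to_csv(path, sep="\t", index_label="gene")


def _gene_symbols(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_multistudy(
    config: SimulationConfig, study_prefix: str = "S"
) -> tuple[list[ExpressionStudy], pd.DataFrame, SyntheticTruth]:
    """Simulate a multi-study cohort.

    Returns ``(studies, annotations, truth)`` where ``annotations`` has one
    row per sample with columns sample_id, study_id, class, time, event,
    exclude_flag (time/event left empty; see :func:`generate_survival_cohort`).
    """
    counts = {c: int(config.samples_per_class.get(c, 0)) for c in CLASSES}
    if all(v == 0 for v in counts.values()):
        raise ValueError("no samples in any class")

    root = np.random.SeedSequence(config.seed)
    _, effect_ss, *study_ss = root.spawn(2 + config.n_studies)
    gene_seed = config.seed if config.gene_seed is None else config.gene_seed
    gene_ss = np.random.SeedSequence([gene_seed, 17]).spawn(1)[0]
    rng = np.random.default_rng(gene_ss)

    genes = _gene_symbols(config.n_genes)
    baseline = rng.normal(
        _BASELINE_MEAN, _BASELINE_SD, size=config.n_genes
    )

    # Assign planted classes to the first block of genes; order is arbitrary
    # but fixed, and downstream analyses never see the ledger.
    n_pan, n_gbm = config.n_pan_glioma_degs, config.n_gbm_specific_degs
    n_gbm_down = int(round(n_gbm * config.frac_down))
    n_pan_down = int(round(n_pan * config.frac_down))
    klass = np.array(["null"] * config.n_genes, dtype=object)
    direction = np.array(["none"] * config.n_genes, dtype=object)
    klass[:n_pan] = "pan_glioma"
    direction[:n_pan] = "up"
    direction[:n_pan_down] = "down"
    klass[n_pan : n_pan + n_gbm] = "gbm_up"
    direction[n_pan : n_pan + n_gbm] = "up"
    klass[n_pan : n_pan + n_gbm_down] = "gbm_down"
    direction[n_pan : n_pan + n_gbm_down] = "down"

    sign = np.where(direction == "down", -1.0, 1.0)
    planted = klass != "null"

    # Planted differential genes represent expressed transcripts: a marker
    # below the detection floor could never be discovered by any pipeline,
    # and the low-signal QC filter exists precisely to drop such probes.
    # Resample planted baselines that fall in the bottom 40% of the
    # baseline distribution, keeping even down-regulated planted genes
    # clear of the bottom-decile mean filter.
    floor = _BASELINE_MEAN + _BASELINE_SD * float(stats.norm.ppf(0.40))
    low = planted & (baseline < floor)
    while low.any():
        baseline[low] = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=low.sum())
        low = planted & (baseline < floor)

    erng = np.random.default_rng(effect_ss)
    effects = np.zeros((config.n_genes, config.n_studies))
    for k in range(config.n_studies):
        theta = sign * config.effect_mean + erng.normal(
            0.0, config.effect_heterogeneity, size=config.n_genes
        )
        effects[:, k] = np.where(planted, theta, 0.0)

    studies: list[ExpressionStudy] = []
    ann_rows = []
    for k in range(config.n_studies):
        study_id = f"{study_prefix}{k + 1:02d}"
        srng = np.random.default_rng(study_ss[k])
        shift = srng.normal(0.0, config.study_baseline_sd, size=config.n_genes)

        cols, labels = [], []
        for c in CLASSES:
            for j in range(counts[c]):
                cols.append(f"{study_id}_{c}_{j + 1:02d}")
                labels.append(c)
        n_samples = len(cols)
        labels_arr = np.array(labels)

        mean = np.tile((baseline + shift)[:, None], (1, n_samples))
        affected = np.isin(labels_arr, GLIOMA_CLASSES)[None, :] & (
            klass == "pan_glioma"
        )[:, None]
        affected |= (labels_arr == "GBM")[None, :] & np.isin(
            klass, ("gbm_up", "gbm_down")
        )[:, None]
        mean = mean + affected * effects[:, k][:, None]

        if config.heavy_tails:
            df = 5.0
            noise = srng.standard_t(df, size=mean.shape)
            noise *= config.residual_sd / np.sqrt(df / (df - 2.0))
        else:
            noise = srng.normal(0.0, config.residual_sd, size=mean.shape)
        values = pd.DataFrame(mean + noise, index=genes, columns=cols)

        if config.gene_dropout > 0:
            keep = srng.random(config.n_genes) >= config.gene_dropout
            if not keep.any():
                raise ValueError("gene_dropout removed every gene")
            values = values.loc[keep]

        studies.append(
            ExpressionStudy(study_id=study_id, values=values, platform_id="synthetic")
        )
        for sid, lab in zip(cols, labels):
            ann_rows.append(
                {
                    "sample_id": sid,
                    "study_id": study_id,
                    "class": lab,
                    "time": np.nan,
                    "event": np.nan,
                    "exclude_flag": False,
                }
            )

    truth = SyntheticTruth(
        genes=pd.DataFrame({"class": klass, "direction": direction}, index=genes),
        effects=pd.DataFrame(
            effects,
            index=genes,
            columns=[f"{study_prefix}{k + 1:02d}" for k in range(config.n_studies)],
        ),
    )
    return studies, pd.DataFrame(ann_rows), truth


def generate_survival_cohort(
    expression: np.ndarray,
    baseline_hazard: float,
    log_hazard_ratio: float,
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential survival times linked to an expression score.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_ratio * (x - mean(x)))``; censoring
    times are independent exponentials with rate ``censor_rate`` (no
    censoring when 0).  Returns a SurvivalTable-shaped DataFrame with
    columns time, event, expression, exclude_flag.
    """
    x = np.asarray(expression, dtype=float)
    if x.size == 0:
        raise ValueError("empty expression vector")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(log_hazard_ratio * (x - x.mean()))
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=x.size)
    else:
        t_cens = np.full(x.size, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event, "expression": x, "exclude_flag": False}
    )
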