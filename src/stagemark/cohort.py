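"""Synthetic stage-structured expression cohorts with known ground truth.

The generator emulates an RSEM-normalized bulk expression cohort of
controls plus stage I-IV tumors.  Expression for an informative gene is
log-normal around a stage-dependent log2 mean:

* *linear-signal* genes carry per-stage offsets ``beta_1..beta_4`` relative
  to controls, following a progression profile
  ``effect_size * (1, 1, stage_gain, stage_gain)``: early-stage tumors are
  modestly shifted and stage III/IV tumors amplified, the progression
  structure the stage-informed models are designed to detect;
* *ordinal-signal* genes follow a monotone trend ``a * X`` in the numeric
  stage ``X in {0..4}``, with slope ``a = +/- effect_size * stage_gain / 4``
  so both gene types reach the same maximal offset at stage IV;
* *flat* genes are near-constant on the output scale (sd 0.1) and exist to
  be caught by the low-variation filter;
* all remaining genes are null.

Signs alternate gene by gene so roughly half of the planted markers are
up- and half down-regulated.  Linear-scale values are
``2**(log2 mean + Gaussian noise)`` times a per-sample library factor;
flat genes are drawn directly on the output scale, unscaled, so their sd
stays below the filter threshold.  The class imbalance of the default
cohort is ~90% cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASS_CANCER, CLASS_NORMAL, ExpressionMatrix, StageDesign
from .errors import ConfigurationError

FLAT_BASE = 50.0
FLAT_SD = 0.1


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a desk-scale cohort with heavy cancer imbalance
    (30 controls vs 270 tumors, stage-II-heavy), 2,000 genes of which nine
    are planted markers (five linear, four ordinal).  ``effect_size`` is
    the early-stage (I/II) log2 offset of a linear-signal gene;
    ``stage_gain`` amplifies stage III/IV offsets, so the maximal offset
    is ``effect_size * stage_gain`` (2.5 x 1.2 = 3.0 log2 units by
    default, of the order of the fold-changes strong diagnostic markers
    show) against a per-gene residual sd of 1.0.  The diagnosis offset
    dominates the progression gradient, as it does for strong clinical
    markers.
    """

    n_control: int = 30
    n_per_stage: tuple[int, int, int, int] = (60, 120, 60, 30)
    n_genes: int = 2000
    n_linear_signal: int = 5
    n_ordinal_signal: int = 4
    n_flat: int = 50
    effect_size: float = 2.5
    stage_gain: float = 1.2
    noise_sd: float = 1.0
    base_mean: float = 6.0
    library_size_range: tuple[float, float] = (0.8, 1.25)
    seed: int = 13

    def validate(self) -> None:
        counts = (self.n_control, *self.n_per_stage, self.n_genes,
                  self.n_linear_signal, self.n_ordinal_signal, self.n_flat)
        if any(c < 0 for c in counts):
            raise ConfigurationError("all cohort counts must be >= 0")
        n_signal = self.n_linear_signal + self.n_ordinal_signal + self.n_flat
        if n_signal > self.n_genes:
            raise ConfigurationError(
                f"signal + flat genes ({n_signal}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.stage_gain < 1:
            raise ConfigurationError("stage_gain must be >= 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must be positive and ordered")
        if self.n_genes == 0 or self.n_control + sum(self.n_per_stage) == 0:
            raise ConfigurationError("cohort must contain genes and samples")


@dataclass
class GroundTruth:
    """Per-gene planted-effect bookkeeping.

    ``beta1..beta4`` are the true per-stage log2 offsets of linear-signal
    genes; ``slope`` is the true log2-per-stage-unit trend of
    ordinal-signal genes.  Null genes have all offsets and slope zero and
    all flags False.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def linear_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_linear_signal"]])

    @property
    def ordinal_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_ordinal_signal"]])

    @property
    def flat_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_flat"]])

    @property
    def planted_genes(self) -> list[str]:
        return self.linear_genes + self.ordinal_genes


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, StageDesign, GroundTruth]:
    """Simulate a cohort; identical configs (same seed) give bitwise-equal output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    stages = np.repeat([0, 1, 2, 3, 4], [config.n_control, *config.n_per_stage])
    n_samples = stages.size
    n_genes = config.n_genes
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]

    n_lin, n_ord, n_flat = config.n_linear_signal, config.n_ordinal_signal, config.n_flat
    is_linear = np.zeros(n_genes, bool)
    is_ordinal = np.zeros(n_genes, bool)
    is_flat = np.zeros(n_genes, bool)
    is_linear[:n_lin] = True
    is_ordinal[n_lin:n_lin + n_ord] = True
    is_flat[n_lin + n_ord:n_lin + n_ord + n_flat] = True

    # alternate up/down across the planted (linear then ordinal) genes
    signs = np.where(np.arange(n_lin + n_ord) % 2 == 0, 1.0, -1.0)
    profile = config.effect_size * np.array([1.0, 1.0, config.stage_gain, config.stage_gain])
    betas = np.zeros((n_genes, 4))
    betas[:n_lin, :] = signs[:n_lin, None] * profile[None, :]
    slopes = np.zeros(n_genes)
    slopes[n_lin:n_lin + n_ord] = (
        signs[n_lin:n_lin + n_ord] * config.effect_size * config.stage_gain / 4.0
    )

    # stage-dependent log2 mean: base + beta_s (linear) or base + a*X (ordinal)
    log2_mean = np.full((n_genes, n_samples), config.base_mean)
    for s in (1, 2, 3, 4):
        cols = stages == s
        log2_mean[:, cols] += betas[:, [s - 1]]
    log2_mean += slopes[:, None] * stages[None, :]

    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    lib = rng.uniform(*config.library_size_range, size=n_samples)
    values = np.exp2(log2_mean + noise) * lib[None, :]

    # flat genes: near-constant on the output scale, never library-scaled,
    # so the sigma < 1 filter is guaranteed to remove them
    flat_rows = np.flatnonzero(is_flat)
    if flat_rows.size:
        values[flat_rows] = np.clip(
            FLAT_BASE + rng.normal(0.0, FLAT_SD, size=(flat_rows.size, n_samples)),
            0.0, None,
        )

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    design = StageDesign(pd.DataFrame({
        "sample_id": sample_ids,
        "class": np.where(stages == 0, CLASS_NORMAL, CLASS_CANCER),
        "stage": stages,
    }))
    truth_table = pd.DataFrame({
        "is_linear_signal": is_linear,
        "is_ordinal_signal": is_ordinal,
        "is_flat": is_flat,
        "beta1": betas[:, 0],
        "beta2": betas[:, 1],
        "beta3": betas[:, 2],
        "beta4": betas[:, 3],
        "slope": slopes,
    }, index=pd.Index(gene_ids, name="gene"))
    return matrix, design, GroundTruth(truth_table)
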