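"""Pre-modelling steps: low-variation filter, voom transform, stratified split.

``voom_transform`` re-implements the voom idea for an intercept-only
per-gene model: counts-per-million on the log2 scale (offsets 0.5 on the
count and 1 on the library size), a lowess trend of sqrt residual
standard deviation against mean log2 count, and per-observation precision
weights equal to the inverse fourth power of the trend evaluated at each
observation's fitted log2 count, clamped to the trend's fitted range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix, StageDesign
from .errors import ConfigurationError

MILLION = 1e6


def filter_low_variance(
    m: ExpressionMatrix, threshold: float = 1.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose sample standard deviation is strictly below ``threshold``.

    The sd is computed on the input (normalized-count) scale, before any
    transformation.  Returns the retained matrix (row order preserved) and
    the removed gene ids.
    """
    if threshold <= 0:
        raise ConfigurationError("filter threshold must be > 0")
    sd = m.values.std(axis=1, ddof=1)
    keep = sd >= threshold
    removed = list(m.values.index[~keep])
    if keep.sum() == 0:
        raise ConfigurationError("low-variance filter removed every gene")
    return ExpressionMatrix(m.values.loc[keep]), removed


@dataclass
class VoomResult:
    """log2-CPM matrix with per-observation precision weights."""

    log_cpm: pd.DataFrame = field(repr=False)
    weights: pd.DataFrame = field(repr=False)
    trend_x: np.ndarray = field(repr=False)  # mean log2 count (sorted)
    trend_y: np.ndarray = field(repr=False)  # fitted sqrt residual sd

    def trend(self, x) -> np.ndarray:
        """Evaluate the fitted sqrt-sd trend, clamped to its observed range."""
        return np.interp(np.asarray(x, float), self.trend_x, self.trend_y)

    def subset_samples(self, sample_ids) -> "VoomResult":
        ids = list(sample_ids)
        return VoomResult(self.log_cpm[ids], self.weights[ids], self.trend_x, self.trend_y)


def voom_transform(m: ExpressionMatrix, span: float = 0.5) -> VoomResult:
    """Transform normalized counts to log2 CPM with precision weights."""
    counts = m.values.to_numpy(dtype=float)
    n_genes, n_samples = counts.shape
    if n_samples < 2:
        raise ConfigurationError("voom requires at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(lib <= 0)]
        raise ConfigurationError(f"samples with zero library size: {bad}")

    log_cpm = np.log2((counts + 0.5) / (lib + 1.0)[None, :] * MILLION)

    # intercept-only residual sd per gene; abscissa is the mean log2 count
    gene_mean = log_cpm.mean(axis=1)
    resid_sd = log_cpm.std(axis=1, ddof=1)
    mean_log_lib = np.mean(np.log2(lib + 1.0))
    sx = gene_mean + mean_log_lib - np.log2(MILLION)
    sy = np.sqrt(resid_sd)

    order = np.argsort(sx, kind="stable")
    if n_genes >= 10:
        fit = lowess(sy[order], sx[order], frac=span, it=3, return_sorted=True)
        tx, ty = fit[:, 0], fit[:, 1]
    else:  # too few genes for a stable smooth: flat trend at the mean
        tx = np.array([sx.min(), sx.max()]) if n_genes > 1 else np.array([sx[0] - 1, sx[0] + 1])
        ty = np.full(2, sy.mean())
    # collapse duplicate abscissae for interpolation
    tx, uniq_idx = np.unique(tx, return_index=True)
    ty = ty[uniq_idx]
    if tx.size == 1:
        tx = np.array([tx[0] - 1.0, tx[0] + 1.0])
        ty = np.repeat(ty, 2)
    ty = np.clip(ty, 1e-6, None)

    # fitted log2 count of each observation under the intercept-only model
    fitted_log_count = gene_mean[:, None] + np.log2(lib + 1.0)[None, :] - np.log2(MILLION)
    trend_at = np.interp(np.clip(fitted_log_count, tx[0], tx[-1]), tx, ty)
    weights = 1.0 / trend_at**4

    gi, si = m.values.index, m.values.columns
    return VoomResult(
        pd.DataFrame(log_cpm, index=gi, columns=si),
        pd.DataFrame(weights, index=gi, columns=si),
        tx, ty,
    )


@dataclass(frozen=True)
class SplitIndex:
    """Stratified train/test partition of the cohort's samples."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    seed: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(d: StageDesign, ratio: float = 0.8, seed: int = 0) -> SplitIndex:
    """Split samples into train/test, stratified on the diagnosis class.

    Per-class train counts are ``round(ratio * class size)`` with
    round-half-away-from-zero; both partitions must keep at least one
    sample of each class.
    """
    if not 0 < ratio < 1:
        raise ConfigurationError("split ratio must lie strictly between 0 and 1")
    classes = d.classes
    present = classes.unique()
    if len(present) < 2:
        raise ConfigurationError("both classes must be present to stratify")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(present):
        ids = np.asarray(classes.index[classes == cls])
        if ids.size < 2:
            raise ConfigurationError(f"class '{cls}' has fewer than 2 samples")
        n_train = _round_half_away(ratio * ids.size)
        if n_train == 0 or n_train == ids.size:
            raise ConfigurationError(
                f"ratio {ratio} leaves class '{cls}' without train or test samples"
            )
        perm = rng.permutation(ids.size)
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    id_order = {s: i for i, s in enumerate(d.sample_ids)}
    train.sort(key=id_order.__getitem__)
    test.sort(key=id_order.__getitem__)
    return SplitIndex(tuple(train), tuple(test), ratio, seed)
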