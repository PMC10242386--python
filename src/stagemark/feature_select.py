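"""Feature-space minimization: Boruta, recursive feature elimination, VIF.

``boruta_select`` is a from-scratch implementation of the shadow-feature
wrapper algorithm: each iteration appends a shuffled ("shadow") copy of
every candidate feature, fits a random forest, and scores a *hit* for
every real feature whose importance beats the best shadow importance.
Features are confirmed or rejected by two-sided binomial tests on their
hit counts (Bonferroni-corrected across features); undecided features at
the iteration cap stay *tentative* and are treated as not selected.

``rfe_select`` wraps cross-validated recursive feature elimination with a
random-forest ranker; ``vif_eliminate`` iteratively removes the feature
with the largest variance inflation factor ``1 / (1 - R^2)`` while it
exceeds the multicollinearity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"

_MIN_SHADOWS = 10     # never fewer shadows than this
_SHADOW_FACTOR = 2    # shadows per active real feature: a stricter null bar


@dataclass
class BorutaResult:
    decisions: pd.Series = field(repr=False)  # feature -> confirmed/tentative/rejected
    hits: pd.Series = field(repr=False)
    n_iterations: int
    alpha: float

    @property
    def confirmed(self) -> list[str]:
        return list(self.decisions.index[self.decisions == CONFIRMED])

    @property
    def tentative(self) -> list[str]:
        return list(self.decisions.index[self.decisions == TENTATIVE])

    @property
    def rejected(self) -> list[str]:
        return list(self.decisions.index[self.decisions == REJECTED])


def _check_xy(x: pd.DataFrame, y: np.ndarray) -> None:
    if x.shape[1] < 2:
        raise ConfigurationError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("both classes must be present")
    if x.shape[0] != len(y):
        raise ConfigurationError("feature matrix and labels disagree on sample count")


def boruta_select(
    x: pd.DataFrame,
    y,
    alpha: float = 0.05,
    max_iter: int = 100,
    seed: int = 0,
    n_estimators: int = 100,
) -> BorutaResult:
    """All-relevant feature selection against shuffled shadow features.

    Deterministic for a fixed seed and invariant to the column order of
    ``x``: features are processed in sorted-id order internally.
    """
    y = np.asarray(y)
    _check_xy(x, y)
    features = sorted(x.columns)
    x = x[features]
    m = len(features)
    hits = {f: 0 for f in features}
    decided: dict[str, str] = {}
    n_iter = 0

    for it in range(1, max_iter + 1):
        active = [f for f in features if decided.get(f) != REJECTED]
        if not active or all(f in decided for f in features):
            break
        n_iter = it
        rng = np.random.default_rng([seed, it])
        xa = x[active].to_numpy()
        n_shadow = max(_SHADOW_FACTOR * len(active), _MIN_SHADOWS)
        shadow_src = xa[:, [i % len(active) for i in range(n_shadow)]]
        shadows = np.column_stack([rng.permutation(col) for col in shadow_src.T])
        design = np.column_stack([xa, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(design, y)
        imp = rf.feature_importances_
        shadow_max = imp[len(active):].max()
        for i, f in enumerate(active):
            if f not in decided and imp[i] > shadow_max:
                hits[f] += 1
        # Two-sided binomial decisions at alpha, Bonferroni-corrected over the m
        # features.  Confirmation is additionally corrected for the sequential
        # looks (one test per iteration), otherwise chance hit streaks confirm
        # spurious features; rejection stays per-look, as dropping a truly
        # relevant feature early merely costs iterations for the others.
        for f in features:
            if f in decided:
                continue
            h = hits[f]
            p_hi = stats.binom.sf(h - 1, it, 0.5)   # evidence of relevance
            p_lo = stats.binom.cdf(h, it, 0.5)      # evidence of irrelevance
            if 2.0 * p_hi * m * it < alpha:
                decided[f] = CONFIRMED
            elif 2.0 * p_lo * m < alpha:
                decided[f] = REJECTED
        if all(f in decided for f in features):
            break

    decisions = pd.Series(
        {f: decided.get(f, TENTATIVE) for f in features}, name="decision"
    ).reindex(features)
    return BorutaResult(decisions, pd.Series(hits).reindex(features), n_iter, alpha)


def _rfe_ranking(x: np.ndarray, y: np.ndarray, seed: int, n_estimators: int) -> list[int]:
    """Backward-elimination order: feature indices from first- to last-eliminated."""
    remaining = list(range(x.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ).fit(x[:, remaining], y)
        worst = remaining[int(np.argmin(rf.feature_importances_))]
        eliminated.append(worst)
        remaining.remove(worst)
    return eliminated + remaining


def rfe_select(
    x: pd.DataFrame,
    y,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 200,
) -> list[str]:
    """Backward elimination with cross-validated subset-size selection.

    Features are eliminated least-important-first (random-forest
    importances); every subset size is scored by stratified k-fold CV
    accuracy, and the size with the best mean accuracy wins.  Exact ties
    keep the larger subset: a feature is discarded only when a smaller
    panel is positively better, the conservative choice for an
    all-relevant biomarker panel.
    """
    y = np.asarray(y)
    if x.shape[1] == 1:
        return list(x.columns)
    _check_xy(x, y)
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ConfigurationError(
            f"folds={folds} exceeds the smallest class size ({counts.min()})"
        )
    arr = x.to_numpy()
    p = arr.shape[1]
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    # score[s] = CV accuracy using the s best-ranked features of each fold
    correct = np.zeros(p)
    total = 0
    for tr, te in skf.split(arr, y):
        order = _rfe_ranking(arr[tr], y[tr], seed, n_estimators)
        total += len(te)
        for size in range(1, p + 1):
            keep = order[p - size:]
            rf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            ).fit(arr[tr][:, keep], y[tr])
            correct[size - 1] += (rf.predict(arr[te][:, keep]) == y[te]).sum()
    best_size = int(np.flatnonzero(correct == correct.max()).max()) + 1
    order = _rfe_ranking(arr, y, seed, n_estimators)
    keep = sorted(order[p - best_size:])
    return [x.columns[i] for i in keep]


# ---------------------------------------------------------------------------
# variance inflation


@dataclass
class VIFRound:
    scores: dict[str, float]
    removed: str | None


@dataclass
class VIFReport:
    rounds: list[VIFRound]
    kept: list[str]

    @property
    def removed(self) -> list[str]:
        return [r.removed for r in self.rounds if r.removed is not None]

    @property
    def final_scores(self) -> dict[str, float]:
        return self.rounds[-1].scores


def vif_from_r2(r2: float) -> float:
    """VIF = 1 / (1 - R^2); +inf for (numerically) perfect collinearity."""
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def _r2_on_others(target: np.ndarray, others: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(target)), others])
    coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    tss = float(((target - target.mean()) ** 2).sum())
    if tss == 0:
        raise ConfigurationError("constant feature: R^2 undefined")
    return 1.0 - float((resid**2).sum()) / tss


def compute_vifs(x: pd.DataFrame) -> dict[str, float]:
    """VIF of each column from regressing it on all the others."""
    if x.shape[1] < 2:
        raise ConfigurationError("VIF needs at least 2 features")
    arr = x.to_numpy(dtype=float)
    if (arr.std(axis=0) == 0).any():
        bad = list(x.columns[arr.std(axis=0) == 0])
        raise ConfigurationError(f"constant features have undefined VIF: {bad}")
    out = {}
    for i, col in enumerate(x.columns):
        others = np.delete(arr, i, axis=1)
        out[col] = vif_from_r2(_r2_on_others(arr[:, i], others))
    return out


def elimination_decision(scores: dict[str, float], threshold: float = 2.0) -> str | None:
    """Feature to remove this round, or None if every VIF is within threshold.

    The round's maximum VIF is removed when it exceeds the threshold; exact
    ties resolve to the lexicographically smallest feature id.
    """
    max_vif = max(scores.values())
    if max_vif <= threshold:
        return None
    return min(f for f, v in scores.items() if v == max_vif)


def vif_eliminate(x: pd.DataFrame, threshold: float = 2.0) -> VIFReport:
    """Iteratively remove the worst multicollinear feature until all VIFs pass."""
    cols = list(x.columns)
    rounds: list[VIFRound] = []
    while len(cols) >= 2:
        scores = compute_vifs(x[cols])
        removed = elimination_decision(scores, threshold)
        rounds.append(VIFRound(scores, removed))
        if removed is None:
            break
        cols.remove(removed)
    if not rounds:  # single feature: trivially independent
        rounds.append(VIFRound({c: 1.0 for c in cols}, None))
    return VIFReport(rounds, cols)
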