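"""PCA of the biomarker subspace and a k-means diagnosis classifier.

PCA is an eigendecomposition of the sample covariance matrix of the
centered (not scaled) biomarker features.  The number of retained
components reconciles three standard criteria: Kaiser-Guttmann
(eigenvalue > 1), the scree elbow (largest perpendicular distance to the
chord joining the first and last eigenvalues), and the smallest count
explaining a target share of variance.  A k = 2 k-means fit in the
retained PC space, with clusters mapped to the majority training class,
acts as the cancer-vs-normal classifier; prediction projects new samples
into PC space and assigns the nearest centroid, with a signed
distance-difference margin (positive = cancer) that doubles as the AUROC
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold

from .containers import CLASS_CANCER, CLASS_NORMAL
from .errors import ConfigurationError
from .metrics import ConfusionCounts, MetricsRecord, compute_metrics


@dataclass
class PCAModel:
    feature_ids: list[str]
    means: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)     # features x components, orthonormal
    eigenvalues: np.ndarray = field(repr=False)  # non-increasing, >= 0
    n_components: int = 0                        # chosen q; 0 = all

    @property
    def q(self) -> int:
        return self.n_components or len(self.eigenvalues)

    def with_components(self, q: int) -> "PCAModel":
        if not 1 <= q <= len(self.eigenvalues):
            raise ConfigurationError(f"component count {q} outside 1..{len(self.eigenvalues)}")
        return replace(self, n_components=q)

    def transform(self, x: pd.DataFrame) -> np.ndarray:
        """Project samples x features onto the top-q loadings."""
        missing = [f for f in self.feature_ids if f not in x.columns]
        if missing:
            raise ConfigurationError(f"missing features: {missing}")
        arr = x[self.feature_ids].to_numpy(dtype=float)
        return (arr - self.means) @ self.loadings[:, : self.q]


def fit_pca(x: pd.DataFrame) -> PCAModel:
    """Eigendecomposition of the sample covariance of centered features.

    Loadings follow the sign convention that each column's
    largest-magnitude entry is positive.
    """
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ConfigurationError("PCA needs >= 2 samples and >= 2 features")
    arr = x.to_numpy(dtype=float)
    if (arr.std(axis=0) == 0).any():
        bad = list(x.columns[arr.std(axis=0) == 0])
        raise ConfigurationError(f"constant features give a degenerate covariance: {bad}")
    means = arr.mean(axis=0)
    cov = np.cov(arr - means, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return PCAModel(list(x.columns), means, evecs, evals)


def variance_explained(eigenvalues) -> tuple[np.ndarray, np.ndarray]:
    """Percent variance per component and the running cumulative percent."""
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        raise ConfigurationError("eigenvalues sum to zero: variance shares undefined")
    pct = 100.0 * ev / total
    return pct, np.cumsum(pct)


@dataclass(frozen=True)
class PcCountCriteria:
    kaiser_count: int
    scree_count: int
    variance_count: int
    var_threshold: float

    @property
    def reconciled(self) -> int:
        return int(np.median([self.kaiser_count, self.scree_count, self.variance_count]))


def _scree_elbow(ev: np.ndarray) -> int:
    """Index (1-based) of the eigenvalue farthest from the first-last chord."""
    p = ev.size
    if p <= 2:
        return 1
    idx = np.arange(1, p + 1, dtype=float)
    dx, dy = p - 1.0, ev[-1] - ev[0]
    norm = math.hypot(dx, dy)
    dist = np.abs(dx * (ev - ev[0]) - dy * (idx - 1.0)) / norm
    return int(np.argmax(dist)) + 1


def pc_count_criteria(eigenvalues, var_threshold: float = 85.0) -> PcCountCriteria:
    """Apply the three component-count criteria and reconcile by their median."""
    ev = np.asarray(getattr(eigenvalues, "eigenvalues", eigenvalues), dtype=float)
    kaiser = max(1, int((ev > 1.0).sum()))
    scree = _scree_elbow(ev)
    _, cum = variance_explained(ev)
    variance = int(np.argmax(cum >= var_threshold)) + 1
    return PcCountCriteria(kaiser, scree, variance, var_threshold)


def silhouette_optimal_k(scores: np.ndarray, k_range=range(2, 9), seed: int = 0) -> int:
    """k maximizing the mean silhouette width over seeded k-means fits."""
    ks = sorted(k_range)
    n = scores.shape[0]
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ConfigurationError(f"k range must lie in [2, {n - 1}]")
    best_k, best_s = ks[0], -np.inf
    for k in ks:
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(scores)
        s = silhouette_score(scores, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


@dataclass
class KMeansClassifier:
    k: int
    centroids: np.ndarray = field(repr=False)  # k x q, in PC space
    cluster_to_class: dict[int, str]
    inertia: float
    seed: int

    @property
    def cancer_centroid(self) -> np.ndarray:
        return next(self.centroids[c] for c, cls in self.cluster_to_class.items()
                    if cls == CLASS_CANCER)

    @property
    def normal_centroid(self) -> np.ndarray:
        return next(self.centroids[c] for c, cls in self.cluster_to_class.items()
                    if cls == CLASS_NORMAL)


def fit_classifier(scores: np.ndarray, labels, k: int = 2, seed: int = 0) -> KMeansClassifier:
    """k-means in PC space with majority-label cluster-to-class mapping."""
    labels = np.asarray(labels)
    if k != 2:
        raise ConfigurationError("the diagnosis classifier requires k = 2")
    if set(np.unique(labels)) != {CLASS_CANCER, CLASS_NORMAL}:
        raise ConfigurationError("training labels must contain both classes")
    km = KMeans(n_clusters=k, n_init=10, tol=1e-6, random_state=seed).fit(scores)
    mapping: dict[int, str] = {}
    for c in range(k):
        members = labels[km.labels_ == c]
        n_cancer = int((members == CLASS_CANCER).sum())
        n_normal = len(members) - n_cancer
        if n_cancer == n_normal:
            raise ConfigurationError(f"cluster {c} has a 50/50 class tie: mapping undefined")
        mapping[c] = CLASS_CANCER if n_cancer > n_normal else CLASS_NORMAL
    if set(mapping.values()) != {CLASS_CANCER, CLASS_NORMAL}:
        raise ConfigurationError(
            "both clusters map to the same majority class: clustering does not "
            "separate the diagnoses"
        )
    return KMeansClassifier(k, km.cluster_centers_, mapping, float(km.inertia_), seed)


def classify_scores(clf: KMeansClassifier, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid classes and margins for PC-space coordinates.

    margin = d(normal centroid) - d(cancer centroid); positive predicts
    cancer, and an exactly equidistant sample is conservatively called
    normal.
    """
    d_cancer = np.linalg.norm(scores - clf.cancer_centroid, axis=1)
    d_normal = np.linalg.norm(scores - clf.normal_centroid, axis=1)
    margin = d_normal - d_cancer
    classes = np.where(margin > 0, CLASS_CANCER, CLASS_NORMAL)
    return classes, margin


def predict(
    pca: PCAModel,
    clf: KMeansClassifier,
    samples: pd.DataFrame,
    input_scale: str = "linear",
) -> pd.DataFrame:
    """Classify new samples (rows) from their biomarker expression (columns).

    ``input_scale='linear'`` applies log2(x + 1) first; ``'log2'`` uses the
    values as given.  Features are matched by id, so column order is
    irrelevant.  Returns a frame with ``predicted_class`` and ``margin``
    in input row order.
    """
    if input_scale not in ("linear", "log2"):
        raise ConfigurationError("input_scale must be 'linear' or 'log2'")
    missing = [f for f in pca.feature_ids if f not in samples.columns]
    if missing:
        raise ConfigurationError(f"samples are missing panel features: {missing}")
    vals = samples[pca.feature_ids].apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        bad = vals.index[vals.isna().any(axis=1)].tolist()
        raise ConfigurationError(f"non-numeric expression values in samples: {bad}")
    if input_scale == "linear":
        if (vals.to_numpy() < 0).any():
            raise ConfigurationError("linear-scale expression must be non-negative")
        vals = np.log2(vals + 1.0)
    scores = pca.transform(vals)
    classes, margin = classify_scores(clf, scores)
    return pd.DataFrame(
        {"predicted_class": classes, "margin": margin}, index=samples.index
    )


def cross_validate(
    x: pd.DataFrame,
    labels,
    folds: int = 5,
    seed: int = 0,
    var_threshold: float = 85.0,
    k: int = 2,
) -> dict:
    """Stratified k-fold CV refitting PCA, component choice, and k-means per fold.

    Held-out predictions are pooled into a single metrics record; fold
    assignment is seeded and reproducible.
    """
    labels = np.asarray(labels)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ConfigurationError("every fold needs both classes: smallest class too small")
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    pooled_true, pooled_pred, pooled_margin = [], [], []
    fold_metrics = []
    for fold, (tr, te) in enumerate(skf.split(x, labels)):
        model = fit_pca(x.iloc[tr])
        q = pc_count_criteria(model.eigenvalues, var_threshold).reconciled
        model = model.with_components(q)
        clf = fit_classifier(model.transform(x.iloc[tr]), labels[tr], k=k, seed=seed)
        classes, margin = classify_scores(clf, model.transform(x.iloc[te]))
        counts_f = ConfusionCounts.from_labels(labels[te], classes)
        fold_metrics.append(compute_metrics(counts_f, margin, labels[te]))
        pooled_true.extend(labels[te])
        pooled_pred.extend(classes)
        pooled_margin.extend(margin)
    pooled = compute_metrics(
        ConfusionCounts.from_labels(pooled_true, pooled_pred),
        np.asarray(pooled_margin),
        np.asarray(pooled_true),
    )
    return {"folds": fold_metrics, "pooled": pooled}
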