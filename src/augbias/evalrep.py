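"""Evaluation of frozen representations.

Linear probing (multinomial logistic regression on an 80/20 stratified split),
k-means clustering with restarts, silhouette, adjusted mutual information, and
a perceptual dissimilarity between augmented view pairs.

The perceptual metric follows the layered feature-space construction of LPIPS:
images pass through a convolutional feature stack, per-layer feature maps are
channel-unit-normalized, and squared differences are averaged spatially and
summed over layers. The default backend uses a fixed, seeded random-weight
stack so no pretrained weights are needed; any callable with the same
signature can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_mutual_info_score, silhouette_score as _sk_silhouette
from sklearn.model_selection import train_test_split

from .nn.autodiff import Tensor, conv2d, relu

__all__ = [
    "RepresentationSet",
    "ClusterReport",
    "linear_probe",
    "cluster_kmeans",
    "silhouette",
    "adjusted_mutual_information",
    "perceptual_dissimilarity",
    "RandomConvPerceptualBackend",
    "evaluate_clustering",
]


@dataclass
class RepresentationSet:
    """Embedding matrix with labels; the common currency of the evaluations."""

    embeddings: np.ndarray
    labels: np.ndarray
    aux_labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be 2-D")
        if len(self.embeddings) != len(self.labels):
            raise ValueError("embeddings/labels length mismatch")
        if not np.isfinite(self.embeddings).all():
            raise ValueError("embeddings contain NaN/Inf")
        if self.aux_labels is not None:
            self.aux_labels = np.asarray(self.aux_labels, dtype=int)


@dataclass
class ClusterReport:
    k: int
    assignments: np.ndarray
    silhouette: float
    ami: float
    top1: float
    per_class_acc: dict[int, float]
    perceptual: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "assignments": self.assignments.tolist(),
            "silhouette": self.silhouette,
            "ami": self.ami,
            "top1": self.top1,
            "per_class_acc": {int(k): v for k, v in self.per_class_acc.items()},
            "perceptual": self.perceptual,
            "extra": self.extra,
        }


# ---------------------------------------------------------------------------
# probing
# ---------------------------------------------------------------------------

def linear_probe(reps: RepresentationSet, train_fraction: float = 0.8,
                 seed: int = 0, labels: np.ndarray | None = None,
                 max_iter: int = 300):
    """Top-1 accuracy and per-class recall of a linear classifier on embeddings.

    The classifier (L2-regularized multinomial logistic regression) is fitted
    on a stratified ``train_fraction`` split of the embeddings only — the
    encoder stays frozen — and scored on the held-out split.
    """
    y = reps.labels if labels is None else np.asarray(labels, dtype=int)
    x = reps.embeddings
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=y)
    train_classes = set(y[train_idx])
    if len(train_classes) < 2 or len(set(y[test_idx])) < 2:
        raise ValueError("need >= 2 classes present in both split halves")
    if set(y) - train_classes:
        raise ValueError("a class is absent from the train split")
    clf = LogisticRegression(max_iter=max_iter, C=1.0)
    clf.fit(x[train_idx], y[train_idx])
    pred = clf.predict(x[test_idx])
    truth = y[test_idx]
    top1 = float((pred == truth).mean())
    per_class = {int(c): float((pred[truth == c] == c).mean()) for c in np.unique(truth)}
    return top1, per_class


# ---------------------------------------------------------------------------
# clustering metrics
# ---------------------------------------------------------------------------

def cluster_kmeans(reps: RepresentationSet, k: int, n_restarts: int = 10,
                   seed: int = 0) -> np.ndarray:
    """Best-inertia k-means assignment over ``n_restarts`` seeded inits."""
    n = len(reps.embeddings)
    if k < 2 or k > n:
        raise ValueError("k must satisfy 2 <= k <= N")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(reps.embeddings)


def silhouette(reps: RepresentationSet, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient, Euclidean metric; singletons contribute 0."""
    assignments = np.asarray(assignments)
    if len(np.unique(assignments)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if len(assignments) < 3:
        raise ValueError("need at least 3 samples")
    return float(_sk_silhouette(reps.embeddings, assignments, metric="euclidean"))


def adjusted_mutual_information(assignments: np.ndarray, labels: np.ndarray) -> float:
    """AMI with the arithmetic-mean entropy normalizer and hypergeometric E[MI]."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if len(assignments) != len(labels):
        raise ValueError("length mismatch")
    return float(adjusted_mutual_info_score(labels, assignments,
                                            average_method="arithmetic"))


# ---------------------------------------------------------------------------
# perceptual dissimilarity
# ---------------------------------------------------------------------------

class RandomConvPerceptualBackend:
    """Fixed random-weight convolutional feature stack for perceptual distance.

    Three stride-2 conv+ReLU layers with He-initialized weights drawn once from
    ``seed``. Channel-unit-normalized per-layer features, squared differences
    averaged over space and channels, summed over layers — the LPIPS recipe
    with uniform (rather than learned) layer weights.
    """

    def __init__(self, seed: int = 0, channels=(8, 16, 32)):
        self.seed = seed
        self.channels = channels
        self._weights: dict[int, list[np.ndarray]] = {}

    def _get_weights(self, in_ch: int) -> list[np.ndarray]:
        if in_ch not in self._weights:
            rng = np.random.default_rng(self.seed)
            ws = []
            prev = in_ch
            for ch in self.channels:
                scale = np.sqrt(2.0 / (prev * 9))
                ws.append(rng.normal(0.0, scale, (ch, prev, 3, 3)))
                prev = ch
            self._weights[in_ch] = ws
        return self._weights[in_ch]

    def features(self, batch: np.ndarray) -> list[np.ndarray]:
        """batch (N,C,H,W) -> list of per-layer feature maps."""
        x = Tensor(batch)
        feats = []
        for w in self._get_weights(batch.shape[1]):
            x = relu(conv2d(x, Tensor(w), stride=2, pad=1))
            feats.append(x.data)
        return feats

    def __call__(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Per-pair distances for two (N,C,H,W) batches."""
        dists = np.zeros(a.shape[0])
        for fa, fb in zip(self.features(a), self.features(b)):
            na = fa / np.sqrt((fa**2).sum(axis=1, keepdims=True) + 1e-10)
            nb = fb / np.sqrt((fb**2).sum(axis=1, keepdims=True) + 1e-10)
            dists += ((na - nb) ** 2).sum(axis=1).mean(axis=(1, 2))
        return dists


def perceptual_dissimilarity(pairs, backend=None) -> float:
    """Mean layered feature-space distance over (view1, view2) pairs.

    ``pairs`` is a sequence of (H,W,C) image pairs or a pair of (N,H,W,C)
    arrays. The default backend is :class:`RandomConvPerceptualBackend`.
    """
    backend = backend or RandomConvPerceptualBackend()
    if isinstance(pairs, tuple) and len(pairs) == 2 and np.asarray(pairs[0]).ndim == 4:
        a, b = (np.asarray(p) for p in pairs)
    else:
        a = np.stack([np.asarray(p[0]) for p in pairs])
        b = np.stack([np.asarray(p[1]) for p in pairs])
    if a.shape != b.shape:
        raise ValueError("views must share a shape")
    a = a.transpose(0, 3, 1, 2)
    b = b.transpose(0, 3, 1, 2)
    return float(backend(a, b).mean())


# ---------------------------------------------------------------------------
# one-call evaluation
# ---------------------------------------------------------------------------

def evaluate_clustering(reps: RepresentationSet, k: int, seed: int = 0,
                        n_restarts: int = 10, probe_fraction: float = 0.8,
                        ami_labels: np.ndarray | None = None,
                        perceptual: float | None = None) -> ClusterReport:
    """K-means + silhouette + AMI + linear probe in one report."""
    assignments = cluster_kmeans(reps, k, n_restarts=n_restarts, seed=seed)
    labels = reps.labels if ami_labels is None else np.asarray(ami_labels)
    top1, per_class = linear_probe(reps, probe_fraction, seed=seed, labels=labels)
    return ClusterReport(
        k=k,
        assignments=assignments,
        silhouette=silhouette(reps, assignments),
        ami=adjusted_mutual_information(assignments, labels),
        top1=top1,
        per_class_acc=per_class,
        perceptual=perceptual,
    )
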