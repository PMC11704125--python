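"""Evaluation metrics against brute-force oracles and analytic cases."""

import itertools
import math

import numpy as np
import pytest

from augbias.evalrep import (
    RandomConvPerceptualBackend,
    RepresentationSet,
    adjusted_mutual_information,
    cluster_kmeans,
    linear_probe,
    perceptual_dissimilarity,
    silhouette,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def silhouette_bruteforce(x: np.ndarray, labels: np.ndarray) -> float:
    """Direct double-loop silhouette; singleton clusters contribute 0."""
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    scores = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            scores[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == other].mean()
                for other in set(labels) if other != labels[i])
        scores[i] = (b - a) / max(a, b)
    return scores.mean()


def ami_bruteforce(u: np.ndarray, v: np.ndarray) -> float:
    """AMI by direct hypergeometric-model expected-MI summation."""
    n = len(u)
    us, vs = sorted(set(u)), sorted(set(v))
    a = np.array([(u == i).sum() for i in us])
    b = np.array([(v == j).sum() for j in vs])
    mi = 0.0
    for i, ui in enumerate(us):
        for j, vj in enumerate(vs):
            nij = ((u == ui) & (v == vj)).sum()
            if nij:
                mi += nij / n * math.log(n * nij / (a[i] * b[j]))
    emi = 0.0
    for ai in a:
        for bj in b:
            lo, hi = max(1, ai + bj - n), min(ai, bj)
            for nij in range(lo, hi + 1):
                p = math.exp(
                    math.lgamma(ai + 1) - math.lgamma(nij + 1) - math.lgamma(ai - nij + 1)
                    + math.lgamma(n - ai + 1) - math.lgamma(bj - nij + 1)
                    - math.lgamma(n - ai - bj + nij + 1)
                    - (math.lgamma(n + 1) - math.lgamma(bj + 1) - math.lgamma(n - bj + 1)))
                emi += p * nij / n * math.log(n * nij / (ai * bj))
    h_u = -sum(ai / n * math.log(ai / n) for ai in a)
    h_v = -sum(bj / n * math.log(bj / n) for bj in b)
    denom = 0.5 * (h_u + h_v) - emi
    return (mi - emi) / denom


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def test_silhouette_two_tight_pairs_matches_hand_formula():
    """{(0,0),(0,1)} vs {(10,0),(10,1)}: s = (b-1)/b with b = (10+sqrt(101))/2."""
    x = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    labels = np.array([0, 0, 1, 1])
    b = (10.0 + np.sqrt(101.0)) / 2.0
    expected = (b - 1.0) / b  # = 0.9002...
    reps = RepresentationSet(x, labels)
    assert silhouette(reps, labels) == pytest.approx(expected, abs=1e-10)
    assert expected == pytest.approx(0.9002, abs=5e-4)


def test_silhouette_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(0)
    for trial in range(5):
        n = rng.integers(10, 50)
        x = rng.normal(size=(n, 3))
        labels = rng.integers(0, 3, n)
        if len(set(labels)) < 2:
            continue
        reps = RepresentationSet(x, labels)
        assert silhouette(reps, labels) == pytest.approx(
            silhouette_bruteforce(x, labels), abs=1e-10)


def test_silhouette_near_zero_for_one_distribution():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(400, 2))
    labels = rng.integers(0, 2, 400)
    assert abs(silhouette(RepresentationSet(x, labels), labels)) < 0.05


def test_silhouette_errors():
    x = np.zeros((4, 2))
    with pytest.raises(ValueError):
        silhouette(RepresentationSet(x, np.zeros(4, dtype=int)), np.zeros(4, dtype=int))


# ---------------------------------------------------------------------------
# adjusted mutual information
# ---------------------------------------------------------------------------

def test_ami_identical_partitions_is_one():
    labels = np.array([0, 0, 1, 1, 2, 2, 2])
    assert adjusted_mutual_information(labels, labels) == pytest.approx(1.0)


def test_ami_matches_bruteforce_on_3x3_contingencies():
    rng = np.random.default_rng(1)
    for _ in range(5):
        u = rng.integers(0, 3, 30)
        v = rng.integers(0, 3, 30)
        assert adjusted_mutual_information(u, v) == pytest.approx(
            ami_bruteforce(u, v), abs=1e-10)


def test_ami_independent_partitions_near_zero():
    rng = np.random.default_rng(2)
    u = rng.integers(0, 10, 10_000)
    v = rng.integers(0, 10, 10_000)
    assert abs(adjusted_mutual_information(u, v)) < 0.02


def test_ami_invariant_to_cluster_relabeling():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 4, 200)
    assignments = rng.integers(0, 4, 200)
    perm = np.array([2, 3, 0, 1])
    assert adjusted_mutual_information(perm[assignments], labels) == pytest.approx(
        adjusted_mutual_information(assignments, labels))


def test_ami_length_mismatch():
    with pytest.raises(ValueError):
        adjusted_mutual_information(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def test_kmeans_recovers_separated_blobs():
    rng = np.random.default_rng(0)
    x = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(8, 0.1, (30, 2))])
    labels = np.repeat([0, 1], 30)
    asg = cluster_kmeans(RepresentationSet(x, labels), 2, seed=0)
    assert adjusted_mutual_information(asg, labels) == pytest.approx(1.0)


def test_kmeans_validation():
    reps = RepresentationSet(np.random.default_rng(0).normal(size=(10, 2)),
                             np.zeros(10, dtype=int))
    with pytest.raises(ValueError):
        cluster_kmeans(reps, 1)
    with pytest.raises(ValueError):
        cluster_kmeans(reps, 11)


# ---------------------------------------------------------------------------
# linear probe
# ---------------------------------------------------------------------------

def test_probe_perfect_on_separable_classes():
    rng = np.random.default_rng(0)
    x = np.vstack([rng.normal(0, 0.2, (50, 4)), rng.normal(5, 0.2, (50, 4))])
    labels = np.repeat([0, 1], 50)
    top1, per_class = linear_probe(RepresentationSet(x, labels), seed=0)
    assert top1 == 1.0
    assert per_class == {0: 1.0, 1: 1.0}


def test_probe_chance_level_on_shuffled_labels():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2000, 8))
    labels = np.repeat([0, 1], 1000)
    top1, _ = linear_probe(RepresentationSet(x, labels), seed=0)
    assert 0.45 <= top1 <= 0.55


def test_per_class_accuracies_average_to_top1():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(300, 6))
    x[:100] += 1.0
    labels = np.repeat([0, 1, 2], 100)
    top1, per_class = linear_probe(RepresentationSet(x, labels), seed=3)
    # weighted by held-out class counts, recalls reproduce overall accuracy
    test_n = 60
    counts = {c: test_n // 3 for c in per_class}
    weighted = sum(per_class[c] * counts[c] for c in per_class) / test_n
    assert weighted == pytest.approx(top1, abs=1e-12)


def test_probe_rejects_single_class():
    x = np.random.default_rng(0).normal(size=(40, 3))
    with pytest.raises(ValueError):
        linear_probe(RepresentationSet(x, np.zeros(40, dtype=int)), seed=0)


# ---------------------------------------------------------------------------
# perceptual dissimilarity
# ---------------------------------------------------------------------------

def test_perceptual_identity_and_symmetry():
    rng = np.random.default_rng(0)
    a = rng.random((4, 16, 16, 1))
    b = rng.random((4, 16, 16, 1))
    backend = RandomConvPerceptualBackend(seed=0)
    assert perceptual_dissimilarity((a, a), backend) == pytest.approx(0.0, abs=1e-12)
    assert perceptual_dissimilarity((a, b), backend) == pytest.approx(
        perceptual_dissimilarity((b, a), backend))
    assert perceptual_dissimilarity((a, b), backend) > 0


def test_perceptual_shape_mismatch():
    a = np.zeros((2, 16, 16, 1))
    b = np.zeros((2, 8, 8, 1))
    with pytest.raises(ValueError):
        perceptual_dissimilarity((a, b))


def test_evaluate_clustering_report_is_consistent():
    from augbias.evalrep import evaluate_clustering

    rng = np.random.default_rng(5)
    x = np.vstack([rng.normal(0, 0.3, (40, 3)), rng.normal(4, 0.3, (40, 3))])
    labels = np.repeat([0, 1], 40)
    report = evaluate_clustering(RepresentationSet(x, labels), k=2, seed=0)
    assert report.k == 2
    assert set(report.assignments) <= {0, 1}
    assert -1 <= report.silhouette <= 1
    assert report.ami == pytest.approx(
        adjusted_mutual_information(report.assignments, labels))
    d = report.to_dict()
    assert d["top1"] == report.top1 and len(d["assignments"]) == 80


def test_representation_set_validation():
    with pytest.raises(ValueError):
        RepresentationSet(np.full((3, 2), np.nan), np.zeros(3, dtype=int))
    with pytest.raises(ValueError):
        RepresentationSet(np.zeros((3, 2)), np.zeros(4, dtype=int))
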