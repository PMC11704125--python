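"""Inter-class bias statistics over accuracy-vs-transformation surfaces.

The substrate is an :class:`AccuracySurface`: per-class linear-probe accuracy
indexed by (class, transformation-parameter value, seed). On top of it this
module provides the full statistics chain of the sweep study:

* pairwise class-accuracy correlations (Pearson, Kendall, Spearman, with
  two-sided p-values), computed on seed-mean curves;
* the opposite-behavior flagging rule — a pair is flagged when at least one of
  the three coefficients is below −0.3 with its own p-value below 0.05;
* the bias ratio — the fraction of classes involved in at least one flagged
  pair;
* behavior categorization of each class (ascending / descending / random) from
  the sign and significance of the OLS slope of accuracy on parameter value;
* class-property metrics (intrinsic dimension, co-occurrence texture contrast,
  high-frequency spectral fraction, effective covariance rank) and their
  ANOVA/MANOVA association with behavior groups;
* superclass mean-accuracy profiles and cross-method overlap of flagged
  classes.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix, graycoprops

__all__ = [
    "AccuracySurface",
    "CorrelationRecord",
    "BiasReport",
    "BehaviorLabel",
    "ClassPropertyRecord",
    "correlate_accuracy_pair",
    "correlate_all_pairs",
    "flag_opposite_pairs",
    "bias_ratio",
    "classify_behavior",
    "classify_all_behaviors",
    "class_property_profile",
    "property_behavior_association",
    "superclass_profile",
    "shared_negative_overlap",
    "intrinsic_dimension_twonn",
    "effective_rank",
    "high_frequency_fraction",
    "texture_contrast",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AccuracySurface:
    """accuracies[class, parameter value, seed] in [0, 1]."""

    accuracies: np.ndarray
    param_name: str
    param_values: np.ndarray
    class_names: list[str]
    superclass_map: dict[str, str] | None = None

    def __post_init__(self):
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        self.param_values = np.asarray(self.param_values, dtype=np.float64)
        if self.accuracies.ndim != 3:
            raise ValueError("accuracies must be (class, value, seed)")
        nc, nv, _ = self.accuracies.shape
        if nv != len(self.param_values):
            raise ValueError("param_values length mismatch")
        if nc != len(self.class_names):
            raise ValueError("class_names length mismatch")
        if self.accuracies.size and (self.accuracies.min() < 0 or self.accuracies.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.accuracies.shape[0]

    def seed_mean(self) -> np.ndarray:
        """(class, value) mean accuracy over seeds."""
        return self.accuracies.mean(axis=2)

    # -- tidy CSV persistence ------------------------------------------------
    def to_csv(self, path: str):
        nc, nv, ns = self.accuracies.shape
        c, v, s = np.meshgrid(np.arange(nc), np.arange(nv), np.arange(ns), indexing="ij")
        pd.DataFrame({
            "class_name": np.asarray(self.class_names)[c.ravel()],
            "param_value": self.param_values[v.ravel()],
            "seed": s.ravel(),
            "accuracy": self.accuracies.ravel(),
        }).to_csv(path, index=False)
        header = {
            "param_name": self.param_name,
            "class_names": list(self.class_names),
            "param_values": self.param_values.tolist(),
            "superclass_map": self.superclass_map,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(header, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str) -> "AccuracySurface":
        with open(str(path) + ".json") as fh:
            header = json.load(fh)
        table = pd.read_csv(path)
        class_names = header["class_names"]
        param_values = np.asarray(header["param_values"])
        ns = int(table["seed"].max()) + 1
        acc = np.zeros((len(class_names), len(param_values), ns))
        cidx = {c: i for i, c in enumerate(class_names)}
        for row in table.itertuples():
            vi = int(np.argmin(np.abs(param_values - row.param_value)))
            acc[cidx[row.class_name], vi, int(row.seed)] = row.accuracy
        return cls(acc, header["param_name"], param_values, class_names,
                   header.get("superclass_map"))


@dataclass
class CorrelationRecord:
    class_a: int
    class_b: int
    pearson: float | None
    kendall: float | None
    spearman: float | None
    p_pearson: float | None
    p_kendall: float | None
    p_spearman: float | None


@dataclass
class BiasReport:
    flagged_pairs: list[tuple]           # (class_a, class_b, [coefficient names])
    ratio: float
    context: dict = field(default_factory=dict)
    class_names: list[str] | None = None

    def flagged_classes(self) -> set[int]:
        out: set[int] = set()
        for a, b, _ in self.flagged_pairs:
            out.add(a)
            out.add(b)
        return out

    def to_json(self) -> str:
        return json.dumps({
            "flagged_pairs": [[a, b, list(c)] for a, b, c in self.flagged_pairs],
            "ratio": self.ratio,
            "context": self.context,
            "class_names": self.class_names,
        }, indent=1)


@dataclass
class BehaviorLabel:
    class_index: int
    label: str          # ascending | descending | random
    slope: float
    slope_p: float


@dataclass
class ClassPropertyRecord:
    class_index: int
    intrinsic_dim: float | None
    texture: float
    fourier: float
    cov_spectrum: float


# ---------------------------------------------------------------------------
# correlations, flagging, ratios
# ---------------------------------------------------------------------------

def _safe_corr(fn, x, y):
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None  # correlation undefined for a constant curve
    res = fn(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_accuracy_pair(surface: AccuracySurface, a: int, b: int) -> CorrelationRecord:
    """Three rank/linear correlations between seed-mean curves of classes a, b."""
    if len(surface.param_values) < 3:
        raise ValueError("need at least 3 parameter values")
    curves = surface.seed_mean()
    xa, xb = curves[a], curves[b]
    pr, pp = _safe_corr(stats.pearsonr, xa, xb)
    kr, kp = _safe_corr(stats.kendalltau, xa, xb)
    sr, sp = _safe_corr(stats.spearmanr, xa, xb)
    return CorrelationRecord(a, b, pr, kr, sr, pp, kp, sp)


def correlate_all_pairs(surface: AccuracySurface) -> list[CorrelationRecord]:
    return [correlate_accuracy_pair(surface, a, b)
            for a, b in itertools.combinations(range(surface.n_classes), 2)]


def flag_opposite_pairs(records: list[CorrelationRecord], threshold: float = -0.3,
                        alpha: float = 0.05) -> list[tuple]:
    """Pairs with >= 1 coefficient below ``threshold`` at its own p < ``alpha``."""
    flagged = []
    for r in records:
        hits = []
        for name in ("pearson", "kendall", "spearman"):
            c = getattr(r, name)
            p = getattr(r, "p_" + name)
            if c is not None and p is not None and c < threshold and p < alpha:
                hits.append(name)
        if hits:
            flagged.append((r.class_a, r.class_b, hits))
    return flagged


def bias_ratio(flagged: list[tuple], n_classes: int) -> float:
    """Fraction of classes appearing in at least one flagged pair."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    classes: set[int] = set()
    for a, b, *_ in flagged:
        classes.add(a)
        classes.add(b)
    return len(classes) / n_classes


def make_bias_report(surface: AccuracySurface, threshold: float = -0.3,
                     alpha: float = 0.05, context: dict | None = None) -> BiasReport:
    records = correlate_all_pairs(surface)
    flagged = flag_opposite_pairs(records, threshold=threshold, alpha=alpha)
    return BiasReport(flagged, bias_ratio(flagged, surface.n_classes),
                      context or {}, list(surface.class_names))


__all__.append("make_bias_report")


# ---------------------------------------------------------------------------
# behavior categorization
# ---------------------------------------------------------------------------

def classify_behavior(surface: AccuracySurface, class_index: int,
                      slope_alpha: float = 0.05) -> BehaviorLabel:
    """Label a class ascending/descending/random from its OLS accuracy slope."""
    if len(surface.param_values) < 3:
        raise ValueError("need at least 3 parameter values")
    y = surface.seed_mean()[class_index]
    x = surface.param_values
    if np.ptp(y) == 0:
        return BehaviorLabel(class_index, "random", 0.0, 1.0)
    res = stats.linregress(x, y)
    if res.pvalue < slope_alpha:
        label = "ascending" if res.slope > 0 else "descending"
    else:
        label = "random"
    return BehaviorLabel(class_index, label, float(res.slope), float(res.pvalue))


def classify_all_behaviors(surface: AccuracySurface, slope_alpha: float = 0.05) -> list[BehaviorLabel]:
    return [classify_behavior(surface, c, slope_alpha) for c in range(surface.n_classes)]


# ---------------------------------------------------------------------------
# class-property metrics
# ---------------------------------------------------------------------------

def intrinsic_dimension_twonn(features: np.ndarray) -> float:
    """Two-nearest-neighbor maximum-likelihood intrinsic dimension.

    For each point, mu = r2 / r1 (distances to the two nearest neighbors);
    the MLE over n points is d = n / sum(log mu).
    """
    x = np.asarray(features, dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for the two-NN estimator")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=3).fit(x)
    dist, _ = nn.kneighbors(x)
    r1, r2 = dist[:, 1], dist[:, 2]
    ok = r1 > 0
    mu = r2[ok] / r1[ok]
    log_mu = np.log(mu)
    s = log_mu.sum()
    if s <= 0:
        return float("nan")
    return float(ok.sum() / s)


def effective_rank(features: np.ndarray) -> float:
    """exp(entropy) of the normalized covariance eigenvalue distribution (>= 1)."""
    x = np.asarray(features, dtype=np.float64)
    x = x - x.mean(axis=0, keepdims=True)
    cov = x.T @ x / max(len(x) - 1, 1)
    ev = np.linalg.eigvalsh(cov)
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        return 1.0
    p = ev / total
    p = p[p > 0]
    return float(np.exp(-(p * np.log(p)).sum()))


def high_frequency_fraction(images: np.ndarray) -> float:
    """Energy above half-Nyquist radial frequency in the mean power spectrum.

    DC is excluded; returns a fraction in [0, 1]."""
    imgs = np.asarray(images, dtype=np.float64)
    if imgs.ndim == 4:
        imgs = imgs.mean(axis=3)
    spec = np.abs(np.fft.fft2(imgs, axes=(1, 2))) ** 2
    spec = np.fft.fftshift(spec, axes=(1, 2)).mean(axis=0)
    h, w = spec.shape
    fy = np.fft.fftshift(np.fft.fftfreq(h))
    fx = np.fft.fftshift(np.fft.fftfreq(w))
    r = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    mask_dc = r > 1e-12
    total = spec[mask_dc].sum()
    if total <= 0:
        return 0.0
    high = spec[mask_dc & (r > 0.25)].sum()  # half of the 0.5 Nyquist frequency
    return float(high / total)


def texture_contrast(images: np.ndarray, levels: int = 32) -> float:
    """Mean gray-level co-occurrence contrast (distance 1, 0 and 90 degrees)."""
    imgs = np.asarray(images, dtype=np.float64)
    if imgs.ndim == 4:
        imgs = imgs.mean(axis=3)
    vals = []
    for img in imgs:
        q = np.clip((img * (levels - 1)).round().astype(np.uint8), 0, levels - 1)
        glcm = graycomatrix(q, distances=[1], angles=[0, np.pi / 2],
                            levels=levels, symmetric=True, normed=True)
        vals.append(graycoprops(glcm, "contrast").mean())
    return float(np.mean(vals))


def _pca_features(images: np.ndarray, n_components: int = 20, seed: int = 0) -> np.ndarray:
    from sklearn.decomposition import PCA

    imgs = np.asarray(images, dtype=np.float64)
    flat = imgs.reshape(len(imgs), -1)
    k = min(n_components, flat.shape[1], len(flat))
    return PCA(n_components=k, random_state=seed).fit_transform(flat)


def class_property_profile(dataset, features: np.ndarray | None = None,
                           n_components: int = 20) -> list[ClassPropertyRecord]:
    """Per-class property metrics on images + per-image features.

    ``features`` defaults to a PCA of raw pixels fitted across the whole
    dataset; a pluggable feature matrix (e.g. pretrained-network embeddings)
    can be passed instead. Classes need >= 2 images; intrinsic dimension is
    reported as None below 3 samples.
    """
    images, labels = dataset.images, dataset.labels
    if features is None:
        features = _pca_features(images, n_components=n_components)
    records = []
    for c in np.unique(labels):
        idx = labels == c
        if idx.sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 images")
        cls_imgs = images[idx]
        cls_feat = features[idx]
        idim = intrinsic_dimension_twonn(cls_feat) if idx.sum() >= 3 else None
        records.append(ClassPropertyRecord(
            class_index=int(c),
            intrinsic_dim=idim,
            texture=texture_contrast(cls_imgs),
            fourier=high_frequency_fraction(cls_imgs),
            cov_spectrum=effective_rank(cls_feat),
        ))
    return records


# ---------------------------------------------------------------------------
# property-behavior association (ANOVA / MANOVA)
# ---------------------------------------------------------------------------

def _wilks_manova(groups: list[np.ndarray]):
    """Wilks' lambda one-way MANOVA with Rao's F approximation."""
    X = np.vstack(groups)
    n, p = X.shape
    g = len(groups)
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp in groups:
        m = grp.mean(axis=0)
        d = grp - m
        W += d.T @ d
        dm = (m - grand).reshape(-1, 1)
        B += len(grp) * (dm @ dm.T)
    T = W + B
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        lam = 1e-300
    else:
        lam = float(np.exp(logdet_w - logdet_t))
    lam = float(np.clip(lam, 1e-300, 1.0))
    q = g - 1
    # Rao's approximation
    t = math.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    df1 = p * q
    df2 = (n - 1 - (p + g) / 2.0) * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return lam, float(F), df1, float(df2), pval


def property_behavior_association(properties: list[ClassPropertyRecord],
                                  behaviors: list[BehaviorLabel]) -> dict:
    """One-way ANOVA per property across behavior groups + Wilks-lambda MANOVA.

    F values substantially above 1 indicate that behavior groups differ in
    that property. Raises when fewer than two behavior groups are present or
    any group has fewer than two classes.
    """
    by_class = {b.class_index: b.label for b in behaviors}
    names = ["intrinsic_dim", "texture", "fourier", "cov_spectrum"]
    rows = []
    labels = []
    for rec in properties:
        vals = [rec.intrinsic_dim, rec.texture, rec.fourier, rec.cov_spectrum]
        if any(v is None or not np.isfinite(v) for v in vals):
            continue
        rows.append(vals)
        labels.append(by_class[rec.class_index])
    X = np.asarray(rows, dtype=np.float64)
    labels = np.asarray(labels)
    groups_ids = sorted(set(labels))
    if len(groups_ids) < 2:
        raise ValueError("need at least 2 behavior groups")
    groups = [X[labels == gid] for gid in groups_ids]
    if any(len(grp) < 2 for grp in groups):
        raise ValueError("each behavior group needs at least 2 classes")

    out: dict = {"groups": groups_ids, "anova": {}, "manova": {}}
    for j, name in enumerate(names):
        cols = [grp[:, j] for grp in groups]
        if np.ptp(np.concatenate(cols)) == 0:
            out["anova"][name] = {"F": 0.0, "p": 1.0}
            continue
        res = stats.f_oneway(*cols)
        F = float(res.statistic) if np.isfinite(res.statistic) else 0.0
        p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        out["anova"][name] = {"F": F, "p": p}
    lam, F, df1, df2, pval = _wilks_manova(groups)
    out["manova"] = {"wilks_lambda": lam, "F": F, "df1": df1, "df2": df2, "p": pval}
    return out


# ---------------------------------------------------------------------------
# superclass profiles and cross-method overlap
# ---------------------------------------------------------------------------

def superclass_profile(surface: AccuracySurface) -> pd.DataFrame:
    """Unweighted mean of member-class seed-mean curves per superclass.

    Returns a tidy frame (superclass, param_value, mean_accuracy) plus the
    argmax parameter value per superclass in ``DataFrame.attrs['argmax']``.
    """
    if surface.superclass_map is None:
        raise ValueError("surface has no superclass_map")
    curves = surface.seed_mean()
    members: dict[str, list[int]] = {}
    for i, cname in enumerate(surface.class_names):
        members.setdefault(surface.superclass_map[cname], []).append(i)
    rows = []
    argmax = {}
    for sc, idx in members.items():
        if not idx:
            raise ValueError(f"superclass {sc} is empty")
        prof = curves[idx].mean(axis=0)
        argmax[sc] = float(surface.param_values[int(np.argmax(prof))])
        for v, acc in zip(surface.param_values, prof):
            rows.append({"superclass": sc, "param_value": v, "mean_accuracy": acc})
    frame = pd.DataFrame(rows)
    frame.attrs["argmax"] = argmax
    return frame


def shared_negative_overlap(reports: list[BiasReport]) -> pd.DataFrame:
    """Pairwise overlap of flagged class sets across methods.

    Returns (method_a, method_b, overlap, jaccard) for every report pair;
    reports must share the same class universe."""
    universes = [tuple(r.class_names) if r.class_names else None for r in reports]
    if len(set(universes)) > 1:
        raise ValueError("reports have mismatched class universes")
    rows = []
    for i, j in itertools.combinations(range(len(reports)), 2):
        si, sj = reports[i].flagged_classes(), reports[j].flagged_classes()
        inter = len(si & sj)
        union = len(si | sj)
        rows.append({
            "method_a": reports[i].context.get("method", str(i)),
            "method_b": reports[j].context.get("method", str(j)),
            "overlap": inter,
            "jaccard": inter / union if union else 0.0,
        })
    return pd.DataFrame(rows)
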