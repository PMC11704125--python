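"""Image classes with controlled property orderings.

Each class is built so one of the class-property metrics has a known value or
ordering: ``("constant",)`` images have zero texture contrast and zero
high-frequency energy; ``("latent", d)`` images live on a d-dimensional linear
manifold in pixel space (fixed smooth basis, uniform coefficients) so the
two-NN intrinsic-dimension estimate should recover d; ``("lowpass",)`` /
``("checkerboard",)`` / ``("periodic", f)`` control spectral content.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..data import ImageDataset
from ..rng import child_rng

__all__ = ["gen_property_classes", "DEFAULT_KINDS"]

DEFAULT_KINDS = [
    ("latent", 2),
    ("latent", 8),
    ("lowpass",),
    ("checkerboard",),
    ("periodic", 4),
    ("constant",),
]


def _latent_images(n, size, d, rng):
    # fixed smooth orthogonal-ish basis; coefficients uniform in [-1, 1]
    basis = np.stack([
        ndimage.gaussian_filter(rng.normal(size=(size, size)), 3.0, mode="wrap")
        for _ in range(d)
    ])
    basis /= np.sqrt((basis**2).sum(axis=(1, 2), keepdims=True))
    coef = rng.uniform(-1.0, 1.0, (n, d))
    imgs = np.tensordot(coef, basis, axes=(1, 0))
    amp = np.abs(imgs).max()
    return 0.5 + 0.45 * imgs / max(amp, 1e-12)


def _lowpass_images(n, size, rng):
    imgs = ndimage.gaussian_filter(rng.normal(size=(n, size, size)),
                                   (0, 4.0, 4.0), mode="wrap")
    imgs /= np.abs(imgs).max()
    return 0.5 + 0.45 * imgs


def _checkerboard_images(n, size, rng):
    yy, xx = np.mgrid[0:size, 0:size]
    out = np.zeros((n, size, size))
    for i in range(n):
        phase = rng.integers(0, 2)
        contrast = rng.uniform(0.6, 1.0)
        board = ((xx + yy + phase) % 2).astype(np.float64)
        out[i] = 0.5 + contrast * (board - 0.5)
    return np.clip(out, 0.0, 1.0)


def _periodic_images(n, size, rng, freq):
    yy, xx = np.mgrid[0:size, 0:size] / size
    out = np.zeros((n, size, size))
    for i in range(n):
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)
        out[i] = 0.5 + 0.45 * wave
    return out


def _constant_images(n, size, rng):
    levels = rng.uniform(0.2, 0.8, n)
    return np.broadcast_to(levels[:, None, None], (n, size, size)).copy()


def gen_property_classes(n_classes: int, n_per_class: int, seed: int,
                         image_size: int = 24,
                         kinds: list[tuple] | None = None) -> ImageDataset:
    """Classes with known property orderings; labels index the class kinds."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if kinds is None:
        kinds = [DEFAULT_KINDS[i % len(DEFAULT_KINDS)] for i in range(n_classes)]
    if len(kinds) != n_classes:
        raise ValueError("kinds length must equal n_classes")

    images = []
    labels = []
    for c, kind in enumerate(kinds):
        rng = child_rng(seed, "property", c)
        name = kind[0]
        if name == "latent":
            imgs = _latent_images(n_per_class, image_size, int(kind[1]), rng)
        elif name == "lowpass":
            imgs = _lowpass_images(n_per_class, image_size, rng)
        elif name == "checkerboard":
            imgs = _checkerboard_images(n_per_class, image_size, rng)
        elif name == "periodic":
            imgs = _periodic_images(n_per_class, image_size, rng, float(kind[1]))
        elif name == "constant":
            imgs = _constant_images(n_per_class, image_size, rng)
        else:
            raise ValueError(f"unknown class kind {name!r}")
        images.append(np.clip(imgs, 0.0, 1.0))
        labels.extend([c] * n_per_class)

    meta = {"generator": "gen_property_classes", "kinds": [list(k) for k in kinds],
            "seed": seed, "image_size": image_size}
    return ImageDataset(np.concatenate(images)[..., None], np.asarray(labels), None, meta)
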