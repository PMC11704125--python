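"""Synthetic centered-cell microscopy crops.

Each image emulates a single-channel field cropped around one detected nucleus:
a central cell rendered as a deformed-ellipse intensity profile with
multiplicative texture, a Poisson number of non-central neighbor cells kept
away from the center, and additive background noise.

Two conditions are generated. Untreated cells draw their shape/texture
parameters from a baseline distribution. Treated cells belong to one of
``n_phenotypes`` morphological sub-phenotypes whose parameter means deviate
from baseline by an amount scaled by ``effect_size`` (radius, eccentricity and
texture grain all shift, so phenotypes differ in size, shape and texture). A
``resemble_fraction`` share of treated cells is drawn from the untreated
parameter distribution while keeping the treated condition label — the
lookalike subpopulation that makes condition separation genuinely hard.

The condition-relevant signal is concentrated in the central cell. Neighbor
cells in treated images respond to the treatment as well (a well-wide
response, at the same effect size but rendered smaller and dimmer), so the
periphery carries a weaker, complementary condition signal, mirroring the
role of inter-cellular context in high-content screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..data import ImageDataset
from ..rng import child_rng

__all__ = ["CellImageConfig", "gen_cell_images"]


@dataclass
class CellImageConfig:
    image_size: int = 64
    n_untreated: int = 100
    n_treated: int = 100
    n_phenotypes: int = 3
    effect_size: float = 0.7
    resemble_fraction: float = 0.2
    neighbor_rate: float = 1.0
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_untreated < 0 or self.n_treated < 0:
            raise ValueError("counts must be >= 0")
        if self.n_phenotypes < 1:
            raise ValueError("n_phenotypes must be >= 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if not 0.0 <= self.resemble_fraction <= 1.0:
            raise ValueError("resemble_fraction must lie in [0, 1]")
        if self.neighbor_rate < 0:
            raise ValueError("neighbor_rate must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size too small to contain the central cell")


# baseline (untreated) morphology, in fractions of image size
_BASE = dict(radius=0.16, ecc=0.20, grain=1.5, tex_amp=0.25, intensity=0.70)

# per-phenotype deviation directions, scaled by effect_size; cycled if
# n_phenotypes exceeds the table. All phenotypes share a common response axis
# (elongation plus coarser internal texture) while cell size and brightness
# stay nearly matched to the untreated population, so the condition signal
# lives in central-cell shape and texture rather than in trivial intensity
# statistics — the subtle regime the microscopy study targets.
_PHENO_DELTAS = [
    dict(radius=+0.35, ecc=+0.50, grain=+2.5, intensity=0.0),   # swollen, coarse
    dict(radius=+0.25, ecc=+0.65, grain=+1.5, intensity=0.0),   # strongly elongated
    dict(radius=+0.30, ecc=+0.35, grain=+3.5, intensity=0.0),   # very coarse texture
    dict(radius=+0.20, ecc=+0.50, grain=+2.0, intensity=0.0),   # intermediate
]


def _smooth_noise(shape, sigma, rng):
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def _render_cell(canvas, cx, cy, radius_px, ecc, theta, grain, tex_amp, intensity, rng):
    """Draw one deformed-ellipse cell onto canvas (max blend), in place."""
    size = canvas.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    # area-preserving elongation: semi-axes r(1+e) and r/(1+e)
    u = (ct * dx + st * dy) / (radius_px * (1.0 + ecc))
    v = (-st * dx + ct * dy) / (radius_px / (1.0 + ecc))
    phi = np.arctan2(v, u)
    p0, p1 = rng.uniform(0, 2 * np.pi, 2)
    boundary = 1.0 + 0.10 * np.sin(3 * phi + p0) + 0.06 * np.sin(5 * phi + p1)
    d = np.sqrt(u**2 + v**2) / boundary
    body = 1.0 / (1.0 + np.exp((d - 1.0) / 0.08))
    texture = 1.0 + tex_amp * _smooth_noise((size, size), grain, rng)
    cell = intensity * body * np.clip(texture, 0.0, 2.0)
    np.maximum(canvas, np.clip(cell, 0.0, 1.0), out=canvas)


def _draw_params(rng, pheno: int, effect_size: float):
    """Sample one cell's morphology; pheno 0 = untreated baseline."""
    p = dict(_BASE)
    if pheno > 0:
        d = _PHENO_DELTAS[(pheno - 1) % len(_PHENO_DELTAS)]
        p["radius"] *= 1.0 + effect_size * d["radius"]
        p["ecc"] = np.clip(p["ecc"] + effect_size * d["ecc"], 0.0, 0.85)
        p["grain"] = max(0.6, p["grain"] + effect_size * d["grain"])
        p["intensity"] = np.clip(p["intensity"] + effect_size * d["intensity"], 0.1, 1.0)
    # within-population variability
    p["radius"] *= rng.uniform(0.88, 1.12)
    p["ecc"] = np.clip(p["ecc"] + rng.uniform(-0.06, 0.06), 0.0, 0.9)
    p["intensity"] = np.clip(p["intensity"] + rng.uniform(-0.06, 0.06), 0.1, 1.0)
    return p


def gen_cell_images(config: CellImageConfig) -> ImageDataset:
    """Generate the two-condition centered-cell dataset.

    Returns an :class:`ImageDataset` with ``labels`` = condition (0 untreated,
    1 treated) and ``aux_labels`` = phenotype id (0 for untreated and for
    treated lookalikes, 1..n_phenotypes otherwise). Bit-identical for a fixed
    config.
    """
    size = config.image_size
    if int(round(_BASE["radius"] * size)) < 3:
        raise ValueError("image_size too small to contain the central cell")
    n_total = config.n_untreated + config.n_treated
    images = np.zeros((n_total, size, size), dtype=np.float64)
    labels = np.zeros(n_total, dtype=int)
    aux = np.zeros(n_total, dtype=int)

    for i in range(n_total):
        treated = i >= config.n_untreated
        rng = child_rng(config.seed, "cell", i)
        labels[i] = int(treated)
        if treated:
            if rng.random() < config.resemble_fraction:
                pheno = 0  # lookalike: untreated morphology, treated label
            else:
                pheno = 1 + int(rng.integers(config.n_phenotypes))
        else:
            pheno = 0
        aux[i] = pheno

        canvas = images[i]
        params = _draw_params(rng, pheno, config.effect_size)
        radius_px = params["radius"] * size
        jitter = rng.uniform(-0.03, 0.03, 2) * size
        cx, cy = size / 2 + jitter[0], size / 2 + jitter[1]
        theta = rng.uniform(0, 2 * np.pi)
        _render_cell(canvas, cx, cy, radius_px, params["ecc"], theta,
                     params["grain"], params["tex_amp"], params["intensity"], rng)

        # neighbors: kept off-center; in treated images they share the central
        # phenotype (well-wide treatment response), so the periphery carries a
        # weaker complementary condition signal
        n_neighbors = int(rng.poisson(config.neighbor_rate))
        margin = radius_px + 2.0
        for _ in range(n_neighbors):
            nb = _draw_params(rng, pheno, config.effect_size)
            nb_radius = nb["radius"] * size * rng.uniform(0.5, 0.7)
            for _attempt in range(20):
                nx, ny = rng.uniform(0, size, 2)
                if np.hypot(nx - cx, ny - cy) >= margin + nb_radius:
                    break
            else:
                continue
            _render_cell(canvas, nx, ny, nb_radius, nb["ecc"],
                         rng.uniform(0, 2 * np.pi), nb["grain"], nb["tex_amp"],
                         nb["intensity"] * 0.5, rng)

        if config.noise_sd > 0:
            canvas += rng.normal(0.0, config.noise_sd, canvas.shape)
        np.clip(canvas, 0.0, 1.0, out=canvas)

    meta = {"generator": "gen_cell_images", **vars(config)}
    return ImageDataset(images[..., None], labels, aux, meta)
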