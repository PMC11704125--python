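"""Procedural glyph images with two independent factors: glyph class and stroke style.

Glyph classes are polyline stroke templates with distinctive orientation
structure (bars, corners, crosses, zigzags), so class identity is legible
under mild perturbations but scrambles under full-circle rotation and flips.
Style is a stroke-thickness level with a small associated slant — an
orientation-free attribute that survives rotation, emulating handwriting
weight and flow. The two factors are sampled independently.
"""

from __future__ import annotations

import numpy as np

from ..data import ImageDataset
from ..rng import child_rng

__all__ = ["gen_glyph_images", "GLYPH_TEMPLATES"]

# stroke templates in unit coordinates; each is a list of (x0,y0,x1,y1) segments
GLYPH_TEMPLATES = [
    [(0.20, 0.50, 0.80, 0.50)],                                            # horizontal bar
    [(0.50, 0.20, 0.50, 0.80)],                                            # vertical bar
    [(0.22, 0.22, 0.78, 0.78)],                                            # diagonal
    [(0.25, 0.20, 0.25, 0.80), (0.25, 0.80, 0.75, 0.80)],                  # L
    [(0.20, 0.25, 0.80, 0.25), (0.50, 0.25, 0.50, 0.80)],                  # T
    [(0.22, 0.22, 0.78, 0.78), (0.22, 0.78, 0.78, 0.22)],                  # X
    [(0.22, 0.25, 0.50, 0.80), (0.50, 0.80, 0.78, 0.25)],                  # V
    [(0.22, 0.25, 0.78, 0.25), (0.78, 0.25, 0.22, 0.78), (0.22, 0.78, 0.78, 0.78)],  # Z
    [(0.30, 0.22, 0.30, 0.78), (0.30, 0.22, 0.72, 0.35), (0.30, 0.55, 0.68, 0.62)],  # F-ish
    [(0.28, 0.30, 0.72, 0.30), (0.28, 0.30, 0.28, 0.70), (0.28, 0.70, 0.72, 0.70)],  # C-ish
]


def _seg_distance(xx, yy, seg):
    x0, y0, x1, y1 = seg
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / max(L2, 1e-12), 0.0, 1.0)
    return np.hypot(xx - (x0 + t * vx), yy - (y0 + t * vy))


def _render_glyph(size, segments, thickness, slant_deg, jitter, rng):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / (size - 1)
    # shear around the glyph center (style slant)
    shear = np.tan(np.deg2rad(slant_deg))
    xs = xx + shear * (yy - 0.5)
    xs = xs + jitter[0]
    ys = yy + jitter[1]
    d = np.full((size, size), np.inf)
    for seg in segments:
        d = np.minimum(d, _seg_distance(xs, ys, seg))
    edge = 0.6 / size
    img = 1.0 / (1.0 + np.exp((d - thickness / 2.0) / edge))
    return img


def _bar_template(angle_deg: float) -> list[tuple]:
    """A single centered bar at the given orientation (unit coordinates)."""
    a = np.deg2rad(angle_deg)
    dx, dy = 0.36 * np.cos(a), 0.36 * np.sin(a)
    return [(0.5 - dx, 0.5 - dy, 0.5 + dx, 0.5 + dy)]


def gen_glyph_images(n_per_class: int, n_classes: int, style_levels: int,
                     seed: int, image_size: int = 32,
                     noise_sd: float = 0.02,
                     template_set: str = "mixed") -> ImageDataset:
    """Glyphs with independent class and style factors.

    ``labels`` = glyph class (exactly ``n_per_class`` each), ``aux_labels`` =
    style level drawn uniformly and independently of class. Raises if a style
    setting would render an empty image.

    ``template_set`` selects the class geometry: ``"mixed"`` uses the
    multi-stroke templates (bars, corners, crosses); ``"bars"`` uses single
    bars at ``n_classes`` evenly spaced orientations in [0°, 180°), so class
    identity is purely orientational — legible under slight rotations, fully
    scrambled by full-circle rotations and flips.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if template_set == "mixed":
        if n_classes > len(GLYPH_TEMPLATES):
            raise ValueError(f"at most {len(GLYPH_TEMPLATES)} glyph classes available")
        templates = GLYPH_TEMPLATES[:n_classes]
        slant_scale = 1.0
    elif template_set == "bars":
        templates = [_bar_template(180.0 * c / n_classes) for c in range(n_classes)]
        slant_scale = 0.0  # slant would alias with orientation classes
    else:
        raise ValueError("template_set must be 'mixed' or 'bars'")
    if style_levels < 1:
        raise ValueError("style_levels must be >= 1")

    # style is deliberately subtle relative to glyph identity: a modest
    # thickness step plus a mild slant, emulating handwriting weight/flow
    thicknesses = [0.06 + (0.02 * l / max(style_levels - 1, 1)) for l in range(style_levels)]
    slants = [slant_scale * (-6.0 + 12.0 * l / max(style_levels - 1, 1))
              for l in range(style_levels)]
    if min(thicknesses) * image_size < 1.0:
        raise ValueError("style renders an empty image: stroke thinner than one pixel")

    n_total = n_per_class * n_classes
    images = np.zeros((n_total, image_size, image_size), dtype=np.float64)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    aux = np.zeros(n_total, dtype=int)

    for i in range(n_total):
        rng = child_rng(seed, "glyph", i)
        style = int(rng.integers(style_levels))
        aux[i] = style
        jitter = rng.uniform(-0.04, 0.04, 2)
        img = _render_glyph(image_size, templates[labels[i]],
                            thicknesses[style], slants[style], jitter, rng)
        if img.max() < 0.1:
            raise ValueError("style renders an empty image")
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        images[i] = np.clip(img, 0.0, 1.0)

    meta = {"generator": "gen_glyph_images", "n_per_class": n_per_class,
            "n_classes": n_classes, "style_levels": style_levels, "seed": seed,
            "image_size": image_size}
    return ImageDataset(images[..., None], labels, aux, meta)
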