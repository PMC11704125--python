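"""Parameterized stochastic image transformations and their compositions.

The unit of augmentation is a :class:`TransformSpec` — a kind (crop, jitter,
flip, rotation, affine, pad, inversion, erase), an application probability and
a kind-specific amplitude. An ordered list of specs forms a
:class:`TransformComposition`; applying a composition to an image draws all
randomness from a single caller-supplied generator, so view pairs are
reproducible. :func:`sweep_compositions` expands one composition into a grid
that varies a single targeted parameter, the substrate of the parameter-sweep
study.

Images are H×W×C float arrays with intensities in [0, 1] (C = 1 for
microscopy-style single channel, 3 for RGB). Every transformation maps that
range into itself.

Conventions (the literature leaves these open):

* ``random_crop_resize`` amplitude is the retained-**area** fraction range
  ``(lo, hi)``; the window is square, uniformly placed, and resized back to the
  input resolution (bilinear).
* ``center_crop_fraction`` amplitude is the retained **side** fraction, so 0.5
  on a 64×64 image keeps the centered 32×32 window.
* ``color_jitter`` on single-channel images degrades to brightness/contrast
  jitter; a hue shift is added only for RGB.
* Rotation and affine warps use bilinear interpolation with reflection padding.
* ``erase`` blanks a rectangle of 10–30 % of the area (scaled by amplitude)
  with the image mean intensity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from skimage import transform as sktf

__all__ = [
    "TransformSpec",
    "TransformComposition",
    "SweepGrid",
    "apply_composition",
    "make_view_pair",
    "sweep_compositions",
    "identity_composition",
    "glyph_set1",
    "glyph_set2",
    "cell_crop_set",
    "cell_rotation_set",
    "cell_center_set",
]

KINDS = {
    "random_crop_resize",
    "center_crop_fraction",
    "color_jitter",
    "hflip",
    "vflip",
    "rotate",
    "affine",
    "pad",
    "invert",
    "erase",
}

_DEFAULT_AMPLITUDE = {
    "random_crop_resize": (0.4, 0.9),
    "center_crop_fraction": 0.5,
    "color_jitter": 0.4,
    "hflip": None,
    "vflip": None,
    "rotate": 15.0,
    "affine": 0.5,
    "pad": 0.15,
    "invert": None,
    "erase": 1.0,
}


@dataclass
class TransformSpec:
    kind: str
    probability: float = 1.0
    amplitude: object = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.amplitude is None:
            self.amplitude = _DEFAULT_AMPLITUDE[self.kind]
        self._validate_amplitude()

    def _validate_amplitude(self):
        a = self.amplitude
        if self.kind == "random_crop_resize":
            lo, hi = (a, a) if np.isscalar(a) else a
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("crop area fractions must lie in (0, 1]")
        elif self.kind == "center_crop_fraction":
            if not (0.0 < a <= 1.0):
                raise ValueError("center-crop side fraction must lie in (0, 1]")
        elif self.kind == "rotate":
            if not (0.0 <= a <= 360.0):
                raise ValueError("rotation amplitude must lie in [0, 360] degrees")
        elif self.kind == "pad":
            if not (0.0 <= a <= 1.0):
                raise ValueError("pad fraction must lie in [0, 1]")
        elif self.kind in ("color_jitter", "affine", "erase"):
            if not (0.0 <= float(a)):
                raise ValueError(f"{self.kind} amplitude must be nonnegative")


@dataclass
class TransformComposition:
    specs: list[TransformSpec]
    name: str = "composition"

    def __post_init__(self):
        if not self.specs:
            raise ValueError("composition must contain at least one spec")

    # -- YAML round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "specs": [
                {"kind": s.kind, "probability": s.probability,
                 "amplitude": list(s.amplitude) if isinstance(s.amplitude, tuple) else s.amplitude}
                for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformComposition":
        specs = [
            TransformSpec(
                kind=s["kind"],
                probability=s.get("probability", 1.0),
                amplitude=tuple(s["amplitude"]) if isinstance(s.get("amplitude"), list) else s.get("amplitude"),
            )
            for s in d["specs"]
        ]
        return cls(specs=specs, name=d.get("name", "composition"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TransformComposition":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class SweepGrid:
    """Targets one parameter field of one spec inside a composition."""

    spec_index: int
    parameter: str  # "probability" or "amplitude"
    values: list = field(default_factory=list)
    n_seeds: int = 5

    def __post_init__(self):
        if self.parameter not in ("probability", "amplitude"):
            raise ValueError("parameter must be 'probability' or 'amplitude'")
        if len(self.values) < 1:
            raise ValueError("grid needs at least one value")
        vals = [v if np.isscalar(v) else tuple(v) for v in self.values]
        scalars = [v for v in vals if np.isscalar(v)]
        if scalars != sorted(scalars):
            raise ValueError("grid values must be sorted ascending")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    def to_dict(self) -> dict:
        return {"spec_index": self.spec_index, "parameter": self.parameter,
                "values": [list(v) if isinstance(v, tuple) else v for v in self.values],
                "n_seeds": self.n_seeds}

    @classmethod
    def from_dict(cls, d: dict) -> "SweepGrid":
        vals = [tuple(v) if isinstance(v, list) else v for v in d["values"]]
        return cls(spec_index=d["spec_index"], parameter=d["parameter"],
                   values=vals, n_seeds=d.get("n_seeds", 5))


# ---------------------------------------------------------------------------
# individual transformations
# ---------------------------------------------------------------------------

def _resize(img: np.ndarray, shape) -> np.ndarray:
    return sktf.resize(img, shape + img.shape[2:], order=1, mode="reflect",
                       anti_aliasing=False, preserve_range=True)


def _crop_resize(img, top, left, size):
    h, w = img.shape[:2]
    if size > h or size > w:
        raise ValueError("crop window larger than image")
    window = img[top : top + size, left : left + size]
    return _resize(window, (h, w))


def _t_random_crop_resize(img, amp, rng):
    lo, hi = (amp, amp) if np.isscalar(amp) else amp
    h, w = img.shape[:2]
    area = rng.uniform(lo, hi)
    size = max(2, int(round(np.sqrt(area) * min(h, w))))
    size = min(size, h, w)
    top = rng.integers(0, h - size + 1)
    left = rng.integers(0, w - size + 1)
    return _crop_resize(img, int(top), int(left), size)


def _t_center_crop_fraction(img, amp, rng):
    h, w = img.shape[:2]
    size = max(2, int(round(amp * min(h, w))))
    top = (h - size) // 2
    left = (w - size) // 2
    return _crop_resize(img, top, left, size)


def _t_color_jitter(img, amp, rng):
    out = img.copy()
    mean = out.mean()
    contrast = 1.0 + rng.uniform(-amp, amp)
    brightness = rng.uniform(-amp, amp) * 0.5
    out = (out - mean) * contrast + mean + brightness
    if img.ndim == 3 and img.shape[2] == 3:
        # cheap hue-ish perturbation: rescale channels around their mean
        gains = 1.0 + rng.uniform(-amp, amp, size=3) * 0.5
        out = out * gains.reshape(1, 1, 3)
    return np.clip(out, 0.0, 1.0)


def _t_hflip(img, amp, rng):
    return img[:, ::-1].copy()


def _t_vflip(img, amp, rng):
    return img[::-1].copy()


def _warp_affine(img, m, offset):
    """Bilinear warp with reflect padding; (row, col) convention, per channel."""
    if img.ndim == 2:
        return ndimage.affine_transform(img, m, offset=offset, order=1, mode="reflect")
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = ndimage.affine_transform(img[..., c], m, offset=offset,
                                               order=1, mode="reflect")
    return out


def _t_rotate(img, amp, rng):
    angle = np.deg2rad(rng.uniform(-amp, amp))
    c, s = np.cos(angle), np.sin(angle)
    m = np.array([[c, s], [-s, c]])
    center = (np.asarray(img.shape[:2]) - 1) / 2.0
    return _warp_affine(img, m, center - m @ center)


def _t_affine(img, amp, rng):
    h, w = img.shape[:2]
    shear = np.deg2rad(rng.uniform(-15.0, 15.0) * amp)
    scale = 1.0 + rng.uniform(-0.15, 0.15) * amp
    ty = rng.uniform(-0.15, 0.15) * amp * h
    tx = rng.uniform(-0.15, 0.15) * amp * w
    # scale + x-shear about the image center, then translate
    m = np.linalg.inv(np.array([[scale, 0.0], [scale * np.tan(shear), scale]]))
    center = (np.asarray(img.shape[:2]) - 1) / 2.0
    return _warp_affine(img, m, center - m @ (center + np.array([ty, tx])))


def _t_pad(img, amp, rng):
    h, w = img.shape[:2]
    p = int(round(amp * min(h, w)))
    if p == 0:
        return img
    pad_width = ((p, p), (p, p)) + (((0, 0),) if img.ndim == 3 else ())
    return _resize(np.pad(img, pad_width), (h, w))


def _t_invert(img, amp, rng):
    return 1.0 - img


def _t_erase(img, amp, rng):
    h, w = img.shape[:2]
    area_frac = rng.uniform(0.1, 0.3) * amp
    aspect = rng.uniform(0.5, 2.0)
    eh = int(round(np.sqrt(area_frac * h * w * aspect)))
    ew = int(round(np.sqrt(area_frac * h * w / aspect)))
    eh, ew = min(max(eh, 1), h), min(max(ew, 1), w)
    top = rng.integers(0, h - eh + 1)
    left = rng.integers(0, w - ew + 1)
    out = img.copy()
    out[top : top + eh, left : left + ew] = img.mean()
    return out


_APPLY = {
    "random_crop_resize": _t_random_crop_resize,
    "center_crop_fraction": _t_center_crop_fraction,
    "color_jitter": _t_color_jitter,
    "hflip": _t_hflip,
    "vflip": _t_vflip,
    "rotate": _t_rotate,
    "affine": _t_affine,
    "pad": _t_pad,
    "invert": _t_invert,
    "erase": _t_erase,
}


def apply_composition(image: np.ndarray, comp: TransformComposition,
                      rng: np.random.Generator) -> np.ndarray:
    """Apply each spec independently with its probability, in order."""
    img = np.asarray(image, dtype=np.float64)
    if np.isnan(img).any():
        raise ValueError("image contains NaN")
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    for spec in comp.specs:
        if spec.probability >= 1.0 or rng.random() < spec.probability:
            img = _APPLY[spec.kind](img, spec.amplitude, rng)
    return np.clip(img, 0.0, 1.0)


def make_view_pair(image: np.ndarray, comp_a: TransformComposition,
                   comp_b: TransformComposition, rng: np.random.Generator):
    """Two independently randomized views of one image (comp_a may equal comp_b)."""
    return apply_composition(image, comp_a, rng), apply_composition(image, comp_b, rng)


def sweep_compositions(base: TransformComposition, grid: SweepGrid) -> list[TransformComposition]:
    """One composition per grid value, varying only the targeted field."""
    if not 0 <= grid.spec_index < len(base.specs):
        raise ValueError("grid spec_index out of range")
    out = []
    for v in grid.values:
        spec = base.specs[grid.spec_index]
        new_spec = dataclasses.replace(spec, **{grid.parameter: v})
        specs = list(base.specs)
        specs[grid.spec_index] = new_spec
        tag = f"{v:g}" if np.isscalar(v) else "-".join(f"{x:g}" for x in v)
        out.append(TransformComposition(
            specs=specs,
            name=f"{base.name}__{spec.kind}.{grid.parameter}={tag}",
        ))
    return out


# ---------------------------------------------------------------------------
# named compositions used by the studies
# ---------------------------------------------------------------------------

def identity_composition() -> TransformComposition:
    return TransformComposition([TransformSpec("hflip", probability=0.0)], name="identity")


def glyph_set1() -> TransformComposition:
    """Glyph-identity-preserving set: padding, inversion, slight rotation, mild crop.

    These operations leave the stroke layout of a glyph legible in both views,
    so agreement training keeps glyph-class information.
    """
    return TransformComposition(
        [
            TransformSpec("pad", probability=0.7, amplitude=0.25),
            TransformSpec("invert", probability=0.5),
            TransformSpec("rotate", probability=0.8, amplitude=8.0),
            TransformSpec("random_crop_resize", probability=1.0, amplitude=(0.45, 1.0)),
        ],
        name="glyph_set1",
    )


def glyph_set2() -> TransformComposition:
    """Glyph-identity-destroying set: vertical flips, full rotation, crop, erasing.

    Full-circle rotation and flips scramble the orientation cues that define
    glyph classes while leaving stroke thickness (style) intact, so agreement
    training favors style information.
    """
    return TransformComposition(
        [
            TransformSpec("vflip", probability=0.5),
            TransformSpec("rotate", probability=1.0, amplitude=360.0),
            TransformSpec("random_crop_resize", probability=0.8, amplitude=(0.4, 0.8)),
            TransformSpec("erase", probability=0.5, amplitude=1.0),
        ],
        name="glyph_set2",
    )


def cell_crop_set() -> TransformComposition:
    """Microscopy set with aggressive random cropping (neighborhood-focused).

    Off-center crops frequently exclude the central cell, so invariance to them
    discards central-cell morphology in favor of field-level context.
    """
    return TransformComposition(
        [
            TransformSpec("color_jitter", probability=0.8, amplitude=0.15),
            TransformSpec("hflip", probability=0.5),
            TransformSpec("vflip", probability=0.5),
            TransformSpec("rotate", probability=0.5, amplitude=15.0),
            TransformSpec("affine", probability=0.5, amplitude=0.5),
            TransformSpec("random_crop_resize", probability=1.0, amplitude=(0.25, 0.35)),
        ],
        name="cell_crop_set",
    )


def cell_rotation_set() -> TransformComposition:
    """Microscopy set replacing random cropping with full-circle rotations.

    Shares chromatic perturbation, flips and mild affine warps with
    :func:`cell_crop_set`; the random crop is swapped for strong (360°)
    rotations, which preserve the centered cell's morphology and texture — the
    condition-relevant signal — while still varying the view.
    """
    return TransformComposition(
        [
            TransformSpec("color_jitter", probability=0.8, amplitude=0.15),
            TransformSpec("hflip", probability=0.5),
            TransformSpec("vflip", probability=0.5),
            TransformSpec("affine", probability=0.5, amplitude=0.5),
            TransformSpec("rotate", probability=1.0, amplitude=360.0),
        ],
        name="cell_rotation_set",
    )


def cell_center_set() -> TransformComposition:
    """Center-focused set: rotations, center cropping, chromatic jitter, flips.

    The centered half-size crop concentrates both views on the central cell,
    discarding neighbors entirely; paired with :func:`cell_crop_set` in the
    dual-composition objective it supplies the morphology-focused loss term.
    """
    return TransformComposition(
        [
            TransformSpec("rotate", probability=1.0, amplitude=360.0),
            TransformSpec("center_crop_fraction", probability=1.0, amplitude=0.5),
            TransformSpec("color_jitter", probability=0.8, amplitude=0.15),
            TransformSpec("hflip", probability=0.5),
            TransformSpec("vflip", probability=0.5),
        ],
        name="cell_center_set",
    )
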