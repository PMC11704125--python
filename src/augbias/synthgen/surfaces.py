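"""Planted accuracy-vs-parameter surfaces for testing the statistics layer.

Emulates the output of a parameter sweep — per-class linear-probe accuracy at
each of ``n_values`` transformation-parameter settings, repeated over
``n_seeds`` training seeds — without any training: each class follows a linear
trend (ascending, descending or flat) plus i.i.d. Gaussian accuracy noise per
seed, clipped to [0, 1]. The planted trend assignment is returned alongside so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..biasstats import AccuracySurface
from ..rng import child_rng

__all__ = ["SurfaceConfig", "gen_accuracy_surfaces"]

_TRENDS = ("ascending", "descending", "flat")


@dataclass
class SurfaceConfig:
    n_classes: int = 6
    n_values: int = 20
    n_seeds: int = 5
    trend_assignment: list[tuple[str, float]] | None = None  # (trend, |slope|) per class
    slope: float = 0.3        # default |slope| over the unit parameter range
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_values < 2:
            raise ValueError("n_values must be >= 2")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.trend_assignment is None:
            # balanced cycle ascending/descending/flat
            self.trend_assignment = [
                (_TRENDS[i % 3], self.slope) for i in range(self.n_classes)
            ]
        if len(self.trend_assignment) != self.n_classes:
            raise ValueError("trend_assignment length must equal n_classes")
        for trend, _ in self.trend_assignment:
            if trend not in _TRENDS:
                raise ValueError(f"unknown trend {trend!r}")


def gen_accuracy_surfaces(config: SurfaceConfig) -> tuple[AccuracySurface, list[str]]:
    """Surface plus the planted per-class trend labels (ground truth)."""
    rng = child_rng(config.seed, "surface")
    v = np.linspace(0.0, 1.0, config.n_values)
    acc = np.zeros((config.n_classes, config.n_values, config.n_seeds))
    truth = []
    for c, (trend, mag) in enumerate(config.trend_assignment):
        base = rng.uniform(0.35, 0.65)
        slope = {"ascending": mag, "descending": -mag, "flat": 0.0}[trend]
        mean_curve = base + slope * (v - 0.5)
        noise = rng.normal(0.0, config.noise_sd, (config.n_values, config.n_seeds))
        acc[c] = np.clip(mean_curve[:, None] + noise, 0.0, 1.0)
        truth.append(trend)
    surface = AccuracySurface(
        accuracies=acc,
        param_name="synthetic_parameter",
        param_values=v,
        class_names=[f"class_{c}" for c in range(config.n_classes)],
    )
    return surface, truth
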