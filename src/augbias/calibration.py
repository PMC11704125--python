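"""Monte-Carlo calibration of the bias-statistics layer on planted surfaces.

These experiments quantify, under the sweep-study noise model, how reliably
the statistics chain recovers planted structure:

* :func:`planted_bias_recovery` — sensitivity and false-flag rate of the
  opposite-behavior flagging rule, and accuracy of the slope-based behavior
  labels, on surfaces with known ascending/descending/flat classes;
* :func:`null_flagging_rates` — behavior-label type-I error and pair-level
  false-flag rate on pure-noise (flat) surfaces;
* :func:`association_calibration` — type-I error and power of the per-property
  ANOVA and the multivariate (Wilks) test across behavior groups.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .biasstats import (
    _wilks_manova,
    classify_all_behaviors,
    correlate_all_pairs,
    flag_opposite_pairs,
)
from .rng import child_rng, child_seed
from .synthgen import SurfaceConfig, gen_accuracy_surfaces

__all__ = ["planted_bias_recovery", "null_flagging_rates", "association_calibration"]


def _trend_cycle(n_classes: int) -> list[str]:
    return [("ascending", "descending", "flat")[i % 3] for i in range(n_classes)]


def planted_bias_recovery(n_replicates: int = 200, n_classes: int = 6,
                          n_values: int = 20, n_seeds: int = 5,
                          slope: float = 0.3, noise_sd: float = 0.02,
                          slope_alpha: float = 0.05, seed: int = 0) -> dict:
    """Recovery rates of the flagging rule and behavior labels.

    A pair is a true opposite pair iff one class ascends and the other
    descends. Returns sensitivity (flagged true pairs / true pairs),
    false_flag_rate (flagged non-opposite pairs / non-opposite pairs) and
    behavior_accuracy (correct ascending/descending/random labels).
    """
    truths = _trend_cycle(n_classes)
    true_pairs = {(a, b) for a, b in itertools.combinations(range(n_classes), 2)
                  if {truths[a], truths[b]} == {"ascending", "descending"}}
    n_pairs = n_classes * (n_classes - 1) // 2
    tp = fp = 0
    correct = total = 0
    label_of = {"ascending": "ascending", "descending": "descending", "flat": "random"}
    for r in range(n_replicates):
        cfg = SurfaceConfig(n_classes=n_classes, n_values=n_values, n_seeds=n_seeds,
                            slope=slope, noise_sd=noise_sd,
                            seed=child_seed(seed, "recovery", r))
        surface, planted = gen_accuracy_surfaces(cfg)
        flagged = {(a, b) for a, b, _ in
                   flag_opposite_pairs(correlate_all_pairs(surface))}
        tp += len(flagged & true_pairs)
        fp += len(flagged - true_pairs)
        for lab in classify_all_behaviors(surface, slope_alpha=slope_alpha):
            total += 1
            correct += lab.label == label_of[planted[lab.class_index]]
    n_true = len(true_pairs) * n_replicates
    n_false = (n_pairs - len(true_pairs)) * n_replicates
    return {
        "sensitivity": tp / n_true,
        "false_flag_rate": fp / n_false,
        "behavior_accuracy": correct / total,
        "n_replicates": n_replicates,
    }


def null_flagging_rates(n_replicates: int = 200, n_classes: int = 6,
                        n_values: int = 20, n_seeds: int = 5,
                        noise_sd: float = 0.02, slope_alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Type-I rates on all-flat (pure accuracy-noise) surfaces."""
    nonrandom = total = 0
    flagged_pairs = 0
    n_pairs = n_classes * (n_classes - 1) // 2
    for r in range(n_replicates):
        cfg = SurfaceConfig(
            n_classes=n_classes, n_values=n_values, n_seeds=n_seeds,
            trend_assignment=[("flat", 0.0)] * n_classes, noise_sd=noise_sd,
            seed=child_seed(seed, "null", r))
        surface, _ = gen_accuracy_surfaces(cfg)
        for lab in classify_all_behaviors(surface, slope_alpha=slope_alpha):
            total += 1
            nonrandom += lab.label != "random"
        flagged_pairs += len(flag_opposite_pairs(correlate_all_pairs(surface)))
    return {
        "behavior_type1": nonrandom / total,
        "pair_flag_rate": flagged_pairs / (n_pairs * n_replicates),
        "n_replicates": n_replicates,
    }


def association_calibration(n_replicates: int = 1000, classes_per_group: int = 10,
                            n_properties: int = 4, shift: float = 0.0,
                            alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rates of ANOVA (first property) and MANOVA between two
    behavior groups whose properties are i.i.d. standard normal, with an
    optional mean ``shift`` (in pooled-SD units) added to the first property
    of the second group."""
    rng = child_rng(seed, "association")
    anova_rej = manova_rej = 0
    for _ in range(n_replicates):
        g1 = rng.normal(size=(classes_per_group, n_properties))
        g2 = rng.normal(size=(classes_per_group, n_properties))
        g2[:, 0] += shift
        f, p = stats.f_oneway(g1[:, 0], g2[:, 0])
        anova_rej += p < alpha
        _, _, _, _, p_m = _wilks_manova([g1, g2])
        manova_rej += p_m < alpha
    return {
        "anova_rejection_rate": anova_rej / n_replicates,
        "manova_rejection_rate": manova_rej / n_replicates,
        "shift": shift,
        "n_replicates": n_replicates,
    }
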