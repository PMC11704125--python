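"""Bias-statistics layer: correlations, flagging rule, behaviors, properties, association."""

import itertools

import numpy as np
import pytest
from scipy import stats

from augbias.biasstats import (
    AccuracySurface,
    BiasReport,
    CorrelationRecord,
    bias_ratio,
    class_property_profile,
    classify_all_behaviors,
    classify_behavior,
    correlate_accuracy_pair,
    correlate_all_pairs,
    effective_rank,
    flag_opposite_pairs,
    intrinsic_dimension_twonn,
    make_bias_report,
    property_behavior_association,
    shared_negative_overlap,
    superclass_profile,
)
from augbias.synthgen import SurfaceConfig, gen_accuracy_surfaces, gen_property_classes


def surface_from_curves(curves, n_seeds=1, superclass_map=None):
    curves = np.asarray(curves, dtype=float)
    acc = np.repeat(curves[:, :, None], n_seeds, axis=2)
    return AccuracySurface(acc, "param", np.linspace(0, 1, curves.shape[1]),
                           [f"class_{i}" for i in range(len(curves))],
                           superclass_map)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_identical_and_reversed_curves():
    up = np.linspace(0.2, 0.8, 10)
    surface = surface_from_curves([up, up, up[::-1]])
    rec = correlate_accuracy_pair(surface, 0, 1)
    assert rec.pearson == pytest.approx(1.0)
    assert rec.spearman == pytest.approx(1.0)
    assert rec.kendall == pytest.approx(1.0)
    rec = correlate_accuracy_pair(surface, 0, 2)
    assert rec.spearman == pytest.approx(-1.0)
    assert rec.kendall == pytest.approx(-1.0)


def test_correlations_match_definitional_formulas():
    """Pearson/Spearman/Kendall against direct implementations on random curves."""
    rng = np.random.default_rng(0)
    x, y = rng.random(20), rng.random(20)
    surface = surface_from_curves([x, y])
    rec = correlate_accuracy_pair(surface, 0, 1)

    xm, ym = x - x.mean(), y - y.mean()
    pearson = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
    assert rec.pearson == pytest.approx(pearson, abs=1e-10)

    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    rxm, rym = rx - rx.mean(), ry - ry.mean()
    spearman = (rxm @ rym) / np.sqrt((rxm @ rxm) * (rym @ rym))
    assert rec.spearman == pytest.approx(spearman, abs=1e-10)

    conc = disc = 0
    for i, j in itertools.combinations(range(20), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        conc += s > 0
        disc += s < 0
    kendall = (conc - disc) / (20 * 19 / 2)
    assert rec.kendall == pytest.approx(kendall, abs=1e-10)


def test_constant_curve_reported_missing_not_nan():
    surface = surface_from_curves([np.full(10, 0.5), np.linspace(0, 1, 10)])
    rec = correlate_accuracy_pair(surface, 0, 1)
    assert rec.pearson is None and rec.p_pearson is None
    assert rec.kendall is None and rec.spearman is None
    # a missing coefficient can never trigger a flag
    assert flag_opposite_pairs([rec]) == []


def test_requires_three_parameter_values():
    surface = surface_from_curves([[0.1, 0.2], [0.3, 0.4]])
    with pytest.raises(ValueError):
        correlate_accuracy_pair(surface, 0, 1)


# ---------------------------------------------------------------------------
# flagging rule: exhaustive truth table
# ---------------------------------------------------------------------------

def test_flagging_rule_truth_table():
    """Flag iff at least one coefficient < -0.3 with its own p < 0.05."""
    coeff_cells = [-0.9, -0.31, -0.3, -0.2, 0.0, 0.5]
    p_cells = [0.001, 0.049, 0.05, 0.2]
    for c_p, p_p in itertools.product(coeff_cells, p_cells):
        for c_k, p_k in itertools.product(coeff_cells[:3], p_cells[:2]):
            rec = CorrelationRecord(0, 1, c_p, c_k, 0.4, p_p, p_k, 0.9)
            expected = (c_p < -0.3 and p_p < 0.05) or (c_k < -0.3 and p_k < 0.05)
            flagged = flag_opposite_pairs([rec])
            assert bool(flagged) == expected, (c_p, p_p, c_k, p_k)
            if flagged:
                hits = flagged[0][2]
                assert ("pearson" in hits) == (c_p < -0.3 and p_p < 0.05)
                assert ("kendall" in hits) == (c_k < -0.3 and p_k < 0.05)


def test_flagging_examples_from_protocol():
    # strong negative pearson with small p -> flagged
    assert flag_opposite_pairs(
        [CorrelationRecord(0, 1, -0.5, 0.2, 0.3, 0.01, 0.5, 0.5)])
    # negative but above threshold -> not flagged even at tiny p
    assert not flag_opposite_pairs(
        [CorrelationRecord(0, 1, -0.2, 0.1, 0.2, 0.001, 0.9, 0.9)])
    # below threshold but not significant -> not flagged
    assert not flag_opposite_pairs(
        [CorrelationRecord(0, 1, 0.1, 0.0, -0.9, 0.9, 0.9, 0.20)])


def test_bias_ratio_accounting():
    assert bias_ratio([], 4) == 0.0
    assert bias_ratio([(0, 1, ["pearson"])], 4) == 0.5
    all_pairs = [(a, b, ["pearson"]) for a, b in itertools.combinations(range(4), 2)]
    assert bias_ratio(all_pairs, 4) == 1.0
    # monotone non-decreasing as pairs accumulate
    prev = 0.0
    for k in range(len(all_pairs)):
        cur = bias_ratio(all_pairs[: k + 1], 4)
        assert cur >= prev
        prev = cur
    with pytest.raises(ValueError):
        bias_ratio([], 1)


# ---------------------------------------------------------------------------
# behavior categorization
# ---------------------------------------------------------------------------

def test_behavior_labels_on_noise_free_trends():
    surface, _ = gen_accuracy_surfaces(SurfaceConfig(
        n_classes=3, n_values=10, n_seeds=1, noise_sd=0.0, seed=0,
        trend_assignment=[("ascending", 0.3), ("descending", 0.3), ("flat", 0.0)]))
    labels = [b.label for b in classify_all_behaviors(surface)]
    assert labels == ["ascending", "descending", "random"]
    flat = classify_behavior(surface, 2)
    assert flat.slope == pytest.approx(0.0)


def test_behavior_slope_matches_ols():
    rng = np.random.default_rng(1)
    curve = 0.5 + 0.2 * np.linspace(0, 1, 15) + rng.normal(0, 0.01, 15)
    surface = surface_from_curves([curve, curve])
    b = classify_behavior(surface, 0)
    res = stats.linregress(surface.param_values, curve)
    assert b.slope == pytest.approx(res.slope, abs=1e-12)
    assert b.slope_p == pytest.approx(res.pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# class-property metrics
# ---------------------------------------------------------------------------

def test_intrinsic_dimension_on_known_manifold():
    rng = np.random.default_rng(0)
    basis = np.linalg.qr(rng.normal(size=(10, 2)))[0]
    pts = rng.uniform(-1, 1, (1000, 2)) @ basis.T
    assert intrinsic_dimension_twonn(pts) == pytest.approx(2.0, abs=0.3)
    with pytest.raises(ValueError):
        intrinsic_dimension_twonn(pts[:2])


def test_effective_rank_approaches_dimension():
    rng = np.random.default_rng(1)
    assert effective_rank(rng.normal(size=(2000, 5))) == pytest.approx(5.0, abs=0.1)
    # rank-1 data
    u = rng.normal(size=(200, 1)) @ rng.normal(size=(1, 6))
    assert effective_rank(u) == pytest.approx(1.0, abs=1e-6)


def test_class_property_profile_fields():
    ds = gen_property_classes(3, 30, seed=0,
                              kinds=[("constant",), ("lowpass",), ("checkerboard",)])
    records = class_property_profile(ds)
    assert [r.class_index for r in records] == [0, 1, 2]
    const = records[0]
    assert const.texture == pytest.approx(0.0)
    assert const.fourier == pytest.approx(0.0)
    assert records[2].fourier > records[1].fourier
    for r in records:
        assert r.cov_spectrum >= 1.0


# ---------------------------------------------------------------------------
# association layer
# ---------------------------------------------------------------------------

def make_properties(values_by_class):
    from augbias.biasstats import ClassPropertyRecord

    return [ClassPropertyRecord(i, v[0], v[1], v[2], v[3])
            for i, v in enumerate(values_by_class)]


def make_behaviors(labels):
    from augbias.biasstats import BehaviorLabel

    return [BehaviorLabel(i, lab, 0.0, 0.5) for i, lab in enumerate(labels)]


def test_identical_property_gives_f_zero():
    props = make_properties([[1.0, 2.0, 0.5, 3.0]] * 8)
    behaviors = make_behaviors(["ascending"] * 4 + ["descending"] * 4)
    out = property_behavior_association(props, behaviors)
    for name in ("intrinsic_dim", "texture", "fourier", "cov_spectrum"):
        assert out["anova"][name]["F"] == 0.0
        assert out["anova"][name]["p"] == 1.0


def test_manova_matches_statsmodels_wilks():
    statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(12, 4))
    vals[6:, 0] += 1.5
    props = make_properties(vals.tolist())
    behaviors = make_behaviors(["ascending"] * 6 + ["descending"] * 6)
    out = property_behavior_association(props, behaviors)

    import pandas as pd

    frame = pd.DataFrame(vals, columns=list("abcd"))
    frame["g"] = ["x"] * 6 + ["y"] * 6
    mv = statsmodels.MANOVA.from_formula("a + b + c + d ~ g", data=frame)
    table = mv.mv_test().results["g"]["stat"]
    assert out["manova"]["wilks_lambda"] == pytest.approx(
        table.loc["Wilks' lambda", "Value"], abs=1e-8)
    assert out["manova"]["p"] == pytest.approx(
        table.loc["Wilks' lambda", "Pr > F"], abs=1e-8)


def test_association_errors():
    props = make_properties(np.random.default_rng(0).normal(size=(4, 4)).tolist())
    with pytest.raises(ValueError):
        property_behavior_association(props, make_behaviors(["ascending"] * 4))
    with pytest.raises(ValueError):
        property_behavior_association(
            props, make_behaviors(["ascending", "ascending", "ascending", "descending"]))


# ---------------------------------------------------------------------------
# superclass profiles & overlap
# ---------------------------------------------------------------------------

def test_superclass_profile_accounting():
    curves = [np.linspace(0.2, 0.8, 5), np.linspace(0.8, 0.2, 5),
              np.full(5, 0.5)]
    mapping = {"class_0": "up", "class_1": "down", "class_2": "up"}
    surface = surface_from_curves(curves, superclass_map=mapping)
    prof = superclass_profile(surface)
    up = prof[prof.superclass == "up"].sort_values("param_value")["mean_accuracy"].to_numpy()
    np.testing.assert_allclose(up, (curves[0] + curves[2]) / 2, atol=1e-12)
    down = prof[prof.superclass == "down"]["mean_accuracy"].to_numpy()
    np.testing.assert_allclose(down, curves[1], atol=1e-12)  # single member
    assert prof.attrs["argmax"]["down"] == pytest.approx(0.0)
    assert prof.attrs["argmax"]["up"] == pytest.approx(1.0)


def test_superclass_profiles_recover_opposite_trends():
    cfg = SurfaceConfig(n_classes=6, n_values=20, n_seeds=3, noise_sd=0.02, seed=5,
                        trend_assignment=[("ascending", 0.3)] * 3 + [("descending", 0.3)] * 3)
    surface, _ = gen_accuracy_surfaces(cfg)
    surface.superclass_map = {f"class_{i}": ("A" if i < 3 else "B") for i in range(6)}
    prof = superclass_profile(surface)
    slopes = {}
    for sc, grp in prof.groupby("superclass"):
        slopes[sc] = stats.linregress(grp.param_value, grp.mean_accuracy).slope
    assert slopes["A"] > 0 > slopes["B"]


def test_shared_negative_overlap_counts_and_jaccard():
    names = [f"class_{i}" for i in range(6)]
    r1 = BiasReport([(0, 1, ["pearson"]), (2, 3, ["kendall"])], 4 / 6,
                    {"method": "m1"}, names)
    r2 = BiasReport([(0, 1, ["spearman"])], 2 / 6, {"method": "m2"}, names)
    r3 = BiasReport([(4, 5, ["pearson"])], 2 / 6, {"method": "m3"}, names)
    table = shared_negative_overlap([r1, r2, r3])
    row12 = table[(table.method_a == "m1") & (table.method_b == "m2")].iloc[0]
    assert row12.overlap == 2 and row12.jaccard == pytest.approx(0.5)
    row13 = table[(table.method_a == "m1") & (table.method_b == "m3")].iloc[0]
    assert row13.overlap == 0 and row13.jaccard == 0.0
    identical = shared_negative_overlap([r1, r1]).iloc[0]
    assert identical.overlap == 4 and identical.jaccard == 1.0

    with pytest.raises(ValueError):
        shared_negative_overlap([r1, BiasReport([], 0.0, {}, names[:3])])


def test_random_overlap_matches_hypergeometric_expectation():
    """Random flagged sets of sizes m1, m2 out of n overlap ~ m1*m2/n on average."""
    rng = np.random.default_rng(0)
    n, m1, m2 = 20, 6, 8
    names = [f"class_{i}" for i in range(n)]
    overlaps = []
    for _ in range(1000):
        s1 = rng.choice(n, m1, replace=False)
        s2 = rng.choice(n, m2, replace=False)
        r1 = BiasReport([(int(a), int(a), ["pearson"]) for a in s1], 0, {"method": "a"}, names)
        r2 = BiasReport([(int(a), int(a), ["pearson"]) for a in s2], 0, {"method": "b"}, names)
        overlaps.append(shared_negative_overlap([r1, r2]).iloc[0].overlap)
    assert np.mean(overlaps) == pytest.approx(m1 * m2 / n, abs=0.15)


# ---------------------------------------------------------------------------
# report assembly + persistence
# ---------------------------------------------------------------------------

def test_bias_report_and_surface_round_trip(tmp_path):
    surface, _ = gen_accuracy_surfaces(SurfaceConfig(n_classes=4, n_values=12,
                                                     n_seeds=3, seed=2))
    report = make_bias_report(surface, context={"method": "simclr"})
    assert report.ratio == bias_ratio(report.flagged_pairs, 4)

    path = str(tmp_path / "surface.csv")
    surface.to_csv(path)
    back = AccuracySurface.from_csv(path)
    np.testing.assert_allclose(back.accuracies, surface.accuracies, atol=1e-12)
    report2 = make_bias_report(back, context={"method": "simclr"})
    assert report2.flagged_pairs == report.flagged_pairs
    assert report2.ratio == report.ratio
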