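"""Generator contracts: determinism, marginals, planted-structure recoverability."""

import numpy as np
import pytest
from scipy import stats

from augbias.biasstats import high_frequency_fraction, intrinsic_dimension_twonn, texture_contrast
from augbias.synthgen import (
    CellImageConfig,
    SurfaceConfig,
    gen_accuracy_surfaces,
    gen_cell_images,
    gen_glyph_images,
    gen_property_classes,
)


def central_moments(images: np.ndarray) -> np.ndarray:
    """Per-image (mass, eccentricity) of the central window — a morphology readout."""
    n, h = len(images), images.shape[1]
    lo, hi = h // 4, 3 * h // 4
    feats = np.zeros((n, 2))
    y, x = np.mgrid[lo:hi, lo:hi]
    for i, img in enumerate(images[..., 0]):
        c = img[lo:hi, lo:hi]
        m = c.sum()
        cy, cx = (c * y).sum() / m, (c * x).sum() / m
        myy = (c * (y - cy) ** 2).sum() / m
        mxx = (c * (x - cx) ** 2).sum() / m
        mxy = (c * (y - cy) * (x - cx)).sum() / m
        tr = myy + mxx
        disc = np.sqrt(max(tr * tr / 4 - (myy * mxx - mxy * mxy), 0.0))
        l1, l2 = tr / 2 + disc, tr / 2 - disc
        feats[i] = (m, np.sqrt(1 - max(l2, 1e-9) / max(l1, 1e-9)))
    return feats


class TestCellImages:
    def test_determinism_and_marginals(self):
        cfg = CellImageConfig(image_size=32, n_untreated=30, n_treated=40,
                              n_phenotypes=2, seed=5)
        a = gen_cell_images(cfg)
        b = gen_cell_images(cfg)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.aux_labels, b.aux_labels)
        assert (a.labels == 0).sum() == 30 and (a.labels == 1).sum() == 40
        assert a.images.min() >= 0 and a.images.max() <= 1
        # untreated have phenotype 0; treated phenotypes within 1..n (0 = lookalike)
        assert (a.aux_labels[a.labels == 0] == 0).all()
        assert a.aux_labels.max() <= 2

    def test_lookalike_fraction(self):
        cfg = CellImageConfig(image_size=32, n_untreated=0, n_treated=600,
                              resemble_fraction=0.25, seed=1)
        ds = gen_cell_images(cfg)
        frac = (ds.aux_labels == 0).mean()
        assert 0.18 < frac < 0.32  # binomial around 0.25

    def test_full_effect_is_linearly_separable(self):
        """Morphology features separate conditions at full effect, no lookalikes."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        ds = gen_cell_images(CellImageConfig(
            image_size=32, n_untreated=150, n_treated=150, effect_size=1.0,
            resemble_fraction=0.0, noise_sd=0.01, seed=3))
        feats = central_moments(ds.images)
        feats = (feats - feats.mean(0)) / feats.std(0)
        acc = cross_val_score(LogisticRegression(), feats, ds.labels, cv=5).mean()
        assert acc >= 0.95

    def test_zero_effect_gives_no_condition_signal(self):
        """effect_size=0: treated and untreated distributions coincide."""
        from augbias.evalrep import RepresentationSet, adjusted_mutual_information, cluster_kmeans

        ds = gen_cell_images(CellImageConfig(
            image_size=32, n_untreated=150, n_treated=150, effect_size=0.0, seed=4))
        feats = central_moments(ds.images)
        feats = (feats - feats.mean(0)) / feats.std(0)
        asg = cluster_kmeans(RepresentationSet(feats, ds.labels), 2, seed=0)
        assert abs(adjusted_mutual_information(asg, ds.labels)) < 0.05

    def test_validation(self):
        with pytest.raises(ValueError):
            CellImageConfig(n_phenotypes=0)
        with pytest.raises(ValueError):
            CellImageConfig(image_size=8)
        with pytest.raises(ValueError):
            CellImageConfig(effect_size=1.5)
        with pytest.raises(ValueError):
            CellImageConfig(resemble_fraction=-0.1)


class TestGlyphImages:
    def test_determinism_and_style_marginals(self):
        a = gen_glyph_images(20, 4, 3, seed=9)
        b = gen_glyph_images(20, 4, 3, seed=9)
        np.testing.assert_array_equal(a.images, b.images)
        assert np.bincount(a.labels).tolist() == [20] * 4
        assert set(a.aux_labels) <= {0, 1, 2}

    def test_single_style_level(self):
        ds = gen_glyph_images(10, 3, 1, seed=0)
        assert (ds.aux_labels == 0).all()

    def test_class_style_independence(self):
        """Chi-square test of independence between glyph class and style."""
        ds = gen_glyph_images(500, 10, 2, seed=2, image_size=20)
        table = np.zeros((10, 2))
        for c, s in zip(ds.labels, ds.aux_labels):
            table[c, s] += 1
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_empty_style_rejected(self):
        with pytest.raises(ValueError, match="empty image"):
            gen_glyph_images(5, 3, 2, seed=0, image_size=8)

    def test_bar_templates_have_orientation_classes(self):
        ds = gen_glyph_images(5, 6, 2, seed=0, template_set="bars")
        assert len(np.unique(ds.labels)) == 6
        with pytest.raises(ValueError):
            gen_glyph_images(5, 3, 2, seed=0, template_set="squiggles")


class TestAccuracySurfaces:
    def test_noise_free_trends_are_exact(self):
        cfg = SurfaceConfig(n_classes=3, n_values=10, n_seeds=2, noise_sd=0.0,
                            trend_assignment=[("ascending", 0.3), ("descending", 0.3),
                                              ("flat", 0.0)], seed=0)
        surface, truth = gen_accuracy_surfaces(cfg)
        curves = surface.seed_mean()
        r = stats.pearsonr(curves[0], curves[1]).statistic
        assert r == pytest.approx(-1.0)  # exact anti-monotone pair
        assert np.ptp(curves[2]) == pytest.approx(0.0)  # flat class: zero slope
        assert truth == ["ascending", "descending", "flat"]

    def test_clipping_and_validation(self):
        cfg = SurfaceConfig(n_classes=2, n_values=5, n_seeds=3, noise_sd=0.5, seed=1)
        surface, _ = gen_accuracy_surfaces(cfg)
        assert surface.accuracies.min() >= 0 and surface.accuracies.max() <= 1
        with pytest.raises(ValueError):
            SurfaceConfig(n_values=1)
        with pytest.raises(ValueError):
            SurfaceConfig(n_seeds=0)
        with pytest.raises(ValueError):
            SurfaceConfig(n_classes=2, trend_assignment=[("sideways", 0.1)] * 2)


class TestPropertyClasses:
    def test_constant_class_has_zero_texture_and_spectrum(self):
        ds = gen_property_classes(2, 10, seed=0, kinds=[("constant",), ("lowpass",)])
        const = ds.images[ds.labels == 0]
        assert texture_contrast(const) == pytest.approx(0.0)
        assert high_frequency_fraction(const) == pytest.approx(0.0)

    def test_checkerboard_has_more_high_frequency_than_lowpass(self):
        ds = gen_property_classes(2, 20, seed=0,
                                  kinds=[("lowpass",), ("checkerboard",)])
        hf_low = high_frequency_fraction(ds.images[ds.labels == 0])
        hf_check = high_frequency_fraction(ds.images[ds.labels == 1])
        assert hf_check > hf_low

    def test_latent_dimension_ordering(self):
        """TwoNN estimates order d=2 below d=8 in most replicates."""
        wins = 0
        for rep in range(10):
            ds = gen_property_classes(2, 400, seed=rep, image_size=16,
                                      kinds=[("latent", 2), ("latent", 8)])
            id2 = intrinsic_dimension_twonn(ds.images[ds.labels == 0].reshape(400, -1))
            id8 = intrinsic_dimension_twonn(ds.images[ds.labels == 1].reshape(400, -1))
            wins += id2 < id8
        assert wins >= 9

    def test_determinism(self):
        a = gen_property_classes(3, 5, seed=7)
        b = gen_property_classes(3, 5, seed=7)
        np.testing.assert_array_equal(a.images, b.images)
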