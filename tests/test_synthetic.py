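"""Tests of the synthetic panel generator: exact class counts, seeded
determinism, closed-form dose-response expectations, spectra geometry and
the analytic ground truth of rendered seed scans."""

import math

import numpy as np
import pandas as pd
import pytest

from dormscreen.classifier import Category
from dormscreen.germination import TreatmentSpec
from dormscreen.morphometrics import SeedShape
from dormscreen.synthetic import (
    NIR_WAVELENGTHS,
    PanelConfig,
    VarietyTruth,
    generate_panel,
    generate_spectra,
    germination_probability,
    largest_remainder_counts,
    render_seed_image,
    simulate_germination,
    simulate_panel_assays,
)


def _make_truth(**overrides) -> VarietyTruth:
    base = dict(
        variety_id="T-1", index=0, true_class=Category.WD,
        true_mechanism="none", g0=0.5, aba_ic50=1e6, hill=1.0, ga_boost=0.0,
        ar_release=0.0, scar_release=0.0, thickness=0.05, area=2.0,
        perimeter=6.0, major_axis=1.8, minor_axis=1.5, eccentricity=0.4,
        solidity=0.98, protein=15.0, moisture=8.0, coat_color="beige",
    )
    base.update(overrides)
    return VarietyTruth(**base)


class TestPanelComposition:
    def test_default_panel_reproduces_reference_counts(self, default_panel):
        _, traits = default_panel
        counts = traits["true_class"].value_counts().to_dict()
        assert counts == {"ND": 141, "WD": 27, "MD": 9, "SD": 12}

    def test_degenerate_proportions_give_single_class(self):
        cfg = PanelConfig(
            n_varieties=4,
            class_proportions={"ND": 1.0, "WD": 0.0, "MD": 0.0, "SD": 0.0},
        )
        truths, traits = generate_panel(cfg)
        assert len(truths) == 4
        assert set(traits["true_class"]) == {"ND"}

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PanelConfig(class_proportions={"ND": 0.5, "WD": 0.3, "MD": 0.1,
                                           "SD": 0.2})

    @pytest.mark.parametrize(
        "n,props",
        [
            (189, {"ND": 141 / 189, "WD": 27 / 189, "MD": 9 / 189, "SD": 12 / 189}),
            (10, {"ND": 0.55, "WD": 0.25, "MD": 0.12, "SD": 0.08}),
            (7, {"ND": 0.5, "WD": 0.5, "MD": 0.0, "SD": 0.0}),
        ],
    )
    def test_largest_remainder_sums_exactly(self, n, props):
        counts = largest_remainder_counts(n, props)
        assert sum(counts.values()) == n
        for k, c in counts.items():
            assert abs(c - props[k] * n) < 1

    def test_seeded_determinism(self):
        cfg = PanelConfig(n_varieties=25, rng_seed=7)
        truths_a, traits_a = generate_panel(cfg)
        truths_b, traits_b = generate_panel(cfg)
        pd.testing.assert_frame_equal(traits_a, traits_b)
        germ_a = simulate_panel_assays(truths_a, cfg)
        germ_b = simulate_panel_assays(truths_b, cfg)
        pd.testing.assert_frame_equal(germ_a, germ_b)

    def test_extending_panel_preserves_early_varieties(self):
        """Per-variety substreams: a larger panel keeps earlier draws."""
        small = generate_panel(PanelConfig(
            n_varieties=10, rng_seed=3,
            class_proportions={"ND": 1.0, "WD": 0, "MD": 0, "SD": 0}))[1]
        large = generate_panel(PanelConfig(
            n_varieties=20, rng_seed=3,
            class_proportions={"ND": 1.0, "WD": 0, "MD": 0, "SD": 0}))[1]
        pd.testing.assert_frame_equal(small, large.iloc[:10])


class TestTruthInvariants:
    def test_class_expectations_bound_in_assay(self, default_panel):
        truths, _ = default_panel
        in_assay = [TreatmentSpec.parse(c)
                    for c in ("NT", "ABA0.1", "ABA1", "ABA10", "GA10")]
        for truth in truths:
            probs = [germination_probability(truth, t) for t in in_assay]
            if truth.true_class == Category.SD:
                assert max(probs) < 0.25
            elif truth.true_class == Category.ND:
                assert min(probs) > 0.75

    def test_sd_traits_shifted_against_nd(self, default_panel):
        _, traits = default_panel
        sd = traits[traits["true_class"] == "SD"]
        nd = traits[traits["true_class"] == "ND"]
        assert sd["thickness"].mean() > nd["thickness"].mean()
        # SD eccentricities span a narrower, lower range by construction.
        assert sd["eccentricity"].max() < nd["eccentricity"].max()
        assert (sd["eccentricity"].max() - sd["eccentricity"].min()) < (
            nd["eccentricity"].max() - nd["eccentricity"].min())

    def test_seedcoat_dormancy_released_by_scarification_not_ar(self):
        truth = _make_truth(true_class=Category.SD, true_mechanism="seedcoat",
                            g0=0.05, aba_ic50=1.0, ga_boost=0.05,
                            ar_release=0.03, scar_release=0.9)
        p_scr = germination_probability(truth, TreatmentSpec.parse("AR1-SCR"))
        p_ar_nt = germination_probability(truth, TreatmentSpec.parse("AR1-NT"))
        assert p_scr >= 0.5
        assert p_ar_nt < 0.25


class TestGerminationSimulation:
    def test_binomial_monte_carlo_mean(self):
        truth = _make_truth(g0=0.5)
        cfg = PanelConfig(n_varieties=1, rng_seed=11,
                          class_proportions={"ND": 0, "WD": 1.0, "MD": 0, "SD": 0})
        assays = simulate_germination(
            truth, [TreatmentSpec.parse("NT")], cfg, n_replicates=10_000)
        fracs = assays[0].fractions()
        se = math.sqrt(0.5 * 0.5 / 10) / math.sqrt(10_000)
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_counts_within_bounds_and_reproducible(self):
        truth = _make_truth(g0=0.9)
        cfg = PanelConfig(n_varieties=1, rng_seed=5,
                          class_proportions={"ND": 0, "WD": 1.0, "MD": 0, "SD": 0})
        arms = [TreatmentSpec.parse(c) for c in ("NT", "ABA10", "GA10")]
        a = simulate_germination(truth, arms, cfg)
        b = simulate_germination(truth, arms, cfg)
        for x, y in zip(a, b):
            assert x.replicates == y.replicates
            assert all(0 <= g <= s for s, g in x.replicates)

    def test_unknown_treatment_code_rejected(self):
        truth = _make_truth()
        cfg = PanelConfig(n_varieties=1,
                          class_proportions={"ND": 0, "WD": 1.0, "MD": 0, "SD": 0})
        with pytest.raises(ValueError, match="unknown treatment"):
            simulate_germination(truth, ["FROST"], cfg)

    def test_panel_assay_table_layout(self, panel_assays):
        assert set(panel_assays.columns) == {
            "variety_id", "round", "treatment", "bio_rep", "tech_rep",
            "sown", "germinated"}
        initial = panel_assays[panel_assays["round"] == "initial"]
        # every variety has the four-arm dose-response round, 3 replicates
        per_var = initial.groupby("variety_id")["treatment"].nunique()
        assert (per_var == 4).all()
        assert (initial.groupby(["variety_id", "treatment"]).size() == 3).all()


class TestSpectra:
    def test_wavelength_grid_has_141_points(self):
        assert NIR_WAVELENGTHS.shape == (141,)
        assert NIR_WAVELENGTHS[0] == 950 and NIR_WAVELENGTHS[-1] == 1650
        exp, cal, _ = generate_spectra(5, 8, seed=1)
        assert exp.shape == (5, 141) and cal.shape == (8, 141)

    def test_zero_outlier_fraction_means_no_outliers(self):
        _, _, idx = generate_spectra(100, 50, outlier_fraction=0.0, seed=1)
        assert idx.size == 0

    def test_outliers_recorded_and_injected(self):
        exp, _, idx = generate_spectra(200, 50, outlier_fraction=0.1, seed=2)
        assert idx.size == 20
        inlier_sd = exp.drop(exp.index[idx]).to_numpy().std()
        outlier_sd = exp.iloc[idx].to_numpy().std()
        assert outlier_sd > inlier_sd

    def test_rank_zero_unit_noise_has_identity_covariance(self):
        exp, _, _ = generate_spectra(10_000, 2, rank=0, noise_sd=1.0, seed=3)
        cov = np.cov(exp.to_numpy(), rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(np.diag(cov) - 1).max() < 0.08
        assert np.abs(off).max() < 0.08

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_spectra(-1, 10)


class TestRenderer:
    def test_disjoint_ellipse_count_and_truth(self):
        rng = np.random.default_rng(0)
        params = [((100 + 150 * (i // 4), 100 + 150 * (i % 4)),
                   (45, 30), rng.uniform(0, math.pi)) for i in range(12)]
        image, truth = render_seed_image(params, (640, 640))
        assert len(truth) == 12
        assert image.shape == (640, 640, 3)
        assert all(isinstance(t, SeedShape) for t in truth)

    def test_circle_truth_eccentricity_zero(self):
        _, truth = render_seed_image([((100, 100), (40, 40), 0.0)], (256, 256))
        assert truth[0].eccentricity == 0.0
        assert truth[0].area == pytest.approx(math.pi * 40 * 40 * (25.4 / 1200) ** 2)

    def test_two_to_one_ellipse_truth(self):
        _, truth = render_seed_image([((150, 150), (80, 40), 0.3)], (512, 512))
        assert truth[0].eccentricity == pytest.approx(math.sqrt(3) / 2, abs=1e-12)
        assert truth[0].solidity == 1.0

    def test_out_of_canvas_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_seed_image([((10, 10), (40, 20), 0.0)], (256, 256))
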