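"""Initial rates, multi-start fitting, confidence intervals, design analysis."""

import numpy as np
import pandas as pd
import pytest

from titrkin import (
    DesignSpec,
    FitOptions,
    KineticParams,
    RateObservation,
    compare_designs,
    confidence_intervals,
    estimate_activity_scaling,
    extract_initial_rate,
    fit_ping_pong,
    generate_rate_table,
    reference_design,
    specific_rate,
)
from titrkin.estimation import frame_to_observations, observations_to_frame
from titrkin.synthetic import design_from_campaigns


def linear_series(slope, taus, S0=400.0, o2=1.3):
    return pd.DataFrame(
        {
            "clock_time_min": np.arange(len(taus), dtype=float),
            "flow_uL_min": 155.0 / np.asarray(taus),
            "residence_time_min": taus,
            "glucose_mM": S0 - slope * np.asarray(taus),
            "o2_mM": o2,
            "product_mM": slope * np.asarray(taus),
            "conversion": slope * np.asarray(taus) / S0,
        }
    )


class TestExtractInitialRate:
    def test_exactly_linear_series_returns_slope_over_enzyme(self):
        df = linear_series(0.56, [1.0, 2.0, 3.0, 4.0])
        obs = extract_initial_rate(df, enzyme_mg_mL=1.0, S0_mM=400.0)
        assert obs.rate == pytest.approx(0.56, rel=1e-12)
        obs2 = extract_initial_rate(df, enzyme_mg_mL=0.05, S0_mM=400.0)
        assert obs2.rate == pytest.approx(0.56 / 0.05, rel=1e-12)
        assert obs2.O == pytest.approx(1.3)

    def test_conversion_window_enforced(self):
        df = linear_series(30.0, [2.0, 3.0, 4.0, 5.0])  # conversions 0.15..0.375
        with pytest.raises(ValueError, match="initial-rate window"):
            extract_initial_rate(df, 1.0, 400.0, max_conversion=0.10)


class TestFitPingPong:
    def test_noiseless_recovery_to_one_permille(self, truth, combined_noiseless):
        fit = fit_ping_pong(combined_noiseless, FitOptions(seed=3))
        got = fit.params.as_array()
        want = truth.as_array()
        assert np.all(np.abs(got - want) / want < 1e-3)
        assert fit.converged and not fit.condition_flag

    def test_single_oxygen_level_flagged_unidentifiable(self, truth):
        """At one O level only apparent constants exist; K_MO is absorbed."""
        obs = [
            RateObservation(S=S, O=0.276, rate=float(specific_rate(S, 0.276, truth)))
            for S in np.geomspace(5, 800, 12)
        ]
        fit = fit_ping_pong(obs, FitOptions(seed=0))
        assert fit.condition_flag

    def test_duplicated_dataset_same_estimate_half_covariance(self, truth):
        atm, hp = reference_design(noise_cv=0.03, seed=5)
        obs = generate_rate_table(atm, truth) + generate_rate_table(hp, truth)
        f1 = fit_ping_pong(obs, FitOptions(seed=1))
        f2 = fit_ping_pong(obs + obs, FitOptions(seed=1))
        assert np.allclose(f2.params.as_array(), f1.params.as_array(), rtol=1e-6)
        ratio = np.diag(f2.covariance) / np.diag(f1.covariance)
        # halves up to the dof correction (n-3 vs 2n-3)
        assert np.allclose(ratio, 0.5, rtol=0.06)

    def test_profile_optimum_matches_grid_search_oracle(self, truth):
        """With K_MS held at its fitted value, a brute-force 200x200 log grid
        over (kcat, K_MO) must place the minimum within one cell of the fit."""
        atm, hp = reference_design(noise_cv=0.03, seed=21)
        obs = generate_rate_table(atm, truth) + generate_rate_table(hp, truth)
        fit = fit_ping_pong(obs, FitOptions(seed=2))
        S = np.array([o.S for o in obs])
        O = np.array([o.O for o in obs])
        y = np.array([o.rate for o in obs])
        # odd count: the fitted value is itself a grid point
        kcat_grid = np.geomspace(fit.params.kcat / 3, fit.params.kcat * 3, 201)
        kmo_grid = np.geomspace(fit.params.K_MO / 3, fit.params.K_MO * 3, 201)
        KC, KM = np.meshgrid(kcat_grid, kmo_grid, indexing="ij")
        den = S[None, None, :] * O[None, None, :] + KM[..., None] * S[None, None, :] + (
            fit.params.K_MS * O[None, None, :]
        )
        rss = np.sum((y - KC[..., None] * S * O / den) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        cell = kcat_grid[1] / kcat_grid[0]
        assert abs(np.log(kcat_grid[i] / fit.params.kcat)) <= np.log(cell)
        assert abs(np.log(kmo_grid[j] / fit.params.K_MO)) <= np.log(cell)

    def test_parameter_recovery_under_noise(self, truth):
        """Median relative error over 20 seeded 3 %-noise campaigns stays small."""
        errs = []
        for seed in range(20):
            atm, hp = reference_design(noise_cv=0.03, seed=300 + 2 * seed)
            obs = generate_rate_table(atm, truth) + generate_rate_table(hp, truth)
            fit = fit_ping_pong(obs, FitOptions(seed=seed))
            errs.append(np.abs(fit.params.as_array() - truth.as_array()) / truth.as_array())
        med = np.median(np.array(errs), axis=0)
        assert med[0] <= 0.05  # kcat
        assert med[1] <= 0.15  # K_MO
        assert med[2] <= 0.15  # K_MS

    def test_too_few_observations_rejected(self, truth):
        obs = [RateObservation(S=100, O=0.5, rate=5.0)] * 2
        with pytest.raises(ValueError):
            fit_ping_pong(obs)


class TestConfidenceIntervals:
    def test_noiseless_intervals_collapse(self, combined_noiseless):
        fit = fit_ping_pong(combined_noiseless, FitOptions(seed=3))
        for name, (lo, hi) in fit.ci95.items():
            assert hi - lo < 1e-6 * getattr(fit.params, name if name == "kcat" else name)

    def test_point_estimate_inside_interval(self, truth):
        atm, hp = reference_design(noise_cv=0.03, seed=9)
        obs = generate_rate_table(atm, truth) + generate_rate_table(hp, truth)
        fit = fit_ping_pong(obs, FitOptions(seed=0))
        theta = fit.params.as_array()
        for i, name in enumerate(("kcat", "K_MO", "K_MS")):
            lo, hi = fit.ci95[name]
            assert lo <= theta[i] <= hi

    def test_bootstrap_seeded_and_reproducible(self, truth):
        atm, hp = reference_design(noise_cv=0.03, seed=13)
        obs = generate_rate_table(atm, truth) + generate_rate_table(hp, truth)
        fit = fit_ping_pong(obs, FitOptions(seed=0))
        a = confidence_intervals(fit, obs, method="bootstrap", n_boot=60, seed=4).ci95
        fit2 = fit_ping_pong(obs, FitOptions(seed=0))
        b = confidence_intervals(fit2, obs, method="bootstrap", n_boot=60, seed=4).ci95
        assert a == b
        for name in a:
            lo, hi = a[name]
            assert lo < getattr(fit2.params, name) < hi


class TestActivityScaling:
    def test_identical_campaigns_ratio_one(self, combined_noiseless):
        res = estimate_activity_scaling(combined_noiseless, combined_noiseless)
        assert res["ratio"] == pytest.approx(1.0, rel=1e-6)

    def test_recovers_degradation_factor(self, truth, combined_noiseless):
        atm, hp = reference_design(noise_cv=0.0)
        from dataclasses import replace

        atm_b = replace(atm, degradation_factor=0.79, label="B")
        hp_b = replace(hp, degradation_factor=0.79, label="B")
        obs_b = generate_rate_table(atm_b, truth) + generate_rate_table(hp_b, truth)
        res = estimate_activity_scaling(combined_noiseless, obs_b)
        assert res["ratio"] == pytest.approx(0.79, rel=1e-6)
        assert res["K_MO"] == pytest.approx(truth.K_MO, rel=1e-4)
        assert res["K_MS"] == pytest.approx(truth.K_MS, rel=1e-4)

    def test_label_swap_inverts_ratio(self, truth, combined_noiseless):
        scaled = [
            RateObservation(o.S, o.O, o.rate * 0.79, campaign="B") for o in combined_noiseless
        ]
        fwd = estimate_activity_scaling(combined_noiseless, scaled)["ratio"]
        rev = estimate_activity_scaling(scaled, combined_noiseless)["ratio"]
        assert fwd * rev == pytest.approx(1.0, rel=1e-6)


class TestCompareDesigns:
    def test_doubling_replicates_shrinks_all_ses_by_sqrt2(self, truth):
        atm, hp = reference_design()
        d = design_from_campaigns([atm, hp])
        tab = compare_designs([d, d.scaled(2)], truth)
        ratio = tab.iloc[0] / tab.iloc[1]
        assert np.allclose(ratio, np.sqrt(2), rtol=1e-9)

    def test_oxygen_far_above_km_makes_kmo_unidentifiable(self, truth):
        pts = tuple((S, O) for S in (25, 100, 200, 400) for O in np.linspace(10.4, 20.0, 6))
        tab = compare_designs([DesignSpec(points=pts)], truth)
        assert tab["rel_se_K_MO"].iloc[0] > 1.0

    def test_singular_information_reported_as_infinite(self, truth):
        tab = compare_designs([DesignSpec(points=((100.0, 0.5),))], truth)
        assert np.isinf(tab.iloc[0]).all()

    def test_fisher_ses_match_monte_carlo_sds(self, truth):
        """Linearization sanity: predicted SEs within 30 % of Monte-Carlo SDs.

        The information matrix assumes the multiplicative noise model, so the
        Monte-Carlo fits use the matching relative weighting."""
        atm, hp = reference_design(noise_cv=0.03)
        d = design_from_campaigns([atm, hp])
        pred = compare_designs([d], truth).iloc[0].to_numpy()
        fits = []
        for seed in range(30):
            a, h = reference_design(noise_cv=0.03, seed=7000 + 2 * seed)
            obs = generate_rate_table(a, truth) + generate_rate_table(h, truth)
            fits.append(
                fit_ping_pong(obs, FitOptions(seed=seed, weighting="relative")).params.as_array()
            )
        mc = np.std(np.array(fits), axis=0, ddof=1) / truth.as_array()
        assert np.all(np.abs(pred - mc) / mc < 0.30)


def test_rate_table_round_trip(combined_noiseless):
    df = observations_to_frame(combined_noiseless)
    back = frame_to_observations(df)
    assert back == combined_noiseless
    with pytest.raises(ValueError, match="o2_mM"):
        frame_to_observations(df.drop(columns=["o2_mM"]))
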