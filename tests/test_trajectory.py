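"""Centile bands, posterior-predictive band probabilities, Bayes inversion
against prevalence, and Monte Carlo SE replication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuroblme.cohort import CohortDesign, TrueParameters, generate_cohort
from neuroblme.model import MCMCConfig, gibbs_sample
from neuroblme.trajectory import (
    AGE_GRID,
    DEFAULT_PREVALENCE,
    PrevalenceTable,
    VolumeBand,
    band_probability,
    diagnosis_posterior,
    fit_centile_bands,
    interpolate_prevalence,
    trajectory_with_mc_se,
)

from conftest import SMALL_DESIGN, make_draws


class TestPrevalence:
    def test_knot_ages_reproduced_exactly(self):
        p = interpolate_prevalence(DEFAULT_PREVALENCE, 65.0)
        np.testing.assert_allclose(p, [0.920, 0.055, 0.025])

    def test_midpoint_is_arithmetic_mean(self):
        p = interpolate_prevalence(DEFAULT_PREVALENCE, 62.5)
        expect = (np.array([0.950, 0.040, 0.010])
                  + np.array([0.920, 0.055, 0.025])) / 2
        np.testing.assert_allclose(p, expect / expect.sum())

    @settings(max_examples=60, deadline=None)
    @given(st.floats(min_value=60.0, max_value=85.0, allow_nan=False))
    def test_interpolation_normalised_everywhere(self, age):
        p = interpolate_prevalence(DEFAULT_PREVALENCE, age)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_out_of_range_rejected(self):
        for age in (59.0, 86.0):
            with pytest.raises(ValueError):
                interpolate_prevalence(DEFAULT_PREVALENCE, age)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PrevalenceTable(
                ages=np.array([60.0, 85.0]),
                p_hc=np.array([0.9, 0.8]),
                p_mci=np.array([0.2, 0.1]),
                p_ad=np.array([0.1, 0.1]),
            )


class TestDiagnosisPosterior:
    def test_hand_computed_bayes_example(self):
        post = diagnosis_posterior([0.2, 0.4, 0.6], [0.7, 0.2, 0.1])
        np.testing.assert_allclose(
            post, [0.5, 2.0 / 7.0, 3.0 / 14.0], atol=1e-12
        )

    def test_equal_likelihoods_return_prevalence(self):
        prior = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(
            diagnosis_posterior([0.4, 0.4, 0.4], prior), prior
        )

    def test_degenerate_prior_is_fixed_point(self):
        np.testing.assert_allclose(
            diagnosis_posterior([0.3, 0.9, 0.5], [1.0, 0.0, 0.0]),
            [1.0, 0.0, 0.0],
        )

    def test_all_zero_likelihood_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            diagnosis_posterior([0.0, 0.0, 0.0], [0.7, 0.2, 0.1])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_posterior_normalised(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.uniform(0.01, 1.0, 3)
        prior = rng.dirichlet(np.ones(3))
        post = diagnosis_posterior(L, prior)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)


def _flat_dataset(n=3000, seed=0, spread=0.01, centre=0.05):
    """Ages uniform on the grid, volumes i.i.d. around a flat mean."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(60, 85, n)
    vol = centre + spread * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "visit": 1,
            "age_years": age,
            "diagnosis": "HC",
            "ventricle_icv": vol,
            "hippocampus_icv_x100": centre * 10 + spread * rng.standard_normal(n),
        }
    )


class TestCentileBands:
    def test_flat_data_gives_horizontal_bands(self):
        """On data with a flat mean and constant spread the fitted centile
        curves match the direct empirical quantiles per age bin."""
        df = _flat_dataset()
        bands = fit_centile_bands(df, "ventricle")
        y = df["ventricle_icv"].to_numpy()
        for band, q in zip(bands[1:], (0.75, 0.50, 0.25)):
            upper_emp = np.quantile(y, q)
            # compare at interior grid ages (rearrangement pushes boundary
            # estimation spikes to the grid ends); tolerance ~4 pointwise
            # quantile-regression standard errors
            for age in (65.0, 72.0, 80.0):
                assert band.upper_at(age) == pytest.approx(
                    upper_emp, abs=0.0025
                )

    def test_bands_never_cross_and_are_ordered(self, default_cohort):
        for region in ("ventricle", "hippocampus"):
            bands = fit_centile_bands(default_cohort, region)
            assert [b.label for b in bands] == [
                "75-100th", "50-75th", "25-50th", "15-25th"
            ]
            for band in bands:
                assert np.all(band.lower <= band.upper + 1e-12)
            # adjacent bands share their boundary curve
            for upper_band, lower_band in zip(bands, bands[1:]):
                np.testing.assert_allclose(
                    upper_band.lower, lower_band.upper
                )
            # the 15th centile curve lies at or below the 25th everywhere
            assert np.all(bands[-1].lower <= bands[-1].upper + 1e-12)

    def test_age_monotone_in_trend_direction(self, default_cohort):
        vent = fit_centile_bands(default_cohort, "ventricle")
        assert all(np.all(np.diff(b.lower) >= -1e-12) for b in vent)
        hip = fit_centile_bands(default_cohort, "hippocampus")
        assert all(np.all(np.diff(b.lower) <= 1e-12) for b in hip)

    def test_top_band_capped_at_empirical_maximum(self, default_cohort):
        bands = fit_centile_bands(default_cohort, "ventricle")
        assert np.all(
            bands[0].upper == default_cohort["ventricle_icv"].max()
        )

    def test_insufficient_data_errors(self):
        df = _flat_dataset(n=120)
        df = df[df.age_years < 78]  # empty 80-85 window
        with pytest.raises(ValueError, match="window"):
            fit_centile_bands(df, "ventricle")
        with pytest.raises(ValueError, match="30 observations"):
            fit_centile_bands(_flat_dataset(n=20), "ventricle")


def _const_band(lo, hi, region="ventricle", label="test"):
    ages = AGE_GRID
    return VolumeBand(region, label, ages, np.full(len(ages), lo),
                      np.full(len(ages), hi))


class TestBandProbability:
    def test_unbounded_band_gives_one(self, ventricle_draws):
        band = _const_band(-1e6, 1e6)
        assert band_probability(ventricle_draws, "HC", 70.0, band) == 1.0

    def test_empty_band_gives_zero(self, ventricle_draws):
        band = _const_band(0.05, 0.05)
        assert band_probability(ventricle_draws, "AD", 70.0, band) \
            <= 1.0 / ventricle_draws.n_draws

    def test_degenerate_limit_is_mean_indicator(self):
        """With sigma2 = 0 and Sigma = 0 the predictive collapses onto the
        fixed-effects mean."""
        beta = np.tile([0.05, 0.01, 0, 0, 0, 0], (20, 1))
        draws = make_draws(beta, sigma2=0.0, Sigma=np.zeros((2, 2)))
        mean_at_78 = 0.05 + 0.01 * (78.0 - draws.age_mean) / draws.age_sd
        inside = _const_band(mean_at_78 - 1e-6, mean_at_78 + 1e-6)
        outside = _const_band(mean_at_78 + 1e-6, mean_at_78 + 1e-3)
        assert band_probability(draws, "HC", 78.0, inside, seed=1) == 1.0
        assert band_probability(draws, "HC", 78.0, outside, seed=1) == 0.0

    def test_band_nesting_monotone(self, ventricle_draws, default_cohort):
        """Enlarging a band can never decrease its predictive probability,
        for any diagnosis."""
        bands = fit_centile_bands(default_cohort, "ventricle")
        for i in range(len(bands) - 1):
            union = bands[i].union(bands[i + 1])
            for dx in ("HC", "MCI", "AD"):
                for age in (60.0, 70.0, 85.0):
                    p_u = band_probability(ventricle_draws, dx, age, union,
                                           seed=9)
                    for part in (bands[i], bands[i + 1]):
                        p = band_probability(ventricle_draws, dx, age, part,
                                             seed=9)
                        assert p_u >= p

    def test_out_of_range_age_rejected(self, ventricle_draws):
        band = _const_band(0.0, 1.0)
        with pytest.raises(ValueError, match="undefined"):
            band_probability(ventricle_draws, "HC", 59.0, band)

    def test_monte_carlo_error_scales_with_draw_count(self, ventricle_draws):
        """Halving the retained draws inflates the replicate spread of the
        band probability by about sqrt(2)."""
        import dataclasses

        full = ventricle_draws
        half = dataclasses.replace(
            full,
            beta=full.beta[::2], sigma2=full.sigma2[::2],
            Sigma=full.Sigma[::2], random_effects=full.random_effects[::2],
            chain=full.chain[::2],
        )
        band = _const_band(0.055, 0.065)
        p_full = [band_probability(full, "HC", 75.0, band, seed=s)
                  for s in range(60)]
        p_half = [band_probability(half, "HC", 75.0, band, seed=s + 500)
                  for s in range(60)]
        ratio = np.std(p_half, ddof=1) / np.std(p_full, ddof=1)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.25)


TRAJ_AGES = np.array([60.0, 72.0, 85.0])
TRAJ_CFG = MCMCConfig(n_chains=2, n_iterations=2500, n_burnin=800, thin=4,
                      seed=0)


@pytest.fixture(scope="module")
def traj(default_cohort):
    return trajectory_with_mc_se(
        default_cohort, "ventricle", n_replicates=3, seed=42,
        config=TRAJ_CFG, age_grid=TRAJ_AGES,
    )


class TestTrajectoryMCSE:
    CFG = TRAJ_CFG

    def test_posterior_normalised_on_full_grid(self, traj):
        sums = traj.groupby(["band", "age"])["p"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_interval_contains_point(self, traj):
        assert (traj["lo"] <= traj["p"] + 1e-12).all()
        assert (traj["p"] <= traj["hi"] + 1e-12).all()

    def test_identical_replicate_seeds_collapse_interval(self, default_cohort):
        out = trajectory_with_mc_se(
            default_cohort, "ventricle", n_replicates=2, config=self.CFG,
            age_grid=np.array([70.0]), replicate_seeds=[7, 7],
        )
        np.testing.assert_allclose(out["hi"] - out["lo"], 0.0, atol=1e-12)

    def test_replicate_count_validated(self, default_cohort):
        with pytest.raises(ValueError):
            trajectory_with_mc_se(default_cohort, "ventricle", n_replicates=1)

    def test_prevalence_recovery_when_model_carries_no_signal(self):
        """With all diagnosis effects zero in the generator, the fitted
        trajectories collapse to the interpolated prevalence at every age:
        the likelihood terms cancel in the Bayes inversion up to Monte
        Carlo and posterior-estimation error."""
        flat_v = TrueParameters(
            beta=(0.055, 0.005, 0.0, 0.0, 0.0, 0.0),
            sigma2=4e-6, Sigma=((2.5e-5, 2.5e-6), (2.5e-6, 6.25e-6)),
        )
        flat_h = TrueParameters(
            beta=(0.45, -0.01, 0.0, 0.0, 0.0, 0.0),
            sigma2=2.25e-4, Sigma=((1.6e-3, -9e-5), (-9e-5, 2.25e-4)),
        )
        design = CohortDesign(
            n_hc_stable=120, n_mci_stable=120, n_ad_stable=120,
            n_conv_hc_mci=0, n_conv_hc_ad=0, n_conv_hc_mci_ad=0,
            n_conv_mci_ad=0,
            retention_by_visit=(1.0, 1.0, 1.0, 1.0), n_single_visit=0,
        )
        df = generate_cohort(design, flat_v, flat_h, seed=5)
        draws = gibbs_sample(
            df, "ventricle",
            config=MCMCConfig(n_chains=2, n_iterations=6000, n_burnin=2000,
                              thin=4, seed=6),
        )
        bands = fit_centile_bands(df, "ventricle")
        rng = np.random.default_rng(7)
        for age in (62.0, 70.0, 78.0, 84.0):
            prior = interpolate_prevalence(DEFAULT_PREVALENCE, age)
            for band in bands:
                probs = [
                    band_probability(draws, dx, age, band, seed=rng)
                    for dx in ("HC", "MCI", "AD")
                ]
                post = diagnosis_posterior(probs, prior)
                np.testing.assert_allclose(post, prior, atol=0.08)
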