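import numpy as np
import pytest

import avitrend as av
from avitrend.hierarchical import inflate_missing_variance


class TestVarianceInflation:
    def test_one_year_gap_adds_c_squared(self):
        years = np.arange(1990, 2001)
        obs_var = np.full(11, 0.04)
        out = inflate_missing_variance(obs_var, 1991, years, c=1.0)
        assert out[0] == pytest.approx(0.04 + 1.0)
        np.testing.assert_allclose(out[1:], 0.04)

    def test_five_year_gap_adds_25(self):
        years = np.arange(1990, 2001)
        out = inflate_missing_variance(np.full(11, 0.04), 1995, years, c=1.0)
        assert out[0] == pytest.approx(0.04 + 25.0)
        assert out[4] == pytest.approx(0.04 + 1.0)

    def test_scale_parameter(self):
        years = np.arange(1990, 1995)
        out = inflate_missing_variance(np.full(5, 0.0), 1994, years, c=0.5)
        np.testing.assert_allclose(out, [0.25 * 16, 0.25 * 9, 0.25 * 4, 0.25, 0.0])

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError):
            inflate_missing_variance(np.ones(3), 1991, np.arange(1990, 1993), c=0.0)


class TestFitHierarchical:
    def test_single_species_near_zero_noise_collapses(self):
        """With tiny noise, the posterior total tracks point × exp(λ) tightly."""
        years = np.arange(2000, 2021)
        slope = 0.02
        idx = np.exp(slope * (years - 2020)) * 100
        s = av.IndexSeries("a", years, idx, 1e-4 * idx)
        sm = av.fit_gam(s)
        est = {"a": av.PopulationEstimate("a", 1000, 1000, 1000, 1e-3, 2020, 2020)}
        post = av.fit_hierarchical(
            [sm], est, mcmc=av.MCMCSettings(chains=2, warmup=200, draws=200, seed=0)
        )
        traj = av.total_trajectory(post)
        expected = 1000 * np.exp(slope * (years - 2020))
        np.testing.assert_allclose(traj.median, expected, rtol=0.01)
        width = (traj.ucl - traj.lcl) / traj.median
        assert np.all(width < 0.02)

    def test_additivity_over_partition(self, small_posterior):
        post, _ = small_posterior
        S = len(post.species_ids)
        w1 = {s: (1.0 if i < S // 2 else 0.0) for i, s in enumerate(post.species_ids)}
        w2 = {s: (0.0 if i < S // 2 else 1.0) for i, s in enumerate(post.species_ids)}
        t_all = av.total_trajectory(post)
        t1 = av.total_trajectory(post, w1)
        t2 = av.total_trajectory(post, w2)
        np.testing.assert_allclose(t1.draws + t2.draws, t_all.draws, rtol=1e-12)

    def test_positive_finite_totals(self, small_posterior):
        post, _ = small_posterior
        traj = av.total_trajectory(post)
        assert np.all(np.isfinite(traj.draws))
        assert np.all(traj.draws > 0)
        assert np.all(traj.lcl <= traj.median)
        assert np.all(traj.median <= traj.ucl)

    def test_truth_recovered_in_interval(self, small_posterior):
        post, truth = small_posterior
        cs = av.summarize_change(post)
        assert cs.pct_change.lcl <= truth.total_pct_change <= cs.pct_change.ucl

    def test_shrinkage_toward_group_mean(self):
        """A noisy outlier in a group of decliners is pulled toward the group."""
        rng = np.random.default_rng(4)
        years = np.arange(2000, 2021)
        smoothed, estimates, species = [], {}, []
        for i in range(12):
            sid = f"s{i}"
            noisy = i == 0
            slope = 0.03 if noisy else -0.02
            se_frac = 0.8 if noisy else 0.03
            idx = 100 * np.exp(slope * (years - 2020) + rng.normal(0, se_frac / 4, len(years)))
            s = av.IndexSeries(sid, years, idx, se_frac * idx)
            smoothed.append(av.fit_gam(s))
            estimates[sid] = av.PopulationEstimate(sid, 900, 1100, 1000, 30, 2020, 2020)
            species.append(
                av.SpeciesRecord(sid, 20.0, "grassland", "resident", "granivore")
            )
        post = av.fit_hierarchical(
            smoothed, estimates, species=species,
            mcmc=av.MCMCSettings(chains=2, warmup=300, draws=300, seed=1),
        )
        theta_post = post.theta.mean(axis=0)
        group_mean = post.group_mean.mean(axis=0)[0]
        mle = smoothed[0].growth_rate  # independent per-species estimate
        assert abs(theta_post[0] - group_mean) < abs(mle - group_mean)

    def test_flat_group_matches_independent_fits(self):
        """With one group and clean data, θ posteriors match per-species slopes."""
        rng = np.random.default_rng(9)
        years = np.arange(2000, 2026)
        slopes = rng.normal(0.0, 0.02, 6)
        smoothed, estimates = [], {}
        for i, b in enumerate(slopes):
            sid = f"s{i}"
            idx = 100 * np.exp(b * (years - 2025))
            s = av.IndexSeries(sid, years, idx, 0.02 * idx)
            smoothed.append(av.fit_gam(s))
            estimates[sid] = av.PopulationEstimate(sid, 1000, 1000, 1000, 50, 2025, 2025)
        post = av.fit_hierarchical(
            smoothed, estimates,
            mcmc=av.MCMCSettings(chains=2, warmup=400, draws=400, seed=2),
        )
        theta_hat = post.theta.mean(axis=0)
        theta_sd = post.theta.std(axis=0)
        for th, sd, b in zip(theta_hat, theta_sd, slopes):
            assert abs(th - b) < max(3.5 * sd, 2e-3)

    def test_species_without_estimate_dropped(self, small_bundle):
        bundle, _ = small_bundle
        smoothed = [av.fit_gam(s) for s in bundle.index_series.values()]
        partial = {k: v for k, v in list(bundle.estimates.items())[:-2]}
        post = av.fit_hierarchical(
            smoothed, partial,
            mcmc=av.MCMCSettings(chains=1, warmup=100, draws=100, seed=0),
        )
        assert len(post.species_ids) == len(partial)

    def test_missing_leading_years_widen_early_uncertainty(self):
        """A species first observed late has group-dominated early years."""
        years = np.arange(1990, 2021)
        smoothed, estimates = [], {}
        for i in range(6):
            sid = f"s{i}"
            first = 2008 if i == 0 else 1990
            yrs = years[years >= first]
            idx = 100 * np.exp(-0.02 * (yrs - 2020))
            s = av.IndexSeries(sid, yrs, idx, 0.05 * idx)
            smoothed.append(av.fit_gam(s))
            estimates[sid] = av.PopulationEstimate(sid, 900, 1100, 1000, 33, 2020, 2020)
        post = av.fit_hierarchical(
            smoothed, estimates, years=years,
            mcmc=av.MCMCSettings(chains=2, warmup=300, draws=300, seed=3),
        )
        i0 = post.species_ids.index("s0")
        lam_sd = post.lam[:, i0, :].std(axis=0)
        # uncertainty in 1990 (18 filled years) far exceeds 2010 (observed)
        assert lam_sd[post.years == 1990][0] > 2 * lam_sd[post.years == 2010][0]
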