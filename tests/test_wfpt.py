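"""First-passage density, choice probability, mean FPT, and the simulator."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import ineqddm as iq
from ineqddm import wfpt
from ineqddm.errors import SpecMismatchError


def _density(boundary, alpha, z, drift):
    return lambda t: np.exp(wfpt.wfpt_logdensity(t, boundary, alpha, z, 0.0, drift))


class TestDensity:
    def test_zero_drift_symmetry(self):
        """At drift 0 and z = 1/2 the two boundaries are exchangeable."""
        t = np.linspace(0.05, 8.0, 40)
        up = wfpt.wfpt_logdensity(t, "upper", 2.0, 0.5, 0.0, 0.0)
        lo = wfpt.wfpt_logdensity(t, "lower", 2.0, 0.5, 0.0, 0.0)
        np.testing.assert_allclose(up, lo, rtol=1e-10)

    def test_zero_density_at_and_before_tau(self):
        assert wfpt.wfpt_logdensity(0.5, "upper", 2.0, 0.5, 0.5, 1.0) == -np.inf
        assert wfpt.wfpt_logdensity(0.3, "upper", 2.0, 0.5, 0.5, 1.0) == -np.inf

    @pytest.mark.parametrize("alpha,z,drift", [(2.16, 0.543, 1.019), (0.5, 0.2, -3.0), (4.0, 0.8, 3.0)])
    def test_normalization_by_quadrature(self, alpha, z, drift):
        up = quad(_density("upper", alpha, z, drift), 0, 300, limit=300)[0]
        lo = quad(_density("lower", alpha, z, drift), 0, 300, limit=300)[0]
        assert abs(up + lo - 1.0) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wfpt.wfpt_logdensity(1.0, "upper", -1.0, 0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            wfpt.wfpt_logdensity(1.0, "upper", 1.0, 1.2, 0.0, 0.0)
        with pytest.raises(ValueError):
            wfpt.wfpt_logdensity(1.0, "upper", 1.0, 0.5, 0.0, np.inf)


class TestChoiceProbability:
    def test_zero_drift_equals_start_point(self):
        assert iq.choice_probability(2.0, 0.5, 0.0) == pytest.approx(0.5)
        assert iq.choice_probability(1.7, 0.31, 0.0) == pytest.approx(0.31)

    def test_limit_behaviour(self):
        assert iq.choice_probability(2.0, 0.5, 60.0) == pytest.approx(1.0)
        assert iq.choice_probability(2.0, 0.5, -60.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_increasing_in_drift(self):
        drifts = np.linspace(-3, 3, 31)
        p = iq.choice_probability(2.16, 0.543, drifts)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_matches_density_integral(self):
        for alpha, z, drift in [(2.16, 0.543, 1.019), (1.0, 0.35, -1.5)]:
            integral = quad(_density("upper", alpha, z, drift), 0, 300, limit=300)[0]
            assert abs(iq.choice_probability(alpha, z, drift) - integral) < 1e-5


class TestMeanDecisionTime:
    def test_zero_drift_closed_form(self):
        # E[T] = x0 (alpha - x0) for a driftless unit diffusion
        assert wfpt.mean_decision_time(2.0, 0.25, 0.0) == pytest.approx(0.5 * 1.5)

    def test_matches_quadrature(self):
        for alpha, z, drift in [(2.16, 0.543, 1.019), (1.5, 0.4, -0.8)]:
            q = quad(
                lambda t: t * (_density("upper", alpha, z, drift)(t) + _density("lower", alpha, z, drift)(t)),
                0, 300, limit=300,
            )[0]
            assert wfpt.mean_decision_time(alpha, z, drift) == pytest.approx(q, rel=1e-6)

    def test_decreases_with_drift_magnitude(self):
        ts = [wfpt.mean_decision_time(2.0, 0.5, v) for v in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(ts) < 0)


class TestSimulator:
    def test_dominant_drift(self):
        rng = np.random.default_rng(0)
        choice, _ = wfpt.simulate_paths(np.full(10_000, 2.0), 0.5, 0.3, 10.0, rng)
        assert (choice == 1).mean() >= 0.999

    def test_zero_drift_symmetry(self):
        rng = np.random.default_rng(1)
        n = 20_000
        choice, _ = wfpt.simulate_paths(np.full(n, 2.0), 0.5, 0.3, 0.0, rng)
        se = np.sqrt(0.25 / n)
        assert abs((choice == 1).mean() - 0.5) < 3 * se

    def test_deterministic_given_seed(self):
        c1, r1 = wfpt.simulate_paths(np.full(50, 2.0), 0.5, 0.3, 1.0, np.random.default_rng(9))
        c2, r2 = wfpt.simulate_paths(np.full(50, 2.0), 0.5, 0.3, 1.0, np.random.default_rng(9))
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_allclose(r1, r2)

    def test_deadline_censoring(self):
        rng = np.random.default_rng(2)
        # enormous boundary, tiny budget: everything must time out
        choice, rt = wfpt.simulate_paths(np.full(200, 50.0), 0.5, 9.9, 0.0, rng)
        assert np.all(choice == -1) and np.all(np.isnan(rt))

    def test_rt_distribution_matches_density(self, table2_params):
        """Kolmogorov distance between simulated decision times and the
        quadrature CDF of the summed first-passage densities."""
        a, z, tau, v = 2.16, 0.543, 0.591, 1.019
        rng = np.random.default_rng(3)
        choice, rt = wfpt.simulate_paths(np.full(50_000, a), z, tau, v, rng)
        dt = rt[choice >= 0] - tau
        grid = np.linspace(1e-4, 40, 8000)
        dens = np.exp(wfpt.wfpt_logdensity(grid, "upper", a, z, 0.0, v)) + np.exp(
            wfpt.wfpt_logdensity(grid, "lower", a, z, 0.0, v)
        )
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        ks = stats.ks_1samp(dt, lambda x: np.interp(x, grid, cdf)).statistic
        assert ks < 0.01


class TestDriftRate:
    def test_hand_arithmetic_at_population_means(self, table2_params):
        f = iq.compute_features((50, 450), scale_yen=100)
        delta = iq.drift_rate(iq.BEST_SPEC, table2_params, f)
        assert delta == pytest.approx(-0.930 * 0.5 + 0.371 * 4.0 + 0.254 * 0.0)

    def test_zero_and_linearity(self, table2_params):
        f = iq.compute_features((100, 400))
        zero = iq.DDMParams(alpha=2.0, z=0.5, tau=0.5, betas={"sr": 0.0, "di": 0.0, "ai": 0.0})
        assert iq.drift_rate(iq.BEST_SPEC, zero, f) == 0.0
        doubled = iq.DDMParams(
            alpha=2.16, z=0.543, tau=0.591,
            betas={k: 2 * v for k, v in table2_params.betas.items()},
        )
        assert iq.drift_rate(iq.BEST_SPEC, doubled, f) == pytest.approx(
            2 * iq.drift_rate(iq.BEST_SPEC, table2_params, f)
        )

    def test_missing_coefficient_raises(self):
        params = iq.DDMParams(alpha=2.0, z=0.5, tau=0.5, betas={"sr": -1.0})
        with pytest.raises(SpecMismatchError):
            iq.drift_rate(iq.BEST_SPEC, params, iq.compute_features((100, 400)))


class TestDatasetLoglik:
    def test_singleton_equals_pointwise_density(self, table2_params, sim_participant):
        one = iq.valid_trials(sim_participant).iloc[:1]
        total, per = iq.loglik_dataset(iq.BEST_SPEC, table2_params, one)
        f = iq.compute_features((int(one["sr_yen"].iloc[0]), int(one["or_yen"].iloc[0])))
        delta = iq.drift_rate(iq.BEST_SPEC, table2_params, f)
        boundary = "upper" if one["choice"].iloc[0] == "reject" else "lower"
        direct = wfpt.wfpt_logdensity(
            one["rt_s"].iloc[0], boundary, table2_params.alpha, table2_params.z,
            table2_params.tau, delta,
        )
        assert total == pytest.approx(float(direct))
        assert len(per) == 1

    def test_duplication_doubles_total(self, table2_params, sim_participant):
        import pandas as pd

        df = iq.valid_trials(sim_participant)
        total, _ = iq.loglik_dataset(iq.BEST_SPEC, table2_params, df)
        total2, _ = iq.loglik_dataset(
            iq.BEST_SPEC, table2_params, pd.concat([df, df], ignore_index=True)
        )
        assert total2 == pytest.approx(2 * total)

    def test_matches_independent_series_reimplementation(self, table2_params, sim_participant):
        """Second implementation oracle: direct large-time eigenfunction sum
        evaluated term by term in plain Python."""
        df = iq.valid_trials(sim_participant)
        df = df[df["rt_s"] > table2_params.tau + 0.3].iloc[:5]
        _, per = iq.loglik_dataset(iq.BEST_SPEC, table2_params, df)
        a, z, tau = table2_params.alpha, table2_params.z, table2_params.tau
        for ll, row in zip(per, df.itertuples(index=False)):
            f = iq.compute_features((row.sr_yen, row.or_yen))
            v = iq.drift_rate(iq.BEST_SPEC, table2_params, f)
            w = z if row.choice == "accept" else 1 - z
            vv = v if row.choice == "accept" else -v
            t = row.rt_s - tau
            s = sum(
                k * np.exp(-(k**2) * np.pi**2 * t / (2 * a**2)) * np.sin(k * np.pi * w)
                for k in range(1, 200)
            )
            oracle = np.log(np.pi / a**2 * s) - vv * a * w - vv**2 * t / 2
            assert ll == pytest.approx(oracle, rel=1e-6)

    def test_rt_below_tau_warns_and_is_minus_inf(self, sim_participant):
        slow = iq.DDMParams(alpha=2.0, z=0.5, tau=5.0, betas={"sr": 0.0, "di": 0.0, "ai": 0.0})
        df = iq.valid_trials(sim_participant)
        with pytest.warns(UserWarning, match="rt <= tau"):
            total, _ = iq.loglik_dataset(iq.BEST_SPEC, slow, df)
        assert total == -np.inf


class TestSimulateDataset:
    def test_cardinality_and_determinism(self, offers56, table2_params):
        a = iq.simulate_dataset(iq.BEST_SPEC, table2_params, offers56, seed=5)
        b = iq.simulate_dataset(iq.BEST_SPEC, table2_params, offers56, seed=5)
        assert len(a) == 56
        import pandas as pd

        pd.testing.assert_frame_equal(a, b)

    def test_inequity_avoider_rejects_more_when_disadvantaged(self, offers56):
        avoider = iq.inequity_avoider().params
        rates = {"1/9": [], "2/3": []}
        for rep in range(100):
            df = iq.simulate_dataset(iq.BEST_SPEC, avoider, offers56, seed=1000 + rep)
            dfv = iq.valid_trials(df)
            for cond in rates:
                sel = dfv[dfv["condition"] == cond]
                rates[cond].append((sel["choice"] == "reject").mean())
        assert np.mean(rates["1/9"]) > np.mean(rates["2/3"])
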