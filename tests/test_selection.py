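"""Drift-spec enumeration, WAIC selection, and the Firth logistic value model."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression

import ineqddm as iq
from ineqddm.errors import InsufficientDataError
from ineqddm.selection import firth_logistic, value_design

from conftest import FAST


class TestEnumeration:
    def test_exactly_nine_specs(self):
        specs = iq.enumerate_drift_specs()
        assert len(specs) == 9
        names = [s.name for s in specs]
        assert len(set(names)) == 9

    def test_contains_printed_specs(self):
        names = {s.name for s in iq.enumerate_drift_specs()}
        assert "sr+or" in names
        assert "constant" in names
        assert "sr+ai+di" in names

    def test_stable_order(self):
        assert [s.name for s in iq.enumerate_drift_specs()] == [
            "sr", "ai", "di", "sr+ai", "sr+di", "ai+di", "sr+or", "sr+ai+di", "constant",
        ]


class TestFirthLogistic:
    def test_finite_under_complete_separation(self):
        """Reject iff DI > 0 on 8 trials: plain ML diverges, Firth does not."""
        df = pd.DataFrame(
            {
                "participant_id": "p",
                "trial_index": range(8),
                "condition": ["1/9", "1/4", "3/7", "2/3", "1/1", "1/1", "3/2", "7/3"],
                "sr_yen": [50, 100, 150, 200, 250, 250, 300, 350],
                "or_yen": [450, 400, 350, 300, 250, 250, 200, 150],
                "choice": ["reject"] * 4 + ["accept"] * 4,
                "rt_s": [1.0] * 8,
            }
        )
        params = iq.fit_value_logistic(df)
        assert np.isfinite(params.vector()).all()
        assert params.gamma_di > 0

    def test_all_accept_participant_stays_finite(self):
        df = pd.DataFrame(
            {
                "participant_id": "p",
                "trial_index": range(7),
                "condition": list(iq.CONDITIONS),
                "sr_yen": [v[0] for v in iq.BASE_OFFERS.values()],
                "or_yen": [v[1] for v in iq.BASE_OFFERS.values()],
                "choice": ["accept"] * 7,
                "rt_s": [1.0] * 7,
            }
        )
        params = iq.fit_value_logistic(df)
        assert np.isfinite(params.vector()).all()
        assert np.abs(params.vector()).max() < 5.0

    def test_insufficient_data_rejected(self, tiny_trials):
        with pytest.raises(InsufficientDataError):
            iq.fit_value_logistic(tiny_trials.iloc[:2])

    def test_matches_independent_penalized_likelihood_optimizer(self, sim_participant):
        """Nelder-Mead on an independently coded Jeffreys-penalized
        log-likelihood must land on the same optimum."""
        X, y = value_design(sim_participant)
        beta, _, conv = firth_logistic(X, y)
        assert conv

        def neg_obj(b):
            eta = X @ b
            ll = y @ eta - np.logaddexp(0, eta).sum()
            p = 1 / (1 + np.exp(-eta))
            sign, logdet = np.linalg.slogdet((X * (p * (1 - p))[:, None]).T @ X)
            return -(ll + 0.5 * logdet)

        res = minimize(neg_obj, beta + 0.3, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
        np.testing.assert_allclose(beta, res.x, atol=1e-3)

    def test_bias_reduction_beats_maximum_likelihood(self):
        """Mean |bias| of Firth estimates below plain ML at n = 20."""
        rng = np.random.default_rng(6)
        truth = np.array([1.0, -0.5, 1.5])
        firth_err, ml_err = [], []
        for _ in range(200):
            X = rng.normal(size=(20, 3))
            p = 1 / (1 + np.exp(-(X @ truth)))
            y = (rng.random(20) < p).astype(float)
            if y.min() == y.max():
                continue
            bf, _, _ = firth_logistic(X, y)
            ml = LogisticRegression(C=np.inf, max_iter=2000, fit_intercept=False)
            ml.fit(X, y)
            firth_err.append(bf - truth)
            ml_err.append(ml.coef_[0] - truth)
        firth_bias = np.abs(np.mean(firth_err, axis=0)).mean()
        ml_bias = np.abs(np.mean(ml_err, axis=0)).mean()
        assert firth_bias < ml_bias


class TestSelection:
    def test_single_participant_single_spec(self, sim_participant):
        table = iq.run_selection(
            sim_participant, specs=[iq.BEST_SPEC], seed=1, **FAST
        )
        assert len(table.table) == 1
        assert table.best_spec == iq.BEST_SPEC
        assert table.per_participant.shape == (1, 1)

    def test_generating_spec_beats_nested_and_constant(self):
        """A small cohort simulated from the sr+ai+di drift prefers it over
        the constant-only and single-regressor alternatives."""
        trials, _ = iq.make_cohort(iq.CohortConfig(n_participants=8, seed=21))
        specs = [iq.BEST_SPEC, iq.DriftSpec(("sr",)), iq.DriftSpec(constant_only=True)]
        table = iq.run_selection(trials, specs=specs, chains=2, burn_in=500, draws=500, seed=2)
        assert table.best_spec == iq.BEST_SPEC

    def test_constant_drift_data_shows_parsimony(self):
        """Data from a constant-only drift: the 6-parameter model cannot beat
        the constant model by more than its extra effective parameters."""
        params = iq.DDMParams(alpha=2.0, z=0.5, tau=0.4, beta0=0.3)
        const = iq.DriftSpec(constant_only=True)
        frames = []
        for i in range(5):
            offers = iq.task.offers_to_frame(iq.generate_offer_set(600 + i))
            frames.append(
                iq.simulate_dataset(const, params, offers, seed=700 + i, participant_id=f"c{i}")
            )
        trials = pd.concat(frames, ignore_index=True)
        table = iq.run_selection(
            trials, specs=[const, iq.BEST_SPEC], chains=2, burn_in=500, draws=500, seed=3
        )
        waics = table.table.set_index("spec")["total_waic"]
        assert waics["constant"] <= waics["sr+ai+di"] + 2 * 6 * 5  # 2*p_waic headroom


@pytest.fixture(scope="module")
def noise_rt_cohort():
    """Choices from a logistic value model; RTs carry no signal."""
    rng = np.random.default_rng(11)
    frames = {}
    gamma = np.array([1.2, 0.5, 0.8])  # gamma0, gamma_ai, gamma_di
    for i in range(3):
        offers = iq.task.offers_to_frame(iq.generate_offer_set(800 + i))
        feats = iq.task.features_frame(offers)
        X = np.column_stack([-feats["sr"], feats["ai"], feats["di"]])
        p = 1 / (1 + np.exp(-(X @ gamma)))
        y = rng.random(len(p)) < p
        df = pd.DataFrame(
            {
                "participant_id": f"n{i}",
                "trial_index": range(len(p)),
                "condition": feats["condition"],
                "sr_yen": feats["sr_yen"],
                "or_yen": feats["or_yen"],
                "choice": np.where(y, "reject", "accept"),
                "rt_s": rng.uniform(0.4, 3.0, len(p)),
            }
        )
        frames[f"n{i}"] = df
    return pd.concat(frames.values(), ignore_index=True)


class TestChoiceOnlyComparison:
    def test_logistic_not_worse_on_choice_only_data(self, noise_rt_cohort):
        groups = {pid: df for pid, df in noise_rt_cohort.groupby("participant_id")}
        fits = {
            pid: iq.sample_posterior(df, iq.BEST_SPEC, seed=4, **FAST)
            for pid, df in groups.items()
        }
        comp = iq.compare_choice_only(noise_rt_cohort, fits, seed=5)
        assert comp.waic_logistic <= comp.waic_ddm + 2.0
        assert len(comp.coefficients) == 3
        assert {"beta_di", "gamma_di"} <= set(comp.coefficients.columns)

    def test_deterministic(self, noise_rt_cohort):
        groups = {pid: df for pid, df in noise_rt_cohort.groupby("participant_id")}
        fits = {
            pid: iq.sample_posterior(df, iq.BEST_SPEC, seed=4, **FAST)
            for pid, df in groups.items()
        }
        a = iq.compare_choice_only(noise_rt_cohort, fits, seed=5)
        b = iq.compare_choice_only(noise_rt_cohort, fits, seed=5)
        assert a.waic_ddm == b.waic_ddm and a.waic_logistic == b.waic_logistic
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)
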