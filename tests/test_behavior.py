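"""Filtering, classical tests, hierarchical logistic inference and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elab import behavior
from elab.behavior import (
    MCMCConfig,
    ModelSpec,
    PosteriorFit,
    PriorSpec,
    avoidance_summary,
    compare_waic,
    filter_anticipations,
    fit_hierarchical_logistic,
    fit_value_integration_model,
    paired_ttest,
    power_simulation,
    summarize_effect,
    wilcoxon_vs_chance,
)

from conftest import make_logistic_trials


def _threat_table(n_participants, n_trials=64, anticipations=0, missing=0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    planted = set(rng.choice(n_participants * n_trials, anticipations + missing, replace=False))
    planted_anticip = set(list(planted)[:anticipations])
    k = 0
    for i in range(n_participants):
        for t in range(n_trials):
            if k in planted_anticip:
                rt = 0.05
            elif k in planted:
                rt = np.nan
            else:
                rt = float(rng.uniform(0.3, 1.2))
            rows.append(
                {
                    "participant_id": f"p{i}",
                    "trial_type": "threat",
                    "condition": "predictable" if t % 2 else "unpredictable",
                    "rt_s": rt,
                    "response": "none" if np.isnan(rt) else ("avoid" if t % 3 else "approach"),
                }
            )
            k += 1
    return pd.DataFrame(rows)


class TestFilterAnticipations:
    @pytest.mark.parametrize(
        "n_part,planted,expected_pct",
        [(60, 7, 0.18), (30, 1, 0.05), (60, 4, 0.1)],
    )
    def test_printed_percentages(self, n_part, planted, expected_pct):
        trials = _threat_table(n_part, anticipations=planted)
        kept, n_removed, pct, n_missing = filter_anticipations(trials)
        assert n_removed == planted
        assert pct == pytest.approx(expected_pct, abs=0.005)
        assert len(kept) == n_part * 64 - planted
        assert n_missing == 0

    def test_no_anticipations(self):
        trials = _threat_table(5)
        kept, n_removed, pct, _ = filter_anticipations(trials)
        assert (n_removed, pct) == (0, 0.0)
        assert len(kept) == len(trials)

    def test_missing_counted_separately(self):
        trials = _threat_table(10, anticipations=2, missing=3)
        kept, n_removed, pct, n_missing = filter_anticipations(trials)
        assert n_removed == 2 and n_missing == 3
        assert len(kept) == 640 - 5

    def test_idempotent(self):
        trials = _threat_table(10, anticipations=4, missing=2)
        kept, *_ = filter_anticipations(trials)
        kept2, n2, pct2, miss2 = filter_anticipations(kept)
        assert (n2, pct2, miss2) == (0, 0.0, 0)
        pd.testing.assert_frame_equal(kept, kept2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            filter_anticipations(pd.DataFrame(columns=["rt_s", "trial_type"]))


class TestAvoidanceSummary:
    def test_simple_proportions(self):
        rows = []
        for k in range(32):
            rows.append(
                {
                    "participant_id": "p0",
                    "condition": "predictable",
                    "response": "avoid" if k < 16 else "approach",
                    "rt_s": 0.5,
                }
            )
        out = avoidance_summary(pd.DataFrame(rows))
        assert out.loc[0, "p_avoid"] == 0.5
        assert not out.loc[0, "flagged"]

    def test_all_avoid_participant(self):
        rows = [
            {"participant_id": "p0", "condition": c, "response": "avoid", "rt_s": 0.4}
            for c in ["predictable"] * 5 + ["unpredictable"] * 5
        ]
        out = avoidance_summary(pd.DataFrame(rows))
        assert (out["p_avoid"] == 1.0).all()

    def test_empty_cell_flagged(self):
        rows = [
            {"participant_id": "p0", "condition": "predictable", "response": "none", "rt_s": np.nan}
        ]
        out = avoidance_summary(pd.DataFrame(rows))
        assert out.loc[0, "flagged"]
        assert np.isnan(out.loc[0, "p_avoid"])


class TestWilcoxon:
    def test_all_at_chance(self):
        res = wilcoxon_vs_chance([0.5] * 8)
        assert res["p"] == 1.0 and res["degenerate"]

    def test_five_above_chance_exact(self):
        # 2^5 sign patterns; all-positive gives the extreme statistic
        res = wilcoxon_vs_chance([0.6, 0.7, 0.55, 0.8, 0.65], n_boot=200, seed=0)
        assert res["V"] == 15.0
        assert res["p"] == pytest.approx(2 * 0.5**5)  # 0.0625

    def test_antisymmetric_sample_near_null(self):
        x = [0.4, 0.45, 0.55, 0.6]
        res = wilcoxon_vs_chance(x, n_boot=200, seed=0)
        assert res["p"] == 1.0  # perfectly mirrored ranks


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_ttest([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], n_boot=100)
        assert (res["t"], res["p"]) == (0.0, 1.0)

    def test_constant_difference_degenerate(self):
        res = paired_ttest([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0], n_boot=100)
        assert res["degenerate"] and np.isinf(res["t"])

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        res = paired_ttest(a, b, n_boot=100, seed=0)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert res["t"] == pytest.approx(t_manual, abs=1e-10)
        assert res["p"] == pytest.approx(
            2 * stats.t.sf(abs(t_manual), df=9), abs=1e-12
        )
        assert 0 <= res["shapiro_p"] <= 1 and 0 <= res["levene_p"] <= 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_ttest([1, 2, 3], [1, 2])


def _stub_posterior(draws_flat, prior_sd=2.5, name="b_x"):
    arr = np.asarray(draws_flat).reshape(1, -1)
    return PosteriorFit(
        spec=ModelSpec(name="stub"),
        priors=PriorSpec(coef_sd=prior_sd),
        config=MCMCConfig(),
        fixed_names=["x"],
        random_names=[],
        draws={name: arr},
        pointwise_loglik=np.zeros((0, 0)),
        data_fingerprint="stub",
        rt_center=0.0,
        n_participants=0,
    )


class TestSavageDickey:
    def test_symmetric_posterior_tails(self):
        rng = np.random.default_rng(0)
        fit = _stub_posterior(rng.normal(0.0, 1.0, 20000))
        s = summarize_effect(fit, "b_x")
        assert s.p_below_zero == pytest.approx(0.5, abs=0.02)
        assert s.p_above_zero == pytest.approx(0.5, abs=0.02)

    def test_posterior_equals_prior_gives_bf_one(self):
        rng = np.random.default_rng(1)
        fit = _stub_posterior(rng.normal(0.0, 2.5, 40000))
        s = summarize_effect(fit, "b_x")
        assert s.bayes_factor_10 == pytest.approx(1.0, rel=0.1)

    def test_conjugate_normal_oracle(self):
        # normal likelihood (known sd) + normal prior: posterior is normal,
        # so the Savage-Dickey ratio has a closed form
        prior_sd = 2.5
        sigma, n, ybar = 1.0, 25, 0.6
        post_var = 1.0 / (1.0 / prior_sd**2 + n / sigma**2)
        post_mean = post_var * (n * ybar / sigma**2)
        analytic_bf10 = stats.norm.pdf(0, 0, prior_sd) / stats.norm.pdf(
            0, post_mean, np.sqrt(post_var)
        )
        rng = np.random.default_rng(2)
        fit = _stub_posterior(
            rng.normal(post_mean, np.sqrt(post_var), 60000), prior_sd=prior_sd
        )
        s = summarize_effect(fit, "b_x")
        assert s.bayes_factor_10 == pytest.approx(analytic_bf10, rel=0.05)


@pytest.mark.filterwarnings("ignore")
class TestHierarchicalLogistic:
    def test_prior_predictive_mode(self):
        spec = ModelSpec(fixed_terms=("condition",), random_terms=())
        cfg = MCMCConfig(n_chains=3, n_iter=4000, n_warmup=1000, seed=0)
        empty = pd.DataFrame(columns=["participant_id", "condition", "rt_s", "response"])
        fit = fit_hierarchical_logistic(spec, PriorSpec(), empty, cfg)
        d = fit.stacked("b_condition")
        assert abs(d.mean()) < 0.1
        assert d.std() == pytest.approx(2.5, rel=0.05)

    def test_recovery_of_condition_effect(self):
        trials = make_logistic_trials(20, beta0=0.3, beta_cond=0.5, sd0=0.3, seed=11)
        spec = ModelSpec(fixed_terms=("condition",), random_terms=("condition",))
        cfg = MCMCConfig(n_chains=3, n_iter=2000, n_warmup=700, seed=2)
        fit = fit_hierarchical_logistic(spec, PriorSpec(), trials, cfg)
        d = fit.stacked("b_condition")
        lo, hi = np.quantile(d, [0.025, 0.975])
        assert lo < 0.5 < hi
        assert d.mean() == pytest.approx(0.5, abs=0.25)
        diag = fit.diagnostics().set_index("parameter")
        assert diag.loc["b_condition", "rhat"] < 1.05

    def test_intercept_logistic_identity_at_chance(self):
        trials = make_logistic_trials(10, beta0=0.0, beta_cond=0.0, sd0=0.0, seed=3)
        spec = ModelSpec(fixed_terms=("condition",), random_terms=())
        cfg = MCMCConfig(n_chains=2, n_iter=1200, n_warmup=400, seed=4)
        fit = fit_hierarchical_logistic(spec, PriorSpec(), trials, cfg)
        s = summarize_effect(fit, "b_intercept")
        assert s.cri_95[0] < 0.0 < s.cri_95[1]

    def test_single_participant_rejected(self):
        trials = make_logistic_trials(1, beta0=0.0, beta_cond=0.0)
        with pytest.raises(ValueError):
            fit_hierarchical_logistic(ModelSpec(), PriorSpec(), trials, MCMCConfig())

    def test_waic_comparison_and_row_order_invariance(self):
        trials = make_logistic_trials(14, beta0=0.2, beta_cond=0.8, sd0=0.3, seed=7)
        spec1 = ModelSpec(fixed_terms=("condition",), random_terms=(), name="cond")
        spec0 = ModelSpec(fixed_terms=(), random_terms=(), name="null")
        cfg = MCMCConfig(n_chains=2, n_iter=1200, n_warmup=400, seed=5)
        f1 = fit_hierarchical_logistic(spec1, PriorSpec(), trials, cfg)
        f0 = fit_hierarchical_logistic(spec0, PriorSpec(), trials, cfg)
        table = compare_waic({"cond": f1, "null": f0})
        assert table.iloc[0]["model"] == "cond"
        # duplicate of the same model: WAIC agrees within MC error
        f1b = fit_hierarchical_logistic(
            spec1, PriorSpec(), trials, MCMCConfig(n_chains=2, n_iter=1200, n_warmup=400, seed=99)
        )
        w1, _ = f1.waic()
        w1b, _ = f1b.waic()
        assert w1 == pytest.approx(w1b, abs=5.0)
        # shuffled rows carry a different fingerprint but same-data check is
        # based on content: identical rows reordered must not error
        shuffled = trials.sample(frac=1.0, random_state=0)
        f1c = fit_hierarchical_logistic(spec1, PriorSpec(), shuffled, cfg)
        assert f1c.waic()[0] == pytest.approx(w1, abs=5.0)

    def test_mismatched_data_rejected(self):
        t1 = make_logistic_trials(6, 0.2, 0.3, seed=1)
        t2 = make_logistic_trials(6, 0.2, 0.3, seed=2)
        cfg = MCMCConfig(n_chains=2, n_iter=600, n_warmup=200, seed=0)
        spec = ModelSpec(fixed_terms=("condition",), random_terms=())
        f1 = fit_hierarchical_logistic(spec, PriorSpec(), t1, cfg)
        f2 = fit_hierarchical_logistic(spec, PriorSpec(), t2, cfg)
        with pytest.raises(ValueError):
            compare_waic({"a": f1, "b": f2})


@pytest.mark.filterwarnings("ignore")
class TestValueIntegration:
    def _tables(self, seed=0, sv_constant=False):
        trials = make_logistic_trials(8, 0.3, 0.4, seed=seed)
        trials["trial"] = np.tile(np.arange(64), 8)
        trials["dyad_id"] = trials["trial"] % 16
        rng = np.random.default_rng(seed)
        hr = trials[["participant_id", "trial"]].copy()
        hr["hr_change_z"] = rng.standard_normal(len(hr))
        sv_rows = []
        for p in trials["participant_id"].unique():
            for d in range(16):
                sv_rows.append(
                    {
                        "participant_id": p,
                        "dyad_id": d,
                        "sv": 0.0 if sv_constant else float(rng.uniform(-0.5, 1.0)),
                    }
                )
        return trials, hr, pd.DataFrame(sv_rows)

    def test_constant_sv_rejected(self):
        trials, hr, sv = self._tables(sv_constant=True)
        with pytest.raises(ValueError):
            fit_value_integration_model(trials, hr, sv)

    def test_smoke_fit_has_four_way_term(self):
        trials, hr, sv = self._tables(seed=3)
        cfg = MCMCConfig(n_chains=2, n_iter=500, n_warmup=200, seed=1)
        fit, n_dropped = fit_value_integration_model(trials, hr, sv, mcmc_cfg=cfg)
        assert n_dropped == 0
        assert "b_condition:rt:hr:sv" in fit.draws
        s = summarize_effect(fit, "b_condition:rt:hr:sv")
        assert np.isfinite(s.median)


class TestPowerSimulation:
    PARAMS = {
        "fixed": {"intercept": 0.2, "condition": 0.0},
        "random_sd": {"intercept": 0.4, "condition": 0.2},
    }

    def test_deterministic_given_seed(self):
        a = power_simulation(self.PARAMS, [10], n_sims=20, seed=3)
        b = power_simulation(self.PARAMS, [10], n_sims=20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effect_power_near_alpha(self):
        res = power_simulation(self.PARAMS, [15], n_sims=150, seed=1)
        p = res.loc[0, "power"]
        # binomial tolerance around alpha = 0.05 at 150 sims
        assert p < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 150) + 0.02

    def test_huge_effect_saturates(self):
        params = {
            "fixed": {"intercept": 0.0, "condition": 2.5},
            "random_sd": {"intercept": 0.3, "condition": 0.2},
        }
        res = power_simulation(params, [20], n_sims=30, seed=2)
        assert res.loc[0, "power"] > 0.95

    def test_monotone_in_sample_size(self):
        params = {
            "fixed": {"intercept": 0.0, "condition": 0.35},
            "random_sd": {"intercept": 0.3, "condition": 0.2},
        }
        res = power_simulation(params, [8, 40], n_sims=80, seed=4)
        assert res.loc[1, "power"] >= res.loc[0, "power"] - 0.1
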