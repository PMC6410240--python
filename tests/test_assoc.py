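"""Association statistics: t-test/Spearman formula oracles, the Cox
partial-likelihood fit against a brute-force grid and lifelines, and
parameter recovery on simulated survival panels."""

import math

import numpy as np
import pandas as pd
import pytest

from mtna import assoc, simulate
from mtna.genotyping import DELETION, NON_DELETION


class TestExpressionTtest:
    def test_identical_means(self):
        res = assoc.expression_ttest([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert res["fold"] == pytest.approx(1.0)

    def test_log2_difference_of_one_doubles(self):
        res = assoc.expression_ttest([2.0, 2.1, 1.9], [1.0, 1.1, 0.9])
        assert res["fold"] == pytest.approx(2.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(1.0, 0.5, size=7)
        b = rng.normal(0.4, 0.5, size=9)
        res = assoc.expression_ttest(a, b)
        sp = math.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        t = (a.mean() - b.mean()) / (sp * math.sqrt(1 / len(a) + 1 / len(b)))
        assert res["t"] == pytest.approx(t)
        assert res["df"] == len(a) + len(b) - 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.expression_ttest([1.0], [1.0, 2.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = assoc.spearman([1, 2, 3, 4, 5], [10, 20, 21, 40, 100])
        assert rho == pytest.approx(1.0)

    def test_reversed_order(self):
        rho, _ = assoc.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_midrank_ties_against_manual_computation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 7.0, 8.0, 9.0])
        rank_x = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        rank_y = np.array([1.5, 1.5, 3.0, 4.0, 5.0])
        expected = np.corrcoef(rank_x, rank_y)[0, 1]
        rho, _ = assoc.spearman(x, y)
        assert rho == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho1, p1 = assoc.spearman(x, y)
        rho2, p2 = assoc.spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            assoc.spearman([1, 1, 1, 1], [1, 2, 3, 4])


def cox_grid_oracle(times, events, x, betas):
    """Direct partial-likelihood evaluation (no ties) on a beta grid."""
    lls = []
    for beta in betas:
        ll = 0.0
        for i, (t, d) in enumerate(zip(times, events)):
            if not d:
                continue
            risk = [j for j in range(len(times)) if times[j] >= t]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
        lls.append(ll)
    return np.array(lls)


def make_df(times, events, x):
    return pd.DataFrame(
        dict(survival_time=times, event=events, x=np.asarray(x, float))
    )


class TestCoxPh:
    def test_matches_grid_oracle_without_ties(self):
        times = [3.1, 5.2, 7.9, 9.4, 12.0, 15.5]
        events = [1, 1, 0, 1, 1, 1]
        x = [1, 0, 1, 0, 1, 0]
        fit = assoc.cox_ph(make_df(times, events, x), covariates=("x",))
        betas = np.arange(-3, 3, 1e-3)
        lls = cox_grid_oracle(times, events, x, betas)
        beta_grid = betas[np.argmax(lls)]
        assert fit.coef("x") == pytest.approx(beta_grid, abs=2e-3)
        (ll_at_hat,) = cox_grid_oracle(times, events, x, [fit.coef("x")])
        assert fit.loglik == pytest.approx(ll_at_hat, abs=1e-9)

    def test_efron_equals_breslow_without_ties(self, rng):
        times = rng.exponential(10, size=30) + rng.uniform(0, 1e-3, 30)
        events = rng.random(30) < 0.8
        x = rng.normal(size=30)
        df = make_df(times, events.astype(int), x)
        fe = assoc.cox_ph(df, covariates=("x",), ties="efron")
        fb = assoc.cox_ph(df, covariates=("x",), ties="breslow")
        assert fe.coef("x") == pytest.approx(fb.coef("x"), abs=1e-8)
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-8)

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        config = simulate.SimConfig(seed=14, p_del=0.5)
        config.survival.n_replicates = 2
        panel = simulate.simulate_survival(config)
        msb = panel[panel.agent == "MSB"].copy()
        msb["survival_time"] = msb["survival_time"].round(0) + 1.0  # force ties
        fit = assoc.cox_ph(msb, covariates=("sex", "genotype"))
        df = pd.DataFrame(
            dict(
                survival_time=msb.survival_time,
                event=msb.event,
                sex_M=(msb.sex == "M").astype(float),
                genotype_deletion=(msb.genotype == DELETION).astype(float),
            )
        )
        cph = lifelines.CoxPHFitter().fit(df, "survival_time", "event")
        for name in ("sex_M", "genotype_deletion"):
            assert fit.coef(name) == pytest.approx(cph.params_[name], abs=1e-5)
            assert fit.summary.loc[name, "se"] == pytest.approx(
                cph.standard_errors_[name], abs=1e-5
            )

    def test_time_scale_invariance(self):
        config = simulate.SimConfig(seed=15, p_del=0.5)
        msb = simulate.simulate_survival(config).query("agent == 'MSB'").copy()
        fit1 = assoc.cox_ph(msb, covariates=("sex", "genotype"))
        msb2 = msb.assign(survival_time=msb.survival_time * 7.3)
        fit2 = assoc.cox_ph(msb2, covariates=("sex", "genotype"))
        assert fit1.summary.coef.to_numpy() == pytest.approx(
            fit2.summary.coef.to_numpy(), abs=1e-8
        )

    def test_null_hazard_recovery(self):
        """All hazard ratios 1: |beta| < 3 SE for the genotype term."""
        within = 0
        for seed in range(20):
            config = simulate.SimConfig(seed=seed, p_del=0.5)
            config.survival.n_replicates = 1
            config.survival.hazard_ratio_deletion = {"MSB": 1.0}
            config.survival.hazard_ratio_male = 1.0
            panel = simulate.simulate_survival(config)
            fit = assoc.cox_ph(panel, covariates=("sex", "genotype"))
            row = fit.summary.loc[f"genotype_{DELETION}"]
            within += abs(row.coef) < 3 * row.se
        assert within >= 19

    def test_hazard_ratio_recovery(self):
        """Median estimate over 50 seeds near the simulated log HR 0.6."""
        coefs = []
        for seed in range(50):
            config = simulate.SimConfig(seed=seed, p_del=0.5)
            config.survival.n_replicates = 1
            config.survival.hazard_ratio_deletion = {"MSB": 0.6}
            panel = simulate.simulate_survival(config)
            fit = assoc.cox_ph(panel, covariates=("sex", "genotype"))
            coefs.append(fit.coef(f"genotype_{DELETION}"))
        assert np.median(coefs) == pytest.approx(math.log(0.6), abs=0.07)

    def test_line_factor_aliasing_is_dropped(self):
        """Genotype is constant within line, so line indicators are partly
        aliased with it; the fit drops aliased columns and still reports a
        genotype coefficient."""
        config = simulate.SimConfig(seed=16, p_del=0.5)
        config.survival.n_lines = 30
        panel = simulate.simulate_survival(config).query("agent == 'MSB'")
        with pytest.warns(UserWarning, match="aliased"):
            fit = assoc.cox_ph(
                panel, covariates=("sex", "genotype"), line_col="line_id"
            )
        assert f"genotype_{DELETION}" in fit.summary.index
        assert any(f.startswith("aliased:") for f in fit.flags)

    def test_too_few_event_times_rejected(self):
        df = make_df([5.0, 5.0, 5.0], [1, 1, 0], [0, 1, 0])
        with pytest.raises(ValueError):
            assoc.cox_ph(df, covariates=("x",))


class TestAgentContrast:
    def make_panel(self, seed, hr_msb=0.5, hr_paraquat=1.0, n_lines=40):
        config = simulate.SimConfig(seed=seed, p_del=0.5)
        config.survival.n_lines = n_lines
        config.survival.hazard_ratio_deletion = {
            "MSB": hr_msb,
            "paraquat": hr_paraquat,
        }
        return simulate.simulate_survival(config)

    def test_effect_only_in_msb(self):
        """Genotype effect injected only into MSB survival: significant for
        MSB, not paraquat, in the majority of seeds. The genotype test uses
        the sex + genotype model: with treatment-coded line factors the
        genotype term is identified only through a single line contrast
        (genotype is constant within line), which has no power here."""
        msb_hits = paraquat_nulls = 0
        n_seeds = 20
        for seed in range(n_seeds):
            contrast = assoc.agent_contrast(self.make_panel(seed), line_col=None)
            by_agent = contrast.set_index("agent")
            msb_hits += by_agent.loc["MSB", "genotype_p"] < 0.05
            paraquat_nulls += by_agent.loc["paraquat", "genotype_p"] > 0.05
        assert msb_hits > n_seeds / 2
        assert paraquat_nulls > n_seeds / 2

    def test_identical_data_identical_statistics(self):
        panel = self.make_panel(3)
        msb = panel[panel.agent == "MSB"]
        cloned = pd.concat(
            [msb, msb.assign(agent="paraquat")], ignore_index=True
        )
        contrast = assoc.agent_contrast(cloned).set_index("agent")
        assert contrast.loc["MSB", "genotype_p"] == pytest.approx(
            contrast.loc["paraquat", "genotype_p"]
        )
        assert contrast.loc["MSB", "spearman_rho"] == pytest.approx(
            contrast.loc["paraquat", "spearman_rho"]
        )

    def test_missing_agent_partial_report(self):
        panel = self.make_panel(4)
        msb_only = panel[panel.agent == "MSB"]
        with pytest.warns(UserWarning, match="paraquat"):
            contrast = assoc.agent_contrast(msb_only)
        assert list(contrast.agent) == ["MSB"]


class TestPrepareLinePanel:
    def test_lines_with_single_replicate_excluded(self):
        config = simulate.SimConfig(seed=20, p_del=0.5)
        config.survival.n_lines = 10
        panel = simulate.simulate_survival(config)
        drop = panel.line_id.iloc[0]
        panel.loc[panel.line_id == drop, "expression_rep2"] = np.nan
        with pytest.warns(UserWarning, match="single expression replicate"):
            kept = assoc.prepare_line_panel(panel)
        assert drop not in set(kept.line_id)
        assert kept.line_id.nunique() == 9
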