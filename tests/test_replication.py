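"""Replication metrics: SESOI, inferiority, PI, exact r-density, BF, meta, pooling."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import blinkrep as br
from blinkrep.replication import _power_fisher, _sample_r_bvn

ORIG = br.StudySummary("study1", -0.45, 34, 1)
REP = br.StudySummary("study2", 0.02, 40, 1)


class TestSesoi:
    def test_solution_hits_target_power(self):
        r33 = br.sesoi_r33(34, 1)
        assert abs(_power_fisher(np.arctanh(r33), 30, 0.05) - 1 / 3) < 1e-8

    def test_shrinks_to_zero_as_power_approaches_alpha(self):
        assert br.sesoi_r33(34, 1, 0.05, 0.051) < 0.02

    def test_power_at_most_alpha_has_no_solution(self):
        with pytest.raises(ValueError, match="power"):
            br.sesoi_r33(34, 1, 0.05, 0.05)

    def test_eighty_percent_solution_matches_simulated_power(self, rng):
        """Invert for 80% power, then verify by simulating the partial-
        correlation test at that effect size (binary covariate partialled)."""
        r80 = br.sesoi_r33(34, 1, 0.05, 0.80)
        n, reps = 34, 20_000
        group = np.repeat([0.0, 1.0], [17, 17])
        x = rng.standard_normal((reps, n))
        y = r80 * x + np.sqrt(1 - r80**2) * rng.standard_normal((reps, n))
        for arr in (x, y):
            for g in (0.0, 1.0):
                m = group == g
                arr[:, m] -= arr[:, m].mean(axis=1, keepdims=True)
        r = (x * y).sum(1) / np.sqrt((x**2).sum(1) * (y**2).sum(1))
        t = r * np.sqrt(30) / np.sqrt(1 - r**2)
        power = np.mean(np.abs(t) > stats.t.ppf(0.975, 30))
        assert power == pytest.approx(0.80, abs=0.02)


class TestInferiority:
    def test_boundary_null_gives_half(self):
        assert br.inferiority_test(-0.27, 40, 1, 0.27) == pytest.approx(0.5)

    def test_large_positive_r_gives_tiny_p(self):
        assert br.inferiority_test(0.999, 40, 1, 0.27) < 1e-8

    def test_equivalent_to_90_ci_exclusion(self):
        # significance at alpha = .05 iff the 90% CI lower bound clears -sesoi
        for r_rep in (-0.05, 0.0, 0.02, 0.10):
            p = br.inferiority_test(r_rep, 40, 1, 0.27)
            lo, _ = br.correlation_ci(r_rep, 40, 1, 0.90)
            assert (p < 0.05) == (lo > -0.27)

    def test_invalid_sesoi_rejected(self):
        with pytest.raises(ValueError):
            br.inferiority_test(0.02, 40, 1, sesoi=1.2)


class TestPredictionInterval:
    def test_symmetric_when_original_r_is_zero(self):
        lo, hi = br.prediction_interval(0.0, 34, 34)
        assert lo == pytest.approx(-hi, abs=1e-12)
        lo_s, hi_s = br.prediction_interval(
            0.0, 34, 34, method="simulation", n_draws=100_000, seed=3
        )
        assert lo_s == pytest.approx(-hi_s, abs=0.02)

    def test_collapses_with_infinite_samples(self):
        lo, hi = br.prediction_interval(-0.45, 10**6, 10**6)
        assert lo == pytest.approx(-0.45, abs=5e-3)
        assert hi == pytest.approx(-0.45, abs=5e-3)

    def test_simulation_agrees_with_closed_form(self):
        lo_f, hi_f = br.prediction_interval(ORIG.r, ORIG.n, REP.n)
        lo_s, hi_s = br.prediction_interval(
            ORIG.r, ORIG.n, REP.n, method="simulation", n_draws=200_000, seed=11
        )
        assert lo_s == pytest.approx(lo_f, abs=0.02)
        assert hi_s == pytest.approx(hi_f, abs=0.02)

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            br.prediction_interval(0.1, 30, 30, level=1.5)


class TestLikelihoodR:
    def test_normalizes_to_one(self):
        val, err = integrate.quad(lambda r: br.likelihood_r(r, 0.3, 20), -1, 1)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rho,n", [(0.0, 10), (0.5, 10), (-0.8, 25)])
    def test_reflection_symmetry(self, rho, n):
        r = np.linspace(-0.9, 0.9, 13)
        np.testing.assert_allclose(
            br.likelihood_r(r, rho, n), br.likelihood_r(-r, -rho, n), rtol=1e-12
        )

    def test_huge_n_stays_finite(self):
        assert np.isfinite(br.log_likelihood_r(0.001, 0.0, 10**6))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            br.likelihood_r(1.0, 0.0, 10)
        with pytest.raises(ValueError):
            br.likelihood_r(0.5, 0.0, 3)


class TestReplicationBF:
    def test_grid_and_quad_agree(self):
        bf_q = br.replication_bf(ORIG, REP, method="quad")
        bf_g = br.replication_bf(ORIG, REP, method="grid")
        assert bf_g == pytest.approx(bf_q, rel=1e-6)

    def test_point_mass_posterior_gives_unit_bf(self):
        # an enormous original null study pins the proponent prior at rho = 0
        orig = br.StudySummary("big-null", 0.0, 10**6, 0)
        bf = br.replication_bf(orig, br.StudySummary("rep", 0.1, 40, 0))
        assert bf == pytest.approx(1.0, abs=1e-3)

    def test_matches_importance_sampling_oracle(self):
        """Successful-replication direction: BF << 1, cross-checked against a
        Monte-Carlo average of the replication density over posterior draws
        obtained by grid inverse-CDF sampling."""
        rep_same = br.StudySummary("rep-same", -0.45, 40, 1)
        bf = br.replication_bf(ORIG, rep_same)
        assert bf < 0.2

        n_o, n_r = ORIG.n - ORIG.k, rep_same.n - rep_same.k
        grid = np.linspace(-1 + 1e-9, 1 - 1e-9, 4096)
        post = br.likelihood_r(ORIG.r, grid, n_o)
        cdf = np.cumsum(post)
        cdf /= cdf[-1]
        rng = np.random.default_rng(5)
        draws = np.interp(rng.random(200_000), cdf, grid)
        den_mc = br.likelihood_r(rep_same.r, draws, n_r).mean()
        bf_mc = br.likelihood_r(rep_same.r, 0.0, n_r) / den_mc
        assert bf == pytest.approx(bf_mc, rel=0.05)

    def test_evidence_accumulates_with_replication_size(self):
        """True rho = 0: median BF grows without bound in n_rep; true rho at
        the original posterior mean: median BF falls toward 0."""
        rng = np.random.default_rng(17)
        post_mean = -0.43
        med_null, med_effect = [], []
        for n_rep in (40, 160, 640):
            r_null = _sample_r_bvn(np.zeros(101), n_rep, rng)
            r_eff = _sample_r_bvn(np.full(101, post_mean), n_rep, rng)
            bfs_null = [
                br.replication_bf(ORIG, br.StudySummary("s", r, n_rep, 0), method="grid")
                for r in r_null
            ]
            bfs_eff = [
                br.replication_bf(ORIG, br.StudySummary("s", r, n_rep, 0), method="grid")
                for r in r_eff
            ]
            med_null.append(np.median(bfs_null))
            med_effect.append(np.median(bfs_eff))
        assert med_null[0] < med_null[1] < med_null[2]
        assert med_effect[0] > med_effect[1] > med_effect[2]
        assert med_effect[-1] < 0.01


class TestMetaFixed:
    def test_single_study_is_identity(self):
        est = br.meta_fixed([REP])
        assert est.r == pytest.approx(REP.r, abs=1e-12)
        assert (est.ci_lo, est.ci_hi) == pytest.approx(
            br.correlation_ci(REP.r, REP.n, REP.k), abs=1e-12
        )

    def test_identical_studies_pool_to_same_r(self):
        studies = [br.StudySummary(f"s{i}", 0.3, 20 + 5 * i, 0) for i in range(3)]
        assert br.meta_fixed(studies).r == pytest.approx(0.3, abs=1e-12)

    def test_order_invariance(self):
        assert br.meta_fixed([ORIG, REP]).r == br.meta_fixed([REP, ORIG]).r

    def test_split_study_with_proportional_weights_is_exact(self):
        # one study of weight 34 vs two same-z halves of weight 17 each
        whole = [br.StudySummary("w", 0.25, 37, 0), REP]
        halves = [
            br.StudySummary("h1", 0.25, 20, 0),
            br.StudySummary("h2", 0.25, 20, 0),
            REP,
        ]
        assert br.meta_fixed(whole).r == pytest.approx(br.meta_fixed(halves).r, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            br.meta_fixed([])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_metafor_fixed_effects(self):
        """Independent cross-check against R metafor (Fisher-z FE model)."""
        script = """
        suppressMessages(library(metafor))
        d <- escalc(measure="ZCOR", ri=c(0.3, -0.1), ni=c(28, 45))
        f <- rma(yi, vi, data=d, method="FE")
        cat(jsonlite::toJSON(list(r=tanh(as.numeric(f$beta)),
                                  lo=tanh(f$ci.lb), hi=tanh(f$ci.ub)), digits=12))
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        est = br.meta_fixed(
            [br.StudySummary("a", 0.3, 28, 0), br.StudySummary("b", -0.1, 45, 0)]
        )
        assert est.r == pytest.approx(ref["r"][0], abs=1e-9)
        assert est.ci_lo == pytest.approx(ref["lo"][0], abs=1e-9)
        assert est.ci_hi == pytest.approx(ref["hi"][0], abs=1e-9)


class TestPooledAnalysis:
    def _dataset(self, seed, n=16, prefix=""):
        cfg = br.SimConfig(n_participants=n, trials_short=40, trials_long=20, seed=seed)
        trials, _ = br.simulate_study(cfg)
        if prefix:
            trials = trials.assign(participant=prefix + trials["participant"])
        return trials

    def test_duplication_invariance(self):
        trials = self._dataset(3)
        single = br.pooled_analysis([(trials, "study2")])
        twin = trials.assign(participant="dup_" + trials["participant"])
        double = br.pooled_analysis([(trials, "study2"), (twin, "study2")])
        assert double.r == pytest.approx(single.r, abs=1e-12)
        assert double.n == 2 * single.n
        assert double.p is None  # pooled re-analysis withholds the p-value

    def test_label_collision_rejected(self):
        trials = self._dataset(3)
        with pytest.raises(ValueError, match="collide"):
            br.pooled_analysis([(trials, "study2"), (trials.copy(), "study2")])

    def test_pooled_r_between_balanced_study_estimates(self):
        a = self._dataset(1, prefix="a_")
        b = self._dataset(2, prefix="b_")
        ra = br.pooled_analysis([(a, "study2")]).r
        rb = br.pooled_analysis([(b, "study2")]).r
        rp = br.pooled_analysis([(a, "study2"), (b, "study2")]).r
        assert min(ra, rb) - 0.05 <= rp <= max(ra, rb) + 0.05


class TestFullReport:
    def test_published_summaries_populate_every_field(self):
        rep = br.full_report(ORIG, REP)
        assert round(rep.sesoi_r33, 2) == 0.27
        assert rep.inferiority_p == pytest.approx(0.038, abs=0.002)
        assert rep.bf_0r == pytest.approx(9.66, rel=0.10)
        assert rep.meta.r == pytest.approx(-0.20, abs=0.02)
        assert rep.pi_lo < rep.pi_hi
        assert rep.pooled is None

    def test_self_replication_direction(self):
        twin = br.StudySummary("twin", -0.45, 34, 1)
        rep = br.full_report(ORIG, twin)
        assert rep.inferiority_p > 0.05  # strong negative r is not "too small"
        assert rep.bf_0r < 1  # and favors the original effect over the null

    def test_report_includes_pooled_when_trials_given(self):
        cfg = br.SimConfig(n_participants=12, trials_short=30, trials_long=15, seed=9)
        t_rep, _ = br.simulate_study(cfg)
        t_orig, _ = br.simulate_study(
            br.SimConfig(n_participants=12, trials_short=30, trials_long=15,
                         seed=10, dialect="study1")
        )
        t_orig = t_orig.assign(participant="s1_" + t_orig["participant"])
        rep = br.full_report(ORIG, REP, rep_trials=t_rep, orig_trials=t_orig)
        assert rep.pooled is not None
        assert rep.pooled.n == 24

    def test_report_table_and_forest(self):
        rep = br.full_report(ORIG, REP)
        tab = br.report_table(rep)
        assert list(tab.columns) == ["quantity", "estimate", "lo", "hi", "p", "method"]
        assert "meta-analytic r" in set(tab["quantity"])
        text = br.forest_text(rep)
        assert "BF_0r" in text and "x" in text
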