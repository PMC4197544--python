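"""Linear-model contrasts, variance moderation, FDR and significance calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from axiswitch import de, rma
from axiswitch.simulate import SimulationConfig, simulate_probe_intensities


def _two_group_sheet(n_per_group=6):
    ids = [f"A_{i}" for i in range(n_per_group)] + [f"B_{i}" for i in range(n_per_group)]
    return pd.DataFrame(
        {"tissue": ["A"] * n_per_group + ["B"] * n_per_group, "replicate": list(range(n_per_group)) * 2},
        index=pd.Index(ids, name="sample_id"),
    )


def bh_stepup_oracle(p):
    """Independent step-up enumeration: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(m) if p[order[j]] >= p[i] - 1e-15
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestLinearFit:
    def test_four_by_three_design_has_df_eight(self, small_sim):
        _, pim, _, expr = small_sim
        fit = de.fit_linear_model(expr, pim.samples)
        assert fit.df == 8
        assert list(fit.groups) == ["SZ", "PNT", "CNT", "RNT"]

    def test_zero_noise_fit_recovers_truth_with_zero_variance(self):
        cfg = SimulationConfig(n_probesets=30, probes_per_probeset=3, noise_sd=0.0, seed=4)
        pim, truth = simulate_probe_intensities(cfg)
        expr = rma.medianpolish_summarize(np.log2(pim.intensities), pim.layout)
        fit = de.fit_linear_model(expr, pim.samples)
        assert np.allclose(fit.s2.values, 0.0, atol=1e-18)
        step = fit.means["CNT"] - fit.means["PNT"]
        planted = truth.probesets["mean_CNT"] - truth.probesets["mean_PNT"]
        assert np.allclose(step[planted.index], planted)

    def test_single_probeset_matches_lstsq_oracle(self):
        rng = np.random.default_rng(0)
        samples = _two_group_sheet(3)
        y = rng.normal(size=6)
        expr = pd.DataFrame([y], index=["PS0"], columns=samples.index)
        fit = de.fit_linear_model(expr, samples)
        X = np.column_stack([(samples["tissue"] == g).astype(float) for g in fit.groups])
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.means.loc["PS0"].values, beta)
        assert fit.s2["PS0"] == pytest.approx(float(rss[0]) / 4)

    def test_empty_group_rejected(self):
        samples = _two_group_sheet(2)
        expr = pd.DataFrame(np.ones((3, 4)), columns=samples.index)
        bad = samples.copy()
        bad["tissue"] = "A"
        with pytest.raises(ValueError):
            de.fit_linear_model(expr, samples.iloc[:0])


class TestModeration:
    def test_identical_variances_shrink_to_that_value(self):
        hyper, st_ = de.moderate_variances(pd.Series([0.7] * 30), df=8)
        assert np.isinf(hyper.d0)
        assert np.allclose(st_.values, 0.7)

    def test_d0_zero_recovers_ordinary_variances(self):
        s2 = pd.Series([0.1, 0.5, 2.0, 1.0])
        _, st_ = de.moderate_variances(s2, df=8, d0_override=0)
        pd.testing.assert_series_equal(st_, s2)

    def test_monte_carlo_recovery_of_prior_scale(self):
        rng = np.random.default_rng(42)
        s2 = pd.Series(rng.chisquare(8, 10000) / 8.0)
        hyper, _ = de.moderate_variances(s2, df=8)
        assert hyper.s0_2 == pytest.approx(1.0, rel=0.05)
        assert hyper.d0 > 100 or np.isinf(hyper.d0)

    def test_informative_prior_recovered(self):
        rng = np.random.default_rng(7)
        d0, s0 = 4.0, 2.0
        sigma2 = d0 * s0 / rng.chisquare(d0, 20000)
        s2 = pd.Series(sigma2 * rng.chisquare(8, 20000) / 8.0)
        hyper, _ = de.moderate_variances(s2, df=8)
        assert hyper.d0 == pytest.approx(d0, rel=0.15)
        assert hyper.s0_2 == pytest.approx(s0, rel=0.1)

    def test_all_zero_variances_rejected_with_advice(self):
        with pytest.raises(ValueError, match="zero-noise"):
            de.moderate_variances(pd.Series([0.0, 0.0, 0.0]), df=8)


class TestContrastStats:
    def test_contrast_coefficients_must_sum_to_zero(self):
        with pytest.raises(ValueError):
            de.ContrastSpec("bad", {"A": 1.0, "B": 0.5})

    def test_equal_group_means_give_t_zero_p_one(self):
        samples = _two_group_sheet(3)
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["PS0"], columns=samples.index
        )
        fit = de.fit_linear_model(expr, samples)
        res = de.compute_contrast_stats(fit, de.ContrastSpec("AB", {"A": -1.0, "B": 1.0}))
        assert res.loc["PS0", "t"] == 0.0
        assert res.loc["PS0", "p"] == pytest.approx(1.0)

    def test_planted_step_recovered_by_pooled_contrast(self):
        cfg = SimulationConfig(
            n_probesets=100, probes_per_probeset=4, noise_sd=0.05, seed=9
        )
        pim, truth = simulate_probe_intensities(cfg)
        expr = rma.medianpolish_summarize(np.log2(pim.intensities), pim.layout)
        fit = de.fit_linear_model(expr, pim.samples)
        pooled = [c for c in de.standard_contrasts() if c.name == "switch_pooled"][0]
        res = de.compute_contrast_stats(fit, pooled)
        sw = truth.probesets[truth.probesets["is_switch"]]
        signed = np.where(sw["direction"] == "down", -1.0, 1.0)
        assert np.allclose(res.loc[sw.index, "logFC"].values, signed * cfg.effect_size, atol=0.1)

    def test_pooled_two_group_contrast_with_d0_zero_equals_classical_t(self):
        rng = np.random.default_rng(123)
        samples = _two_group_sheet(6)
        for _ in range(50):
            y = rng.normal(size=12) + np.r_[np.zeros(6), rng.normal(scale=2) * np.ones(6)]
            expr = pd.DataFrame([y], index=["PS0"], columns=samples.index)
            fit = de.fit_linear_model(expr, samples)
            mod = de.moderate_variances(fit.s2, fit.df, d0_override=0)
            res = de.compute_contrast_stats(
                fit, de.ContrastSpec("BA", {"B": 1.0, "A": -1.0}), mod
            )
            t_ref, p_ref = stats.ttest_ind(y[6:], y[:6], equal_var=True)
            assert res.loc["PS0", "t"] == pytest.approx(t_ref, rel=1e-10)
            assert res.loc["PS0", "p"] == pytest.approx(p_ref, rel=1e-10)


class TestBhFdr:
    def test_stepup_oracle_example(self):
        q = de.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_enumeration_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 11))
            assert np.allclose(de.bh_fdr(p), bh_stepup_oracle(p))

    def test_degenerate_inputs(self):
        assert np.allclose(de.bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert de.bh_fdr([0.123])[0] == pytest.approx(0.123)
        with pytest.raises(ValueError):
            de.bh_fdr([-0.1, 0.5])

    def test_q_values_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        p = pd.Series(rng.uniform(size=40), index=[f"g{i}" for i in range(40)])
        perm = p.sample(frac=1, random_state=1)
        q1 = de.bh_fdr(p)
        q2 = de.bh_fdr(perm).reindex(q1.index)
        pd.testing.assert_series_equal(q1, q2)


class TestCallSignificant:
    def test_threshold_is_strict(self):
        df = pd.DataFrame({"logFC": [1.0], "t": [5.0], "p": [0.046], "q": [0.046]})
        results, summary = de.call_significant(df)
        assert not results["contrast"]["significant"].any()
        assert summary.loc["contrast", "n_significant"] == 0

    def test_down_biased_switch_cohort_recovered(self, small_sim):
        cfg, pim, truth, expr = small_sim
        results, summary = de.run_contrasts(expr, pim.samples)
        pooled = results["switch_pooled"]
        sw = truth.probesets[truth.probesets["is_switch"]]
        detected = pooled.loc[sw.index]
        detected = detected[detected["significant"]]
        assert len(detected) / len(sw) >= 0.95
        down = (detected["direction"] == "down").mean()
        half_width = 2.576 * np.sqrt(0.64 * 0.36 / len(detected))
        assert abs(down - (sw["direction"] == "down").mean()) < half_width + 0.02

    def test_null_simulation_keeps_false_positive_rate_controlled(self):
        cfg = SimulationConfig(
            n_probesets=5000, probes_per_probeset=1, switch_fraction=0.0,
            marker_fraction=0.0, noise_sd=0.25, seed=21,
        )
        pim, _ = simulate_probe_intensities(cfg)
        expr = rma.medianpolish_summarize(np.log2(pim.intensities), pim.layout)
        results, summary = de.run_contrasts(expr, pim.samples)
        assert summary["n_significant"].sum() <= 0.046 * 5000 * len(results)


class TestGeneLevel:
    def test_any_significant_probeset_makes_gene_significant(self):
        res = pd.DataFrame(
            {
                "logFC": [2.0, -1.0, 0.5],
                "q": [0.001, 0.5, 0.9],
                "significant": [True, False, False],
                "direction": ["up", "down", "up"],
            },
            index=["PS0", "PS1", "PS2"],
        )
        ann = pd.Series({"PS0": "G1", "PS1": "G1", "PS2": "G2"})
        calls = de.gene_level_calls(res, ann)
        assert bool(calls.loc["G1", "significant"])
        assert calls.loc["G1", "direction"] == "up"  # smallest-q probe-set wins
        assert not bool(calls.loc["G2", "significant"])


class TestCasiBias:
    def _setup(self, shift=0.0, seed=0):
        cfg = SimulationConfig(n_probesets=200, probes_per_probeset=2, seed=seed)
        pim, truth = simulate_probe_intensities(cfg)
        expr = rma.medianpolish_summarize(np.log2(pim.intensities), pim.layout)
        ann = pd.Series(
            {ps: f"G{i}" for i, ps in enumerate(expr.index)}, name="gene_id"
        )
        casi_ps = list(expr.index[:20])
        if shift:
            # replicate-linked shift: replicate 1 of every tissue moves up
            rep1 = pim.samples.index[pim.samples["replicate"] == 1]
            expr.loc[casi_ps, rep1] += shift
        casi_genes = [ann[ps] for ps in casi_ps]
        return expr, pim.samples, casi_genes, ann

    def test_null_casi_genes_show_no_strong_bias(self):
        expr, samples, casi, ann = self._setup()
        res = de.casi_bias_check(expr, samples, casi, ann, B=200, seed=1)
        assert res.applicable
        assert res.p > 0.05
        assert "no strong" in res.verdict

    def test_replicate_linked_shift_is_flagged(self):
        expr, samples, casi, ann = self._setup(shift=1.5)
        res = de.casi_bias_check(expr, samples, casi, ann, B=200, seed=1)
        assert res.flagged_bias and res.p < 0.05

    def test_empty_casi_list_not_applicable(self):
        expr, samples, _, ann = self._setup()
        res = de.casi_bias_check(expr, samples, [], ann, B=10)
        assert not res.applicable
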