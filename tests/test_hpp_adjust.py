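import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rankoverlap import hpp_adjust as ha
from rankoverlap.quadrants import RRHOConfig
from rankoverlap.synthetic_bench import make_scenario


def _expr(rows, index, columns=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(rows, index=index,
                        columns=columns or [f"s{k}" for k in range(rows.shape[1])])


class TestSelectPredictors:
    def test_independent_features_all_predictors(self, rng):
        """With a stringent significance level no pair passes, so the
        scheme degenerates to a plain permutation."""
        expr = _expr(rng.normal(size=(10, 8)), [f"g{k}" for k in range(10)])
        asg = ha.select_predictors(expr, alpha_sig=1e-8)
        assert asg.predicted_map == {}
        assert len(asg.predictor_set) == 10

    def test_collinear_pair_recovers_slope(self, rng):
        x = rng.normal(size=12)
        idx = ["ga", "gb", "gc", "gd"]
        expr = _expr(
            np.vstack([x, 2.0 * x, rng.normal(size=12), rng.normal(size=12)]),
            idx,
        )
        asg = ha.select_predictors(expr, alpha_sig=1e-6)
        assert set(asg.predicted_map) <= {"ga", "gb"}
        (y, (x_lab, beta1)) = next(iter(asg.predicted_map.items()))
        expected = 2.0 if y == "gb" else 0.5
        assert beta1 == pytest.approx(expected, abs=1e-6)

    def test_noisy_slope_recovery_within_3_se(self):
        g = np.random.default_rng(7)
        m = 50
        x = g.normal(size=m)
        beta = 1.7
        y = beta * x + g.normal(scale=0.3, size=m)
        expr = _expr(np.vstack([x, y]), ["gx", "gy"])
        asg = ha.select_predictors(expr, alpha_sig=0.05)
        assert "gy" in asg.predicted_map or "gx" in asg.predicted_map
        lab, (pred, b1) = next(
            (k, v) for k, v in asg.predicted_map.items()
        )
        # reference OLS fit of the same pair
        if lab == "gy":
            slope, _, _, _, se = stats.linregress(x, y)[:5]
        else:
            slope, _, _, _, se = stats.linregress(y, x)[:5]
        assert b1 == pytest.approx(slope, abs=1e-9)
        true = beta if lab == "gy" else 1 / beta
        assert abs(slope - true) < 3 * se + 0.05

    def test_requires_three_samples(self):
        expr = _expr([[1.0, 2.0], [2.0, 1.0]], ["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            ha.select_predictors(expr)

    def test_constant_features_are_predictors(self, rng):
        expr = _expr(
            np.vstack([np.ones(8), rng.normal(size=(3, 8))]),
            ["const", "g1", "g2", "g3"],
        )
        asg = ha.select_predictors(expr)
        assert "const" in asg.predictor_set
        assert "const" not in asg.predicted_map

    def test_mutual_best_predictors_cycle_broken(self, rng):
        x = rng.normal(size=10)
        expr = _expr(np.vstack([x, x * 1.001 + 1e-9]), ["ga", "gb"])
        asg = ha.select_predictors(expr, alpha_sig=0.05)
        # one of the two must stay a predictor; the smaller label wins
        assert "ga" in asg.predictor_set
        assert list(asg.predicted_map) == ["gb"]


class TestHppPermute:
    def test_empty_predicted_map_is_plain_permutation(self, rng):
        asg = ha.plain_assignment([f"g{k}" for k in range(20)])
        vals = pd.Series(rng.normal(size=20),
                         index=[f"g{k}" for k in range(20)])
        out = ha.hpp_permute(asg, vals, np.random.default_rng(1))
        assert sorted(out) == pytest.approx(sorted(vals))
        assert not out.equals(vals)

    def test_r_equal_one_copies_predictor(self):
        asg = ha.PredictorAssignment(
            predictor_set=["gx"], predicted_map={"gy": ("gx", 1.0)},
            flavour="pvalue",
        )
        vals = pd.Series([0.3, 0.9], index=["gx", "gy"])
        out = ha.hpp_permute(asg, vals, np.random.default_rng(0))
        assert out["gy"] == out["gx"]

    def test_r_equal_zero_is_bootstrap_draw(self):
        asg = ha.PredictorAssignment(
            predictor_set=["gx"], predicted_map={"gy": ("gx", 0.0)},
            flavour="pvalue",
        )
        vals = pd.Series([0.3, 0.9], index=["gx", "gy"])
        out = ha.hpp_permute(asg, vals, np.random.default_rng(0))
        assert out["gy"] in set(vals)

    def test_fold_change_chain_evaluation(self):
        asg = ha.PredictorAssignment(
            predictor_set=["g1"],
            predicted_map={"g2": ("g1", 2.0), "g3": ("g2", 0.5)},
        )
        vals = pd.Series([1.5, 0.0, 0.0], index=["g1", "g2", "g3"])
        out = ha.hpp_permute(asg, vals, np.random.default_rng(0))
        assert out["g2"] == pytest.approx(2.0 * out["g1"])
        assert out["g3"] == pytest.approx(0.5 * out["g2"])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ha.PredictorAssignment(
                predictor_set=[],
                predicted_map={"a": ("b", 1.0), "b": ("a", 1.0)},
            )

    def test_topological_order_never_reads_unset(self, rng):
        """Randomized chain structures: every predictor appears before
        its dependants in the evaluation order."""
        for _ in range(20):
            n = int(rng.integers(5, 30))
            labels = [f"g{k}" for k in range(n)]
            roots = labels[: max(1, n // 4)]
            pm = {}
            for k, lab in enumerate(labels[len(roots):], start=len(roots)):
                parent = labels[int(rng.integers(0, k))]
                pm[lab] = (parent, 1.0)
            asg = ha.PredictorAssignment(predictor_set=roots, predicted_map=pm)
            seen = set(asg.predictor_set)
            for lab in asg.topo_order:
                assert pm[lab][0] in seen
                seen.add(lab)


class TestNullAndBeta:
    def test_null_deterministic(self):
        a, b = make_scenario("random", n=150, seed=2)
        cfg = RRHOConfig(algorithm="grid", render_resolution=None)
        n1 = ha.null_min_logp(a, b, (None, None), cfg, R=25, seed=3)
        n2 = ha.null_min_logp(a, b, (None, None), cfg, R=25, seed=3)
        for q in n1:
            assert np.array_equal(n1[q], n2[q])

    def test_planted_signal_below_all_null(self):
        sc = make_scenario("planted", n=400, seed=0, n_overlap=30, n_top=40)
        cfg = RRHOConfig(algorithm="grid", step=5, quadrant_names=("dd",),
                         render_resolution=None)
        from rankoverlap.minp_search import grid_search
        from rankoverlap.ranked_io import QUADRANTS

        obs = grid_search(sc.list_a, sc.list_b, QUADRANTS["dd"], step=5)
        null = ha.null_min_logp(sc.list_a, sc.list_b, (None, None), cfg,
                                R=30, seed=0)
        assert obs.slp.log_p < null["dd"].min()

    def test_hpp_null_matches_plain_permutation_when_independent(self):
        """With no predicted features the HPP null and the plain
        permutation null are draws from the same distribution."""
        a, b = make_scenario("random", n=120, seed=5)
        cfg = RRHOConfig(algorithm="grid", step=4, quadrant_names=("dd",),
                         render_resolution=None)
        asg = ha.plain_assignment(a.labels)
        hpp = ha.null_min_logp(a, b, (asg, asg), cfg, R=100, seed=1)["dd"]
        plain = ha.null_min_logp(a, b, (None, None), cfg, R=100, seed=2)["dd"]
        ks = stats.ks_2samp(hpp, plain)
        assert ks.pvalue > 0.01

    def test_beta_uniform_sample_gives_1_1(self):
        g = np.random.default_rng(0)
        fit = ha.fit_beta_mom(g.uniform(size=20_000))
        assert fit.alpha == pytest.approx(1.0, abs=0.05)
        assert fit.beta == pytest.approx(1.0, abs=0.05)
        assert fit.accepted

    def test_beta_parameter_recovery(self):
        g = np.random.default_rng(1)
        fit = ha.fit_beta_mom(g.beta(2.0, 5.0, size=10_000))
        assert fit.alpha == pytest.approx(2.0, rel=0.10)
        assert fit.beta == pytest.approx(5.0, rel=0.10)

    def test_constant_sample_rejected(self):
        fit = ha.fit_beta_mom(np.full(50, 0.3))
        assert not fit.accepted


class TestEndToEndHPP:
    def test_run_rrho_with_expression_matrices(self):
        """Full pipeline with the correlation-aware adjustment: the HPP
        null reflects the supplied expression correlation structure and
        produces finite adjusted P-values."""
        from rankoverlap.quadrants import run_rrho

        g = np.random.default_rng(11)
        a, b = make_scenario("random", n=80, seed=6)
        base = g.normal(size=(80, 12))
        # correlate neighbouring features pairwise
        base[1::2] = 0.9 * base[0::2] + 0.1 * g.normal(size=(40, 12))
        labels = sorted(map(str, a.labels))
        expr = pd.DataFrame(base, index=labels)
        cfg = RRHOConfig(algorithm="grid", step=2, adjust="hpp",
                         permutations=30, render_resolution=None, seed=2)
        res = run_rrho(a, b, cfg, expr_a=expr, expr_b=expr)
        for q in res.quadrants.values():
            assert q.p_adjusted is not None
            assert 0.0 <= q.p_adjusted <= 1.0

    def test_missing_expression_features_rejected(self):
        from rankoverlap.quadrants import run_rrho

        a, b = make_scenario("random", n=50, seed=1)
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)),
                            index=sorted(map(str, a.labels))[:10])
        cfg = RRHOConfig(algorithm="grid", adjust="hpp", permutations=20,
                         render_resolution=None)
        with pytest.raises(ValueError, match="lacks"):
            run_rrho(a, b, cfg, expr_a=expr)


class TestAdjust:
    def test_uniform_null_identity(self):
        fit = ha.BetaFit(alpha=1.0, beta=1.0, ks_p=0.5, accepted=True)
        p, logp = ha.adjust_pvalue(1e-4, fit, np.array([]))
        assert p == pytest.approx(1e-4, rel=1e-9)

    def test_boundary_of_significance(self):
        fit = ha.BetaFit(alpha=1.0, beta=1.0, ks_p=0.5, accepted=True)
        p, _ = ha.adjust_pvalue(0.05, fit, np.array([]))
        assert p == pytest.approx(0.05, rel=1e-12)

    def test_linear_scaling(self):
        # empirical fallback with 5th percentile 0.005
        fit = ha.BetaFit(alpha=np.nan, beta=np.nan, ks_p=0.0, accepted=False)
        sample = np.full(100, 0.005)
        p, _ = ha.adjust_pvalue(1e-4, fit, sample)
        assert p == pytest.approx(1e-3, rel=1e-9)

    def test_monotone_and_capped(self):
        fit = ha.BetaFit(alpha=1.0, beta=1.0, ks_p=0.5, accepted=True)
        ps = [ha.adjust_pvalue(x, fit, np.array([]))[0]
              for x in (1e-8, 1e-4, 1e-2, 0.5, 1.0)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        assert ps[-1] <= 1.0

    def test_survives_tiny_min_p(self):
        fit = ha.BetaFit(alpha=0.5, beta=3.0, ks_p=0.5, accepted=True)
        p, logp = ha.adjust_pvalue(None, fit, np.array([]), log_min_p=-5000.0)
        assert p == 0.0  # underflow on the natural scale
        assert np.isfinite(logp) and logp < -4000

    def test_degenerate_threshold_warns_to_one(self, caplog):
        fit = ha.BetaFit(alpha=np.nan, beta=np.nan, ks_p=0.0, accepted=False)
        with caplog.at_level("WARNING"):
            p, logp = ha.adjust_pvalue(0.5, fit, np.zeros(50))
        assert p == 1.0 and logp == 0.0
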