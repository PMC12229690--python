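import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylopred as pp
from phylopred.pgls import DesignSpec, fit_gls, fit_ols, fit_pgls_ml_lambda
from phylopred.predict import (
    TargetSpec,
    loo_self_validation,
    predict_equation,
    predict_phylo_informed,
    target_from_tree,
)

from conftest import sim_with_retry


def table_from(labels, x, y):
    return pd.DataFrame({"x": x, "y": y}, index=pd.Index(labels, name="taxon"))


class TestEquationPrediction:
    def test_point_is_linear_combination(self):
        tab = table_from(list("ABCDE"), [0, 1, 2, 3, 4.0], [0, 1, 2, 3, 4.0])
        fit = fit_ols(tab, DesignSpec("y ~ x"))
        res = predict_equation(fit, TargetSpec("h", {"x": 5.0}), mode="ols")
        assert res.point == pytest.approx(5.0)
        assert res.epsilon_u == 0.0

    def test_ols_interval_matches_textbook_formula(self, rng):
        x = np.arange(5.0)
        y = np.array([0.1, 1.2, 1.9, 3.3, 3.8])
        tab = table_from(list("ABCDE"), x, y)
        fit = fit_ols(tab, DesignSpec("y ~ x"))
        xh = 2.5
        res = predict_equation(fit, TargetSpec("h", {"x": xh}), mode="ols", alpha=0.05)
        # independent closed-form evaluation
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / 3
        xr = np.array([1.0, xh])
        var = s2 * (1 + xr @ np.linalg.inv(X.T @ X) @ xr)
        tcrit = stats.t.ppf(0.975, 3)
        assert res.point == pytest.approx(xr @ beta)
        assert res.variance == pytest.approx(var)
        assert res.upper - res.lower == pytest.approx(2 * tcrit * np.sqrt(var))

    def test_pgls_generic_requires_gls_fit(self):
        tab = table_from(list("ABC"), [1.0, 2, 3], [1.0, 2, 4])
        fit = fit_ols(tab, DesignSpec("y ~ x"))
        with pytest.raises(ValueError):
            predict_equation(fit, TargetSpec("h", {"x": 1.0}), mode="pgls_generic")

    def test_placement_invariance(self, random_tree_factory, rng):
        """Equation predictions ignore the target's position; the informed
        prediction does not."""
        t = random_tree_factory(n_tips=12, seed=6)
        cov = pp.vcv(t)
        tab = pp.simulate_bm_traits(t, pp.TraitSimConfig(r=0.5), rng)
        hold = cov.taxon_order[0], cov.taxon_order[5]
        obs = tab.drop(index=list(hold))
        fit = fit_gls(obs, DesignSpec("y ~ x"), cov.restrict(list(obs.index)), lam=1.0)
        xv = {"x": 0.37}
        t1 = target_from_tree(cov, list(obs.index), hold[0], xv)
        t2 = target_from_tree(cov, list(obs.index), hold[1], xv)
        e1 = predict_equation(fit, t1, mode="pgls_generic")
        e2 = predict_equation(fit, t2, mode="pgls_generic")
        assert e1.point == pytest.approx(e2.point)
        p1 = predict_phylo_informed(fit, t1)
        p2 = predict_phylo_informed(fit, t2)
        assert p1.point != pytest.approx(p2.point, abs=1e-8)


class TestPhyloInformed:
    def test_root_attachment_collapses_to_equation(self, random_tree_factory, rng):
        t = random_tree_factory(n_tips=10, seed=3)
        cov = pp.vcv(t)
        tab = pp.simulate_bm_traits(t, pp.TraitSimConfig(r=0.5), rng)
        fit = fit_gls(tab, DesignSpec("y ~ x"), cov, lam=1.0)
        tgt = TargetSpec(
            "h", {"x": 1.0}, v_h=np.zeros(fit.n), v_hh=float(np.mean(np.diag(cov.V)))
        )
        informed = predict_phylo_informed(fit, tgt)
        generic = predict_equation(fit, tgt, mode="pgls_generic")
        assert informed.epsilon_u == pytest.approx(0.0, abs=1e-12)
        assert informed.point == pytest.approx(generic.point)
        assert informed.variance == pytest.approx(generic.variance)

    def test_matches_explicit_matrix_oracle(self):
        """Four known taxa with a hand-built covariance; every quantity is
        re-derived with explicit inverses."""
        labels = list("ABCD")
        V = np.array(
            [
                [1.0, 0.6, 0.2, 0.2],
                [0.6, 1.0, 0.2, 0.2],
                [0.2, 0.2, 1.0, 0.5],
                [0.2, 0.2, 0.5, 1.0],
            ]
        )
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.3, 0.9, 2.4, 2.7])
        tab = table_from(labels, x, y)
        cov = pp.CovarianceStructure(V, labels)
        fit = fit_gls(tab, DesignSpec("y ~ x"), cov, lam=1.0)
        v_h = np.array([0.55, 0.55, 0.2, 0.2])
        v_hh = 1.0
        tgt = TargetSpec("h", {"x": 1.5}, v_h=v_h, v_hh=v_hh)
        res = predict_phylo_informed(fit, tgt, alpha=0.05)

        Vi = np.linalg.inv(V)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        resid = y - X @ beta
        s2 = resid @ Vi @ resid / 2
        eps = v_h @ Vi @ resid
        xr = np.array([1.0, 1.5])
        d = xr - X.T @ Vi @ v_h
        var = s2 * (v_hh - v_h @ Vi @ v_h) + s2 * d @ np.linalg.inv(X.T @ Vi @ X) @ d
        tcrit = stats.t.ppf(0.975, 2)
        assert res.epsilon_u == pytest.approx(eps, abs=1e-8)
        assert res.point == pytest.approx(xr @ beta + eps, abs=1e-8)
        assert res.variance == pytest.approx(var, abs=1e-8)
        assert res.lower == pytest.approx(res.point - tcrit * np.sqrt(var), abs=1e-8)

    def test_random_instances_match_oracle(self, random_tree_factory, rng):
        for seed in range(8):
            n = int(rng.integers(6, 50))
            t = random_tree_factory(n_tips=n, seed=100 + seed, ext_rate=0.3)
            cov = pp.vcv(t)
            tab = pp.simulate_bm_traits(t, pp.TraitSimConfig(r=0.4), rng)
            hold = cov.taxon_order[int(rng.integers(n))]
            obs = tab.drop(index=[hold])
            sub = cov.restrict(list(obs.index))
            fit = fit_gls(obs, DesignSpec("y ~ x"), sub, lam=1.0)
            tgt = target_from_tree(cov, list(obs.index), hold, {"x": tab.loc[hold, "x"]})
            res = predict_phylo_informed(fit, tgt)
            Vi = np.linalg.inv(sub.V)
            y, X, _ = DesignSpec("y ~ x").matrices(obs.loc[sub.taxon_order])
            beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
            eps = tgt.v_h @ Vi @ (y - X @ beta)
            assert abs(res.epsilon_u - eps) < 1e-8

    def test_interval_shrinks_to_zero_with_branch_length(self):
        """Grafting the target ever closer to a sister tip drives the
        prediction-interval width to zero, and width is monotone
        non-decreasing in terminal branch length."""
        base = pp.read_newick("((A:12,B:12):8,(C:15,D:15):5);")
        tab = table_from(list("ABCD"), [0.1, 0.9, 2.2, 2.8], [0.0, 1.1, 2.0, 3.1])
        widths = []
        points = []
        for div_age in (8.0, 4.0, 2.0, 0.5, 0.05, 0.0005):
            t = pp.graft_tip(base, "A", divergence_age=div_age, tip_age=0.0, label="H")
            cov = pp.vcv(t)
            fit = fit_gls(tab, DesignSpec("y ~ x"), cov.restrict(list("ABCD")), lam=1.0)
            # the hypothetical species shares its sister's predictor value
            tgt = target_from_tree(cov, list("ABCD"), "H", {"x": 0.1})
            res = predict_phylo_informed(fit, tgt)
            widths.append(res.upper - res.lower)
            points.append(res.point)
        assert all(w2 <= w1 + 1e-12 for w1, w2 in zip(widths, widths[1:]))
        assert widths[-1] < 0.01 * widths[0]
        # and the prediction converges to the sister's observed value
        assert points[-1] == pytest.approx(tab.loc["A", "y"], abs=1e-3)

    def test_lambda_zero_equals_ols_point(self, random_tree_factory, rng):
        t = random_tree_factory(n_tips=12, seed=44)
        t = pp.standardize_height(t)
        cov = pp.vcv(t)
        tab = pp.simulate_bm_traits(t, pp.TraitSimConfig(r=0.5), rng)
        hold = cov.taxon_order[-1]
        obs = tab.drop(index=[hold])
        fit0 = fit_gls(obs, DesignSpec("y ~ x"), cov.restrict(list(obs.index)), lam=0.0)
        ols = fit_ols(obs, DesignSpec("y ~ x"))
        tgt = target_from_tree(cov, list(obs.index), hold, {"x": tab.loc[hold, "x"]})
        informed = predict_phylo_informed(fit0, tgt)
        eq = predict_equation(ols, tgt, mode="ols")
        assert informed.epsilon_u == pytest.approx(0.0, abs=1e-10)
        assert informed.point == pytest.approx(eq.point, abs=1e-8)


class TestLooSelfValidation:
    def test_collinear_data_zero_errors(self, random_tree_factory):
        t = random_tree_factory(n_tips=8, seed=1)
        cov = pp.vcv(t)
        x = np.linspace(0.0, 1.0, 8)
        tab = table_from(cov.taxon_order, x, 2.0 * x - 1.0)
        loo = loo_self_validation(tab, DesignSpec("y ~ x"), t)
        assert np.max(np.abs(loo["error"])) < 1e-8

    def test_matches_manual_per_taxon_recomputation(self, random_tree_factory, rng):
        t = random_tree_factory(n_tips=20, seed=13)
        t = pp.standardize_total_length(t)
        cov = pp.vcv(t)
        tab = pp.simulate_bm_traits(t, pp.TraitSimConfig(r=0.5), rng)
        loo = loo_self_validation(tab, DesignSpec("y ~ x"), cov)
        glob = fit_pgls_ml_lambda(tab, DesignSpec("y ~ x"), cov)
        lam = glob.lam
        Vfull = pp.transform_lambda(cov, lam)
        phylo = loo[loo["method"] == "phylo_informed"].set_index("taxon")
        for label in cov.taxon_order[:5]:
            others = [tx for tx in cov.taxon_order if tx != label]
            sub = Vfull.restrict(others)
            Vi = np.linalg.inv(sub.V)
            resid = glob.resid.loc[others].to_numpy()
            v_h, _ = Vfull.cross(label, others)  # off-diagonals already scaled
            eps = v_h @ Vi @ resid
            xr = np.array([1.0, tab.loc[label, "x"]])
            expected = xr @ glob.params.to_numpy() + eps
            assert phylo.loc[label, "predicted"] == pytest.approx(expected, abs=1e-8)

    def test_needs_enough_taxa(self, three_tip):
        tab = table_from(list("ABC"), [1.0, 2, 3], [1.0, 2, 4])
        with pytest.raises(ValueError):
            loo_self_validation(tab, DesignSpec("y ~ x"), three_tip)
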