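import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altifun import (
    DegenerateInputError,
    UsageError,
    anova_lsd,
    hellinger,
    plspm,
    rda,
    simulate_function_panel,
)
from altifun.synth import PATH_BLOCK_ORDER


class TestAnovaLsd:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.normal(size=12))
        g = pd.Series(["a"] * 6 + ["b"] * 6, index=v.index)
        res = anova_lsd(v, g)
        t, p = stats.ttest_ind(v[g == "a"], v[g == "b"])
        assert res.f_statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)

    def test_separated_group_gets_its_own_letter(self):
        v = pd.Series([1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 10.0, 10.1, 9.9])
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=v.index)
        res = anova_lsd(v, g)
        assert res.letters["a"] == res.letters["b"]
        assert res.letters["c"] not in (res.letters["a"], res.letters["b"])

    def test_letters_consistent_with_pairwise_tests(self):
        """Groups sharing a letter are never significantly different."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            k = int(rng.integers(3, 6))
            means = rng.normal(0, 2, k)
            v, g = [], []
            for i in range(k):
                v.extend(means[i] + rng.normal(0, 1, 5))
                g.extend([f"g{i}"] * 5)
            res = anova_lsd(pd.Series(v), pd.Series(g))
            for a in res.letters.index:
                for b in res.letters.index:
                    if a != b and set(res.letters[a]) & set(res.letters[b]):
                        assert res.pairwise_p.loc[a, b] > res.alpha
            # adjacent-in-mean non-significant pairs must share a letter
            order = list(res.group_means.sort_values(ascending=False).index)
            for a, b in zip(order, order[1:]):
                if res.pairwise_p.loc[a, b] > res.alpha:
                    assert set(res.letters[a]) & set(res.letters[b])

    def test_degenerate_and_invalid_inputs(self):
        v = pd.Series([1.0, 1.0, 2.0, 2.0])
        g = pd.Series(["a", "a", "b", "b"], index=v.index)
        with pytest.raises(DegenerateInputError):
            anova_lsd(v, g)
        with pytest.raises(UsageError):
            anova_lsd(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "a", "b"]))


class TestRda:
    def _xy(self, n=40, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x1", "x2", "x3"])
        beta = rng.normal(size=(3, 5))
        y = pd.DataFrame(
            x.to_numpy() @ beta + noise * rng.normal(size=(n, 5)),
            columns=[f"y{j}" for j in range(5)],
        )
        return y, x

    def test_perfect_constraint_explains_everything(self):
        y, x = self._xy(noise=0.0)
        assert rda(y, x).proportion_explained == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_predictors_explain_almost_nothing(self):
        rng = np.random.default_rng(2)
        n = 100
        y = pd.DataFrame(rng.normal(size=(n, 6)))
        x = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        assert rda(y, x).proportion_explained < 0.05

    def test_single_predictor_matches_regression_direction(self):
        rng = np.random.default_rng(3)
        n = 50
        x = pd.DataFrame({"x": rng.normal(size=n)})
        y = pd.DataFrame(
            np.outer(x["x"], [1.0, -2.0, 0.5]) + 0.1 * rng.normal(size=(n, 3))
        )
        res = rda(y, x)
        yc = y - y.mean()
        xc = (x - x.mean()) / x.std(ddof=1)
        beta = np.linalg.lstsq(xc, yc, rcond=None)[0].ravel()
        cos = np.abs(beta @ res.species_scores["RDA1"]) / (
            np.linalg.norm(beta) * np.linalg.norm(res.species_scores["RDA1"])
        )
        assert cos > 0.999

    def test_explained_proportion_monotone_in_predictors(self):
        y, x = self._xy(noise=1.0, seed=4)
        props = [
            rda(y, x[cols]).proportion_explained
            for cols in (["x1"], ["x1", "x2"], ["x1", "x2", "x3"])
        ]
        assert props[0] <= props[1] <= props[2]

    def test_collinear_columns_named(self):
        y, x = self._xy(noise=1.0, seed=5)
        x = x.copy()
        x["dup"] = 2 * x["x1"]
        with pytest.raises(UsageError, match="dup"):
            rda(y, x)

    def test_hellinger_rows_are_unit_sphere(self):
        rng = np.random.default_rng(6)
        rel = pd.DataFrame(rng.dirichlet(np.ones(5), size=8))
        h = hellinger(rel)
        np.testing.assert_allclose((h**2).sum(axis=1), 1.0, atol=1e-12)


class TestPlspm:
    def _chain(self, n=50):
        alt = np.linspace(-1, 1, n)
        data = pd.DataFrame({"A": alt, "B": alt.copy(), "C": alt.copy()})
        pm = pd.DataFrame(0, index=list("ABC"), columns=list("ABC"))
        pm.loc["B", "A"] = pm.loc["C", "B"] = 1
        return data, {"A": ["A"], "B": ["B"], "C": ["C"]}, pm

    def test_noiseless_chain_recovers_unit_paths(self):
        data, blocks, pm = self._chain()
        model = plspm(data, blocks, pm)
        assert model.paths.loc["B", "A"] == pytest.approx(1.0, abs=1e-6)
        assert model.paths.loc["C", "B"] == pytest.approx(1.0, abs=1e-6)
        assert model.gof == pytest.approx(1.0, abs=1e-6)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        _, truth = simulate_function_panel(n_plots_per_group=10, seed=7)
        data = truth.manifest_panel
        blocks = {b: [f"{b}_m"] for b in ("altitude", "pH", "EF-N")}
        blocks["altitude"] = ["altitude_m"]
        pm = pd.DataFrame(0, index=list(blocks), columns=list(blocks))
        pm.loc["pH", "altitude"] = pm.loc["EF-N", "pH"] = pm.loc["EF-N", "altitude"] = 1
        m1 = plspm(data, blocks, pm)
        m2 = plspm(data.sample(frac=1.0, random_state=1), blocks, pm)
        pd.testing.assert_frame_equal(m1.paths, m2.paths, atol=1e-9, rtol=0)

    def test_three_planted_paths_recovered(self):
        """Planted altitude→EF-N = 0.5, pH→EF-N = 0.4, fungi→EMF = −0.5 are
        each recovered within ±0.12 (mean over 10 seeds, n = 200)."""
        pm_true = pd.DataFrame(0.0, index=PATH_BLOCK_ORDER, columns=PATH_BLOCK_ORDER)
        pm_true.loc["pH", "altitude"] = -0.4  # so pH varies with the design
        pm_true.loc["EF-N", "altitude"] = 0.5
        pm_true.loc["EF-N", "pH"] = 0.4
        pm_true.loc["EMF", "fungi"] = -0.5
        names = ["altitude", "pH", "fungi", "EF-N", "EMF"]
        blocks = {b: [f"{b}_m"] for b in names}
        blocks["altitude"] = ["altitude_m"]
        inner = (pm_true.loc[names, names] != 0).astype(int)
        acc = []
        for seed in range(10):
            _, truth = simulate_function_panel(
                n_plots_per_group=50, true_paths=pm_true, seed=seed
            )
            model = plspm(truth.manifest_panel, blocks, inner)
            acc.append(model.paths.loc[names, names])
        est = sum(acc) / len(acc)
        for t, s in [("EF-N", "altitude"), ("EF-N", "pH"), ("EMF", "fungi")]:
            assert est.loc[t, s] == pytest.approx(pm_true.loc[t, s], abs=0.12)

    def test_path_signs_match_partial_correlations(self):
        _, truth = simulate_function_panel(n_plots_per_group=100, seed=11)
        data = truth.manifest_panel
        names = ["altitude", "pH", "EF-N"]
        blocks = {"altitude": ["altitude_m"], "pH": ["pH_m"], "EF-N": ["EF-N_m"]}
        pm = pd.DataFrame(0, index=names, columns=names)
        pm.loc["pH", "altitude"] = pm.loc["EF-N", "altitude"] = pm.loc["EF-N", "pH"] = 1
        model = plspm(data, blocks, pm)
        x = data[["altitude_m", "pH_m", "EF-N_m"]].to_numpy()
        prec = np.linalg.inv(np.corrcoef(x, rowvar=False))
        partial = -prec[0, 2] / np.sqrt(prec[0, 0] * prec[2, 2])
        assert np.sign(model.paths.loc["EF-N", "altitude"]) == np.sign(partial)

    def test_bootstrap_flags_strong_paths(self):
        data, blocks, pm = self._chain()
        rng = np.random.default_rng(8)
        noisy = data + 0.2 * rng.normal(size=data.shape)
        model = plspm(noisy, blocks, pm, n_bootstrap=199, seed=3)
        pt = model.path_table.set_index(["source", "target"])
        assert pt.loc[("A", "B"), "p"] < 0.001

    def test_cycle_rejected(self):
        data, blocks, pm = self._chain()
        pm.loc["A", "C"] = 1
        with pytest.raises(UsageError):
            plspm(data, blocks, pm)
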