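import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altifun import (
    DegenerateInputError,
    UsageError,
    aggregate_relative_abundance,
    alpha_diversity,
    anosim,
    anosim_r,
    bray_curtis,
    pcoa,
)
from altifun.community import _anosim_r_from_ranks

from conftest import make_otu_table


class TestRelativeAbundance:
    def test_printed_dominant_phyla_sum(self):
        """Group means for three dominant phyla at 22.38 / 25.69 / 28.26 %
        must total 76.33 % — the published mid-altitude value."""
        counts = [2238, 2569, 2826, 2367]  # out of 10,000 reads
        tab = make_otu_table(
            {"s1": counts, "s2": counts},
            {"s1": "HB2", "s2": "HB2"},
            taxonomy={"t1": "Acidobacteriota", "t2": "Proteobacteria",
                      "t3": "Actinobacteriota", "t4": "Other"},
        )
        means = aggregate_relative_abundance(tab, "phylum").group_means()["HB2"]
        dominant = means.loc[["Acidobacteriota", "Proteobacteria", "Actinobacteriota"]]
        assert 100 * dominant.sum() == pytest.approx(76.33, abs=1e-9)

    def test_single_taxon_is_all_ones(self):
        tab = make_otu_table({"s1": [7], "s2": [3]}, {"s1": "A", "s2": "A"})
        props = aggregate_relative_abundance(tab, "phylum").proportions
        assert (props.to_numpy() == 1.0).all()

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        tab = make_otu_table(
            {f"s{j}": rng.integers(0, 50, size=10).tolist() for j in range(4)},
            {f"s{j}": "A" for j in range(4)},
        )
        props = aggregate_relative_abundance(tab, "phylum").proportions
        np.testing.assert_allclose(props.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_sample_rejected(self):
        tab = make_otu_table({"s1": [1, 2], "s2": [0, 0]}, {"s1": "A", "s2": "A"})
        with pytest.raises(DegenerateInputError):
            aggregate_relative_abundance(tab, "phylum")


class TestAlphaDiversity:
    def test_uniform_community_closed_forms(self):
        tab = make_otu_table({"s1": [10, 10, 10, 10]}, {"s1": "A"})
        a = alpha_diversity(tab).loc["s1"]
        assert a["shannon"] == pytest.approx(math.log(4), abs=1e-12)
        assert a["simpson"] == pytest.approx(0.75, abs=1e-12)

    def test_chao1_equals_richness_without_singletons(self):
        tab = make_otu_table({"s1": [5, 3, 2, 2]}, {"s1": "A"})
        a = alpha_diversity(tab).loc["s1"]
        assert a["chao1"] == a["observed"] == 4

    def test_hand_computed_estimators(self):
        counts = np.array([5, 3, 1, 1])
        tab = make_otu_table({"s1": counts.tolist()}, {"s1": "A"})
        a = alpha_diversity(tab).loc["s1"]
        f1, f2 = 2, 0  # singletons, doubletons
        assert a["chao1"] == pytest.approx(4 + f1 * (f1 - 1) / (2 * (f2 + 1)))
        p = counts / counts.sum()
        assert a["shannon"] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
        assert a["simpson"] == pytest.approx(1 - (p**2).sum(), abs=1e-12)
        # ACE by direct evaluation of the standard formula (rare cutoff 10):
        # here every taxon is rare, so S_abund=0 and the formula is explicit
        s_rare, n_rare = 4, 10
        c_ace = 1 - f1 / n_rare
        top = s_rare / c_ace
        gamma = max(
            top * sum(i * (i - 1) * f for i, f in [(1, 2), (3, 1), (5, 1)])
            / (n_rare * (n_rare - 1)) - 1,
            0,
        )
        assert a["ace"] == pytest.approx(top + f1 / c_ace * gamma)

    def test_empty_taxon_changes_nothing(self):
        base = make_otu_table({"s1": [5, 3, 1, 1]}, {"s1": "A"})
        padded = make_otu_table({"s1": [5, 3, 1, 1, 0]}, {"s1": "A"})
        pd.testing.assert_series_equal(
            alpha_diversity(base).loc["s1"], alpha_diversity(padded).loc["s1"]
        )


class TestBrayCurtis:
    def test_identical_and_disjoint_pairs(self):
        tab = make_otu_table(
            {"a": [1, 2, 0, 0], "b": [1, 2, 0, 0], "c": [0, 0, 3, 4]},
            {"a": "A", "b": "A", "c": "A"},
        )
        d = bray_curtis(tab)
        assert d.loc["a", "b"] == 0
        assert d.loc["a", "c"] == 1

    def test_hand_computed_pair(self):
        tab = make_otu_table({"a": [1, 2, 3], "b": [2, 2, 0]}, {"a": "A", "b": "A"})
        assert bray_curtis(tab).loc["a", "b"] == pytest.approx(0.4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                    min_size=3, max_size=6))
    def test_symmetry_bounds_and_taxon_order_invariance(self, rows):
        cols = {f"s{j}": [max(r[j], 1) for r in rows] for j in range(4)}
        tab = make_otu_table(cols, {f"s{j}": "A" for j in range(4)})
        d = bray_curtis(tab).to_numpy()
        assert np.allclose(d, d.T) and (d >= 0).all() and (d <= 1).all()
        perm = np.random.default_rng(0).permutation(tab.counts.shape[0])
        shuffled = make_otu_table(
            {k: list(np.asarray(v)[perm]) for k, v in cols.items()},
            {f"s{j}": "A" for j in range(4)},
        )
        np.testing.assert_allclose(bray_curtis(shuffled).to_numpy(), d, atol=1e-12)


class TestPcoa:
    def test_points_on_a_line_are_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]),
                         index=list("abcd"), columns=list("abcd"))
        ord_ = pcoa(d)
        axis1 = ord_.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(axis1))
        np.testing.assert_allclose(np.sort(gaps), np.sort(np.diff(x)), atol=1e-8)

    def test_two_samples_single_axis(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
        ord_ = pcoa(d)
        assert ord_.coordinates.shape[1] == 1
        assert ord_.proportion_explained[0] == pytest.approx(1.0)

    def test_full_embedding_reproduces_euclidean_distances(self, toy_table):
        d = bray_curtis(toy_table)
        sq = np.sqrt(d)  # sqrt-Bray is Euclidean-embeddable
        ord_ = pcoa(sq)
        emb = ord_.coordinates.to_numpy()
        recon = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, sq.to_numpy(), atol=1e-8)

    def test_agrees_with_reference_implementation(self, toy_table):
        import skbio

        d = bray_curtis(toy_table)
        mine = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        pos = mine.eigenvalues[mine.eigenvalues > 1e-10]
        np.testing.assert_allclose(
            pos, theirs.eigvals.to_numpy()[: len(pos)], atol=1e-8
        )
        for k in range(mine.coordinates.shape[1]):
            a = mine.coordinates.iloc[:, k].to_numpy()
            b = theirs.samples.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(UsageError):
            pcoa(d)


class TestAnosim:
    def _random_distance(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_perfect_separation_gives_r_one(self):
        ids = list("abcdef")
        d = np.full((6, 6), 0.9)
        d[:3, :3] = d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0)
        dm = pd.DataFrame(d, index=ids, columns=ids)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        assert anosim_r(dm, groups) == pytest.approx(1.0)

    def test_statistic_matches_exhaustive_enumeration(self):
        """R and its permutation p-value agree with brute force over all
        6! relabelings of a 6-sample distance matrix."""
        dm = self._random_distance(6, seed=3)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=dm.index)
        r_obs = anosim_r(dm, groups)
        from scipy.stats import rankdata

        a = dm.to_numpy()
        iu = np.triu_indices(6, 1)
        ranks = rankdata(a[iu])
        g = groups.to_numpy()
        r_brute = []
        for perm in itertools.permutations(range(6)):
            gp = g[list(perm)]
            within = gp[iu[0]] == gp[iu[1]]
            r_brute.append(_anosim_r_from_ranks(ranks, within))
        r_brute = np.array(r_brute)
        assert r_obs == pytest.approx(r_brute[0])  # identity permutation
        p_exact = (r_brute >= r_obs - 1e-12).mean()
        res = anosim(dm, groups, n_permutations=999, seed=1)
        assert res["R"] == pytest.approx(r_obs)
        assert abs(res["p"] - p_exact) < 0.08

    def test_agrees_with_reference_implementation(self):
        import skbio

        dm = self._random_distance(9, seed=8)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=dm.index)
        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            grouping=groups.to_numpy(), permutations=0,
        )
        assert anosim_r(dm, groups) == pytest.approx(theirs["test statistic"])

    def test_seeded_reproducibility_and_bounds(self):
        dm = self._random_distance(8, seed=5)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.index)
        r1 = anosim(dm, groups, n_permutations=199, seed=7)
        r2 = anosim(dm, groups, n_permutations=199, seed=7)
        assert r1 == r2
        assert -1 <= r1["R"] <= 1 and 0 < r1["p"] <= 1

    def test_singleton_group_rejected(self):
        dm = self._random_distance(5, seed=0)
        groups = pd.Series(["a"] * 4 + ["b"], index=dm.index)
        with pytest.raises(UsageError):
            anosim(dm, groups, n_permutations=99, seed=0)
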