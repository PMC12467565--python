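import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import skbio

from altifun import (
    UsageError,
    beta_mntd,
    beta_nti,
    partition_processes,
    raup_crick_bray,
    simulate_communities,
    simulate_tree,
    write_newick,
)
from altifun.assembly import PROCESSES

from conftest import make_otu_table


def tree_from(newick: str) -> skbio.TreeNode:
    return skbio.TreeNode.read([newick], format="newick")


TOY_TREE = "(t1:1,(t2:1,t3:1):1);"  # d(t1,t2) = 3


class TestBetaMntd:
    def test_identical_samples_give_zero(self):
        tab = make_otu_table({"a": [3, 2, 1], "b": [3, 2, 1]}, {"a": "A", "b": "A"})
        d = beta_mntd(tab, tree_from(TOY_TREE))
        assert d.loc["a", "b"] == 0

    def test_hand_computed_toy_pair(self):
        # sample a holds only t1, sample b only t2: both directions see the
        # 3-unit path between them, so the weighted mean is exactly 3
        tab = make_otu_table({"a": [5, 0, 0], "b": [0, 7, 0]}, {"a": "A", "b": "A"})
        d = beta_mntd(tab, tree_from(TOY_TREE))
        assert d.loc["a", "b"] == pytest.approx(3.0)

    def test_taxon_order_invariance(self):
        tree = simulate_tree(12, seed=0)
        tab, _ = simulate_communities(tree, "drift", n_samples=3, depth=1000, seed=1)
        d1 = beta_mntd(tab, tree)
        perm = np.random.default_rng(0).permutation(len(tab.taxon_ids))
        from altifun.io import OtuTable

        shuffled = OtuTable(
            tab.counts.iloc[perm], tab.taxonomy.iloc[perm], tab.metadata
        )
        pd.testing.assert_frame_equal(beta_mntd(shuffled, tree), d1)

    def test_missing_taxon_reported(self):
        tab = make_otu_table({"a": [1, 1, 1, 1], "b": [1, 1, 1, 1]}, {"a": "A", "b": "A"})
        with pytest.raises(UsageError, match="t4"):
            beta_mntd(tab, tree_from(TOY_TREE))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_picante_comdistnt(self, tmp_path):
        """Abundance-weighted betaMNTD equals picante::comdistnt."""
        tree = simulate_tree(20, seed=2)
        tab, _ = simulate_communities(tree, "drift", n_samples=4, depth=2000, seed=2)
        mine = beta_mntd(tab, tree, weighted=True)
        write_newick(tree, tmp_path / "tree.nwk")
        tab.counts.T.to_csv(tmp_path / "comm.csv")
        script = tmp_path / "s.R"
        script.write_text(
            f"""suppressMessages(library(picante))
comm <- as.matrix(read.csv("{tmp_path}/comm.csv", row.names=1, check.names=FALSE))
tree <- read.tree("{tmp_path}/tree.nwk")
res <- comdistnt(comm, cophenetic(tree), abundance.weighted=TRUE)
write.csv(as.matrix(res), "{tmp_path}/out.csv")
"""
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.csv", index_col=0)
        np.testing.assert_allclose(
            mine.to_numpy(), theirs.loc[mine.index, mine.columns].to_numpy(), atol=1e-10
        )


class TestBetaNti:
    def test_star_tree_is_flagged_undefined(self):
        star = tree_from("(t1:1,t2:1,t3:1,t4:1);")
        tab = make_otu_table({"a": [9, 1, 0, 0], "b": [0, 0, 5, 5]}, {"a": "A", "b": "A"})
        b = beta_nti(tab, star, n_nulls=99, seed=0)
        assert np.isnan(b.loc["a", "b"])

    def test_drift_communities_are_calibrated(self):
        """Neutral communities must rarely exceed |betaNTI| > 2 (the
        null-model false-positive rate stays at or below 10%)."""
        tree = simulate_tree(64, seed=1)
        iu = np.triu_indices(5, 1)
        vals = []
        for seed in range(10):
            tab, _ = simulate_communities(tree, "drift", n_samples=5, depth=2000, seed=seed)
            vals.extend(beta_nti(tab, tree, n_nulls=99, seed=seed).to_numpy()[iu])
        vals = np.asarray(vals)
        assert np.nanmean(np.abs(vals) > 2) <= 0.10

    def test_heterogeneous_selection_is_detected(self):
        """Divergent environmental filtering of a conserved trait pushes
        betaNTI well above the +2 selection threshold."""
        tree = simulate_tree(64, seed=2)
        iu = np.triu_indices(4, 1)
        medians = []
        for seed in range(5):
            tab, _ = simulate_communities(
                tree, "heterogeneous_selection", n_samples=4, depth=2000,
                env_values=[-2, -2, 2, 2], seed=seed,
            )
            medians.append(np.median(beta_nti(tab, tree, n_nulls=99, seed=seed).to_numpy()[iu]))
        assert np.median(medians) > 2

    def test_branch_length_scale_invariance(self):
        """Scaling every branch length scales obs and null betaMNTD equally,
        so betaNTI itself is scale-free."""
        tree = simulate_tree(16, seed=3)
        tab, _ = simulate_communities(tree, "drift", n_samples=3, depth=1000, seed=3)
        b1 = beta_nti(tab, tree, n_nulls=99, seed=9)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 7.5
        b2 = beta_nti(tab, scaled, n_nulls=99, seed=9)
        pd.testing.assert_frame_equal(b1, b2)

    def test_determinism_under_fixed_seed(self):
        tree = simulate_tree(16, seed=4)
        tab, _ = simulate_communities(tree, "drift", n_samples=3, depth=1000, seed=4)
        pd.testing.assert_frame_equal(
            beta_nti(tab, tree, n_nulls=99, seed=5), beta_nti(tab, tree, n_nulls=99, seed=5)
        )

    def test_too_few_nulls_rejected(self):
        tree = simulate_tree(8, seed=0)
        tab, _ = simulate_communities(tree, "drift", n_samples=2, depth=1000, seed=0)
        with pytest.raises(UsageError):
            beta_nti(tab, tree, n_nulls=10, seed=0)


class TestRaupCrick:
    def test_bounds_and_identical_pair(self):
        tree = simulate_tree(32, seed=5)
        tab, _ = simulate_communities(tree, "drift", n_samples=4, depth=2000, seed=5)
        rc = raup_crick_bray(tab, n_nulls=99, seed=5)
        iu = np.triu_indices(4, 1)
        assert np.nanmax(np.abs(rc.to_numpy()[iu])) <= 1
        dup = make_otu_table(
            {"a": [5, 3, 2, 4, 6], "b": [5, 3, 2, 4, 6]}, {"a": "A", "b": "A"}
        )
        rc2 = raup_crick_bray(dup, n_nulls=199, seed=1)
        assert rc2.loc["a", "b"] <= -0.9  # obs Bray = 0 beats essentially every null

    def test_dispersal_limitation_is_detected(self):
        """Disjoint regional pools make observed turnover exceed the
        richness-preserving null, driving RC above +0.95."""
        tree = simulate_tree(64, seed=6)
        iu = np.triu_indices(4, 1)
        hits = []
        for seed in range(10):
            tab, _ = simulate_communities(
                tree, "dispersal_limitation", n_samples=4, depth=2000, seed=seed
            )
            rc = raup_crick_bray(tab, n_nulls=99, seed=seed).to_numpy()[iu]
            hits.append(np.mean(rc > 0.95))
        assert np.mean(hits) >= 0.5

    def test_sparse_sample_is_flagged(self):
        tab = make_otu_table({"a": [9, 0, 0], "b": [3, 3, 3]}, {"a": "A", "b": "A"})
        rc = raup_crick_bray(tab, n_nulls=99, seed=0)
        assert np.isnan(rc.loc["a", "b"])


class TestPartition:
    def _mats(self, bnti_val, rc_val, ids=("a", "b", "c")):
        n = len(ids)
        b = pd.DataFrame(bnti_val, index=list(ids), columns=list(ids), dtype=float)
        r = pd.DataFrame(rc_val, index=list(ids), columns=list(ids), dtype=float)
        np.fill_diagonal(b.values, 0)
        np.fill_diagonal(r.values, 0)
        return b, r

    def test_pure_heterogeneous_selection(self):
        b, r = self._mats(3.0, 0.0)
        groups = pd.Series({"a": "G", "b": "G", "c": "G"})
        res = partition_processes(b, r, groups)
        assert res.fractions.loc["G", "heterogeneous_selection"] == 1.0
        assert res.dominant.loc["G"] == "deterministic"

    def test_pure_drift(self):
        b, r = self._mats(0.0, 0.0)
        groups = pd.Series({"a": "G", "b": "G", "c": "G"})
        res = partition_processes(b, r, groups)
        assert res.fractions.loc["G", "drift_and_others"] == 1.0
        assert res.dominant.loc["G"] == "stochastic"

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(8)]
        b = rng.normal(0, 3, (8, 8))
        b = (b + b.T) / 2
        r = rng.uniform(-1, 1, (8, 8))
        r = (r + r.T) / 2
        bdf, rdf = self._mats(b, r, ids)
        groups = pd.Series(["G1"] * 4 + ["G2"] * 4, index=ids)
        res = partition_processes(bdf, rdf, groups)
        np.testing.assert_allclose(res.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert list(res.fractions.columns) == PROCESSES
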