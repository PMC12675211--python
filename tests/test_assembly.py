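import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from seepcomm import (
    CommunityTable,
    NullModelConfig,
    bmntd,
    bnti,
    classify_assembly,
    classify_pairs,
    mntd,
    nti,
    process_fractions,
    raup_crick_bray,
    simulate_tree,
)
from seepcomm.tree import patristic_matrix
from tests.conftest import random_table


# ---------------------------------------------------------------------------
# independent oracles

def mntd_bruteforce(counts, dist, weighted):
    """Nearest-neighbor search by explicit double loop."""
    present = [i for i, c in enumerate(counts) if c > 0]
    total = sum(counts[i] for i in present)
    value = 0.0
    for i in present:
        nearest = min(dist[i][j] for j in present if j != i)
        w = counts[i] / total if weighted else 1.0 / len(present)
        value += w * nearest
    return value


def bmntd_bruteforce(counts_j, counts_k, dist, weighted):
    """The half-sum-of-means definition evaluated by explicit double loops."""
    pj = [i for i, c in enumerate(counts_j) if c > 0]
    pk = [i for i, c in enumerate(counts_k) if c > 0]
    tj, tk = sum(counts_j[i] for i in pj), sum(counts_k[i] for i in pk)
    term1 = sum(
        (counts_j[i] / tj if weighted else 1.0 / len(pj))
        * min(dist[i][m] for m in pk)
        for i in pj
    )
    term2 = sum(
        (counts_k[m] / tk if weighted else 1.0 / len(pk))
        * min(dist[m][i] for i in pj)
        for m in pk
    )
    return 0.5 * (term1 + term2)


# ---------------------------------------------------------------------------
# MNTD / NTI

class TestMntd:
    def test_two_tips_single_nearest_pair(self, small_tree):
        dist, order = patristic_matrix(small_tree, ["A", "B", "C"])
        assert mntd([1, 1, 0], dist) == pytest.approx(2.0)

    def test_star_tree_all_present(self):
        star = TreeNode.read(["(A:1.5,B:1.5,C:1.5,D:1.5);"])
        dist, _ = patristic_matrix(star, ["A", "B", "C", "D"])
        assert mntd([1, 1, 1, 1], dist) == pytest.approx(3.0)

    @pytest.mark.parametrize("weighted", [False, True])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_trees(self, seed, weighted):
        tree = simulate_tree(8, seed=seed)
        dist, order = patristic_matrix(tree)
        rng = np.random.default_rng(seed)
        counts = np.zeros(8)
        present = rng.choice(8, size=5, replace=False)
        counts[present] = rng.integers(1, 9, size=5)
        assert mntd(counts, dist, weighted) == pytest.approx(
            mntd_bruteforce(counts, dist, weighted), abs=1e-12
        )

    def test_single_present_taxon_errors(self, small_tree):
        dist, _ = patristic_matrix(small_tree, ["A", "B", "C"])
        with pytest.raises(ValueError):
            mntd([3, 0, 0], dist)


class TestNti:
    def test_star_tree_null_is_degenerate(self, caplog):
        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        df = pd.DataFrame({"s1": [1, 1, 1, 0], "s2": [0, 1, 1, 1]},
                          index=["A", "B", "C", "D"])
        with caplog.at_level("WARNING", logger="seepcomm.assembly"):
            out = nti(CommunityTable(df), star, NullModelConfig(n_null=99, seed=0))
        assert out.isna().all()
        assert "zero null sd" in caplog.text

    def test_random_tip_subsets_center_near_zero(self):
        """NTI over random communities on a random tree is a calibrated
        z-score: mean near 0 over many samples."""
        tree = simulate_tree(30, seed=1)
        rng = np.random.default_rng(2)
        cols = {}
        for j in range(40):
            c = np.zeros(30, dtype=int)
            pres = rng.choice(30, size=10, replace=False)
            c[pres] = rng.integers(1, 20, size=10)
            cols[f"s{j}"] = c
        table = CommunityTable(
            pd.DataFrame(cols, index=[t.name for t in tree.tips()])
        )
        out = nti(table, tree, NullModelConfig(n_null=199, seed=3))
        assert abs(out.mean()) < 0.5

    def test_tight_clade_sample_is_clustered(self):
        """All abundance inside one shallow clade on a deep tree gives a
        clearly positive NTI (phylogenetic clustering)."""
        newick = "((A:0.05,B:0.05,C:0.05,D:0.05):3.0,(E:1,F:1,(G:0.5,H:0.5):1):1);"
        tree = TreeNode.read([newick])
        order = [t.name for t in tree.tips()]
        counts = [5 if n in "ABCD" else 0 for n in order]
        df = pd.DataFrame({"s1": counts, "s2": [1] * 8}, index=order)
        out = nti(CommunityTable(df), tree, NullModelConfig(n_null=199, seed=4))
        assert out["s1"] > 1.0


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI

class TestBmntd:
    def test_identical_samples_are_zero(self, small_tree):
        df = pd.DataFrame({"s1": [2, 1, 1], "s2": [2, 1, 1]}, index=["A", "B", "C"])
        out = bmntd(CommunityTable(df), small_tree)
        assert out["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_sister_clades_give_stem_path(self, paired_clade_tree):
        df = pd.DataFrame({"s1": [1, 1, 0, 0], "s2": [0, 0, 1, 1]},
                          index=["A", "B", "C", "D"])
        out = bmntd(CommunityTable(df), paired_clade_tree)
        # every nearest cross-clade path is 0.1 + 1 + 1 + 0.1
        assert out["s1", "s2"] == pytest.approx(2.2)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_bruteforce_oracle(self, weighted):
        rng = np.random.default_rng(10)
        for rep in range(10):
            tree = simulate_tree(int(rng.integers(4, 11)), seed=rep)
            n = len(list(tree.tips()))
            table = random_table(rng, n_taxa=n, n_samples=int(rng.integers(2, 7)))
            dist, order = patristic_matrix(tree, table.taxon_ids)
            counts = table.data.loc[order].to_numpy()
            out = bmntd(table, tree, abundance_weighted=weighted)
            for j in range(table.n_samples - 1):
                for k in range(j + 1, table.n_samples):
                    expected = bmntd_bruteforce(counts[:, j], counts[:, k], dist, weighted)
                    assert out.data[j, k] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_picante_comdistnt(self, tmp_path):
        """Independent cross-check against the R implementation this chain
        mirrors. Abundance-weighted mode matches exactly; presence mode is
        compared on equal-richness samples, where the averaging conventions
        coincide."""
        tree = simulate_tree(8, seed=3)
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 5, size=(8, 3))  # equal richness: all present
        names = sorted(t.name for t in tree.tips())
        df = pd.DataFrame(counts, index=names, columns=["s1", "s2", "s3"])
        table = CommunityTable(df)
        tree.write(str(tmp_path / "t.nwk"))
        df.T.to_csv(tmp_path / "comm.csv")
        script = f"""
        suppressMessages(library(picante))
        tr <- read.tree("{tmp_path}/t.nwk")
        comm <- as.matrix(read.csv("{tmp_path}/comm.csv", row.names=1))
        d <- cophenetic(tr)
        w <- comdistnt(comm, d, abundance.weighted=TRUE)
        u <- comdistnt(comm, d, abundance.weighted=FALSE)
        cat(as.vector(w), as.vector(u), sep=",")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        )
        vals = np.array([float(x) for x in out.stdout.strip().split(",")])
        ref_w, ref_u = vals[:3], vals[3:]
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(
            bmntd(table, tree, abundance_weighted=True).data[iu], ref_w, atol=1e-9
        )
        np.testing.assert_allclose(
            bmntd(table, tree, abundance_weighted=False).data[iu], ref_u, atol=1e-9
        )


class TestBnti:
    def test_identical_samples_have_degenerate_null(self, small_tree, caplog):
        """Identical membership zeroes observed and every null betaMNTD
        (conspecifics contribute 0 under any tip relabelling), so the
        z-score is undefined and flagged."""
        df = pd.DataFrame({"s1": [2, 1, 1], "s2": [2, 1, 1]}, index=["A", "B", "C"])
        with caplog.at_level("WARNING", logger="seepcomm.assembly"):
            out = bnti(CommunityTable(df), small_tree, NullModelConfig(n_null=99, seed=0))
        assert np.isnan(out.loc["s1", "s2"])
        assert "zero null sd" in caplog.text

    def test_same_niche_segment_pair_is_strongly_negative(self):
        """Two dense samples of the same segment of a ladderized pool turn
        over among close relatives: observed turnover distances sit far
        below the taxa-shuffle null."""
        from seepcomm.synth import simulate_pool_tree

        tree = simulate_pool_tree(200, seed=5)
        names = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(6)
        cols = {}
        for s in ("s1", "s2"):
            c = np.zeros(200, dtype=int)
            segment = np.arange(50)  # first quarter of the ladder
            pres = segment[rng.random(50) < 0.55]
            c[pres] = rng.integers(1, 30, size=len(pres))
            cols[s] = c
        table = CommunityTable(pd.DataFrame(cols, index=names))
        out = bnti(table, tree, NullModelConfig(n_null=299, seed=7))
        assert out.loc["s1", "s2"] < -2

    def test_symmetry_and_nan_diagonal(self, small_dataset):
        table = small_dataset["table"]
        out = bnti(table, small_dataset["tree"], NullModelConfig(n_null=99, seed=1))
        assert np.isnan(np.diag(out.to_numpy())).all()
        off = out.to_numpy()
        np.testing.assert_allclose(off, off.T, equal_nan=True)


# ---------------------------------------------------------------------------
# Raup-Crick

class TestRaupCrick:
    def test_values_bounded(self, small_dataset):
        out = raup_crick_bray(small_dataset["table"], n_null=99, seed=0)
        vals = out.to_numpy()[np.triu_indices(len(out), 1)]
        assert ((vals >= -1) & (vals <= 1)).all()

    def test_identical_samples_read_as_homogenised(self):
        """Two identical samples from a diverse metacommunity are far more
        similar than richness/abundance-preserving null draws."""
        rng = np.random.default_rng(1)
        hits = 0
        for seed in range(10):
            base = rng.integers(1, 20, size=15)
            other = rng.integers(0, 20, size=(15, 4))
            df = pd.DataFrame(
                np.column_stack([base, base, other]),
                index=[f"T{i}" for i in range(15)],
                columns=[f"s{j}" for j in range(6)],
            )
            df.iloc[0] = np.maximum(df.iloc[0], 1)
            df.iloc[1] = np.maximum(df.iloc[1], 1)
            out = raup_crick_bray(
                CommunityTable(df), n_null=99, seed=seed, pairs=[("s0", "s1")]
            )
            hits += out.loc["s0", "s1"] <= -0.9
        assert hits >= 9

    def test_observed_below_every_null_is_exactly_minus_one(self):
        rng = np.random.default_rng(2)
        base = rng.integers(5, 20, size=12)
        noise = rng.integers(0, 15, size=(12, 3))
        df = pd.DataFrame(
            np.column_stack([base, base, noise]),
            index=[f"T{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(5)],
        )
        df.iloc[2] = np.maximum(df.iloc[2], 1)
        out = raup_crick_bray(CommunityTable(df), n_null=199, seed=3,
                              pairs=[("s0", "s1")])
        # identical samples: BC_obs = 0, below every non-degenerate null
        assert out.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_non_integer_counts_rejected(self):
        df = pd.DataFrame({"s1": [0.5, 1.2], "s2": [1.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="integer"):
            raup_crick_bray(CommunityTable(df), n_null=99, seed=0)


# ---------------------------------------------------------------------------
# classification

def _expected_process(z, rc):
    if z > 2:
        return "heterogeneous_selection"
    if z < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


class TestClassification:
    @pytest.mark.parametrize("z", [-3.0, -2.1, -2.0, 0.0, 2.0, 2.1, 3.0])
    @pytest.mark.parametrize("rc", [-1.0, -0.96, -0.95, 0.0, 0.95, 0.96, 1.0])
    def test_truth_table_with_boundary_fall_through(self, z, rc):
        assert classify_assembly(z, rc) == _expected_process(z, rc)

    @pytest.mark.parametrize(
        "z, rc, expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (-2.5, 0.99, "homogeneous_selection"),  # selection precedes RC
            (0.5, 0.99, "dispersal_limitation"),
            (0.5, -0.99, "homogenizing_dispersal"),
            (0.5, 0.2, "undominated"),
        ],
    )
    def test_quoted_examples(self, z, rc, expected):
        assert classify_assembly(z, rc) == expected

    def test_nan_inputs_are_unclassified(self):
        assert classify_assembly(float("nan"), 0.0) == "unclassified"
        assert classify_assembly(0.0, float("nan")) == "unclassified"


class TestProcessFractions:
    @staticmethod
    def _pair_table(processes, group="ROV1"):
        rows = []
        for i, proc in enumerate(processes):
            z = {"heterogeneous_selection": 3.0, "homogeneous_selection": -3.0}.get(proc, 0.0)
            rc = {"dispersal_limitation": 0.99, "homogenizing_dispersal": -0.99}.get(proc, 0.0)
            rows.append(
                {"sample_1": f"{group}_a{i}", "sample_2": f"{group}_b{i}",
                 "bnti": z, "rc_bray": rc, "process": proc}
            )
        table = pd.DataFrame(rows)
        group_of = pd.Series(
            group, index=pd.unique(table[["sample_1", "sample_2"]].to_numpy().ravel())
        )
        return table, group_of

    def test_seven_depth_site_arithmetic(self):
        processes = ["homogeneous_selection"] * 18 + ["undominated"] * 3
        table, group_of = self._pair_table(processes)
        out = process_fractions(table, group_of)
        hs = out.set_index("process").loc["homogeneous_selection"]
        assert hs["fraction"] == pytest.approx(18 / 21)
        assert hs["n_pairs"] == 21

    def test_counts_split_over_all_five_processes(self):
        from seepcomm import PROCESSES

        counts = {"heterogeneous_selection": 7, "homogeneous_selection": 5,
                  "dispersal_limitation": 7, "homogenizing_dispersal": 0,
                  "undominated": 2}
        processes = [p for p, k in counts.items() for _ in range(k)]
        table, group_of = self._pair_table(processes)
        out = process_fractions(table, group_of).set_index("process")
        for p in PROCESSES:
            assert out.loc[p, "fraction"] == pytest.approx(counts[p] / 21)
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_pair_spanning_groups_rejected(self):
        table, _ = self._pair_table(["undominated"])
        group_of = pd.Series({"ROV1_a0": "ROV1", "ROV1_b0": "ROV2"})
        with pytest.raises(ValueError, match="spans"):
            process_fractions(table, group_of)

    def test_classify_pairs_round_trip(self, small_dataset):
        table = small_dataset["table"]
        ids = table.sample_ids[:4]
        z = pd.DataFrame(0.0, index=ids, columns=ids)
        z.iloc[0, 1] = z.iloc[1, 0] = -2.5
        rc = pd.DataFrame(0.99, index=ids, columns=ids)
        pairs = [(ids[0], ids[1]), (ids[2], ids[3])]
        out = classify_pairs(z, rc, pairs)
        assert list(out["process"]) == ["homogeneous_selection", "dispersal_limitation"]
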