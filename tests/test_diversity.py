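import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_random_panel
from ssrpop import diversity
from ssrpop.errors import DataError, ParameterError
from ssrpop.io import SSRPanel


@pytest.fixture()
def hand_panel():
    """5 accessions x 3 loci (one 2-allele marker + one single locus)."""
    calls = np.array(
        [
            [1.0, 0.0, 1.0],
            [1.0, 1.0, np.nan],
            [0.0, 1.0, 1.0],
            [1.0, 0.0, 0.0],
            [np.nan, 0.0, 1.0],
        ]
    )
    return SSRPanel([f"a{i}" for i in range(5)], ["MA_100", "MA_120", "MB_100"], calls)


class TestFrequencies:
    def test_hand_counted(self, hand_panel):
        f = diversity.allele_frequencies(hand_panel)
        assert f.band_freq["MA_100"] == pytest.approx(3 / 4)  # 3 of 4 scored
        assert f.band_freq["MA_120"] == pytest.approx(2 / 5)
        assert f.band_freq["MB_100"] == pytest.approx(3 / 4)
        np.testing.assert_allclose(f.marker_freqs["MA"], [(3 / 4) / (3 / 4 + 2 / 5), (2 / 5) / (3 / 4 + 2 / 5)])

    def test_fixed_band(self):
        panel = SSRPanel(["a", "b"], ["M_1"], np.array([[1.0], [1.0]]))
        f = diversity.allele_frequencies(panel)
        assert f.band_freq["M_1"] == 1.0

    def test_all_missing_marker_excluded(self):
        panel = SSRPanel(["a", "b"], ["M_1", "N_1"], np.array([[np.nan, 1.0], [np.nan, 0.0]]))
        f = diversity.allele_frequencies(panel)
        assert f.excluded_markers == ["M"]


class TestMAFFilter:
    def test_zero_threshold_is_identity(self, hand_panel):
        assert diversity.maf_filter(hand_panel, 0.0).equals(hand_panel)

    def test_idempotent_and_matches_bruteforce(self, rng):
        panel = make_random_panel(rng, n=30, n_markers=10)
        out = diversity.maf_filter(panel, 0.1)
        freqs = diversity.allele_frequencies(panel).band_freq
        expect = [l for l in panel.locus_ids if freqs[l] >= 0.1]
        assert out.locus_ids == expect
        assert diversity.maf_filter(out, 0.1).equals(out)

    @pytest.mark.parametrize("thr", [-0.1, 0.5, 0.7])
    def test_threshold_domain(self, hand_panel, thr):
        with pytest.raises(ParameterError):
            diversity.maf_filter(hand_panel, thr)


class TestPICAndH:
    def test_closed_forms(self):
        panel = SSRPanel(["a", "b", "c", "d"], ["M_1", "M_2"],
                         np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float))
        f = diversity.allele_frequencies(panel)
        pic_s, _ = diversity.pic(f)
        h_s, _ = diversity.gene_diversity(f)
        assert pic_s["M"] == pytest.approx(0.375)  # 1 - 0.5 - 0.125
        assert h_s["M"] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        panel = SSRPanel(["a", "b"], ["M_1"], np.array([[1.0], [1.0]]))
        f = diversity.allele_frequencies(panel)
        assert diversity.pic(f)[0]["M"] == 0.0
        assert diversity.gene_diversity(f)[0]["M"] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_h_dominates_pic(self, seed):
        """0 <= PIC <= H <= 1 - 1/k for every marker on random panels."""
        panel = make_random_panel(np.random.default_rng(seed), n=12, n_markers=6)
        f = diversity.allele_frequencies(panel)
        pic_s, _ = diversity.pic(f)
        h_s, _ = diversity.gene_diversity(f)
        for m in f.marker_freqs:
            k = len(f.marker_freqs[m])
            assert -1e-12 <= pic_s[m] <= h_s[m] + 1e-12
            assert h_s[m] <= 1 - 1 / k + 1e-12


class TestAlleleSummary:
    def test_brute_force_partition(self, rng):
        panel = make_random_panel(rng, n=10, n_markers=12)
        df = diversity.allele_summary(panel)
        from ssrpop.io import split_locus_id

        counts = {}
        for l in panel.locus_ids:
            m = split_locus_id(l)[0]
            counts[m] = counts.get(m, 0) + 1
        assert df.attrs["total_markers"] == len(counts)
        assert df.attrs["total_alleles"] == panel.n_loci
        assert (df["n_alleles"] == df["allele_count"] * df["n_markers"]).all()


class TestDistances:
    def test_identical_and_complementary(self):
        calls = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=float)
        d = diversity.distance_matrix(SSRPanel(["a", "b", "c"], ["L_1", "L_2", "L_3", "L_4"], calls))
        assert d.matrix[0, 1] == 0.0
        assert d.matrix[0, 2] == 1.0

    def test_matches_bruteforce(self, rng):
        panel = make_random_panel(rng, n=6, n_markers=3)
        d = diversity.distance_matrix(panel).matrix
        X = panel.calls
        for i, j in itertools.combinations(range(panel.n_accessions), 2):
            m = ~np.isnan(X[i]) & ~np.isnan(X[j])
            expect = np.mean(X[i, m] != X[j, m])
            assert d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_reorder_invariance(self, rng):
        panel = make_random_panel(rng, n=6, n_markers=3, missing_rate=0)
        d1 = diversity.distance_matrix(panel)
        order = ["acc3", "acc1", "acc6", "acc2", "acc5", "acc4"]
        d2 = diversity.distance_matrix(panel.select_accessions(order))
        for a, b in itertools.combinations(order, 2):
            i1, j1 = d1.ids.index(a), d1.ids.index(b)
            i2, j2 = d2.ids.index(a), d2.ids.index(b)
            assert d1.matrix[i1, j1] == pytest.approx(d2.matrix[i2, j2])

    def test_no_shared_loci_error(self):
        calls = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(DataError, match="share no scored loci"):
            diversity.distance_matrix(SSRPanel(["a", "b"], ["L_1", "L_2"], calls))


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return diversity.DistanceMatrix([f"t{i}" for i in range(n)], d)


class TestUPGMA:
    def test_three_taxon_hand_example(self):
        dm = diversity.DistanceMatrix(["A", "B", "C"], np.array(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]))
        tree = diversity.upgma(dm)
        heights = diversity.tree_tip_heights(tree)
        assert all(h == pytest.approx(0.3) for h in heights.values())
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}
        assert ab.find("A").length == pytest.approx(0.1)

    def test_ultrametric_on_random_matrices(self, rng):
        for n in (3, 5, 6):
            tree = diversity.upgma(random_distance_matrix(rng, n))
            assert diversity.is_ultrametric(tree, tol=1e-9)

    def test_matches_scipy_average_linkage(self, rng):
        """Cophenetic distances agree with scipy's average-linkage oracle."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        for n in (4, 5, 6):
            dm = random_distance_matrix(rng, n)
            tree = diversity.upgma(dm)
            Z = linkage(squareform(dm.matrix, checks=False), method="average")
            expect = squareform(cophenet(Z))
            for i, j in itertools.combinations(range(n), 2):
                got = tree.find(f"t{i}").distance(tree.find(f"t{j}"))
                assert got == pytest.approx(expect[i, j], abs=1e-9)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = diversity.DistanceMatrix(list("ABCD"), d)
        tree = diversity.neighbor_joining(dm)
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(d[i, j], abs=1e-9)

    def test_matches_skbio_oracle_on_additive_matrices(self, rng):
        import skbio

        for trial in range(3):
            # build an additive matrix from a random ultrametric-ish tree
            n = 6
            dm = random_distance_matrix(rng, n)
            base = diversity.neighbor_joining(dm)
            dist_add = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                dist_add[i, j] = dist_add[j, i] = base.find(f"t{i}").distance(base.find(f"t{j}"))
            dm_add = diversity.DistanceMatrix([f"t{i}" for i in range(n)], dist_add)
            mine = diversity.neighbor_joining(dm_add)
            oracle = skbio.tree.nj(skbio.DistanceMatrix(dist_add, [f"t{i}" for i in range(n)]))
            for i, j in itertools.combinations(range(n), 2):
                a, b = f"t{i}", f"t{j}"
                assert mine.find(a).distance(mine.find(b)) == pytest.approx(
                    oracle.find(a).distance(oracle.find(b)), abs=1e-6
                )

    def test_negative_branch_clamped(self):
        d = np.array(
            [[0.0, 0.1, 0.4, 0.4], [0.1, 0.0, 0.45, 0.4], [0.4, 0.45, 0.0, 0.05], [0.4, 0.4, 0.05, 0.0]]
        )
        tree = diversity.neighbor_joining(diversity.DistanceMatrix(list("ABCD"), d))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


class TestClusterReport:
    def test_threshold_above_root_single_group(self, rng):
        dm = random_distance_matrix(rng, 5)
        tree = diversity.upgma(dm)
        rep = diversity.cluster_report(tree, dm, gd_thresholds=(1e6,))
        assert rep[0]["n_groups"] == 1

    def test_planted_partition_cut(self):
        # two clusters: within-distance 0.1, between 0.6
        n = 6
        d = np.full((n, n), 0.6)
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    d[i, j] = 0.0 if i == j else 0.1
        dm = diversity.DistanceMatrix([f"t{i}" for i in range(n)], d)
        tree = diversity.upgma(dm)
        rep = diversity.cluster_report(tree, dm, gd_thresholds=(0.5,))[0]
        assert rep["n_groups"] == 2
        assert rep["within_mean_gd"] == pytest.approx(0.1)
        assert rep["between_mean_gd"] == pytest.approx(0.6)

    def test_group_mean_equals_bruteforce(self, rng):
        dm = random_distance_matrix(rng, 6)
        tree = diversity.upgma(dm)
        rep = diversity.cluster_report(tree, dm, gd_thresholds=(np.median(dm.matrix),))[0]
        pos = {a: i for i, a in enumerate(dm.ids)}
        within = [
            dm.matrix[pos[a], pos[b]]
            for g in rep["groups"].values()
            for a, b in itertools.combinations(g, 2)
        ]
        if within:
            assert rep["within_mean_gd"] == pytest.approx(float(np.mean(within)))
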