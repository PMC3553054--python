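"""Distances, neighbor joining, bootstrap consensus, concordance statistics."""

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from gbskit.popgen import (
    ConcordanceTable,
    DistanceMatrix,
    GenotypeMatrix,
    RunSummaryStats,
    bootstrap_consensus,
    compare_runs,
    genotype_concordance,
    neighbor_joining,
    p_distance,
    pairwise_informative,
    _bipartitions,
)
from gbskit.variants import GenotypeCall, GenotypeCode, MISSING_CALL, VariantRecord


def make_matrix(rows: dict[str, str]) -> GenotypeMatrix:
    """Build a matrix from per-sample genotype strings.

    Characters: 'R' hom-ref(A), 'A' hom-alt(G), 'H' het(A/G), '.' missing.
    """
    samples = list(rows)
    n_sites = len(next(iter(rows.values())))
    records = []
    for k in range(n_sites):
        calls = {}
        for s in samples:
            ch = rows[s][k]
            if ch == ".":
                calls[s] = MISSING_CALL
            elif ch == "R":
                calls[s] = GenotypeCall(GenotypeCode.HOM_REF, ("A",), 5)
            elif ch == "A":
                calls[s] = GenotypeCall(GenotypeCode.HOM_ALT, ("G",), 5)
            else:
                calls[s] = GenotypeCall(GenotypeCode.HET, ("A", "G"), 5)
        records.append(VariantRecord("c", k, "A", ("G",), "SNP", calls))
    return GenotypeMatrix.from_records(records, samples)


class TestPairwiseInformative:
    def test_identical_rows_give_zero(self):
        m = make_matrix({"x": "RRAAR", "y": "RRAAR"})
        table = pairwise_informative(m)
        assert table.differing.iloc[0] == 0

    def test_counts_differing_non_missing_sites(self):
        m = make_matrix({"x": "RRRRRR", "y": "AARRRA"})
        assert pairwise_informative(m).differing.iloc[0] == 3

    def test_missing_sites_excluded(self):
        m = make_matrix({"x": "R.RA", "y": "AAR."})
        table = pairwise_informative(m)
        assert table.differing.iloc[0] == 1
        assert table.shared.iloc[0] == 2

    def test_relation_to_p_distance(self):
        m = make_matrix({"x": "RRAARAR.RA", "y": "RAARRA.RRA"})
        table = pairwise_informative(m)
        d = p_distance(m)
        # counting hets as differing sites, informative = shared x p exactly
        assert table.differing.iloc[0] == table.shared.iloc[0] * d.values[0, 1]


class TestPDistance:
    def test_four_in_ten(self):
        m = make_matrix({"x": "R" * 10, "y": "AAAA" + "R" * 6})
        assert p_distance(m).values[0, 1] == pytest.approx(0.4)

    def test_diagonal_zero_and_symmetric(self):
        m = make_matrix({"x": "RRAR", "y": "ARRA", "z": "RRRR"})
        d = p_distance(m)
        assert np.allclose(np.diag(d.values), 0)
        assert np.allclose(d.values, d.values.T)

    def test_het_counts_half_against_homozygote(self):
        m = make_matrix({"x": "H", "y": "R"})
        assert p_distance(m).values[0, 1] == pytest.approx(0.5)

    def test_no_shared_sites_is_error(self):
        m = make_matrix({"x": "R.", "y": ".R"})
        with pytest.raises(ValueError, match="share no"):
            p_distance(m)

    def test_brute_force_recount(self):
        rng = np.random.default_rng(4)
        chars = np.array(list("RAH."))
        rows = {f"s{i}": "".join(rng.choice(chars, size=80)) for i in range(4)}
        m = make_matrix(rows)
        d = p_distance(m)
        value = {"R": frozenset("A"), "A": frozenset("G"), "H": frozenset("AG")}
        for i, a in enumerate(rows):
            for j, b in enumerate(rows):
                if i >= j:
                    continue
                diffs = shared = 0.0
                for x, y in zip(rows[a], rows[b]):
                    if "." in (x, y):
                        continue
                    shared += 1
                    if x != y:
                        diffs += 0.5 if "H" in (x, y) else 1.0
                assert d.values[i, j] == pytest.approx(diffs / shared)


def tree_bipartitions(tree, taxa):
    return _bipartitions(tree, frozenset(taxa))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABC"), D))
        lengths = {t.name: t.length for t in tree.children}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    @staticmethod
    def _additive_four():
        # tree ((A:1,B:2):3,C:4,D:5) with internal edge 3
        return DistanceMatrix(
            list("ABCD"),
            np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float),
        )

    def test_additive_four_taxon_recovered_exactly(self):
        dm = self._additive_four()
        tree = neighbor_joining(dm)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        dm.values[i, j]
                    )

    def test_additive_six_taxon_recovered_exactly(self):
        # build distances from a known tree via its path metric
        import itertools

        edges = {
            ("A", "u"): 1.0,
            ("B", "u"): 1.5,
            ("u", "v"): 2.0,
            ("C", "v"): 0.5,
            ("v", "w"): 1.0,
            ("D", "w"): 2.5,
            ("w", "x"): 1.5,
            ("E", "x"): 3.0,
            ("F", "x"): 0.75,
        }
        import networkx as nx

        g = nx.Graph()
        for (a, b), w in edges.items():
            g.add_edge(a, b, weight=w)
        taxa = list("ABCDEF")
        D = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            D[i, j] = D[j, i] = nx.shortest_path_length(
                g, taxa[i], taxa[j], weight="weight"
            )
        tree = neighbor_joining(DistanceMatrix(taxa, D))
        for i, j in itertools.combinations(range(6), 2):
            assert tree.find(taxa[i]).distance(tree.find(taxa[j])) == pytest.approx(
                D[i, j]
            )

    def test_topology_agrees_with_skbio_oracle(self):
        rng = np.random.default_rng(8)
        # random additive-ish matrix: perturbed distances keep the topology
        dm = self._additive_four()
        ours = tree_bipartitions(neighbor_joining(dm), dm.labels)
        theirs_tree = skbio_nj(SkbioDM(dm.values, dm.labels))
        theirs = tree_bipartitions(theirs_tree, dm.labels)
        assert ours == theirs

    def test_label_permutation_gives_isomorphic_tree(self):
        dm = self._additive_four()
        perm = [2, 0, 3, 1]
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm2)
        assert tree_bipartitions(t1, dm.labels) == tree_bipartitions(t2, dm.labels)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 6
            pts = rng.random((n, 3))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(n)], D))
            for node in tree.traverse():
                if node.length is not None:
                    assert node.length >= 0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(list("AB"), np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(list("AB"), np.array([[0, -1], [-1, 0]], float))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(list("AB"), np.zeros((2, 2))))


class TestBootstrapConsensus:
    def test_duplicate_samples_get_full_support(self):
        rng = np.random.default_rng(9)
        rows = {}
        base = "".join(rng.choice(list("RA"), size=100))
        rows["dup1"] = base
        rows["dup2"] = base
        for i in range(3):
            rows[f"far{i}"] = "".join(rng.choice(list("RA"), size=100))
        m = make_matrix(rows)
        _, supports = bootstrap_consensus(m, B=60, seed=2)
        taxa = frozenset(rows)
        side = frozenset({"dup1", "dup2"})
        if min(taxa) in side:  # bipartitions are stored on the side
            side = taxa - side  # excluding the smallest taxon
        assert supports.get(side) == 1.0

    def test_single_replicate_equals_its_tree(self):
        rng = np.random.default_rng(10)
        rows = {f"s{i}": "".join(rng.choice(list("RA"), size=60)) for i in range(5)}
        m = make_matrix(rows)
        tree, supports = bootstrap_consensus(m, B=1, seed=5)
        # every retained bipartition has support 1.0 (it came from one tree)
        assert all(v == 1.0 for v in supports.values())

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        rows = {f"s{i}": "".join(rng.choice(list("RA"), size=50)) for i in range(5)}
        m = make_matrix(rows)
        _, s1 = bootstrap_consensus(m, B=40, seed=3)
        _, s2 = bootstrap_consensus(m, B=40, seed=3)
        assert s1 == s2

    def test_supports_majority_rule(self):
        rng = np.random.default_rng(12)
        rows = {f"s{i}": "".join(rng.choice(list("RA"), size=40)) for i in range(6)}
        m = make_matrix(rows)
        tree, supports = bootstrap_consensus(m, B=50, seed=8)
        assert all(0.5 < v <= 1.0 for v in supports.values())
        # consensus tree is serializable newick with support labels
        newick = str(tree)
        assert newick.endswith(";\n") or newick.endswith(";")


class TestConcordance:
    def test_published_set_a_counts(self):
        table = ConcordanceTable.from_counts((115, 3, 71), (0, 1, 2))
        assert table.percent_validated == 98.4

    def test_published_set_b_counts(self):
        table = ConcordanceTable.from_counts((111, 9, 67), (0, 5, 0))
        assert table.percent_validated == 97.4

    def test_identical_call_sets_are_fully_concordant(self):
        calls = {
            ("S1", 1): GenotypeCall(GenotypeCode.HOM_REF, ("A",), 5),
            ("S1", 2): GenotypeCall(GenotypeCode.HET, ("A", "G"), 5),
            ("S2", 1): GenotypeCall(GenotypeCode.HOM_ALT, ("G",), 5),
        }
        table = genotype_concordance(calls, dict(calls))
        assert table.percent_validated == 100.0
        assert table.concordant == {"AA": 1, "AB": 1, "BB": 1}

    def test_missing_pairs_excluded_and_strata(self):
        a = {
            ("S", 1): GenotypeCall(GenotypeCode.HOM_REF, ("A",), 5),
            ("S", 2): GenotypeCall(GenotypeCode.HET, ("A", "G"), 5),
            ("S", 3): MISSING_CALL,
        }
        b = {
            ("S", 1): GenotypeCall(GenotypeCode.HOM_ALT, ("G",), 5),
            ("S", 2): GenotypeCall(GenotypeCode.HET, ("A", "G"), 5),
            ("S", 3): GenotypeCall(GenotypeCode.HOM_REF, ("A",), 5),
        }
        table = genotype_concordance(a, b)
        assert table.discordant == {"AA": 1, "AB": 0, "BB": 0}
        assert table.concordant == {"AA": 0, "AB": 1, "BB": 0}

    def test_key_mismatch_is_error(self):
        a = {("S", 1): MISSING_CALL}
        b = {("S", 2): MISSING_CALL}
        with pytest.raises(ValueError, match="mismatched keys"):
            genotype_concordance(a, b)


class TestCompareRuns:
    def test_published_selective_gain(self):
        cmp = compare_runs(
            RunSummaryStats(6252, 11.7), RunSummaryStats(8652, 25.2)
        )
        assert cmp.snp_pct_change == 38.4
        assert cmp.depth_ratio > 2.0  # "more than doubling"

    def test_published_multiplex_doubling(self):
        cmp = compare_runs(RunSummaryStats(6252, 11.7), RunSummaryStats(6846, 16.0))
        assert cmp.snp_pct_change == 9.5
        assert round(cmp.depth_pct_change) == 37

    def test_identical_runs(self):
        cmp = compare_runs(RunSummaryStats(100, 5.0), RunSummaryStats(100, 5.0))
        assert cmp.snp_pct_change == 0.0 and cmp.depth_pct_change == 0.0

    def test_zero_baseline_is_error(self):
        with pytest.raises(ValueError):
            compare_runs(RunSummaryStats(0), RunSummaryStats(10))
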