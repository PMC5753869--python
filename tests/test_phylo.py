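"""Distances, neighbor joining, bootstrap, and topology classification."""

import io
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from drivescan.phylo import (
    CLASS_A,
    CLASS_B,
    CLASS_C,
    CLASS_U,
    JC69,
    WindowAlignment,
    aggregate_window_classes,
    bootstrap_supports,
    classify_window_topology,
    distance_matrix,
    jc69_distance,
    neighbor_joining_tree,
    outgroup_subspecies_tally,
    root_at_outgroup,
    tree_splits,
    window_alignment,
)


def aln_from_strings(seqs: dict[str, str], meta=None, interval=(0, None)):
    names = sorted(seqs)
    L = len(next(iter(seqs.values())))
    mat = np.array([[ord(seqs[n][i]) for n in names] for i in range(L)], dtype=np.uint8)
    variant = (mat != mat[:, [0]]).any(axis=1)
    return WindowAlignment(
        interval=(0, L),
        names=names,
        meta=meta or {},
        var_positions=np.nonzero(variant)[0],
        var_matrix=mat[variant],
        length=L,
    )


def read_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def random_additive_tree(rng, n):
    """Random bifurcating tree with positive branch lengths (the NJ oracle)."""
    nodes = [TreeNode(name=f"t{i}", length=round(rng.uniform(0.1, 2.0), 4)) for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], length=round(rng.uniform(0.1, 2.0), 4))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


class TestDistances:
    def test_identical_pair_distance_zero(self):
        aln = aln_from_strings({"a": "ACGT", "b": "ACGT", "c": "AGGT"})
        dm = distance_matrix(aln)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == pytest.approx(0.25)

    def test_jc69_closed_form(self):
        # p = 0.06 -> d = -0.75 ln(0.92)
        assert jc69_distance(0.06) == pytest.approx(-0.75 * math.log(0.92))
        assert jc69_distance(0.06) == pytest.approx(0.0625, abs=5e-4)

    def test_jc69_saturation_capped(self):
        assert jc69_distance(0.8) == 5.0
        assert jc69_distance(0.9, d_max=7.0) == 7.0

    def test_jc69_matrix_matches_scalar(self):
        aln = aln_from_strings({"a": "A" * 50, "b": "A" * 47 + "CCC", "c": "A" * 50})
        dm = distance_matrix(aln, model=JC69)
        assert dm["a", "b"] == pytest.approx(jc69_distance(3 / 50))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = neighbor_joining_tree(d)
        # three-point formulas: la = (dab+dac-dbc)/2 etc.
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_quartet_recovers_topology_and_lengths(self):
        # pendant edges 1, internal edge 1: d(A,B)=d(C,D)=2, cross distances 3
        d = DistanceMatrix(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
            ["A", "B", "C", "D"],
        )
        tree = neighbor_joining_tree(d)
        assert frozenset({"A", "B"}) in tree_splits(tree) or frozenset({"C", "D"}) in tree_splits(tree)
        for tip in tree.tips():
            assert tip.length == pytest.approx(1.0)
        dm_back = tree.tip_tip_distances()
        assert dm_back["A", "C"] == pytest.approx(3.0)

    def test_same_matrix_gives_identical_newick(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, list("abcdef"))
        assert str(neighbor_joining_tree(dm)) == str(neighbor_joining_tree(dm))

    def test_tip_order_permutation_does_not_change_output(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ids = list("fedcba")
        dm1 = DistanceMatrix(d, ids)
        perm = [3, 1, 5, 0, 4, 2]
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        assert str(neighbor_joining_tree(dm1)) == str(neighbor_joining_tree(dm2))

    def test_asymmetric_matrix_is_an_error(self):
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 3], [2, 3, 0]], list("abc"))
        dm.data[0, 1] = 5.0
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining_tree(dm)

    def test_random_additive_matrices_recover_generating_topology(self):
        """Four-point-condition oracle: NJ is exact on additive distances."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            true = random_additive_tree(rng, n)
            dm = true.tip_tip_distances()
            est = neighbor_joining_tree(dm)
            assert est.compare_rfd(true, rooted=False) == 0.0


class TestBootstrap:
    def _aln(self):
        block = {"a": "AAAA", "b": "AAAA", "c": "TTTT", "d": "TTTT"}
        return aln_from_strings({k: v * 10 for k, v in block.items()})

    def test_zero_replicates_returns_no_supports(self):
        aln = self._aln()
        tree = neighbor_joining_tree(distance_matrix(aln))
        assert bootstrap_supports(aln, tree, 0, seed=1) == {}

    def test_strong_signal_gets_high_support(self):
        aln = self._aln()
        tree = neighbor_joining_tree(distance_matrix(aln))
        supports = bootstrap_supports(aln, tree, 100, seed=1)
        assert supports and all(v >= 95.0 for v in supports.values())

    def test_fixed_seed_reproducible(self):
        aln = self._aln()
        tree = neighbor_joining_tree(distance_matrix(aln))
        assert bootstrap_supports(aln, tree, 50, seed=9) == bootstrap_supports(aln, tree, 50, seed=9)


META = {
    "OUT": ("spr", "outgroup", False),
    **{f"D{i}": ("dom", "noncarrier", False) for i in (1, 2)},
    **{f"M{i}": ("mus", "noncarrier", False) for i in (1, 2)},
    **{f"C{i}": ("cas", "noncarrier", False) for i in (1, 2)},
    **{f"tD{i}": ("dom", "carrier", True) for i in (1, 2)},
    **{f"tM{i}": ("mus", "carrier", True) for i in (1, 2)},
    **{f"tC{i}": ("cas", "carrier", True) for i in (1, 2)},
}
POPS = ["cas", "dom", "mus"]


def classify(newick, focal="dom"):
    tree = read_tree(newick)
    rooted = root_at_outgroup(tree, ["OUT"])
    return classify_window_topology(rooted, META, focal, ingroup_populations=POPS)


class TestClassifier:
    def test_drivers_outside_ingroup_clade_is_class_c(self):
        nwk = "(OUT,((tD1,tD2),((D1,D2),((M1,M2),(C1,C2)))));"
        assert classify(nwk) == CLASS_C

    def test_driver_inside_focal_subspecies_is_class_a(self):
        nwk = "(OUT,((D1,(D2,tD1)),((M1,M2),(C1,C2))));"
        assert classify(nwk) == CLASS_A

    def test_driver_inside_ingroup_but_outside_focal_is_class_b(self):
        nwk = "(OUT,((D1,D2),(tD1,((M1,M2),(C1,C2)))));"
        assert classify(nwk) == CLASS_B

    def test_classification_is_per_focal_subspecies(self):
        # dom driver recombined into dom; mus driver unrecombined
        nwk = "(OUT,((tM1,tM2),((D1,(D2,tD1)),((M1,M2),(C1,C2)))));"
        assert classify(nwk, "dom") == CLASS_A
        assert classify(nwk, "mus") == CLASS_C

    def test_missing_focal_driver_tips_is_unclassifiable(self):
        nwk = "(OUT,((D1,D2),((M1,M2),(C1,C2))));"
        assert classify(nwk, "dom") == CLASS_U

    def test_single_focal_noncarrier_is_unclassifiable(self):
        nwk = "(OUT,((D1,tD1),((M1,M2),(C1,C2))));"
        assert classify(nwk, "dom") == CLASS_U

    def test_missing_outgroup_is_an_error(self):
        tree = read_tree("((D1,tD1),((M1,M2),(C1,C2)));")
        with pytest.raises(ValueError, match="outgroup"):
            root_at_outgroup(tree, ["OUT"])


class TestTally:
    def test_mus_driver_outgroup_to_other_drivers(self):
        nwk = "(OUT,((tM1,tM2),((tD1,tD2),(tC1,tC2))));"
        rooted = root_at_outgroup(read_tree(nwk), ["OUT"])
        tally = outgroup_subspecies_tally([rooted], META, POPS, "driver")
        assert tally["mus"] == 1.0 and tally["none"] == 0.0

    def test_interleaved_drivers_score_none(self):
        nwk = "(OUT,((tM1,tD1),((tD2,tM2),(tC1,tC2))));"
        rooted = root_at_outgroup(read_tree(nwk), ["OUT"])
        tally = outgroup_subspecies_tally([rooted], META, POPS, "driver")
        assert tally["none"] == 1.0

    def test_fractions_over_windows(self):
        trees = []
        for nwk in (
            "(OUT,((tM1,tM2),((tD1,tD2),(tC1,tC2))));",
            "(OUT,((tM1,tM2),((tD1,tD2),(tC1,tC2))));",
            "(OUT,((tD1,tD2),((tM1,tM2),(tC1,tC2))));",
            "(OUT,((tM1,tD1),((tD2,tM2),(tC1,tC2))));",
        ):
            trees.append(root_at_outgroup(read_tree(nwk), ["OUT"]))
        tally = outgroup_subspecies_tally(trees, META, POPS, "driver")
        assert tally["mus"] == 0.5
        assert tally["dom"] == 0.25
        assert tally["none"] == 0.25


class TestAggregation:
    def test_segment_fractions_and_all_c_set(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "start": [0, 5000, 10_000, 15_000],
                "end": [5000, 10_000, 15_000, 20_000],
                "dom": ["C", "C", "A", "C"],
                "mus": ["C", "A", "C", "C"],
            }
        )
        summary = aggregate_window_classes(frame, ["dom", "mus"], segment_size=10_000)
        seg0_dom = summary.segment_fractions.query(
            "segment_start == 0 and population == 'dom'"
        ).iloc[0]
        assert seg0_dom["frac_C"] == 1.0
        # window C for dom but A for mus is excluded from the all-C set
        assert summary.all_c_windows == [(0, 5000), (15_000, 20_000)]

    def test_zero_all_c_windows(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"start": [0], "end": [5000], "dom": ["A"], "mus": ["C"]}
        )
        summary = aggregate_window_classes(frame, ["dom", "mus"], segment_size=10_000)
        assert summary.all_c_windows == []


class TestWindowAlignment:
    def test_invariant_window_flagged_unclassifiable(self, small_run):
        from drivescan.phylo import is_classifiable
        from drivescan.pseudot import ConsensusSet

        cs = ConsensusSet(
            "A" * 100, (0, 100),
            {"a": {}, "b": {}, "c": {}, "d": {}},
            {n: ("dom", "noncarrier", False) for n in "abcd"},
        )
        aln = window_alignment(cs, (0, 50))
        assert aln.n_variant_columns == 0
        assert not is_classifiable(aln)

    def test_window_straddling_interval_end_is_truncated_and_flagged(self, small_run):
        cs = small_run.consensus
        a, b = cs.interval
        aln = window_alignment(cs, (b - 2000, b + 3000))
        assert aln.interval == (b - 2000, b)
        assert aln.truncated

    def test_classification_invariant_under_tip_insertion_order(self, small_run):
        """Rooting invariance: permuting the consensus tip order leaves
        every window class unchanged (NJ sorts tips internally)."""
        from drivescan.phylo import classify_windows
        from drivescan.pseudot import ConsensusSet

        cs = small_run.consensus
        rng = np.random.default_rng(0)
        names = list(cs.subs)
        perm = [names[i] for i in rng.permutation(len(names))]
        shuffled = ConsensusSet.__new__(ConsensusSet)
        shuffled.interval = cs.interval
        shuffled.ref_seq = cs.ref_seq
        shuffled.subs = {n: cs.subs[n] for n in perm}
        shuffled.meta = cs.meta
        windows = small_run.cohort.truth.windows[:15]
        pops = list(small_run.config.populations)
        f1 = classify_windows(cs, windows, pops)
        f2 = classify_windows(shuffled, windows, pops)
        for p in pops:
            assert list(f1[p]) == list(f2[p])
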