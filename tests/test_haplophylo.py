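"""Tests for haplotype distances, counterpart classification, paralog
screening, NJ/bootstrap/midpoint trees and monophyly scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from clonescan.core import SegmentHaplotypes
from clonescan.haplophylo import (
    bootstrap_support,
    classify_grouping,
    closest_counterpart,
    hap_distance_matrix,
    midpoint_root,
    monophyly_scan,
    nj_tree,
    paralog_screen,
    read_newick,
    write_newick,
)


def make_segment(haps, individuals=None, positions=None):
    haps = np.asarray(haps, dtype=np.int8)
    n_ind = haps.shape[0] // 2
    individuals = individuals or [f"L{i + 1}" for i in range(n_ind)]
    positions = positions if positions is not None else np.arange(1, haps.shape[1] + 1)
    return SegmentHaplotypes(
        contig="c1", start=1, end=int(max(positions)) + 1,
        positions=positions, individuals=individuals, haplotypes=haps,
    )


class TestDistances:
    def test_matches_bruteforce_hamming(self):
        rng = np.random.default_rng(0)
        seg = make_segment(rng.integers(0, 4, size=(8, 20)))
        d = hap_distance_matrix(seg)
        labels = seg.labels()
        for i, j in itertools.combinations(range(8), 2):
            brute = sum(a != b for a, b in zip(seg.haplotypes[i], seg.haplotypes[j]))
            assert d.loc[labels[i], labels[j]] == brute
        assert (d.to_numpy().diagonal() == 0).all()
        assert np.array_equal(d.to_numpy(), d.to_numpy().T)

    def test_proportion_scale(self):
        h = np.zeros((4, 20), dtype=np.int8)
        h[1, :3] = 1
        seg = make_segment(h)
        d = hap_distance_matrix(seg)
        assert d.loc["L1.1", "L1.2"] == 3
        assert d.loc["L1.1", "L1.2"] / 20 == pytest.approx(0.15)


class TestCounterpart:
    def dist(self, values, labels):
        return pd.DataFrame(values, index=labels, columns=labels)

    def test_margin_boundaries(self):
        labels = ["A.1", "A.2", "B.1", "B.2", "C.1", "C.2"]
        m = np.full((6, 6), 50)
        np.fill_diagonal(m, 0)
        m[0, 2] = m[2, 0] = 1   # A.1 closest: B.1
        m[0, 3] = m[3, 0] = 4   # runner-up 4 -> margin 3 boundary
        res = closest_counterpart(self.dist(m, labels), "A.1")
        assert res.best == "B.1" and res.unambiguous
        m[0, 3] = m[3, 0] = 3
        res = closest_counterpart(self.dist(m, labels), "A.1")
        assert not res.unambiguous
        m[0, 3] = m[3, 0] = 1  # tie
        res = closest_counterpart(self.dist(m, labels), "A.1")
        assert res.d1 == res.d2 and not res.unambiguous

    def test_own_haplotypes_excluded(self):
        labels = ["A.1", "A.2", "B.1", "B.2", "C.1", "C.2"]
        m = np.full((6, 6), 50)
        np.fill_diagonal(m, 0)
        m[0, 1] = m[1, 0] = 1  # own haplotype closest, must be ignored
        m[0, 4] = m[4, 0] = 5
        res = closest_counterpart(self.dist(m, labels), "A.1")
        assert res.best == "C.1" and res.d1 == 5


def incongruent_segment():
    """A's haplotypes match B.1 and C.2 reciprocally with wide margins."""
    m = 30
    h = {}
    rng = np.random.default_rng(1)
    base = rng.integers(0, 2, m).astype(np.int8)
    far1 = (base + 1) % 2
    far2 = base.copy(); far2[::2] = 1 - far2[::2]
    h["A.1"] = base.copy()
    h["B.1"] = base.copy(); h["B.1"][0] = 1 - h["B.1"][0]      # d=1 to A.1
    h["A.2"] = far1.copy()
    h["C.2"] = far1.copy(); h["C.2"][1] = 1 - h["C.2"][1]      # d=1 to A.2
    h["B.2"] = far2.copy()
    h["C.1"] = far2.copy(); h["C.1"][2] = 1 - h["C.1"][2]
    rows = [h["A.1"], h["A.2"], h["B.1"], h["B.2"], h["C.1"], h["C.2"]]
    return make_segment(np.array(rows), individuals=["A", "B", "C"])


class TestClassifyGrouping:
    def test_incongruent_toy_with_bruteforce_rule_check(self):
        seg = incongruent_segment()
        status, pattern = classify_grouping(seg, "A")
        assert status == "incongruent" and pattern == frozenset({"B", "C"})
        # brute-force verification of every rule on the distance matrix
        d = hap_distance_matrix(seg)
        for focal, best in [("A.1", "B.1"), ("A.2", "C.2")]:
            others = [c for c in d.columns if not c.startswith("A")]
            vals = sorted(d.loc[focal, others])
            assert d.loc[focal, best] == vals[0] and vals[1] - vals[0] >= 3
            assert d.loc[focal, best] < d.loc["A.1", "A.2"]

    def test_identical_within_pair_undetermined(self):
        h = np.zeros((6, 20), dtype=np.int8)
        h[2:, :] = 1
        h[2, 5] = h[4, 6] = 0
        seg = make_segment(h, individuals=["A", "B", "C"])
        status, _ = classify_grouping(seg, "A")
        assert status == "undetermined"

    def test_congruent_pair(self):
        rng = np.random.default_rng(2)
        base1 = rng.integers(0, 2, 30).astype(np.int8)
        base2 = (base1 + 1) % 2
        mid = base1.copy(); mid[:15] = base2[:15]
        rows = []
        # A and B share both haplotype lineages; C is distant from both
        for delta, src in [((0,), base1), ((1,), base2)]:
            a = src.copy(); rows.append(a)
        b1 = base1.copy(); b1[0] ^= 1
        b2 = base2.copy(); b2[1] ^= 1
        rows += [b1, b2, mid, (mid + 1) % 2]
        seg = make_segment(np.array(rows), individuals=["A", "B", "C"])
        status, pattern = classify_grouping(seg, "A")
        assert status == "congruent" and pattern == frozenset({"B"})

    def test_clonal_simulation_never_incongruent(self):
        from clonescan.simpop import SimConfig, run_simulation

        cfg = SimConfig(pop_size=40, genome_length=4000, mutation_rate=4e-5,
                        crossover_rate=0.0, cloning_rate=1.0, n_generations=400,
                        sample_size=5, seed=17, n_contigs=4)
        ss = run_simulation(cfg)
        for seg in ss.to_segments():
            if seg.n_snps < 5:
                continue
            for ind in seg.individuals:
                status, _ = classify_grouping(seg, ind)
                assert status != "incongruent"


class TestParalogScreen:
    def frame(self, n_contigs=2, n_high=2, n_low=2):
        rows = []
        for k in range(n_high):
            rows.append({"haplotype": "h1", "contig": f"t{k % n_contigs}", "identity": 0.95})
        for k in range(n_low):
            rows.append({"haplotype": "h1", "contig": f"t{(k + n_high) % max(n_contigs,1)}",
                         "identity": 0.70})
        return pd.DataFrame(rows)

    def test_examples(self):
        # 11 distinct hit contigs -> drop
        many = pd.DataFrame(
            {"haplotype": "h1", "contig": [f"t{i}" for i in range(11)], "identity": 0.7}
        )
        assert not paralog_screen(many)
        ten = many.iloc[:10]
        assert paralog_screen(ten)
        # 2 high + 8 low -> keep; 3 high -> drop
        keep = pd.DataFrame(
            {"haplotype": "h1", "contig": [f"t{i}" for i in range(10)],
             "identity": [0.95, 0.92] + [0.7] * 8}
        )
        assert paralog_screen(keep)
        drop = pd.DataFrame(
            {"haplotype": "h1", "contig": ["t1", "t2", "t3"], "identity": 0.93}
        )
        assert not paralog_screen(drop)

    def test_empty_hits_kept(self):
        assert paralog_screen(pd.DataFrame(columns=["haplotype", "contig", "identity"]))


def brute_force_min_evolution(dist: pd.DataFrame):
    """Least-squares/minimum-evolution topology over all unrooted 4- or
    5-leaf topologies, via exhaustive branch-length least squares."""
    labels = list(dist.index)
    n = len(labels)
    best = (None, np.inf)
    for topo in _unrooted_topologies(labels):
        length, sse = _fit_lengths(topo, dist)
        if sse < best[1] - 1e-9:
            best = (topo, sse)
    return best[0]


def _unrooted_topologies(labels):
    if len(labels) == 4:
        a, b, c, d = labels
        yield from [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    else:
        raise NotImplementedError


def _fit_lengths(topo, dist):
    # quartet ((a,b),(c,d)): path matrix over 5 edges
    (a, b), (c, d) = topo
    pairs = list(itertools.combinations([a, b, c, d], 2))
    edges = [a, b, c, d, "int"]
    x = np.zeros((len(pairs), 5))
    y = np.zeros(len(pairs))
    for k, (u, v) in enumerate(pairs):
        y[k] = dist.loc[u, v]
        x[k, edges.index(u)] = 1
        x[k, edges.index(v)] = 1
        same_side = {u, v} in ({a, b}, {c, d})
        if not same_side:
            x[k, 4] = 1
    coef, res, *_ = np.linalg.lstsq(x, y, rcond=None)
    fit = x @ coef
    return coef, ((fit - y) ** 2).sum()


class TestTrees:
    def test_nj_recovers_additive_quartet(self):
        # additive metric on ((a,b),(c,d))
        labels = ["a", "b", "c", "d"]
        m = pd.DataFrame(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 5], [9, 10, 5, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = nj_tree(m)
        # the unique additive topology groups {a,b} vs {c,d}
        splits = [frozenset(t.name for t in nd.tips()) for nd in tree.non_tips()]
        assert any(s in (frozenset("ab"), frozenset("cd")) for s in splits)
        topo = brute_force_min_evolution(m)
        assert {frozenset(topo[0]), frozenset(topo[1])} == {frozenset("ab"), frozenset("cd")}
        # NJ branch lengths reproduce the additive distances exactly
        for u, v in itertools.combinations(labels, 2):
            tu = tree.find(u)
            assert tu.distance(tree.find(v)) == pytest.approx(m.loc[u, v])

    def test_three_leaves_single_topology(self):
        m = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = nj_tree(m)
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]

    def test_fewer_than_three_leaves_rejected(self):
        m = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_unanimous_signal_full_support(self):
        # two clearly separated clades; every resampled column supports them
        h = np.zeros((8, 30), dtype=np.int8)
        h[4:, :] = 1
        h[1, 0] ^= 1; h[3, 1] ^= 1; h[5, 2] ^= 1; h[7, 3] ^= 1
        seg = make_segment(h, individuals=["A", "B", "C", "D"])
        tree = bootstrap_support(seg, n_boot=100, rng=0)
        split = frozenset(["A.1", "A.2", "B.1", "B.2"])
        found = {
            frozenset(t.name for t in nd.tips()): getattr(nd, "support", None)
            for nd in tree.non_tips()
        }
        all_tips = frozenset(seg.labels())
        supports = [
            s for bp, s in found.items()
            if bp == split or all_tips - bp == split
        ]
        assert supports and supports[0] == pytest.approx(100.0)


class TestMidpointRoot:
    def test_three_leaf_long_branch(self):
        tree = read_newick("(a:1,b:1,c:5);")
        rooted = midpoint_root(tree)
        # diameter path a-c (or b-c) has length 6; midpoint is 3.0 from c,
        # placed on c's branch
        c = rooted.find("c")
        assert c.accumulate_to_ancestor(rooted) == pytest.approx(3.0)

    def test_balanced_ultrametric_center(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        rooted = midpoint_root(tree)
        for leaf in "abcd":
            assert rooted.find(leaf).accumulate_to_ancestor(rooted) == pytest.approx(2.0)

    def test_bipartitions_preserved(self):
        tree = read_newick("((a:1,b:2):0.5,(c:1,(d:2,e:1):0.3):0.7,f:4);")
        all_tips = frozenset("abcdef")
        def splits(t):
            out = set()
            for nd in t.non_tips(include_self=False):
                s = frozenset(x.name for x in nd.tips())
                if 2 <= len(s) <= len(all_tips) - 2:
                    out.add(min(s, all_tips - s, key=sorted))
            return out
        before = splits(tree)
        after = splits(midpoint_root(tree))
        assert before <= after


class TestMonophylyScan:
    def rooted_with_supports(self, newick):
        return read_newick(newick)

    def test_target_clade_detected(self):
        t = self.rooted_with_supports(
            "((L1.1:1,(L2.1:1,L3.1:1)100:1)100:1,((L1.2:1,L4.1:1)80:1,(L4.2:1,L2.2:1):1):1);"
        )
        targets = {"L1.1", "L2.1", "L3.1", "L1.2", "L2.2", "L3.2"}
        rep = monophyly_scan(t, targets, support_min=70)
        assert frozenset({"L1.1", "L2.1", "L3.1"}) in rep.clades
        k = rep.clades.index(frozenset({"L1.1", "L2.1", "L3.1"}))
        assert rep.sizes[k] == 3
        assert rep.one_per_individual[k]
        assert rep.root_separated[k]

    def test_scattered_targets_no_clade(self):
        t = self.rooted_with_supports(
            "((L1.1:1,L4.1:1)90:1,((L2.1:1,L5.1:1)90:1,(L3.1:1,L6.1:1)90:1)90:1);"
        )
        rep = monophyly_scan(t, {"L1.1", "L2.1", "L3.1"}, support_min=70)
        assert not rep.any_clade

    def test_support_threshold_boundary(self):
        t69 = self.rooted_with_supports("((L1.1:1,L2.1:1)69:1,(L3.1:1,L4.1:1):1);")
        rep = monophyly_scan(t69, {"L1.1", "L2.1"}, support_min=70)
        assert not rep.any_clade
        t70 = self.rooted_with_supports("((L1.1:1,L2.1:1)70:1,(L3.1:1,L4.1:1):1);")
        rep = monophyly_scan(t70, {"L1.1", "L2.1"}, support_min=70)
        assert rep.any_clade

    def test_two_haplotypes_same_individual_not_one_per(self):
        t = self.rooted_with_supports("((L1.1:1,L1.2:1)95:1,(L3.1:1,L4.1:1):1);")
        rep = monophyly_scan(t, {"L1.1", "L1.2"}, support_min=70)
        assert rep.any_clade and not rep.one_per_individual[0]

    def test_leaf_order_invariance(self):
        a = "((L1.1:1,(L2.1:1,L3.1:1)90:1)90:1,(L4.1:1,L4.2:1):1);"
        b = "(((L3.1:1,L2.1:1)90:1,L1.1:1)90:1,(L4.2:1,L4.1:1):1);"
        ta = monophyly_scan(self.rooted_with_supports(a), {"L1.1", "L2.1", "L3.1"})
        tb = monophyly_scan(self.rooted_with_supports(b), {"L1.1", "L2.1", "L3.1"})
        assert set(ta.clades) == set(tb.clades)


class TestNewickRoundTrip:
    def test_write_read_supports(self, tmp_path):
        h = np.zeros((8, 30), dtype=np.int8)
        h[4:, :] = 1
        h[1, 0] ^= 1; h[3, 1] ^= 1; h[5, 2] ^= 1; h[7, 3] ^= 1
        seg = make_segment(h, individuals=["A", "B", "C", "D"])
        tree = bootstrap_support(seg, n_boot=50, rng=1)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert sorted(t.name for t in back.tips()) == sorted(seg.labels())
        sups = [getattr(nd, "support", None) for nd in back.non_tips()]
        assert any(s is not None for s in sups)
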