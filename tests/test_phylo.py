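"""Region filtering, NJ correctness (least-squares brute force), concordance,
and hybridization-event recovery against planted truth."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import nnls

from clonalpop.errors import ValidationError
from clonalpop import phylo, synthetic as syn
from clonalpop.phylo import (
    RegionAlignment,
    RegionTree,
    assign_subgenomes,
    average_distance_matrix,
    clade_support,
    concordance_score,
    infer_hybrid_events,
    neighbor_joining,
    region_tree,
    select_regions,
    tree_splits,
)


# ---------------------------------------------------------------------------
# oracles


def random_additive_tree(n, rng):
    """Random unrooted binary tree topology with positive branch lengths,
    returned as (splits, leaf-pair distance matrix)."""
    # build by stepwise addition on an edge list
    edges = {}  # edge id -> (u, v, length)
    nodes = [0, 1, 2]
    internal = [-1]
    next_edge = 0
    for leaf in (0, 1, 2):
        edges[next_edge] = (leaf, -1, rng.uniform(0.1, 1.0))
        next_edge += 1
    next_internal = -2
    for leaf in range(3, n):
        eid = rng.choice(list(edges))
        u, v, length = edges.pop(eid)
        w = next_internal
        next_internal -= 1
        split = rng.uniform(0.2, 0.8) * length
        edges[next_edge] = (u, w, split)
        edges[next_edge + 1] = (w, v, length - split)
        edges[next_edge + 2] = (leaf, w, rng.uniform(0.1, 1.0))
        next_edge += 3
    # distances by path sums
    adj = {}
    for u, v, length in edges.values():
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))
    d = np.zeros((n, n))
    for src in range(n):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, length in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + length
                    stack.append(y)
        for dst in range(n):
            d[src, dst] = seen[dst]
    splits = _splits_from_adj(adj, n)
    return splits, d


def _splits_from_adj(adj, n):
    leaves = set(range(n))
    splits = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < 0 and v < 0:
                side = _leaves_beyond(adj, u, v, n)
                if 2 <= len(side) <= n - 2:
                    canon = frozenset(side) if 0 not in side else frozenset(leaves - side)
                    splits.add(canon)
    return splits


def _leaves_beyond(adj, u, v, n):
    """Leaves reachable from v when the edge (u, v) is removed."""
    seen = {u, v}
    stack = [v]
    out = set()
    while stack:
        x = stack.pop()
        if 0 <= x < n:
            out.add(x)
        for y, _ in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return out


def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists."""
    base = [(0, -1), (1, -1), (2, -1)]
    tops = [base]
    next_internal = -2
    for leaf in range(3, n):
        new = []
        for edges in tops:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                rest = edges[:i] + edges[i + 1 :]
                new.append(rest + [(u, w), (w, v), (leaf, w)])
        tops = new
        next_internal -= 1
    return tops


def least_squares_best_tree(d, n):
    """Brute force: fit branch lengths (non-negative least squares) on every
    topology, return (SSE, splits) of the best fit."""
    best = (np.inf, None)
    pair_idx = list(itertools.combinations(range(n), 2))
    for edges in enumerate_topologies(n):
        adj = {}
        for k, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((v, k))
            adj.setdefault(v, []).append((u, k))
        a = np.zeros((len(pair_idx), len(edges)))
        for row, (i, j) in enumerate(pair_idx):
            # path edges from i to j
            stack = [(i, [])]
            seen = {i}
            while stack:
                x, path = stack.pop()
                if x == j:
                    a[row, path] = 1.0
                    break
                for y, k in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append((y, path + [k]))
        target = np.array([d[i, j] for i, j in pair_idx])
        b, _ = nnls(a, target)
        sse = float(((a @ b - target) ** 2).sum())
        if sse < best[0]:
            full_adj = {}
            for u, v in edges:
                full_adj.setdefault(u, []).append((v, 1.0))
                full_adj.setdefault(v, []).append((u, 1.0))
            best = (sse, _splits_from_adj(full_adj, n))
    return best


def _nj_splits(labels, d):
    tree = neighbor_joining(labels, d)
    leaves = frozenset(labels)
    raw = tree_splits(tree)
    return {frozenset(int(x) for x in s) for s in raw}


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_four_leaf_additive_exact(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        d[2, 3] = d[3, 2] = 7.0
        d[3, 0] = 6.0
        tree = neighbor_joining(["A", "B", "C", "D"], d)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)

    def test_three_leaves_star_fit(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(["a", "b", "c"], d)
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths["a"] == pytest.approx(0.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_identical_sequences_zero_branches(self):
        aln = RegionAlignment("r", {"a": "ACGT", "b": "ACGT", "c": "ACGT"}, 4)
        rt = region_tree(aln)
        assert all(t.branch_length == 0 for t in rt.tree.get_terminals())

    def test_fewer_than_three_leaves_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(["a", "b"], np.zeros((2, 2)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 12))
    def test_recovers_generating_tree_up_to_twelve_leaves(self, seed, n):
        """NJ is consistent on additive matrices: it must reproduce the
        splits of the generating tree (the unique zero-residual least-squares
        optimum) for any size up to 12 leaves."""
        rng = np.random.default_rng(seed)
        true_splits, d = random_additive_tree(n, rng)
        got = _nj_splits([str(i) for i in range(n)], d)
        renamed = {frozenset(str(x) for x in s) for s in true_splits}
        got_named = {frozenset(str(x) for x in s) for s in got}
        assert got_named == renamed

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_least_squares_brute_force(self, seed):
        """For sizes where full topology enumeration is feasible, the NJ
        topology coincides with the global least-squares optimum (zero SSE on
        additive input)."""
        rng = np.random.default_rng(seed)
        n = 6
        true_splits, d = random_additive_tree(n, rng)
        sse, best_splits = least_squares_best_tree(d, n)
        assert sse < 1e-12
        assert best_splits == true_splits
        assert _nj_splits([str(i) for i in range(n)], d) == {
            frozenset(s) for s in true_splits
        }


# ---------------------------------------------------------------------------
# region selection


class TestSelectRegions:
    def _aln(self, rid, labels, length=100, gaps=0):
        seq = "A" * (length - gaps) + "-" * gaps
        return RegionAlignment(rid, {l: seq for l in labels}, length)

    def test_ploidy_mismatch_rejected(self):
        ploidy = {"1": 1, "2": 2}
        good = self._aln("r1", ["1", "2a", "2b"])
        missing = self._aln("r2", ["1", "2a"])  # diploid lost one subgenome
        kept = select_regions([good, missing], ploidy, n=2)
        assert [a.region_id for a in kept] == ["r1"]

    def test_gap_fraction_rejected(self):
        ploidy = {"1": 1, "2": 2}
        gappy = self._aln("r1", ["1", "2a", "2b"], length=100, gaps=20)
        clean = self._aln("r2", ["1", "2a", "2b"])
        kept = select_regions([gappy, clean], ploidy, n=2, gap_threshold=0.15)
        assert [a.region_id for a in kept] == ["r2"]
        # the laxer threshold used for the second species admits it
        kept25 = select_regions([gappy, clean], ploidy, n=2, gap_threshold=0.25)
        assert len(kept25) == 2

    def test_longest_n_kept(self):
        ploidy = {"1": 1}
        alns = [self._aln(f"r{i:02d}", ["1"], length=100 + i) for i in range(60)]
        kept = select_regions(alns, ploidy, n=50)
        assert len(kept) == 50
        assert kept[0].length == 159
        assert min(a.length for a in kept) == 110

    def test_warns_when_too_few(self):
        ploidy = {"1": 1}
        with pytest.warns(UserWarning, match="survive"):
            out = select_regions([self._aln("r1", ["1"])], ploidy, n=50)
        assert len(out) == 1


# ---------------------------------------------------------------------------
# support / concordance


def _tree_from_newick(rid, text):
    from clonalpop.io_formats import read_newick

    return RegionTree(rid, read_newick(text))


class TestCladeSupport:
    def test_identical_trees_full_support(self):
        trees = [
            _tree_from_newick(f"r{i}", "((a:1,b:1):1,(c:1,d:1):1,e:1);")
            for i in range(50)
        ]
        cs = clade_support(trees)
        assert cs.of({"a", "b"}) == 1.0
        assert cs.of({"c", "d"}) == 1.0
        assert cs.of({"a"}) == 1.0  # trivial clade
        assert cs.of({"a", "c"}) == 0.0

    def test_partial_support_counted(self):
        t1 = "((a:1,b:1):1,(c:1,d:1):1,e:1);"
        t2 = "((a:1,c:1):1,(b:1,d:1):1,e:1);"
        trees = [_tree_from_newick(f"x{i}", t1) for i in range(30)] + [
            _tree_from_newick(f"y{i}", t2) for i in range(20)
        ]
        cs = clade_support(trees)
        assert cs.of({"a", "b"}) == pytest.approx(0.6)
        assert cs.of({"a", "c"}) == pytest.approx(0.4)

    def test_conflicting_halves_excluded_from_consensus(self):
        t1 = "((a:1,b:1):1,c:1,d:1);"
        t2 = "((a:1,c:1):1,b:1,d:1);"
        trees = [_tree_from_newick("r1", t1), _tree_from_newick("r2", t2)]
        cs = clade_support(trees)
        assert cs.of({"a", "b"}) == pytest.approx(0.5)
        assert cs.of({"a", "c"}) == pytest.approx(0.5)
        cons_splits = tree_splits(cs.consensus)
        assert cons_splits == set()  # neither 0.5 clade reaches majority

    def test_differing_leaf_sets_rejected(self):
        t1 = _tree_from_newick("r1", "((a:1,b:1):1,c:1,d:1);")
        t2 = _tree_from_newick("r2", "((a:1,b:1):1,c:1,e:1);")
        with pytest.raises(ValidationError, match="symmetric difference"):
            clade_support([t1, t2])


class TestConcordance:
    def test_identical_trees_score_one(self):
        trees = [
            _tree_from_newick(f"r{i}", "((a:1,b:1):1,(c:1,d:1):1,e:1);")
            for i in range(5)
        ]
        assert concordance_score(trees) == pytest.approx(1.0)

    def test_fully_conflicting_trees_score_zero(self):
        t1 = _tree_from_newick("r1", "((a:1,b:1):1,c:1,d:1);")
        t2 = _tree_from_newick("r2", "((a:1,c:1):1,b:1,d:1);")
        assert concordance_score([t1, t2]) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_clonal_simulation_concordant(self, seed):
        # regions long enough to resolve even the shallow post-hybridization
        # splits; without recombination all regions share one genealogy
        cfg = syn.SimConfig(
            n_haploid_lineages=8,
            genome_length=1_000_000,
            n_contigs=4,
            n_hybrid_events=3,
            descendants_per_event=(2, 2),
            n_regions=15,
            region_length_range=(8_000, 12_000),
            seed=seed,
        )
        strains, truth, gm = syn.simulate_population(cfg)
        alns = syn.region_alignments(strains, cfg, np.random.default_rng(seed + 1))
        ploidy_map = {s.strain_id: s.ploidy for s in strains}
        trees = [region_tree(a) for a in select_regions(alns, ploidy_map, n=15)]
        assert concordance_score(trees) >= 0.8

    def test_label_invariance(self, small_sim, small_sim_regions):
        cfg, strains, truth, gm = small_sim
        ploidy_map = {s.strain_id: s.ploidy for s in strains}
        selected = select_regions(small_sim_regions, ploidy_map, n=10)
        trees = [region_tree(a) for a in selected]
        score = concordance_score(trees)
        shuffled = [
            RegionAlignment(
                a.region_id,
                {k: a.sequences[k] for k in reversed(sorted(a.sequences))},
                a.length,
            )
            for a in selected
        ]
        trees2 = [region_tree(a) for a in shuffled]
        assert concordance_score(trees2) == pytest.approx(score)


# ---------------------------------------------------------------------------
# subgenome assignment and event inference


class TestEventInference:
    def test_planted_events_recovered(self, small_sim, small_sim_regions):
        cfg, strains, truth, gm = small_sim
        ploidy_map = {s.strain_id: s.ploidy for s in strains}
        labels, avg = average_distance_matrix(small_sim_regions)
        asg = assign_subgenomes(labels, avg, ploidy_map)
        # every subgenome must map to its planted parental lineage
        for (sid, letter), lineage in truth.subgenome_lineage.items():
            if (sid, letter) in asg.assignments:
                assert asg.assignments[(sid, letter)] == lineage
        result = infer_hybrid_events(asg, labels, avg, ploidy_map)
        got = sorted(sorted(g.members) for g in result.groups)
        want = sorted(sorted(e.members) for e in truth.events)
        assert got == want
        assert result.unplaced == []

    def test_haploid_strain_assigned_to_own_cluster(self, small_sim, small_sim_regions):
        cfg, strains, truth, gm = small_sim
        ploidy_map = {s.strain_id: s.ploidy for s in strains}
        labels, avg = average_distance_matrix(small_sim_regions)
        asg = assign_subgenomes(labels, avg, ploidy_map)
        for s in strains:
            if s.ploidy == 1:
                assert asg.assignments[(s.strain_id, "")] == s.strain_id

    def test_tetraploid_reports_four_lineages(self):
        cfg = syn.SimConfig(
            n_haploid_lineages=8,
            genome_length=400_000,
            n_contigs=4,
            n_hybrid_events=3,
            descendants_per_event=(2, 2),
            make_tetraploid=True,
            n_regions=20,
            seed=17,
        )
        strains, truth, gm = syn.simulate_population(cfg)
        rng = np.random.default_rng(99)
        alns = syn.region_alignments(strains, cfg, rng)
        ploidy_map = {s.strain_id: s.ploidy for s in strains}
        labels, avg = average_distance_matrix(alns)
        asg = assign_subgenomes(labels, avg, ploidy_map)
        result = infer_hybrid_events(asg, labels, avg, ploidy_map)
        assert "t1" in result.tetraploids
        expected = sorted(
            truth.subgenome_lineage[("t1", c)] for c in "abcd"
        )
        assert result.tetraploids["t1"] == expected

    def test_same_pair_twice_with_divergence_gives_two_groups(self):
        cfg = syn.SimConfig(
            n_haploid_lineages=4,
            genome_length=400_000,
            n_contigs=4,
            post_hybridization_divergence=0.004,
            descendants_per_event=(2, 2),
            n_regions=20,
            seed=8,
        )
        rng = np.random.default_rng(8)
        haps, tree, pool = syn.simulate_clonal_haploids(cfg, rng)
        strains, truth = syn.plant_hybridizations(
            haps, tree, cfg, rng, pool,
            event_pairs=[("L01", "L02"), ("L01", "L02")],
        )
        alns = syn.region_alignments(strains, cfg, rng)
        ploidy_map = {s.strain_id: s.ploidy for s in strains}
        labels, avg = average_distance_matrix(alns)
        asg = assign_subgenomes(labels, avg, ploidy_map)
        # within-event distance ~0.004, between-event ~0.008: force the
        # threshold between the two scales
        result = infer_hybrid_events(
            asg, labels, avg, ploidy_map, tau_event=0.006
        )
        assert len(result.groups) == 2

    def test_no_diploids_no_events(self):
        cfg = syn.SimConfig(
            n_haploid_lineages=4,
            genome_length=200_000,
            n_contigs=4,
            n_hybrid_events=0,
            n_regions=10,
            seed=3,
        )
        strains, truth, gm = syn.simulate_population(cfg)
        alns = syn.region_alignments(strains, cfg, np.random.default_rng(3))
        ploidy_map = {s.strain_id: s.ploidy for s in strains}
        labels, avg = average_distance_matrix(alns)
        asg = assign_subgenomes(labels, avg, ploidy_map)
        result = infer_hybrid_events(asg, labels, avg, ploidy_map)
        assert result.groups == []
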