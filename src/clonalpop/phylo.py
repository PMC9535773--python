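"""Per-region trees with multilabeled leaves and hybridization-event grouping.

A diploid hybrid contributes two leaves per region tree (one per subgenome,
labelled ``<strain><letter>``); in a strictly clonal species every region
shares one genealogy, so region trees are concordant and each subgenome
clusters with its parental haploid lineage across all regions.  Diploids
whose subgenome pairs trace to the same parental lineage pair — and lie
within a small post-hybridization distance of each other — are grouped into
a single hybridization event.

Trees are neighbor-joining on p-distances.  This is a deliberate substitution
for maximum-likelihood inference: the downstream readouts (topological
concordance, clade support, event grouping) depend only on topology, for
which NJ is consistent on additive distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .errors import ValidationError


# ---------------------------------------------------------------------------
# region alignments


@dataclass
class RegionAlignment:
    """One aligned genomic region; labels follow the multilabel convention."""

    region_id: str
    sequences: dict[str, str]
    length: int

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValidationError(
                f"{self.region_id}: unequal sequence lengths {sorted(lengths)}"
            )

    def gap_fraction(self, label: str) -> float:
        seq = self.sequences[label]
        return (seq.count("-") + seq.count("N")) / len(seq) if seq else 0.0


def labels_for_strain(strain_id: str, ploidy: int) -> list[str]:
    """Expected leaf labels of one strain: bare id (haploid) or id + letter."""
    if ploidy == 1:
        return [strain_id]
    return [strain_id + letter for letter in "abcdefgh"[:ploidy]]


def select_regions(
    alignments: Sequence[RegionAlignment],
    ploidy: Mapping[str, int],
    n: int = 50,
    gap_threshold: float = 0.15,
) -> list[RegionAlignment]:
    """Ploidy-match and gap filters, then the n longest regions.

    A region is kept only when every strain contributes exactly as many
    sequences as its ploidy and no sequence exceeds the gap-fraction
    threshold.  Ties in length break by region id.  Fewer than ``n``
    survivors produce a warning, not an error.
    """
    expected = {
        label for sid, p in ploidy.items() for label in labels_for_strain(sid, p)
    }
    surviving = []
    for aln in alignments:
        if set(aln.sequences) != expected:
            continue
        if any(aln.gap_fraction(label) > gap_threshold for label in aln.sequences):
            continue
        surviving.append(aln)
    surviving.sort(key=lambda a: (-a.length, a.region_id))
    if len(surviving) < n:
        warnings.warn(
            f"only {len(surviving)} regions survive filtering (requested {n})",
            stacklevel=2,
        )
    return surviving[:n]


def p_distance_matrix(aln: RegionAlignment) -> tuple[list[str], np.ndarray]:
    """Pairwise fraction of differing columns, ignoring gap columns per pair."""
    labels, diff, comp = _diff_comp_counts(aln)
    if (comp == 0).any():
        i, j = np.argwhere(comp == 0)[0]
        raise ValidationError(
            f"{aln.region_id}: no comparable columns for {labels[i]} vs {labels[j]}"
        )
    return labels, diff / comp


def _diff_comp_counts(aln: RegionAlignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pairwise counts of (differing columns, comparable columns)."""
    labels = sorted(aln.sequences)
    arr = np.frombuffer(
        "".join(aln.sequences[l] for l in labels).encode(), dtype=np.uint8
    ).reshape(len(labels), -1)
    valid = (arr != ord("-")) & (arr != ord("N"))
    comp = valid.astype(float) @ valid.astype(float).T
    matches = np.zeros_like(comp)
    for base in b"ACGT":
        m = ((arr == base) & valid).astype(float)
        matches += m @ m.T
    return labels, comp - matches, comp


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(labels: Sequence[str], dist: np.ndarray) -> Tree:
    """Classic neighbor joining with deterministic tie-breaking.

    The Q-criterion minimiser is chosen; ties break by the lexicographically
    smallest pair of subtree representative labels.  Negative branch lengths
    are clamped to zero.  The returned tree is unrooted (trifurcating root).
    """
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs at least 3 leaves")
    if dist.shape != (len(labels), len(labels)):
        raise ValidationError("distance matrix shape mismatch")
    nodes: list[Clade] = [Clade(name=str(l)) for l in labels]
    reps = [str(l) for l in labels]  # smallest leaf label per subtree
    d = dist.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[i], reps[j]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = max(li, 0.0)
        child_j.branch_length = max(lj, 0.0)
        new = Clade(clades=[child_i, child_j])
        new_d = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
    # final three: star join with exactly fitted lengths
    (a, b, c) = nodes
    la = max((d[0, 1] + d[0, 2] - d[1, 2]) / 2.0, 0.0)
    lb = max((d[0, 1] + d[1, 2] - d[0, 2]) / 2.0, 0.0)
    lc = max((d[0, 2] + d[1, 2] - d[0, 1]) / 2.0, 0.0)
    a.branch_length, b.branch_length, c.branch_length = la, lb, lc
    root = Clade(clades=[a, b, c])
    return Tree(root=root, rooted=False)


@dataclass
class RegionTree:
    region_id: str
    tree: Tree

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tree.get_terminals())


def region_tree(aln: RegionAlignment) -> RegionTree:
    """Neighbor-joining tree of one region's p-distance matrix."""
    labels, d = p_distance_matrix(aln)
    return RegionTree(aln.region_id, neighbor_joining(labels, d))


# ---------------------------------------------------------------------------
# splits, support, consensus, concordance


def tree_splits(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial splits, each canonicalised to the side without the
    lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.get_terminals())
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if side == leaves:
            continue
        canon = side if ref not in side else leaves - side
        if 2 <= len(canon) <= len(leaves) - 2:
            splits.add(canon)
    return splits


@dataclass
class CladeSupport:
    """Occurrence fraction of every observed clade, plus the majority-rule
    consensus tree (clades with support > 0.5)."""

    support: dict[frozenset[str], float]
    consensus: Tree
    n_trees: int

    def of(self, clade: Iterable[str]) -> float:
        key = frozenset(clade)
        return self.support.get(key, 0.0)


def clade_support(trees: Sequence[RegionTree]) -> CladeSupport:
    """Fraction of region trees containing each clade (either split side)."""
    if not trees:
        raise ValidationError("no trees given")
    leaf_sets = {t.leaf_names for t in trees}
    if len(leaf_sets) > 1:
        a = min(leaf_sets, key=sorted)
        b = max(leaf_sets, key=sorted)
        raise ValidationError(
            f"trees have differing leaf sets; symmetric difference "
            f"{sorted(a ^ b)}"
        )
    leaves = trees[0].leaf_names
    counts: dict[frozenset[str], int] = {}
    for rt in trees:
        seen: set[frozenset[str]] = set()
        for split in tree_splits(rt.tree):
            seen.add(split)
            seen.add(leaves - split)
        for clade in seen:
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    support = {clade: c / n for clade, c in counts.items()}
    for leaf in leaves:  # trivial clades have support 1 by definition
        support[frozenset({leaf})] = 1.0
    support[leaves] = 1.0
    consensus = _majority_consensus(leaves, support, n)
    return CladeSupport(support, consensus, n)


def _majority_consensus(
    leaves: frozenset[str], support: Mapping[frozenset[str], float], n_trees: int
) -> Tree:
    ref = min(leaves)
    # canonical (ref-free) clades above majority; mutually compatible by
    # the pigeonhole argument, so they nest into a rooted tree
    chosen = sorted(
        (
            clade
            for clade, s in support.items()
            if s > 0.5 and ref not in clade and 1 < len(clade) < len(leaves)
        ),
        key=lambda c: (-len(c), sorted(c)),
    )
    root = Clade(name=None)
    root_members: dict[frozenset[str], Clade] = {leaves: root}
    nested: dict[frozenset[str], Clade] = {}
    for clade in chosen:
        node = Clade()
        node.confidence = support[clade]
        parent_key = min(
            (k for k in root_members if clade < k),
            key=len,
        )
        root_members[parent_key].clades.append(node)
        root_members[clade] = node
        nested[clade] = node
    for leaf in sorted(leaves):
        parent_key = min(
            (k for k in root_members if leaf in k),
            key=len,
        )
        root_members[parent_key].clades.append(Clade(name=leaf))
    return Tree(root=root, rooted=False)


def concordance_score(trees: Sequence[RegionTree]) -> float:
    """Mean over tree pairs of 1 - normalized Robinson-Foulds distance.

    1.0 means all region topologies agree — the strong-phylogenetic-signal
    criterion for clonality; 0.0 means every resolvable split conflicts.
    """
    if len(trees) < 2:
        raise ValidationError("concordance needs at least 2 trees")
    leaf_sets = {t.leaf_names for t in trees}
    if len(leaf_sets) > 1:
        raise ValidationError("trees have differing leaf sets")
    splits = [tree_splits(t.tree) for t in trees]
    total = 0.0
    pairs = 0
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            s1, s2 = splits[i], splits[j]
            denom = len(s1) + len(s2)
            rf = len(s1 ^ s2) / denom if denom else 0.0
            total += 1.0 - rf
            pairs += 1
    return total / pairs


# ---------------------------------------------------------------------------
# subgenome -> lineage assignment


def average_distance_matrix(
    alignments: Sequence[RegionAlignment],
) -> tuple[list[str], np.ndarray]:
    """Length-weighted mean p-distance across regions (shared label set)."""
    if not alignments:
        raise ValidationError("no alignments given")
    labels = sorted(alignments[0].sequences)
    for aln in alignments:
        if sorted(aln.sequences) != labels:
            raise ValidationError("alignments have differing label sets")
    diff = np.zeros((len(labels), len(labels)))
    comp = np.zeros_like(diff)
    for aln in alignments:
        _, d, c = _diff_comp_counts(aln)
        diff += d
        comp += c
    if (comp == 0).any():
        raise ValidationError("a label pair has no comparable columns in any region")
    return labels, diff / comp


def split_label(label: str, ploidy: Mapping[str, int]) -> tuple[str, str]:
    """Decompose a leaf label into (strain_id, subgenome letter)."""
    if label in ploidy and ploidy[label] == 1:
        return label, ""
    sid, letter = label[:-1], label[-1]
    if sid in ploidy and ploidy[sid] > 1 and letter in "abcdefgh":
        return sid, letter
    raise ValidationError(f"cannot decompose leaf label {label!r}")


@dataclass
class SubgenomeAssignment:
    assignments: dict[tuple[str, str], str]  # (strain, letter) -> cluster name
    ambiguous: list[tuple[str, str]]
    cluster_members: dict[str, list[str]]  # cluster name -> leaf labels
    tau_lineage: float


def assign_subgenomes(
    labels: Sequence[str],
    dist: np.ndarray,
    ploidy: Mapping[str, int],
    tau_lineage: float | None = None,
    ambiguity_tolerance: float | None = None,
) -> SubgenomeAssignment:
    """Cluster subgenomes into parental lineages by single linkage.

    The default threshold is half the median distance between haploid
    strains, i.e. well below between-lineage divergence and far above the
    post-hybridization scale.  Clusters containing a haploid strain are named
    after it ("sampled parent"); pure-subgenome clusters get synthetic
    ``anc<N>`` names, the unsampled/extinct parent case.  A subgenome whose
    two nearest clusters are closer than the ambiguity tolerance is flagged
    and left unassigned.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    labels = list(labels)
    haploid_idx = [
        k for k, l in enumerate(labels) if l in ploidy and ploidy[l] == 1
    ]
    if tau_lineage is None:
        if len(haploid_idx) >= 2:
            hap_d = dist[np.ix_(haploid_idx, haploid_idx)]
            tau_lineage = 0.5 * float(np.median(hap_d[np.triu_indices(len(haploid_idx), 1)]))
        else:
            tau_lineage = 0.5 * float(np.median(dist[np.triu_indices(len(labels), 1)]))
    if ambiguity_tolerance is None:
        ambiguity_tolerance = 0.1 * tau_lineage
    z = linkage(squareform(dist, checks=False), method="single")
    flat = fcluster(z, t=tau_lineage, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for k, c in enumerate(flat):
        clusters.setdefault(int(c), []).append(k)
    # name clusters
    names: dict[int, str] = {}
    anc = 0
    for c, members in sorted(clusters.items(), key=lambda kv: sorted(labels[k] for k in kv[1])[0]):
        haps = sorted(labels[k] for k in members if k in set(haploid_idx))
        if haps:
            names[c] = haps[0]
        else:
            anc += 1
            names[c] = f"anc{anc}"
    # mean distance from each leaf to each cluster, for ambiguity flagging
    assignments: dict[tuple[str, str], str] = {}
    ambiguous: list[tuple[str, str]] = []
    cluster_ids = sorted(clusters)
    for k, label in enumerate(labels):
        means = {}
        for c in cluster_ids:
            others = [m for m in clusters[c] if m != k]
            if others:
                means[c] = float(dist[k, others].mean())
        own = int(flat[k])
        strain, letter = split_label(label, ploidy)
        own_mean = means.get(own)  # None when the leaf is alone in its cluster
        others = {c: v for c, v in means.items() if c != own}
        if own_mean is not None and others:
            if min(others.values()) - own_mean < ambiguity_tolerance:
                ambiguous.append((strain, letter))
                continue
        assignments[(strain, letter)] = names[own]
    members_named = {
        names[c]: sorted(labels[k] for k in ks) for c, ks in clusters.items()
    }
    return SubgenomeAssignment(assignments, ambiguous, members_named, tau_lineage)


# ---------------------------------------------------------------------------
# hybridization events


@dataclass
class HybridEventGroup:
    event_id: int
    parents: tuple[str, str]
    members: list[str]


@dataclass
class HybridEventResult:
    groups: list[HybridEventGroup]
    tetraploids: dict[str, list[str]]  # strain -> its 4 lineage assignments
    unplaced: list[str]
    tau_event: float


def infer_hybrid_events(
    assignment: SubgenomeAssignment,
    labels: Sequence[str],
    dist: np.ndarray,
    ploidy: Mapping[str, int],
    tau_event: float | None = None,
) -> HybridEventResult:
    """Group diploids into hybridization events.

    Two diploids belong to the same event when their subgenomes map to the
    same unordered parental-lineage pair and both corresponding subgenome
    pairs lie within ``tau_event`` of each other; events are the connected
    components of that relation.  The default ``tau_event`` is five times the
    median within-lineage-cluster distance (the post-hybridization scale).
    Strains with unassigned subgenomes are reported as unplaced, and
    tetraploids are reported with their four lineage assignments.
    """
    labels = list(labels)
    index = {l: k for k, l in enumerate(labels)}
    label_of = {}
    for label in labels:
        label_of[split_label(label, ploidy)] = label

    if tau_event is None:
        within = []
        for members in assignment.cluster_members.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    within.append(dist[index[members[i]], index[members[j]]])
        tau_event = (
            5.0 * float(np.median(within)) if within else 0.25 * assignment.tau_lineage
        )

    diploids = sorted(s for s, p in ploidy.items() if p == 2)
    unplaced = []
    placed: dict[str, dict[str, str]] = {}  # strain -> lineage -> leaf label
    for s in diploids:
        keys = [(s, "a"), (s, "b")]
        if any(k in assignment.ambiguous or k not in assignment.assignments for k in keys):
            unplaced.append(s)
            continue
        la, lb = (assignment.assignments[k] for k in keys)
        if la == lb:  # both subgenomes in one cluster: not an F1 signature
            unplaced.append(s)
            continue
        placed[s] = {la: label_of[(s, "a")], lb: label_of[(s, "b")]}

    # union-find over diploids sharing a parental pair
    parent_ptr = {s: s for s in placed}

    def find(s: str) -> str:
        while parent_ptr[s] != s:
            parent_ptr[s] = parent_ptr[parent_ptr[s]]
            s = parent_ptr[s]
        return s

    by_pair: dict[tuple[str, str], list[str]] = {}
    for s, m in placed.items():
        by_pair.setdefault(tuple(sorted(m)), []).append(s)
    for pair, members in by_pair.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                s, t = members[i], members[j]
                ok = all(
                    dist[index[placed[s][lin]], index[placed[t][lin]]] <= tau_event
                    for lin in pair
                )
                if ok:
                    parent_ptr[find(s)] = find(t)

    comp: dict[str, list[str]] = {}
    for s in placed:
        comp.setdefault(find(s), []).append(s)
    groups = []
    ordered = sorted(comp.values(), key=lambda ms: sorted(ms)[0])
    for event_id, members in enumerate(ordered, start=1):
        pair = tuple(sorted(placed[members[0]]))
        groups.append(HybridEventGroup(event_id, pair, sorted(members)))

    tetraploids = {}
    for s, p in ploidy.items():
        if p == 4:
            lins = []
            for letter in "abcd":
                key = (s, letter)
                lins.append(assignment.assignments.get(key, "unassigned"))
            tetraploids[s] = sorted(lins)
    return HybridEventResult(groups, tetraploids, sorted(unplaced), tau_event)
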