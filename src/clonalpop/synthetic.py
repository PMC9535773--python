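"""Synthetic clonal populations with planted hybridization, aneuploidy and LOH.

The generator emulates the data underlying a population-genomic survey of
strictly clonal black yeasts in which haploid strains occasionally fuse into
stable, highly heterozygous F1 diploids:

* a Yule genealogy of haploid lineages with infinite-sites mutations, giving
  between-lineage divergences on the percent scale;
* rare fusion events of two haploid genomes into diploids whose two subgenomes
  never recombine, each event spawning several descendant strains separated
  only by a much smaller post-hybridization divergence (and optionally one
  diploid x diploid tetraploid);
* negative-binomial sequencing-depth tracks with planted aneuploid segments;
* copy-neutral and deletion loss-of-heterozygosity tracts;
* per-ploidy assembly statistics (size, gene count, core-BUSCO mean copy).

Everything is driven by a single seed; identical configs give bit-identical
outputs.  All coordinates are 0-based half-open on a genome partitioned into
equal-size contigs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io_formats import (
    AssemblyStats,
    DepthRaw,
    GenotypeMatrix,
    StrainMeta,
    write_assembly_stats,
    write_depth_tsv,
    write_fasta_alignment,
    write_genotype_vcf,
    write_strain_table,
)

_BASES = np.array(list("ACGT"))

# Assembly-statistic distributions per ploidy (means/SDs of the surveyed
# H. werneckii cohort; the tetraploid column had a single strain, so its
# spreads are this module's own choice).
ASSEMBLY_PARAMS: dict[int, dict[str, tuple[float, float]]] = {
    1: {"size": (26.52e6, 1.47e6), "genes": (9519, 665), "copy": (1.00, 0.03)},
    2: {"size": (49.30e6, 1.74e6), "genes": (20417, 1709), "copy": (1.70, 0.08)},
    4: {"size": (94.67e6, 3.00e6), "genes": (46596, 2500), "copy": (3.10, 0.25)},
}


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class AneuploidSegmentSpec:
    strain_id: str
    contig: str
    start: int
    end: int
    copy_number: int


@dataclass
class LOHTractSpec:
    strain_id: str
    contig: str
    start: int
    end: int
    copy_neutral: bool = True


@dataclass
class SimConfig:
    """Parameters of one simulated clonal population.

    ``theta`` is the per-site divergence scale on the height-normalised
    lineage genealogy: two lineages whose paths sum to length ``t`` differ at
    an expected fraction ``theta * t`` of sites, so the deepest pairs sit near
    ``2 * theta`` (default 4%) and shallow pairs lower, matching the 2-4%
    between-lineage SNP distances of the surveyed populations.
    ``post_hybridization_divergence`` is the expected pairwise difference
    fraction between two descendants of the same fusion event (default 0.05%,
    i.e. a separation of scales of roughly 40-80x).
    """

    n_haploid_lineages: int = 12
    genome_length: int = 1_000_000
    n_contigs: int = 10
    theta: float = 0.02
    terminal_branch_fraction: float = 0.5
    n_hybrid_events: int = 7
    descendants_per_event: tuple[int, int] = (2, 6)
    post_hybridization_divergence: float = 0.0005
    recombination_rate: float = 0.0
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    # one NB draw per fine window: per-base coverage is autocorrelated at
    # read scale, so ~100 bp is the effective independent noise grain; the
    # resulting 30-kbp window medians are still noisier than real tracks
    depth_fine_window: int = 100
    make_tetraploid: bool = False
    aneuploid_segments: list[AneuploidSegmentSpec] = field(default_factory=list)
    loh_tracts: list[LOHTractSpec] = field(default_factory=list)
    n_regions: int = 50
    region_length_range: tuple[int, int] = (1_364, 5_089)
    habitat_categories: tuple[str, ...] = (
        "brine",
        "seawater",
        "tap water",
        "surface",
        "other",
    )
    continent_categories: tuple[str, ...] = (
        "Europe",
        "Asia",
        "North America",
        "South America",
    )
    label_bias: float = 0.75  # probability a strain takes its group's label
    seed: int = 0

    def contig_table(self) -> list[tuple[str, int, int]]:
        """Equal-size contigs named ctg01.. tiling [0, genome_length)."""
        size = self.genome_length // self.n_contigs
        bounds = []
        for i in range(self.n_contigs):
            start = i * size
            end = self.genome_length if i == self.n_contigs - 1 else (i + 1) * size
            bounds.append((f"ctg{i + 1:02d}", start, end))
        return bounds


@dataclass
class HybridEventTruth:
    event_id: int
    parents: tuple[str, str]  # unordered pair, stored sorted
    members: list[str]


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery tests."""

    lineage_tree_newick: str
    ploidy: dict[str, int]
    subgenome_lineage: dict[tuple[str, str], str]  # (strain, letter) -> lineage
    events: list[HybridEventTruth]
    tetraploid_strain: str | None = None
    tetraploid_source_events: tuple[int, int] | None = None
    aneuploid_segments: list[AneuploidSegmentSpec] = field(default_factory=list)
    loh_tracts: list[LOHTractSpec] = field(default_factory=list)


@dataclass
class SimStrain:
    """One simulated strain: subgenome letter -> sorted mutation positions."""

    strain_id: str
    subgenomes: dict[str, np.ndarray]

    @property
    def ploidy(self) -> int:
        return len(self.subgenomes)


# ---------------------------------------------------------------------------
# lineage genealogy (Yule) with infinite-sites mutations


class _Node:
    __slots__ = ("name", "children", "length", "muts")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.children: list[_Node] = []
        self.length = length
        self.muts: np.ndarray = np.empty(0, dtype=np.int64)

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6g}"


def _yule_tree(
    n: int, rng: np.random.Generator, terminal_fraction: float = 0.5
) -> tuple[_Node, list[_Node]]:
    """Random bifurcating genealogy over n leaves, height normalised to 1.

    All splits are compressed into the oldest ``1 - terminal_fraction`` of
    the height, so every leaf pair diverges along a path of length between
    ``2 * terminal_fraction`` and 2.  With the default 0.5 and a per-site
    scale ``theta``, pairwise divergences span ``theta`` to ``2 * theta``.
    """
    if not (0 <= terminal_fraction < 1):
        raise ValidationError("terminal_branch_fraction must lie in [0, 1)")
    root = _Node()
    # (node, birth_time) of active lineages
    active: list[tuple[_Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = rng.integers(k)
        node, birth = active.pop(idx)
        node.length = t - birth if node is not root else 0.0
        left, right = _Node(), _Node()
        node.children = [left, right]
        active.append((left, t))
        active.append((right, t))
    present = (
        t / (1.0 - terminal_fraction) if t > 0 else rng.exponential(1.0 / n)
    )
    for i, (node, birth) in enumerate(active):
        node.length = present - birth
        node.name = f"L{i + 1:02d}"
    _scale(root, 1.0 / present)
    leaves = sorted((nd for nd, _ in active), key=lambda nd: nd.name)
    return root, leaves


def _scale(node: _Node, factor: float) -> None:
    node.length *= factor
    for c in node.children:
        _scale(c, factor)


class _PositionPool:
    """Draws never-before-used genome positions (infinite-sites model)."""

    def __init__(self, genome_length: int, rng: np.random.Generator):
        self.length = genome_length
        self.rng = rng
        self.used: set[int] = set()

    def draw(self, n: int) -> np.ndarray:
        if len(self.used) + n > self.length:
            raise ValidationError(
                "genome_length too small for the requested mutation load"
            )
        out: list[int] = []
        while len(out) < n:
            cand = self.rng.integers(0, self.length, size=2 * (n - len(out)) + 8)
            for p in cand:
                p = int(p)
                if p not in self.used:
                    self.used.add(p)
                    out.append(p)
                    if len(out) == n:
                        break
        return np.array(sorted(out), dtype=np.int64)


def simulate_clonal_haploids(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], str, _PositionPool]:
    """Simulate haploid lineages on a Yule genealogy without recombination.

    Returns ``(haplotypes, tree_newick, position_pool)`` where each haplotype
    is the sorted array of mutated positions carried by that lineage.  The
    expected pairwise difference between two lineages is ``theta`` times
    their path length on the height-1 genealogy.
    """
    if config.n_haploid_lineages < 2:
        raise ValidationError("need at least 2 haploid lineages")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    root, leaves = _yule_tree(
        config.n_haploid_lineages, rng, config.terminal_branch_fraction
    )
    # total branch length drives the expected mutation count
    total_len = _total_length(root)
    expected = config.theta * config.genome_length * total_len
    if expected > config.genome_length:
        raise ValidationError(
            f"expected segregating sites ({expected:.0f}) exceed genome_length"
        )
    pool = _PositionPool(config.genome_length, rng)
    _drop_mutations(root, config.theta * config.genome_length, pool, rng)
    haplotypes: dict[str, np.ndarray] = {}
    _collect(root, np.empty(0, dtype=np.int64), haplotypes)
    ordered = {lf.name: haplotypes[lf.name] for lf in leaves}
    return ordered, root.newick() + ";", pool


def _total_length(node: _Node) -> float:
    return node.length + sum(_total_length(c) for c in node.children)


def _drop_mutations(
    node: _Node, rate: float, pool: _PositionPool, rng: np.random.Generator
) -> None:
    n = rng.poisson(rate * node.length)
    node.muts = pool.draw(int(n))
    for c in node.children:
        _drop_mutations(c, rate, pool, rng)


def _collect(node: _Node, inherited: np.ndarray, out: dict[str, np.ndarray]) -> None:
    carried = np.sort(np.concatenate([inherited, node.muts]))
    if not node.children:
        out[node.name] = carried
    for c in node.children:
        _collect(c, carried, out)


# ---------------------------------------------------------------------------
# hybridization events


def plant_hybridizations(
    haplotypes: dict[str, np.ndarray],
    tree_newick: str,
    config: SimConfig,
    rng: np.random.Generator,
    pool: _PositionPool,
    event_pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[list[SimStrain], SimulationTruth]:
    """Fuse pairs of haploid lineages into F1 diploid strains.

    Every lineage is also sampled as one haploid strain (named after the
    lineage).  Each fusion event spawns 2-6 diploid descendants that only
    accumulate private post-hybridization mutations on both subgenomes; the
    subgenomes never recombine with each other.  Optionally one tetraploid is
    formed by fusing diploids from the first two events.
    """
    lineages = list(haplotypes)
    n_pairs = len(lineages) * (len(lineages) - 1) // 2
    if event_pairs is not None:
        for a, b in event_pairs:
            if a == b:
                raise ValidationError(f"event between identical lineages {a!r}")
        # the same unordered pair may fuse more than once (independent events)
        pairs = [tuple(sorted(p)) for p in event_pairs]
    else:
        if config.n_hybrid_events > n_pairs:
            raise ValidationError(
                f"{config.n_hybrid_events} events exceed {n_pairs} distinct "
                "lineage pairs"
            )
        all_pairs = [
            (lineages[i], lineages[j])
            for i in range(len(lineages))
            for j in range(i + 1, len(lineages))
        ]
        idx = rng.choice(len(all_pairs), size=config.n_hybrid_events, replace=False)
        pairs = [all_pairs[i] for i in sorted(idx)]

    strains: list[SimStrain] = []
    truth_subgenomes: dict[tuple[str, str], str] = {}
    for name, hap in haplotypes.items():
        strains.append(SimStrain(name, {"": hap.copy()}))
        truth_subgenomes[(name, "")] = name

    # private mutations per descendant subgenome: two descendants of one event
    # then differ at ~post_hybridization_divergence of sites per subgenome
    private_rate = config.post_hybridization_divergence * config.genome_length / 2.0

    events: list[HybridEventTruth] = []
    lo, hi = config.descendants_per_event
    for event_id, (pa, pb) in enumerate(pairs, start=1):
        n_desc = int(rng.integers(lo, hi + 1))
        # the F1 founder accumulates its own mutations before spawning
        # descendants, so members of one event form a coherent clade and two
        # events on the same lineage pair stay distinguishable
        founder_a = np.concatenate(
            [haplotypes[pa], pool.draw(int(rng.poisson(private_rate)))]
        )
        founder_b = np.concatenate(
            [haplotypes[pb], pool.draw(int(rng.poisson(private_rate)))]
        )
        members = []
        for d in range(1, n_desc + 1):
            sid = f"d{event_id}_{d}"
            sub_a = np.sort(np.concatenate([founder_a, pool.draw(int(rng.poisson(private_rate)))]))
            sub_b = np.sort(np.concatenate([founder_b, pool.draw(int(rng.poisson(private_rate)))]))
            strains.append(SimStrain(sid, {"a": sub_a, "b": sub_b}))
            truth_subgenomes[(sid, "a")] = pa
            truth_subgenomes[(sid, "b")] = pb
            members.append(sid)
        events.append(HybridEventTruth(event_id, (pa, pb), members))

    tetraploid_strain = None
    tetraploid_sources = None
    if config.make_tetraploid:
        # pick two events with disjoint parental pairs, so the tetraploid
        # carries four distinct lineages (the diploid x diploid fusion case)
        disjoint = [
            (e1, e2)
            for i, e1 in enumerate(events)
            for e2 in events[i + 1 :]
            if not set(e1.parents) & set(e2.parents)
        ]
        if not disjoint:
            raise ValidationError(
                "tetraploid requires two hybrid events with disjoint parents"
            )
        e1, e2 = disjoint[0]
        d1 = next(s for s in strains if s.strain_id == e1.members[0])
        d2 = next(s for s in strains if s.strain_id == e2.members[0])
        subs = {}
        for letter, (src, src_letter) in zip(
            "abcd", [(d1, "a"), (d1, "b"), (d2, "a"), (d2, "b")]
        ):
            extra = pool.draw(int(rng.poisson(private_rate)))
            subs[letter] = np.sort(np.concatenate([src.subgenomes[src_letter], extra]))
            truth_subgenomes[("t1", letter)] = truth_subgenomes[
                (src.strain_id, src_letter)
            ]
        strains.append(SimStrain("t1", subs))
        tetraploid_strain = "t1"
        tetraploid_sources = (e1.event_id, e2.event_id)

    truth = SimulationTruth(
        lineage_tree_newick=tree_newick,
        ploidy={s.strain_id: s.ploidy for s in strains},
        subgenome_lineage=truth_subgenomes,
        events=events,
        tetraploid_strain=tetraploid_strain,
        tetraploid_source_events=tetraploid_sources,
        aneuploid_segments=list(config.aneuploid_segments),
        loh_tracts=list(config.loh_tracts),
    )
    return strains, truth


# ---------------------------------------------------------------------------
# strains -> genotype matrix / region alignments


def _ref_alt_bases(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic ancestral/derived bases per position (Knuth hash)."""
    h = (positions.astype(np.uint64) * np.uint64(2654435761)) >> np.uint64(7)
    ref_idx = (h % np.uint64(4)).astype(np.int64)
    step = ((h >> np.uint64(2)) % np.uint64(3)).astype(np.int64)
    alt_idx = (ref_idx + 1 + step) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def genotype_matrix(strains: Sequence[SimStrain], config: SimConfig) -> GenotypeMatrix:
    """Collect all segregating mutations into an allele-dosage matrix."""
    all_pos = np.unique(
        np.concatenate(
            [sub for s in strains for sub in s.subgenomes.values()]
            or [np.empty(0, dtype=np.int64)]
        )
    )
    dosage = np.zeros((len(all_pos), len(strains)), dtype=np.int16)
    for j, s in enumerate(strains):
        for sub in s.subgenomes.values():
            dosage[np.searchsorted(all_pos, sub), j] += 1
    ref, alt = _ref_alt_bases(all_pos)
    contigs = np.empty(len(all_pos), dtype=object)
    local = np.empty(len(all_pos), dtype=np.int64)
    for name, start, end in config.contig_table():
        sel = (all_pos >= start) & (all_pos < end)
        contigs[sel] = name
        local[sel] = all_pos[sel] - start
    return GenotypeMatrix(
        contigs,
        local,
        ref,
        [(a,) for a in alt],
        [s.strain_id for s in strains],
        {s.strain_id: s.ploidy for s in strains},
        dosage,
    )


def region_alignments(
    strains: Sequence[SimStrain],
    config: SimConfig,
    rng: np.random.Generator,
    n_regions: int | None = None,
):
    """Extract phased per-region alignments (one sequence per subgenome).

    Regions are non-overlapping intervals with lengths drawn from
    ``region_length_range``; each subgenome sequence is the shared ancestral
    sequence with that subgenome's substitutions applied.  Labels follow the
    multilabeled-leaf convention: bare strain id for haploids, id + letter
    for higher ploidy.
    """
    from .phylo import RegionAlignment  # local import to avoid a cycle

    n_regions = config.n_regions if n_regions is None else n_regions
    lo, hi = config.region_length_range
    contig_table = config.contig_table()
    # lay regions down left-to-right with random gaps so they never overlap
    lengths = rng.integers(lo, hi + 1, size=n_regions)
    total = int(lengths.sum())
    if total > config.genome_length // 2:
        raise ValidationError("regions would cover more than half the genome")
    slack = config.genome_length - total
    gaps = rng.multinomial(slack, np.ones(n_regions) / n_regions)
    out = []
    cursor = 0
    for i in range(n_regions):
        cursor += int(gaps[i])
        start, end = cursor, cursor + int(lengths[i])
        cursor = end
        anc = rng.integers(0, 4, size=end - start)
        _, alt = _ref_alt_bases(np.arange(start, end, dtype=np.int64))
        alt_idx = np.searchsorted(_BASES, alt)  # ACGT sorted already
        seqs: dict[str, str] = {}
        for s in strains:
            for letter, sub in s.subgenomes.items():
                label = s.strain_id if s.ploidy == 1 else s.strain_id + letter
                i0, i1 = np.searchsorted(sub, [start, end])
                hit = sub[i0:i1] - start
                arr = anc.copy()
                # derived base must differ from the ancestral one
                arr[hit] = (anc[hit] + 1 + alt_idx[hit] % 3) % 4
                seqs[label] = "".join(_BASES[arr])
        region_id = f"region{i + 1:03d}"
        out.append(RegionAlignment(region_id, seqs, end - start))
    return out


# ---------------------------------------------------------------------------
# depth and LOH


def simulate_depth(
    strain_ploidy: int,
    segments: Sequence[AneuploidSegmentSpec],
    config: SimConfig,
    rng: np.random.Generator,
    deletion_tracts: Sequence[LOHTractSpec] = (),
) -> DepthRaw:
    """Negative-binomial depth in fine windows, scaled by local copy number.

    Window means are ``depth_mean * copy / ploidy``; the baseline copy number
    equals the strain ploidy outside planted segments.  Deletion (non
    copy-neutral) LOH tracts halve the local copy number of a diploid.
    """
    if config.depth_mean <= 0:
        raise ValidationError("depth_mean must be positive")
    contigs, starts, ends, copies = [], [], [], []
    for name, cstart, cend in config.contig_table():
        w = config.depth_fine_window
        edges = np.arange(0, cend - cstart, w)
        for s in edges:
            e = min(s + w, cend - cstart)
            contigs.append(name)
            starts.append(s)
            ends.append(e)
            copies.append(strain_ploidy)
    starts_a = np.array(starts)
    ends_a = np.array(ends)
    contigs_a = np.array(contigs, dtype=object)
    copies_a = np.array(copies, dtype=float)
    for seg in segments:
        sel = (contigs_a == seg.contig) & (starts_a >= seg.start) & (ends_a <= seg.end)
        copies_a[sel] = seg.copy_number
    for tract in deletion_tracts:
        if tract.copy_neutral:
            continue
        sel = (
            (contigs_a == tract.contig)
            & (starts_a >= tract.start)
            & (ends_a <= tract.end)
        )
        copies_a[sel] = copies_a[sel] / 2.0
    mean = config.depth_mean * copies_a / strain_ploidy
    k = config.depth_dispersion
    depth = np.where(
        mean > 0, rng.negative_binomial(k, k / (k + np.maximum(mean, 1e-9))), 0
    ).astype(float)
    return DepthRaw(contigs_a, starts_a, ends_a, depth)


def plant_loh(
    strains: Sequence[SimStrain],
    tracts: Sequence[LOHTractSpec],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SimStrain]:
    """Collapse heterozygosity within the given tracts of diploid strains.

    Inside a tract every site where the two subgenomes disagree is overwritten
    with one randomly chosen subgenome's allele (both copies become equal).
    Copy-neutral tracts leave depth untouched; deletion tracts are later
    reflected in :func:`simulate_depth` via ``deletion_tracts``.
    """
    contig_offsets = {name: start for name, start, _ in config.contig_table()}
    by_id = {s.strain_id: s for s in strains}
    out = {s.strain_id: {k: v.copy() for k, v in s.subgenomes.items()} for s in strains}
    for tract in tracts:
        strain = by_id.get(tract.strain_id)
        if strain is None:
            raise ValidationError(f"LOH tract on unknown strain {tract.strain_id}")
        if strain.ploidy != 2:
            raise ValidationError(
                f"LOH tract on non-diploid strain {tract.strain_id} "
                f"(ploidy {strain.ploidy})"
            )
        offset = contig_offsets[tract.contig]
        g0, g1 = offset + tract.start, offset + tract.end
        subs = out[tract.strain_id]
        donor = "a" if rng.random() < 0.5 else "b"
        other = "b" if donor == "a" else "a"
        d, o = subs[donor], subs[other]
        d_in = d[(d >= g0) & (d < g1)]
        o_keep = o[(o < g0) | (o >= g1)]
        subs[other] = np.sort(np.concatenate([o_keep, d_in]))
    return [SimStrain(s.strain_id, out[s.strain_id]) for s in strains]


# ---------------------------------------------------------------------------
# habitat / geography labels with group bias


def assign_metadata(
    strains: Sequence[SimStrain],
    truth: SimulationTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[StrainMeta]:
    """Habitat and continent labels skewed toward each strain's group.

    Every hybridization event (and every haploid lineage) gets a preferred
    habitat and continent; members take the preferred label with probability
    ``label_bias`` and a uniform draw otherwise.  This plants the
    group-by-habitat association that the enrichment stage is meant to
    detect.
    """
    group_of: dict[str, str] = {}
    for e in truth.events:
        for m in e.members:
            group_of[m] = f"event{e.event_id}"
    for s in strains:
        group_of.setdefault(s.strain_id, f"lineage_{s.strain_id}")
    prefs: dict[str, tuple[str, str]] = {}
    for g in sorted(set(group_of.values())):
        prefs[g] = (
            config.habitat_categories[int(rng.integers(len(config.habitat_categories)))],
            config.continent_categories[
                int(rng.integers(len(config.continent_categories)))
            ],
        )
    meta = []
    for s in strains:
        hab_pref, cont_pref = prefs[group_of[s.strain_id]]
        hab = (
            hab_pref
            if rng.random() < config.label_bias
            else config.habitat_categories[int(rng.integers(len(config.habitat_categories)))]
        )
        cont = (
            cont_pref
            if rng.random() < config.label_bias
            else config.continent_categories[
                int(rng.integers(len(config.continent_categories)))
            ]
        )
        meta.append(
            StrainMeta(
                strain_id=s.strain_id,
                habitat=hab,
                habitat_class=hab,
                location=cont,
                continent=cont,
                ploidy_label=s.ploidy,
            )
        )
    return meta


# ---------------------------------------------------------------------------
# assembly statistics


def simulate_assembly_stats(
    ploidy: int,
    rng: np.random.Generator,
    strain_id: str = "sim",
    truncate_sd: float | None = None,
) -> AssemblyStats:
    """Draw assembly size, gene count and core-BUSCO mean copy for a ploidy.

    Values come from independent normals centred on the per-ploidy cohort
    means; ``truncate_sd`` restricts each draw to mean +- that many SDs
    (exact truncated-normal sampling).
    """
    if ploidy not in ASSEMBLY_PARAMS:
        raise ValidationError(f"unsupported ploidy {ploidy}")
    p = ASSEMBLY_PARAMS[ploidy]

    def draw(mu: float, sd: float) -> float:
        if truncate_sd is None:
            return float(rng.normal(mu, sd))
        u = rng.uniform(
            stats.norm.cdf(-truncate_sd), stats.norm.cdf(truncate_sd)
        )
        return float(mu + sd * stats.norm.ppf(u))

    return AssemblyStats(
        strain_id=strain_id,
        assembly_size=max(1, int(round(draw(*p["size"])))),
        n_genes=max(1, int(round(draw(*p["genes"])))),
        busco_core_mean_copy=max(0.0, draw(*p["copy"])),
    )


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulator (clonal / recombining contrast)


def simulate_wright_fisher(
    n_individuals: int,
    genome_length: int,
    mutation_rate: float,
    recombination_rate: float,
    n_generations: int,
    sample_size: int,
    seed: int,
    min_segregating_sites: int | None = None,
) -> GenotypeMatrix:
    """Forward haploid Wright-Fisher population under the infinite-sites model.

    With ``recombination_rate == 0`` offspring copy a single parent (strictly
    clonal): the sample genealogy is one tree and is simulated exactly by
    tracking parent indices and dropping Poisson mutations on the coalescent
    branches.  With ``recombination_rate > 0`` haplotypes are evolved
    explicitly and offspring are crossover mosaics of two parents
    (Poisson(recombination_rate * genome_length) breakpoints).

    Rates are per bp per generation.  ``min_segregating_sites`` doubles the
    mutation rate (same genealogy, clonal mode only) until the sampled matrix
    reaches the requested number of segregating sites.
    """
    if sample_size > n_individuals:
        raise ValidationError("sample_size exceeds population size")
    if n_generations < 1:
        raise ValidationError("need at least one generation")
    rng = np.random.default_rng(seed)
    if recombination_rate == 0:
        return _wf_clonal(
            n_individuals,
            genome_length,
            mutation_rate,
            n_generations,
            sample_size,
            rng,
            min_segregating_sites,
        )
    return _wf_recombining(
        n_individuals,
        genome_length,
        mutation_rate,
        recombination_rate,
        n_generations,
        sample_size,
        rng,
    )


def _wf_clonal(
    n: int,
    length: int,
    mu: float,
    gens: int,
    sample_size: int,
    rng: np.random.Generator,
    min_seg: int | None,
) -> GenotypeMatrix:
    parents = rng.integers(0, n, size=(gens, n))
    sample = rng.choice(n, size=sample_size, replace=False)
    # trace sample lineages backward, recording coalescences
    nodes: list[dict] = [
        {"time": 0, "children": [], "leaf": i} for i in range(sample_size)
    ]
    active: dict[int, int] = {}
    for node_id, ind in enumerate(sample):
        if int(ind) in active:  # two sample slots on one individual: merge now
            prev = active[int(ind)]
            nodes.append({"time": 0, "children": [prev, node_id], "leaf": None})
            active[int(ind)] = len(nodes) - 1
        else:
            active[int(ind)] = node_id
    for g in range(1, gens + 1):
        if len(active) == 1:
            break
        pa = parents[gens - g]
        merged: dict[int, list[int]] = {}
        for ind, node_id in active.items():
            merged.setdefault(int(pa[ind]), []).append(node_id)
        active = {}
        for p, ids in merged.items():
            if len(ids) == 1:
                active[p] = ids[0]
            else:
                nodes.append({"time": g, "children": ids, "leaf": None})
                active[p] = len(nodes) - 1
    roots = list(active.values())
    parent_time = {}
    for node in nodes:
        for c in node["children"]:
            parent_time[c] = node["time"]
    rate = mu * length
    for attempt in range(30):
        positions, carrier_sets = _drop_wf_mutations(
            nodes, roots, parent_time, rate, length, rng, sample_size
        )
        if min_seg is None or len(positions) >= min_seg:
            break
        rate *= 2.0
    else:  # pragma: no cover - defensive
        raise ValidationError("could not reach requested segregating sites")
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    dosage = carrier_sets[order]
    samples = [f"s{i + 1:02d}" for i in range(sample_size)]
    ref, alt = _ref_alt_bases(positions)
    return GenotypeMatrix(
        np.array(["ctg01"] * len(positions), dtype=object),
        positions,
        ref,
        [(a,) for a in alt],
        samples,
        {s: 1 for s in samples},
        dosage,
    )


def _drop_wf_mutations(nodes, roots, parent_time, rate, length, rng, sample_size):
    """Poisson mutations on genealogy branches -> (positions, loci x samples)."""
    # leaves reachable below each node
    below: list[list[int]] = [[] for _ in nodes]
    for i, node in enumerate(nodes):
        if node["leaf"] is not None:
            below[i] = [node["leaf"]]
    # nodes were appended in time order, so children precede parents
    for i, node in enumerate(nodes):
        for c in node["children"]:
            below[i] = below[i] + below[c] if node["leaf"] is None else below[i]
    positions: list[int] = []
    rows: list[np.ndarray] = []
    used: set[int] = set()
    root_set = set(roots)
    for i, node in enumerate(nodes):
        if i in root_set or i not in parent_time:
            continue
        branch = parent_time[i] - node["time"]
        n_mut = rng.poisson(rate * branch)
        if n_mut == 0:
            continue
        carriers = np.zeros(sample_size, dtype=np.int16)
        carriers[below[i]] = 1
        for _ in range(int(n_mut)):
            p = int(rng.integers(0, length))
            while p in used:
                p = int(rng.integers(0, length))
            used.add(p)
            positions.append(p)
            rows.append(carriers)
    if not positions:
        return np.empty(0, dtype=np.int64), np.empty((0, sample_size), dtype=np.int16)
    pos = np.array(positions, dtype=np.int64)
    mat = np.vstack(rows)
    # deduplicate identical positions cannot happen (infinite sites); keep
    # only segregating columns for the sample
    seg = (mat.sum(axis=1) > 0) & (mat.sum(axis=1) < sample_size)
    return pos[seg], mat[seg]


def _wf_recombining(
    n: int,
    length: int,
    mu: float,
    rec: float,
    gens: int,
    sample_size: int,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    pop = np.zeros((n, 0), dtype=bool)
    pos = np.empty(0, dtype=np.int64)
    used: set[int] = set()
    genome_mu = mu * length
    genome_rec = rec * length
    for g in range(gens):
        par_a = rng.integers(0, n, size=n)
        par_b = rng.integers(0, n, size=n)
        n_cross = rng.poisson(genome_rec, size=n)
        new = pop[par_a].copy()
        for i in np.flatnonzero(n_cross):
            cuts = np.sort(rng.integers(0, length, size=n_cross[i]))
            take_b = (np.searchsorted(cuts, pos, side="right") % 2) == 1
            new[i, take_b] = pop[par_b[i], take_b]
        # new mutations: one carrier each
        n_new = rng.poisson(genome_mu, size=n)
        total = int(n_new.sum())
        if total:
            cols = np.zeros((n, total), dtype=bool)
            new_pos = np.empty(total, dtype=np.int64)
            k = 0
            for i in np.flatnonzero(n_new):
                for _ in range(int(n_new[i])):
                    p = int(rng.integers(0, length))
                    while p in used:
                        p = int(rng.integers(0, length))
                    used.add(p)
                    new_pos[k] = p
                    cols[i, k] = True
                    k += 1
            new = np.hstack([new, cols])
            pos = np.concatenate([pos, new_pos])
        pop = new
        if (g + 1) % 20 == 0 or g == gens - 1:
            counts = pop.sum(axis=0)
            keep = (counts > 0) & (counts < n)
            lost = pos[~keep & (counts == 0)]
            for p in lost:
                used.discard(int(p))  # lost sites may mutate again later
            pop = pop[:, keep]
            pos = pos[keep]
    sample = rng.choice(n, size=sample_size, replace=False)
    mat = pop[sample]
    counts = mat.sum(axis=0)
    seg = (counts > 0) & (counts < sample_size)
    mat = mat[:, seg]
    pos = pos[seg]
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    mat = mat[:, order]
    samples = [f"s{i + 1:02d}" for i in range(sample_size)]
    ref, alt = _ref_alt_bases(pos)
    return GenotypeMatrix(
        np.array(["ctg01"] * len(pos), dtype=object),
        pos,
        ref,
        [(a,) for a in alt],
        samples,
        {s: 1 for s in samples},
        mat.T.astype(np.int16),
    )


# ---------------------------------------------------------------------------
# one-call population simulation + on-disk export


def simulate_population(
    config: SimConfig,
) -> tuple[list[SimStrain], SimulationTruth, GenotypeMatrix]:
    """Simulate lineages, plant hybridizations and LOH, build the genotype matrix."""
    rng = np.random.default_rng(config.seed)
    haplotypes, tree, pool = simulate_clonal_haploids(config, rng)
    strains, truth = plant_hybridizations(haplotypes, tree, config, rng, pool)
    if config.loh_tracts:
        strains = plant_loh(strains, config.loh_tracts, config, rng)
    gm = genotype_matrix(strains, config)
    return strains, truth, gm


def _truth_to_json(truth: SimulationTruth) -> dict:
    return {
        "lineage_tree_newick": truth.lineage_tree_newick,
        "ploidy": truth.ploidy,
        "subgenome_lineage": {
            f"{sid}|{letter}": lin
            for (sid, letter), lin in truth.subgenome_lineage.items()
        },
        "events": [
            {"event_id": e.event_id, "parents": list(e.parents), "members": e.members}
            for e in truth.events
        ],
        "tetraploid_strain": truth.tetraploid_strain,
        "tetraploid_source_events": truth.tetraploid_source_events,
        "aneuploid_segments": [asdict(a) for a in truth.aneuploid_segments],
        "loh_tracts": [asdict(t) for t in truth.loh_tracts],
    }


def write_simulation(config: SimConfig, out_dir: str | Path) -> SimulationTruth:
    """Run the full simulator and write every artifact to ``out_dir``.

    Outputs: genotypes.vcf, regions/*.fasta, depth/<strain>.tsv,
    assembly_stats.tsv, strains.tsv, truth.json.
    """
    out = Path(out_dir)
    (out / "regions").mkdir(parents=True, exist_ok=True)
    (out / "depth").mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)
    haplotypes, tree, pool = simulate_clonal_haploids(config, rng)
    strains, truth = plant_hybridizations(haplotypes, tree, config, rng, pool)
    if config.loh_tracts:
        strains = plant_loh(strains, config.loh_tracts, config, rng)
    gm = genotype_matrix(strains, config)
    write_genotype_vcf(gm, out / "genotypes.vcf")
    for aln in region_alignments(strains, config, rng):
        write_fasta_alignment(aln.sequences, out / "regions" / f"{aln.region_id}.fasta")
    seg_by_strain: dict[str, list[AneuploidSegmentSpec]] = {}
    for seg in config.aneuploid_segments:
        seg_by_strain.setdefault(seg.strain_id, []).append(seg)
    loh_by_strain: dict[str, list[LOHTractSpec]] = {}
    for tract in config.loh_tracts:
        loh_by_strain.setdefault(tract.strain_id, []).append(tract)
    stats_rows = []
    for s in strains:
        raw = simulate_depth(
            s.ploidy,
            seg_by_strain.get(s.strain_id, []),
            config,
            rng,
            loh_by_strain.get(s.strain_id, []),
        )
        write_depth_tsv(raw, out / "depth" / f"{s.strain_id}.tsv")
        stats_rows.append(
            simulate_assembly_stats(s.ploidy, rng, strain_id=s.strain_id)
        )
    write_assembly_stats(stats_rows, out / "assembly_stats.tsv")
    write_strain_table(assign_metadata(strains, truth, config, rng), out / "strains.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1)
    return truth
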