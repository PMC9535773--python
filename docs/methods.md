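# Methods

This note documents the models and procedures implemented in `clonalpop`,
the parameters that matter, and what the synthetic data does and does not
emulate.

## The biological setting

The package targets populations with the following structure: a set of
haploid clonal lineages diverged at the percent scale; rare fusion events in
which two haploid genomes merge into a stable diploid whose subgenomes never
recombine with each other (no meiosis, no haploidization); and descendants
of each fusion event that differ from each other only by mutations
accumulated after the event — a separation of scales of one to two orders
of magnitude between post-hybridization and between-lineage divergence.
Aneuploid segments and loss-of-heterozygosity (LOH) tracts overlay this
structure in individual strains.

## Ploidy classification (`clonalpop.ploidy`)

Three criteria, each with a haploid band, a diploid band and a gap between:

| criterion | haploid | diploid | tetraploid |
|---|---|---|---|
| assembly size | < 31 Mbp | > 46 Mbp | > 80 Mbp |
| predicted genes | < 13,000 | > 18,000 | > 36,000 |
| core-BUSCO mean copy | < 1.1 | > 1.5 | > 1.5 |

A call is made only when all criteria agree; a value between bands or a
mixed pattern yields `unclear`. Core BUSCOs are those present (copy ≥ 1) in
every strain of the species set; the copy criterion is the arithmetic mean
copy number over that core set, computed with the strain under
classification included in the set. The tetraploid size/gene bands are this
package's own (the calibration cohort contained a single tetraploid); they
sit midway between the observed diploid and tetraploid values and are
configurable. The copy-number criterion deliberately has no tetraploid band:
BUSCO copy estimates in highly fragmented polyploid assemblies are noisy, so
size and gene count decide between diploid and tetraploid.

## LD decay (`clonalpop.ld_decay`)

Loci are filtered to biallelic sites whose minor allele is carried by at
least two strains (singletons carry no linkage information). For every
same-contig pair within `max_dist` (default 10,000 bp), r² is the squared
Pearson correlation of ploidy-scaled dosages (dosage/ploidy) across strains;
on phased haploid data this estimator equals the classical
D²/(p_A q_A p_B q_B) haplotype formula exactly, which the test suite asserts.
The genotype-dosage form is the default because real inputs are unphased
diploid VCFs.

Pairs are binned by distance (default 100 bp) and the bin means smoothed
with a tricube-weighted local mean (span: fraction of the distance range,
default 0.3). A generalized additive model would serve equally; the readout
— the smallest bin midpoint at which the smoothed curve falls below half of
its maximum — is robust to the smoother choice, which is why a simple local
mean is used. A curve that never crosses reports "not reached": the clonal
signature.

## Aneuploidy and LOH (`clonalpop.karyotype`)

Depth tracks are summarised as the per-window (default 30 kbp) weighted
median of the input depth values divided by the genome-wide weighted median
(both interpolated, to avoid integer snapping on discrete counts). Windows
are assigned to the nearest copy band k/ploidy (k = 1 … 2×ploidy) when
within `band_tolerance` (default 0.15) of it; maximal runs of at least
`min_run` (default 5) consecutive windows in one non-baseline band become
segments. The run-length procedure is the explicit form of what is usually
judged visually from depth plots; `band_tolerance` and `min_run` are the two
knobs introduced for that purpose, and 5 windows × 30 kbp = 150 kbp is the
package's own minimum segment size — there is no community-standard value.
The window statistic is the median by default (robust to coverage spikes);
a mean option exists because plot legends in the field sometimes average.

Heterozygosity tracks count heterozygous calls (0 < dosage < ploidy) in
25-kbp windows, normalised by the genome-wide median window count. Runs of
at least `min_run` windows below `loh_het_threshold` (default 0.1 of the
median) are LOH segments; their mean depth ratio — resampled onto the 25-kbp
grid by interval-weighted mean — classifies them as `deletion` (within
tolerance of 0.5), `copy_neutral` (within tolerance of 1.0) or `ambiguous`
otherwise. Ambiguous segments are reported, never dropped.

Median normalisation has one intrinsic caveat: if a large fraction of a
genome is aneuploid, the genome-wide median itself shifts and all ratios
shift with it. At the few-percent aneuploid fractions typical of real
genomes the effect is negligible; the simulator tests keep planted fractions
in that regime.

## Region trees and hybridization events (`clonalpop.phylo`)

Regions are filtered so that each strain contributes exactly as many
sequences as its ploidy (a diploid missing one subgenome would silently
collapse heterozygosity) and no sequence exceeds a gap-fraction threshold
(0.15 default, 0.25 for noisier assemblies); the n = 50 longest survivors
are used. Each region yields a neighbor-joining tree on p-distances
(gap-excluded fraction of differing columns). NJ is implemented with a
deterministic lexicographic tie-break and non-negative branch clamping, and
is used instead of maximum likelihood deliberately: the downstream readouts
(concordance, clade support, grouping) depend on topology only, and NJ is
consistent on additive distances — the test suite verifies exact recovery of
additive matrices up to 12 leaves and agreement with a brute-force
least-squares search over all topologies where enumeration is feasible.

Cross-region agreement is quantified two ways: clade support (the fraction
of region trees containing each clade, with a majority-rule consensus tree)
and a concordance score, the mean over tree pairs of 1 − normalized
Robinson–Foulds distance. A score of 1 means every region shares one
topology — the strong-phylogenetic-signal criterion for clonality.

Subgenome-to-lineage assignment uses the length-weighted average p-distance
across regions: single-linkage clustering at τ_lineage, which defaults to
half the median distance between haploid strains — far above the
post-hybridization scale and below between-lineage divergence. Clusters
containing a haploid strain take its name (sampled parent); pure-subgenome
clusters get synthetic `anc<N>` names (the unsampled or extinct parent
case). A subgenome whose own-cluster and nearest-other-cluster mean
distances differ by less than a tolerance (0.1 × τ_lineage) is flagged
ambiguous and left unassigned.

Diploids sharing the same unordered parental-lineage pair are linked when
both corresponding subgenome pairs lie within τ_event, defaulting to five
times the median within-cluster distance (the post-hybridization replicate
scale); connected components are hybridization events. Strains with
unassigned or same-cluster subgenomes are reported as unplaced. Tetraploids
are reported separately with their four lineage assignments. Because the
ambiguity criterion for near-threshold cases has no canonical value, the
component count under a range of τ_event values can be obtained by passing
the threshold explicitly.

## Enrichment (`clonalpop.enrichment`)

Groups × habitat (or continent) tables are tested with Fisher's exact test:
the exact two-sided hypergeometric sum for 2×2 tables, and for anything
larger a Monte-Carlo p-value — random fixed-margin tables generated by
permuting category labels over individuals, compared by fixed-margin table
probability, with the add-one estimator (1 + hits)/(n_sim + 1), which is
biased upward and therefore never anti-conservative. Default n_sim = 10,000
with a mandatory seed. No multiple-testing correction is applied (two tests
per species); raw p-values are reported.

## The synthetic-data generator (`clonalpop.synthetic`)

**Lineages.** A Yule genealogy over `n_haploid_lineages` (default 12),
height-normalised to 1, with all splits compressed into the oldest
`1 − terminal_branch_fraction` of the height (default fraction 0.5). With
the per-site scale `theta` (default 0.02) this bounds pairwise divergence in
[θ, 2θ] = [2%, 4%] — every pair of lineages is resolvably distinct, as in
the calibration populations. Mutations follow the infinite-sites model
(every site mutates at most once, enforced by a global position pool), which
matches the biallelic SNP-matrix assumptions downstream and makes count
oracles exact.

**Hybridization.** Each event fuses two distinct lineages; the F1 founder
first accumulates its own private mutations, then each of its 2–6
descendant strains adds further private mutations on both subgenomes, at a
scale set by `post_hybridization_divergence` (default 0.05%, i.e. 40–80×
below between-lineage divergence). Founder drift makes each event a coherent
clade and keeps two independent events on the same lineage pair
distinguishable. Subgenomes never recombine. Optionally one tetraploid is
formed by fusing diploids from two parent-disjoint events.

**Wright–Fisher contrast.** A forward haploid Wright–Fisher population
provides the clonal/recombining LD contrast. In clonal mode (r = 0) the
sample genealogy is traced exactly through the recorded parent indices and
mutations are dropped as a Poisson process on its branches — offspring are
perfect copies, so the four-gamete test cannot fail. With r > 0 haplotypes
are evolved explicitly and offspring are crossover mosaics of two parents.
Default scales used in the analyses: N = 200, 100-kbp genome, 2,000
generations (10 N, ample for coalescence of a 40-sample), mutation rate
adjusted upward if needed to reach a requested number of segregating sites.

**Depth.** Negative-binomial draws (dispersion 10 — real coverage is
overdispersed relative to Poisson) with mean `depth_mean × copy/ploidy`, one
draw per 100-bp fine window: per-base coverage is autocorrelated at read
scale, so ~100 bp is the effective independent unit. The resulting 30-kbp
window medians have ≈3–4% relative noise — substantially noisier than real
per-base tracks, so recovery results on synthetic data are conservative in
that respect.

**Assembly statistics.** Independent normals per ploidy centred on the
calibration cohort (haploid 26.52 ± 1.47 Mbp, 9,519 ± 665 genes, copy
1.00 ± 0.03; diploid 49.30 ± 1.74 Mbp, 20,417 ± 1,709 genes, copy
1.70 ± 0.08; tetraploid centred on 94.67 Mbp and 46,596 genes with spreads
chosen by this package, the cohort having had a single tetraploid). Note
that the diploid gene-count spread places ≈6% of ±2 SD draws below the
18,000-gene band edge; those draws are classified `unclear` — the
classifier's designed abstention, mirroring the borderline genomes of the
real cohorts — and never misassigned to the wrong ploidy.

**Labels.** Each event group and haploid lineage draws a preferred habitat
and continent; members adopt the preference with probability `label_bias`
(default 0.75), planting the group–habitat association the enrichment stage
detects.

**What the simulator does not emulate.** Read-level artifacts (mapping
bias, GC-coverage coupling, duplicate reads), genotyping error and missing
calls, indels and structural variation, gaps in alignments (the gap filter
is exercised with constructed fixtures instead), selection, and demography
beyond constant population size. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
generative model, not robustness to upstream bioinformatic noise.

## Numerical choices

Coordinates are 0-based half-open everywhere internally; VCF positions are
converted on read/write. Dosage uses −1 as the missing sentinel. Distances
use pairwise-complete loci; PCA mean-imputes missing dosages per locus and
reports eigenvalue shares of the total variance. NJ clamps negative branch
lengths to zero and breaks Q-criterion ties by the lexicographically
smallest subtree representatives, making trees deterministic. Weighted
medians interpolate (midpoint rule). The Monte-Carlo Fisher comparison uses
a 10⁻⁹ log-probability slack when comparing table probabilities to avoid
floating-point ties. All generators accept a single integer seed;
identical configurations produce bit-identical outputs, which the test
suite asserts at the file level.

## Problem sizes used in the shipped analyses

The acceptance script and test suite run the LD analysis at N = 200 with
40 samples and ≥ 2,000 segregating sites over 100 kbp (five replicates),
event recovery at the 12-lineage / 7-event / 2–6-descendant configuration
(20 replicates in the tests), karyotype recovery on 6-Mbp genomes with
8-window planted segments (20 replicates), and the ploidy classifier on
1,000 truncated draws per ploidy. These sizes were chosen so each check is
statistically meaningful while the whole suite runs in about two minutes.
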