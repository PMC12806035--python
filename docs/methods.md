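# Methods

This note records the model, its assumptions, the default parameters and
the design decisions behind `mtlineage`, in the spirit of a simulator's
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Intracellular model

A cell's mtDNA is a multiset of *haplotypes* (sets of variants carried by
one molecule) with copy counts; the total copy number at birth is N
(default 500, a typical somatic value; config-exposed). Variants are
(position, allele) pairs on an abstract reference of length L = 16,569 bp;
the reference base of a site is a fixed periodic assignment, so each site
has three possible alternate alleles. The model is finite-sites: the same
variant can recur in independent lineages (homoplasy), while a second hit
at an already-mutated site of the *same molecule* is redrawn.

**Replication.** A division first doubles the pool from C to 2C molecules.
`strict_doubling` copies every molecule exactly once. `relaxed` performs C
sequential replication events whose templates are drawn uniformly *with
replacement from the growing pool* (a Pólya-urn scheme) — the simplest
process in which some molecules replicate several times and others not at
all, which is what "relaxed replication" of mtDNA means; it adds
replication noise on top of segregation noise. Each replication event adds
K ~ Poisson(μ·L) de-novo variants (default μ = 1e-7 per site per
replication, i.e. ~1.7e-3 expected variants per event; mtDNA mutates one
to two orders of magnitude faster than nuclear DNA, and this default is a
placeholder in that range that should be set explicitly for quantitative
work). In strict mode the per-event Poisson draws are realised through the
exact equivalence "sum of C Poisson(μL) counts = Poisson(C·μL) total, each
mutation landing on a uniform event", which the Poisson-count test
exercises.

**Segregation.** The doubled pool is partitioned uniformly into two halves
(multivariate hypergeometric over haplotype counts). This yields the exact
daughter-VAF variance p(1−p)/(2N−1) and makes neutral VAF a martingale;
both are closed forms in `theory.py` and are checked against the simulator
by Monte Carlo, and the fixation probability of a neutral variant (its
current frequency) is verified against an exact absorbing-Markov-chain
solve of the drift chain for small N.

**Bottleneck.** If configured, each daughter passes through a bottleneck
immediately after segregation: b surviving molecules sampled without
replacement, then relaxed re-expansion back to N (which can itself add
mutations). Applying it inside division keeps the copy-number invariant
(every cell is born with N copies) simple.

**Transfer.** Horizontal transfer moves k molecules (without replacement)
from donor to recipient — *move* semantics, so both cells' VAFs change and
per-variant copies are conserved across the pair. Transfer deliberately
breaks the equal-copy-number invariant; when it is enabled the doubling
step therefore operates on the cell's current copy number instead of
insisting on N.

## Tissue model

Development is a founder expanding through g synchronous divisions
(2^g cells, all at division depth g). Adult homeostasis is a Moran
process: per step one uniformly chosen cell divides and one cell chosen
uniformly among the *other* pre-division cells dies (a daughter never dies
in its birth step), keeping the size constant while the number of
surviving founder-era lineages decays — the test suite checks this decay
is monotone in the number of steps. A synchronous-culling alternative
(every cell divides, a uniform half survives) is available behind
`renewal_mode`. Branch lengths are integer division counts, not wall-clock
time, because mutations accrue per replication.

The recorded genealogy is pruned to any cell sample by suppressing
unifurcations (summing branch lengths); the result is rooted at the sample
MRCA. Reconstructed trees are unrooted, so all truth/reconstruction
comparisons use cophenetic (path) distances, which are rooting-invariant.

**RNG discipline.** One root integer seed; every cell's division stream is
keyed by (seed, cell id) via numpy `SeedSequence` spawn keys, and cell ids
use binary-heap labelling (children 2i+1, 2i+2), so outputs are bit-stable
and independent of iteration order. Population-level choices (Moran picks,
sampling, sequencing) use separate keyed streams.

## Sequencing model

Per cell-variant entry with true VAF p: coverage ~ Poisson(depth) (a
`fixed` mode exists for closed-form tests), alt ~ Binomial(cov, q) with
q = p(1−e) + (1−p)e/3 (per-read miscall rate e, default 0, split evenly
over the three alternative bases), and a call requires
alt ≥ support_threshold (default 2) — the literal "supported by at least
two reads" rule, applied per cell-variant. "50×" is interpreted as mean
per-site depth. The detection probability at fixed coverage is the
binomial upper tail in `theory.py`; at 1% VAF and 50× with 2-read support
it is ≈ 0.089, which is why sub-percent heteroplasmies effectively vanish
from sequenced matrices.

The VAF > cutoff filter (default 0.01) is applied per matrix *entry*
(strictly greater survives), then all-zero columns are dropped; it is
idempotent. The empirical clone-informative filter selects variants with
heteroplasmy ≥ 5% in ≥ 80% of some predefined clone's cells. The WGS
coverage helper implements reads × fraction × bases-per-pair / L with
bases_per_pair defaulting to 300 (PE150).

## Reconstruction

Cell-cell distances over VAF vectors: euclidean (the generic default of
`vaf_distance`), manhattan, or `jaccard_binarized` (one minus the Jaccard
index of variant presence sets, presence = VAF > 0; two variant-free cells
are at distance 0). Neighbor joining is the classical O(n³) agglomeration
on the Q-criterion with standard limb lengths, per-join clamping of
negative limbs to zero, and deterministic tie-breaking by smallest label
pair; n = 2 returns the trivial one-edge tree. NJ's consistency on
additive matrices is the module's primary oracle (random integer-branch
trees are recovered with Robinson–Foulds distance 0 and path distances to
1e-9), and an independent implementation (scikit-bio's `nj`) is used as a
cross-check on noisy matrices. Newick output is canonical: children sorted
by smallest descendant label, integer-valued lengths written as integers.

## Evaluation metrics

**Clone assignment.** Tips of the truth tree are split into k = 20 clades
of similar size by greedy largest-clade splitting from the root's
children. Every clone is a clade and the procedure is deterministic.

**Clone aggregation score.** No standard formula exists in the
literature we operationalise here, so the definition is deliberately
isolated in one function: for clone c with n_c ≥ 2 tips, CAS(c) is the
mean over its tips of the same-clone fraction among the tip's
m = n_c − 1 nearest other tips by reconstructed cophenetic distance
(ties by label; singleton clones score 1 by convention). It is 1 for a
perfectly monophyletic clone in an ultrametric reconstruction and has
expectation (n_c − 1)/(n − 1) under random labels — the two properties
all sanity checks rely on. Caveat: on strongly non-ultrametric trees a
deep intra-clade split can put an outside tip nearer than a clade-mate,
so identity reconstruction is only guaranteed CAS = 1 on ultrametric
truth trees (e.g. pure synchronous growth); the sanity checks use that
setting. Per-cell scores are reported alongside per-clone ones.

**Closest-pair ground-truth distance.** For each tip, its nearest
neighbour in the reconstruction is found (ties by label) and the pair's
path distance in the truth tree, in divisions, is reported; identity
reconstruction attains each tip's true nearest-relative distance, and
shuffled labels recover the mean distance to a random other tip. A
`terminal_edges` mode instead sums the pair's two terminal truth-tree
edges, covering the alternative reading of "terminal branch length". Both
metrics depend only on distance *ranks* in the reconstruction plus truth
distances, hence are invariant to rerooting and uniform rescaling of the
reconstruction (property-tested).

## Benchmark design

One replicate: simulate, sample, then score three matrices of the same
cells — `all_vaf` (exact heteroplasmies), `vaf_gt_cutoff` (entries ≤ 0.01
zeroed), `sequenced` (50×, 2-read support). Replicates use independent
31-bit seeds derived from the root seed; paired per-replicate mean
differences are tested with one-sided sign tests.

**Metric choice.** The benchmark preset uses `jaccard_binarized`. This is
an a-priori design decision, not a fit: the benchmark's contrast is the
inclusion or exclusion of variants at VAF ≤ 0.01, and under a
squared-magnitude metric such a variant contributes O(1e-5) to a pairwise
distance — the conditions would differ only negligibly through the very
quantity they manipulate. A presence-based metric lets low-frequency
variants act with full weight, which is also how mtDNA barcodes are used
for clonal grouping in practice. The generic `vaf_distance` default stays
euclidean; the metric is a flag recorded in every run manifest.

**Problem sizes.** The benchmark preset (`desk`) uses g = 8 (256 cells),
1000 renewal steps, 100 sampled cells, N = 500, μ = 1e-7, depth 50,
support 2, cutoff 0.01, k = 20, 20 replicates — a desk-scale setting
chosen once so the full replicated benchmark runs in well under a minute.
A full-size `full` preset (1024 cells, 2000 steps, 200 sampled) is
provided for longer runs, and a `tiny` preset for smoke tests. Monte-Carlo
sizes elsewhere (1e5 divisions for the variance law, 1e4 lineages for
fixation, 1e6 replication events for the Poisson law, 100 random trees for
NJ) are set so each check resolves its target well within three standard
errors.

## What the generator does and does not emulate

The simulator captures neutral intracellular drift, lineage erosion under
homeostasis, and depth/support censoring — the minimal machinery needed to
ask how much lineage signal VAF matrices retain. It deliberately omits:
selection on variants or cells (no purifying selection against deleterious
heteroplasmies), copy-number variation between cells and over the cell
cycle, mutational signatures and strand asymmetry, modality-specific
coverage profiles (cDNA-restricted coverage, ATAC insertion bias, UMI
consensus calling), RNA editing artifacts, and spatial structure. Passing
benchmarks here therefore speak to the *population-genetic* limits of
mtDNA lineage tracing, not to platform-specific artifacts of any
particular assay.

## Numerical notes

* Q-matrix minima are searched over the strict upper triangle because
  floating-point evaluation order makes Q asymmetric in the last ulp.
* Observed VAF with zero coverage is 0; Jaccard distance between two
  empty variant sets is 0.
* A VAF matrix with zero variants yields an all-zero distance matrix with
  a warning (reconstruction on it is a star and scores at the null level).
* `make_founder` places round(f·N) copies of each pre-existing variant,
  independently across variants, so co-occurrence on molecules is random.
* Branch lengths are floats holding integer division counts; the Newick
  writer prints them as integers.
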