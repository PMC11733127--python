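# Methods

This note documents the models, conventions and numerical choices
behind `culturomix`, in the order the pipeline uses them.

## Data model and conventions

Relative abundances are stored as fractions in [0, 1]; percentages
appear only in printed summaries. `AbundanceTable` carries an explicit
mode: `counts` (non-negative integers), `fraction` (each row sums to 1
within 1e-9, or is all-zero), or `functional` (non-negative reals with
no row-sum constraint). The third mode exists because KO functional
abundance is defined here as the *unnormalized* sum of the carrier
taxa's fractions — a KO table is not a closed composition, and
aggregated/profile tables reuse the same relaxation.

All-zero samples are retained everywhere (empty plates are real
observations: per-sample richness can legitimately be 0); operations
that cannot handle them (Hellinger transform, ordination) drop them
with a warning rather than failing. Detection means "fraction strictly
greater than a threshold", default 0 — any nonzero abundance counts —
with the threshold exposed as a parameter throughout. Features missing
from a taxonomy aggregate into an explicit `unassigned` bucket, since
mOTU taxonomies are routinely incomplete. Writers emit tab-separated
UTF-8 with lexicographic feature order, so outputs are byte-identical
across runs.

## Hellinger distance

All distance-based analyses use the Hellinger distance: Euclidean
distance between square roots of closed compositions. It is bounded by
√2 (attained on disjoint supports), insensitive to double zeros, and
embeds in Euclidean space, which licenses PCA, UPGMA and
centroid-based dispersion tests downstream.

## Faith's phylogenetic diversity

PD of a sample is the sum of branch lengths over the union of
root-to-leaf paths of its detected taxa, *root-inclusive* by default
(the path connecting the set's ancestor to the tree root is counted,
matching the behavior of the common ecology libraries; a
`include_root=False` variant sums only below the most recent common
ancestor). The empty set has PD 0.

## Permutation tests

Mantel (Pearson r over off-diagonal entries, two-sided), PERMANOVA
(pseudo-F from sums of squared distances) and PERMDISP (ANOVA F on
distances to group centroids in PCoA space) share one protocol:
seeded `numpy` Generator, default 999 permutations, Monte-Carlo
p-value `(exceedances + 1) / (permutations + 1)` — never zero. For
small problems (n ≤ 8 objects, or few distinct label assignments) an
exhaustive mode enumerates every relabeling and reports the exact tail
probability (identity included, so still positive); this is what the
oracle tests compare against.

PERMDISP follows Anderson's procedure: samples are embedded by
principal coordinates (negative-eigenvalue axes truncated — for
Hellinger distances these are numerical noise, since the distance is
Euclidean-embeddable), each sample's distance to its *group centroid*
is computed once, and group labels are permuted over those distances.
Centroids, not spatial medians, are used; singleton groups contribute
a zero dispersion rather than an error.

The variance ratio for modification *m* is
`W_m / B` where `W_m` sums, over features, the unbiased variance of
abundances across donors at *m*, and `B` sums, over features, the
variance across modifications of the donor-mean profile. A low ratio
means the modification pushes all donors toward a similar composition
relative to how much modifications differ from one another. `B = 0`
flags the ratios undefined (NaN) instead of dividing. The ratio is
invariant under global rescaling of abundances (both terms scale with
the square of the factor).

UPGMA clustering sorts labels lexicographically before linkage so tie
breaking, and hence the dendrogram, is deterministic; the cophenetic
correlation is the Pearson r between original and cophenetic
distances over pairs.

## Growth profiles and phylogenetic association

A taxon's growth profile is its mean relative abundance per
modification, averaged over donors (a per-donor mode keeps one column
per donor × modification). Two complementary comparisons are
provided:

* `rank_distance_distribution` — profiles *aggregated* to a rank, all
  pairwise Hellinger distances within the rank (profiles renormalized
  inside the transform, so only profile *shape* matters). Useful as a
  descriptive summary, but note a structural caveat: aggregation
  averages many taxa into smooth, mutually similar profiles, so
  coarser ranks have systematically *smaller* pairwise distances
  regardless of any biological signal. This construction therefore
  cannot, even in principle, show species-level profiles as the most
  similar.
* `relatedness_distance_distribution` — the direct test of "more
  closely related taxa have more similar growth profiles": pairwise
  distances between *species-level* profiles, stratified by the rank
  a pair shares — within one phylum, one family, one genus, and
  (comparing donor-specific profiles of the same taxon) within one
  species. Under phylogenetic signal the stratum medians decrease
  from phylum to species; with the phylogenetically structured
  generator components switched off, the phylum/family/genus strata
  are exchangeable and their ordering is at chance. The species
  stratum is excluded from that null check: the same taxon responds
  identically to a modification in every donor by construction, so
  its stratum sits low with or without phylogenetic signal.

## The combination-design engine

Scores follow the three printed formulas exactly (see README),
including the 1/n prefactor inside `MRA_total`. A consequence worth
knowing: with detection threshold 0 and closed per-sample
compositions, the union of detected features covers each sample's
whole mass, so `MRA_total = 1/n` identically and the ranking reduces
to maximizing the *sum* of the target's relative abundances over the
combination — larger combinations where the target persists win. A
`total_prefactor=False` variant (plain mean of per-feature means,
making `MRA_total ≈ 1`) is available for sensitivity analysis and is
off by default.

Ranking order: ratio descending, then detected-feature count `m`
ascending, then `MRA_target` descending, then the lexicographic
modification tuple — fully deterministic and invariant to enumeration
order. Subsets are enumerated lazily by size and scored in vectorized
chunks (2048 combinations at a time) into a bounded top-N selection,
so memory is constant in the number of candidates. Per-donor scoring
is primary; pooled mode averages donor fractions per modification
first. Pruning the candidate pool to modifications where the target
is detected in at least one donor is on by default — it mirrors how a
practitioner combines exactly the media a target grew on — and
`prune=False` streams the full enumeration.

## Synthetic communities

The generator emulates the statistical structure of a real campaign:

* **Phylogeny** — a Yule (pure-birth) topology grown by uniform leaf
  splitting, with i.i.d. Exponential(mean 0.1) branch lengths. Trees
  are not ultrametric; all lengths are positive.
* **Taxonomy** — ranks derived by cutting the tree at five increasing
  depths (defaults at fractions 0.07/0.16/0.28/0.44/0.62 of tree
  height, chosen so a 150-leaf tree yields realistic counts of
  roughly 6 phyla and 120 genera, echoing the ~10 phyla per few
  hundred species seen in real gut catalogs). Labels nest by
  construction.
* **Baselines** — donor × taxon weights from a shared log-normal core
  (σ = 1.5) times a donor-specific log-normal perturbation (σ = 0.8),
  so donor identity dominates composition while modifications still
  shift it.
* **Modification effects** — per modification, log growth multipliers
  are a Brownian-motion draw on the tree (each edge contributes
  N(0, σ_phylo² · length) shared by its descendants; leaf-pair
  covariance is σ_phylo² × shared root-path length) plus
  N(0, σ_iid²) i.i.d. noise; defaults σ_phylo = 1.0, σ_iid = 0.4.
  With probability p_kill = 0.3 a uniformly chosen internal (non-root)
  clade is killed outright, emulating the phylogenetically coherent
  losses antibiotic-like modifications cause. The base medium has
  zero effects and no kills.
* **Planted target** — a taxon from the lower quartile of the shared
  baseline core (low-abundance, like the hard-to-culture species that
  motivate targeted enrichment) gets +delta (default 4 log units,
  ~55×) in a random supporting set of 5 modifications and is excused
  from kills there. The supporting set is the ground truth design
  runs are scored against.
* **Sequencing** — each culture plate draws `depth` (default 5 × 10⁴)
  multinomial reads from the closed product of baseline × growth
  multiplier; one stool sample per donor draws from the closed
  baselines alone. Every stochastic step takes an explicit seed, and
  identical seeds give bit-identical bundles.

Default dimensions (150 taxa, 6 donors, 20 modifications + base) are
a desk-scale analog of a 6-donor × 50-modification campaign;
full-size generation is a matter of parameters.

**What the simulator does and does not capture.** It reproduces
donor-dominated composition, phylogenetically structured modification
preferences, clade-level kills, compositional closure and
depth-limited detection. It does not model ecological interactions
beyond closure (competition, cross-feeding), strain-level variation,
plate-scraping/extraction noise (no quantitative model of these steps
exists to emulate; multinomial-at-depth is a package choice), or the
extreme sparsity of real plates — with the log-normal baseline widths
above, most of the 150 taxa are detected in most samples, whereas
real campaigns detect only a small fraction of the catalog per plate.
Passing recovery tests therefore demonstrate correctness of the
design machinery under the modeled noise, not performance guarantees
on real data.

## Problem sizes and calibration constants

The validation suites use: 200 random (tree, subset) instances for the
Faith's-PD oracle; full 24-permutation enumeration at n = 4 for
Mantel; 100 random univariate datasets for the PERMANOVA/ANOVA
equivalence; random instances with ≤ 8 modifications for the ranking
oracle; and 50 simulated campaigns at the default generator settings
for design recovery (pass criterion: pooled top-1 vs planted set
Jaccard > 0.5 in ≥ 90% of replicates) and for the phylogeny–growth
association (monotone stratum medians in ≥ 80% of seeds under strong
signal, chance-level ordering under the null). The 90%/80% thresholds
are repository calibration constants describing the generator's
defaults, not claims about real data.

## Known limitations

* The variance-ratio grouping admits more than one reading when there
  is exactly one sample per donor × modification; the implemented
  definition (across-donor variance at a modification ÷
  across-modification variance of donor-mean profiles) is the one
  under which "low ratio = modification dominates donors".
* Whether PD should include the root path, and whether dispersion
  tests should use centroids or spatial medians, are conventions;
  both defaults are stated above and the PD convention is a flag.
* The aggregated rank-distance summary is kept for completeness but,
  per the caveat above, should not be used to infer phylogenetic
  signal; use the relatedness-stratified distribution.
* ANCOM-style differential abundance, rarefaction, Shannon/Simpson
  indices and network/graphics dashboards are out of scope; outputs
  are TSV/JSON for downstream tooling.
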