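# Methods

`ghfcooc` analyses the joint distribution of glycoside hydrolase (GH)
gene families across prokaryotic genomes: which families tend to occur
in the same species, how those co-occurrences organise into modules,
and how the modules map onto enzymatic functions.  This note records
the models, conventions and numerical choices behind each stage.

## Input model and bias control

The unit of observation is a sequenced strain: taxonomy labels
(species, genus, domain, phylum) plus a non-negative integer gene count
for each GH family (GHF).  Genome collections over-represent a few
heavily sequenced species, so across-species statistics are computed on
species-level matrices, one row per species (per genus for strains with
no species name):

* **aveF** — the per-family arithmetic mean over a species' strains,
  rounded to an integer.  Rounding is half-away-from-zero (2.5 → 3),
  not banker's rounding; the convention is stated so tests can be
  exact, and it matches common spreadsheet behaviour.
* **minF / maxF** — the complete count vector of the single strain
  with the fewest / most *distinct* families present (counts ≥ 1).
  "Fewest families" is the number of families, not total genes.  Ties
  are broken by strain name: minF takes the name that sorts first,
  maxF the one that sorts last.  Collation is case-insensitive by
  Unicode code point after case folding — deterministic and
  locale-free, one consistent reading of alphabetic order.  The result
  is independent of input record order.

All three matrices share the same rows and the union of all observed
family columns, zero-filled; an optional post-step drops all-zero
columns (downstream correlation skips zero-variance columns anyway).

## Occurrence statistics

For a family and a domain (bacteria or archaea), the occurrence
frequency is `n_species_with_≥1_gene / n_species`, and the average
gene number is `total_genes / n_species_with_≥1_gene`, so the average
is ≥ 1 whenever defined and is not deflated for rare families.  Both
use aveF.  Robustness flags — "frequency at least 5 percentage points
higher in one domain", "average at least one copy larger" — are granted
only when the condition holds in aveF, minF and maxF alike; the plain
higher-frequency call uses aveF only.  "5% higher" is an absolute gap
in percentage points, not a ratio.  For the one-copy comparison a
family absent from a domain counts as 0 copies there.

## Co-occurrence edges

Each unordered family pair receives a tie-corrected Spearman rank
correlation per matrix (mid-ranks, then Pearson), with a two-sided
p-value from the t approximation on n − 2 degrees of freedom.  A pair
is a **validated edge** only if rho > 0.45 and p < 0.001 in *all
three* matrices; demanding agreement between the average profile and
both extreme strain choices removes edges that depend on which strain
happened to represent a species.  Strength classes follow the aveF
coefficient: strong (> 0.6), moderate-high (0.5–0.6], moderate-low
(0.45–0.5].  No multiple-testing correction is applied by default —
the rule is a raw dual threshold — but Benjamini–Hochberg adjustment
is available.  Constant columns are skipped and logged rather than
failing the run; pairs not computable in every matrix are reported
unvalidated with a reason code.  The species-level network uses the
same machinery on aveF rows with rho > 0.8, p < 0.001.

## Networks, modules, topology

Validated edges form a simple weighted undirected graph (weight = the
aveF rho); nodes exist only through edges, so unconnected families
never enter the graph.  Modules come from Louvain modularity
maximisation on edge weights at resolution 1, with a required,
recorded seed: a given seed reproduces the partition exactly, which is
the strongest determinism a greedy heuristic admits.  Modularity is
the weighted Newman–Girvan Q; values above roughly 0.4 indicate
modular structure.  Topology metrics follow common
network-visualisation defaults: the clustering coefficient is the
unweighted mean local coefficient over all nodes (degree < 2
contributes 0); average path length and diameter are unweighted hop
counts on the largest connected component.  These conventions are
echoed in the summary metadata.

## Functional groups and type-X microbes

Twelve curated groups (A–L) ship with the package: nine network
modules, three of which are subdivided by primary enzyme function
(bulk lignocellulose A vs pectin-debranching B; hexosaminidases G vs
alpha-glycosidases H; fungal cell wall K vs supplemental
lignocellulose L).  The subdivision rests on literature-curated enzyme
annotations and is therefore configuration, not inference.  GH55 and
GH64 (endo/exo-β-1,3-glucanases) belong to both K and L and count
toward both in fit scoring and dose sums; GH144 is deliberately
ungrouped.  One documented tension in the curation: the group-E module
is sometimes discussed as five families (GH137/138/139/142/143) while
the packaged table carries six, adding GH141; the table is taken as
authoritative and the discrepancy recorded here rather than resolved.

A species **fits** group X at level *partial* when ≥ 2 member families
are present, *large* when ≥ 75 % are (threshold `ceil(0.75·size)`, and
never below 2), *perfect* when all are — so perfect ⇒ large ⇒ partial,
and the three levels coincide for two-family groups.  Prevalence
tables default to the partial level.  Collection overlap reports
|X∩Y|/|Y| plus an exact-subset flag; an empty Y is covered vacuously.

## Gene-dose matrix (aveG)

Per species, member-family aveF counts are summed per group (shared
families counted in each listing group).  For display the sums are
square-rooted — compressing the long right tail of gene doses — and
each species row is z-scored with the population (n) standard
deviation, so a row shows which functions are enriched relative to
that species' own profile.  Constant vectors map to zeros (detected by
an exact max = min test, immune to floating-point SD residue).  The
square root is applied strictly before the z-score.  Row-wise
normalisation is the default; a per-column option exists because
either axis is a defensible heatmap convention, and the choice is
recorded in the output metadata.  Subsetting to a species list (e.g.
known cellulolytic bacteria) re-transforms on the subset.

## Mirror-tree statistic

Co-evolution between two protein families is screened as the Pearson
correlation between their inter-protein distance matrices, matched
over the shared organisms and compared over the strict lower triangle
(n ≥ 4 organisms required).  The p-value is the two-sided t-test on
C(n,2) pairs; those pairs are not independent, so it is an optimistic
screening value and is labelled as such.  Inputs are PHYLIP square
distance matrices; homolog search, alignment and tree building are out
of scope.

## Synthetic communities and what they show

The generator plants known structure in otherwise realistic-looking
profiles.  Defaults — the package's study conditions — are 500
species with 1–3 strains each, 60 families, 5 planted groups of 6
families (activation probability 0.5 per species and group,
within-group presence 0.95), background presence 0.03, gene counts
1 + Poisson(λ−1) with λ = 2, strain-level dropout/duplication noise
0.05, and 6 % archaea.  The sizes are chosen so a full pipeline run
takes well under a second while giving the correlation estimates
n = 500 observations; activation at 0.5 maximises presence variance
and hence the planted rank correlations.  Optionally each planted
group prefers one phylum (its activation multiplied there), which
reproduces the module–phylum correspondence seen in species networks.
Strain noise only perturbs families already present in the species
profile — dropout or duplication — so minF/maxF selection remains
meaningful; spontaneous strain-level gains are not modelled.

The planted truth (which species activated which groups) yields the
expected validated pairs (all within-group pairs of any group
activated in ≥ 2 species) and the family→group labels for adjusted
Rand scoring of detected modules, restricted to planted families that
entered the network.  By convention an empty edge prediction has
precision 1 with a flag, recall 0.

What passing recovery tests shows: the three-matrix rule and Louvain
pipeline reliably recover block-structured presence/absence signal of
this strength from zero-inflated counts, and produce essentially no
edges (≤ 1 % of pairs) when no structure is planted.  What it does not
show: performance on real genome snapshots, whose family marginals are
heavy-tailed and phylogenetically autocorrelated in ways the generator
does not attempt to fit — common descent, lateral transfer and shared
habitat all correlate families beyond the planted-block model.

## Degenerate inputs and tie-breaks

Constant vectors raise (scalar correlation) or are skipped with a log
line (matrix-level); empty matrices cannot be written; a strain with
neither species nor genus is an error; mixed domains within one
species group are an error naming the group.  Louvain module ids are
renumbered by size then smallest member, so equal seeds give equal
files byte-for-byte.  The end-to-end driver writes JSON with sorted
keys and no timestamps for the same reason.

## Known limitations

* Spearman p-values use the t approximation everywhere; for the
  smallest communities an exact permutation test would be preferable.
* The species network on thousands of rows computes a dense rank
  correlation matrix (O(n²) memory); fine to a few thousand species.
* Group curation is frozen configuration; re-deriving it from a new
  network requires the user to supply the module→group split.
* The mirror-tree p-value inherits the non-independence caveat above.
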