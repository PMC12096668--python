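# Methods

This note records the models, rules and numerical choices behind each
module, the assumptions the synthetic generator makes, and the limits of
what passing tests demonstrate.

## Trees and supports (`phylo_io`)

Node supports live on the 0–100 scale throughout: MPBP (maximum parsimony
bootstrap proportion), MLBS (maximum likelihood bootstrap support) and BPP
(Bayesian posterior probability, ×100). Support-label dialects describe how
`/`-separated tokens on internal-node labels map to those fields; the
adaptive triple dialect follows the common concatenated-tree convention
that a two-token label means MLBS/BPP. Posterior probabilities supplied on
the [0, 1] scale are rescaled on read when `bpp_as_probability=True`.

Trees are stored rooted as parsed, but all cross-tree clade comparison is
done on *unrooted* bipartitions, so root placement can never change a
concordance verdict. A clade is compared against a locus tree by first
restricting it to that tree's taxon set (loci rarely share identical
specimen coverage); restrictions with fewer than two members count as
absent, and a restriction whose complement is a single taxon is a trivial
split displayed by every tree.

Supermatrix concatenation pads missing taxa with `?` (distinct from the
alignment gap `-`, so unsequenced loci are distinguishable from indels).
Partition coordinates are 0-based half-open internally and exported 1-based
inclusive, the convention of the usual partition-file formats. The bundled
six aligned lengths (755, 1283, 1452, 1338, 1160, 893 bp) sum to 6,881 bp;
the concatenation reports whatever its inputs sum to.

## Grouping (`concordance`)

Two splits of one universe are compatible iff one of A⊆B, B⊆A, A∩B=∅,
A∪B=U holds; `conflicts` is the negation and is verified in tests against
brute-force enumeration of every tree topology on up to six taxa.
Majority-rule consensus retains bipartitions whose frequency strictly
exceeds the threshold (≥ 0.5 guarantees mutual compatibility), annotated
with frequency × 100.

Three IEL rules are implemented. The operative default is the
conservative-locus (modified) rule: a clade is an IEL at a locus iff it
occurs in both that locus's MP and Bayesian consensus trees with MPBP ≥ 70
and BPP ≥ 95, ties passing. Classical concordance (presence in ≥ 3/4 of
loci, implemented as ≥ ceil(f·L); six loci → five) and nondiscordance
(well-supported somewhere, contradicted nowhere by a clade that is itself
well supported at the same thresholds) are selectable. With L loci the
majority denominator counts all loci by default; a conserved backbone locus
can be excluded via `exclude_loci`.

Published support tables list sub-threshold cells (MPBP 33, 50, 51, 63) as
IELs when the same clade passes the thresholds elsewhere; the direct cell
counts also disagree with the printed resolution row at two loci (rpb1: 10
countable vs 11 printed; tef1α: 10 vs 9). Rather than guess the intended
rule, `strict_thresholds=False` reproduces the lenient reading (a present
cell is an IEL when the clade passes at ≥ 1 locus) and the default stays
strict. Only the two internally consistent columns (actin 12/15, hisps
13/15) are asserted against the published row.

## Ranking (`ranking`)

Candidates are species-tree clades with evidence: route (a), IEL at ≥ 1
locus, or route (b), BPP ≥ 95 and MPBP-or-MLBS ≥ 70 on the species tree.
The full ingroup and clades containing outgroup taxa are never candidates.
"Well differentiated" has no numeric definition in the GCPSR literature;
it is operationalized as the candidate test plus most-inclusive-first
acceptance on a deterministic preorder traversal (children ordered by
smallest member label): a candidate nested inside an accepted species is
recorded as absorbed substructure, not ranked. This reproduces both
behaviours a ranking rule must show — a weakly supported species rescued by
its IELs remains separate from its strongly supported sister, while two
mating groups with no differentiating clade collapse into one phylogenetic
species. Divergent substructures (the "possible subspecies" situation) are
recorded but never promoted; no rule for promoting them is invented.

Exhaustive subdivision: leaves covered by no accepted candidate form
maximal unassigned subtrees, each becoming its own species flagged
`residual` (default), or merged into the nearest assigned species
(`ATTACH_SISTER`). The loud default is deliberate: silently attaching
unplaced individuals would hide delimitation failures.

Partition comparison classifies connected components of the group
intersection graph into identical pairs, k→1 mergers, 1→k splits, and
complex overlaps.

## Mating (`mating`)

IF% is the share of pairings scored crustose-diploid, IS% the share scored
black-line or white-fluffy, and N counts *all* pairing attempts including
unscored ones — which is why published rows can have IF + IS < 100.
Comparisons use full precision; only display rounds to one decimal.

Intersterility groups are connected components of the tester graph with an
edge where a pair's interfertile proportion (over all its replicate
pairings) reaches `edge_threshold` = 0.5. Components, not cliques, because
haploid tester compatibility is treated as transitive and components
tolerate sparse pairing designs; average-linkage agglomeration is available
for dense matrices. No numeric threshold separating "same group" from
"gene flow between groups" exists in the literature; 0.5 is this package's
default and is exposed in configuration. Cross-component interfertile
pairs are always retained as gene-flow evidence, and `gene_flow_report`
lists group pairs above a reporting floor (default 10%) in descending
order.

Unknown isolates are assigned to the tester panel with maximal IF%, with
an ambiguity flag when ≥ 2 panels exceed the edge threshold, the top two
panels are within 10 points, or residual intersterility with even the best
panel reaches 25% — the last condition marks divergent lineages that can
only be assigned tentatively.

## Morphometry (`morphometry`)

Q = length/width per spore, summarized like the raw dimensions. The shape
scale is half-open on every boundary (a Q of exactly 1.05 is subglobose);
the 1.8–2.0 band absent from the published scale is surfaced as
`unclassified-gap` rather than silently bridged. Trimmed ranges use
nearest-rank percentiles (rank ⌈p·n⌉ on sorted values) so bounds stay
within observed values; linear interpolation is available. SD uses the n−1
denominator. The error limit is interpreted as the two-sided 95%
confidence half-width t(0.975, n−1)·SD/√n; at the sample sizes of the
bundled table this is numerically indistinguishable from the z-based
1.96·SD/√n, so the interpretation cannot be wrong at printed precision.
Between-species tests are Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom (pooled-variance t available); when
a summary carries only a printed mean ± EL, the SD is back-derived as
EL·√n / t. No multiple-testing correction is applied by default (published
comparisons report raw P < 0.01); a Bonferroni option exists.

Applying these tests to the bundled published table shows that the printed
claim — every species pair significantly different in length or Q at
P < 0.01 except gallica–violacea — does not follow from the printed
summary values alone: seventeen pairs are non-significant on length at
0.01 (gallica–violacea is by far the most extreme, |t| ≈ 0.65, p ≈ 0.51),
and at the 0.01 level one further pair (algida–sinensis, p ≈ 0.039/0.037)
is non-significant on both variables. What does hold, and is asserted in
tests, is that gallica–violacea is the unique pair separable neither by
length nor by Q at the 5% level. The discrepancy presumably reflects
information (raw measurements, specimen-level structure) not recoverable
from the printed means, error limits and counts.

Confidence ellipses in (L<sub>m</sub>, Q<sub>m</sub>) space use the error
limits as radii; the SVG layer is a plain standalone rendering intended for
inspection, not publication typography.

## Synthetic data (`simulate`)

The generator emulates the statistical structure the analyses consume, not
the data-generating biology below it:

* **Gene trees.** A species-guide topology places each planted species as a
  clade; per locus, each species clade survives with probability
  `concordance_prob` (default 5/6) and draws (MPBP, BPP) from the
  concordant law U[85,100] × U[96,100], or is perturbed by regrafting one
  random member to the root, with the reduced clade drawing from the
  discordant law U[10,69] × U[50,94]. Discordance as single-taxon
  regrafting (rather than coalescent simulation) is deliberate: grouping
  logic consumes only clade presence and supports, so topological realism
  beyond clade disruption adds nothing the tests could detect. The backbone
  above the species is an unresolved polytomy by default, making the
  species clades the deepest resolved units; a resolved random backbone is
  available, but note that well-supported multi-species backbone clades
  are legitimate candidates under the ranking rule and will then delimit
  higher-level lineages — choosing candidate hypotheses above the species
  level is the analyst's decision, not the generator's.
* **Species tree.** Per-clade MPBP/MLBS/BPP triples from
  U[85,100]² × U[96,100], with named clades forcible to exact triples
  (e.g. a (51/30/95) clade to exercise the IEL-only ranking route).
* **Mating.** Every tester pair receives `pairings_per_pair` replicate
  pairings (default 40), each independently interfertile with the pair's
  probability: 0.85 within groups, 0.02 between, overridable per group
  pair to plant gene flow. Replication is per tester pair because
  compatibility is a pair property estimated by repeated pairings —
  real designs pair each tester pair tens of times, giving group-pair
  totals in the hundreds to thousands — and because component-based
  delimitation is only meaningful when per-pair proportions have
  concentrated: at one or two replicates per pair, a single 2%-probability
  fertile reaction would bridge two groups. Non-fusing outcomes split
  0.9 black-line / 0.1 white-fluffy; published matrices do not decompose
  IS, so this is a free parameter. A planted gene-flow probability near
  the 0.5 edge threshold can still stochastically merge groups (some pair
  proportions cross the threshold); the exact-count fixture in
  `datasets.gene_flow_fixture` is used where exact published percentages
  are needed.
* **Spores.** Per-species bivariate normal (length, width), truncated at
  zero by redraw, ≥ 30 spores per specimen (the conventional minimum),
  default parameters spanning the 7.6–9.5 μm range typical of the group.

Default scale mirrors the motivating study: 15 species × 12 individuals ×
6 loci, 16 intersterility groups × 5 testers. All randomness flows through
`numpy.random.default_rng(seed)`; identical seed and configuration give
byte-identical outputs.

What passing the synthetic recovery tests does *not* show: robustness to
correlated discordance (hybridization, introgression), to support values
miscalibrated relative to clade truth, to non-transitive mating
compatibility, or to non-normal, specimen-clustered spore measurements.
The generator draws supports from laws that respect the thresholds by
construction, so recovery under the default conditions demonstrates the
pipeline's logic, not the method's field performance.

## Pipeline and CLI

Problem sizes used by the test suite and the reproduction script: 100
seeded pipeline runs at 15 × 12 × 6 for phylogenetic-species recovery, 20
seeded mating simulations at 16 × 5 with 40 replicates per tester pair,
1,000 seeded samples of n = 30 for the error-limit coverage check, and
full bipartition-pair enumeration over 4–6 taxa for the conflict oracle —
sizes chosen so the whole suite completes in well under a minute while
keeping Monte-Carlo error far below the margins being asserted.

Every CLI subcommand is pure given (inputs, config, seed); outputs embed
the configuration hash and seed but never timestamps, so re-runs are
byte-identical. Exit codes: 0 success, 2 validation error, 3 runtime
error.

## Known limitations

* IEL recognition evaluates supplied candidate clades (species-tree clades
  by default); it does not enumerate every clade of every locus tree, so an
  IEL present only in a single-locus tree and absent from the species tree
  will not be surfaced.
* The ranking rule delimits the most inclusive supported clades; it has no
  notion of a concordance-to-discordance *transition depth*, which is why
  candidate pools containing well-supported backbone clades should be
  curated.
* `MatingMatrix` treats replicate pairings as exchangeable; plate, date or
  scorer effects are out of scope.
* Back-derived SDs inherit the rounding of printed error limits; at n in
  the hundreds this perturbs t statistics in the second decimal at most.
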