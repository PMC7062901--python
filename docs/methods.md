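# Methods

This note records the models, conventions and numerical choices behind
`phylogeo`, in the order the pipeline runs them.

## Observational model

A *spot* is a microdissected group of 2–5 adjacent tumor glands and is
treated as clonal: a heterozygous somatic mutation present in the spot
sits at VAF ≈ 0.5 × cellularity, and an absent mutation at the
sequencing error floor.  Spots carry section-plane coordinates in mm
with an arbitrary per-slide origin; only within-slide pairwise
distances are ever used, so origin and orientation are free, and
distances between spots on different slides are undefined.  Phenotype
labels (S/I/M) are inputs produced by histopathology; a spot may lack a
label only if it is excluded from phylogeography (it still participates
in genotyping).

## Genotyping chain

Order: call → singleton-noise removal → admixed-spot removal → public
promotion → scope classification → homoplasy resolution → subclone
collapse.  The chain is deterministic and idempotent.  Admixture
removal runs before promotion because admixed spots carry unions of
genotypes and would distort prevalence counts.

Thresholds (all `PipelineConfig` fields):

| parameter | default | meaning |
| --- | --- | --- |
| `vaf_call_threshold` | 0.05 | present iff VAF ≥ 0.05 (inclusive, so a printed 5% call is positive) |
| `min_depth` | 20 reads | below → call missing |
| `singleton_noise_vaf` | 0.06 | single-carrier private mutation with VAF strictly below → absent |
| `public_promotion_fraction` | 0.90 | present in strictly more than this fraction of callable spots → public, absences flipped |
| `max_missing_fraction` | 0.30 | spot with more missing loci is excluded with a warning |
| `homoplasy_flip_budget` | 5% of cells | resolution aborts beyond this, advising manual review |

The promotion denominator is the non-excluded spots with a non-missing
call at that locus.  Missing calls resolve to present for public
(promoted) loci and to absent otherwise — complete genotypes require a
convention, and weak evidence should not create private mutations.

**Admixture.**  A spot is flagged when (a) it is pivotal for at least
one four-gamete violation (removing it makes that locus pair
compatible) and (b) its median private-VAF to median public-VAF ratio
is below 0.5.  In a clonal spot the two medians are comparable (ratio
≈ 1); in a two-clone mixture each component's privates are diluted by
the other's cells.  Note the ratio for an exactly even two-clone
mixture with equally many privates per component is 0.5 in expectation
— the boundary — so detection is reliable for uneven mixtures or
unequal private counts, and read noise decides the knife-edge case.
Deconvolving admixed spots is out of scope; they are excluded.

**Homoplasy resolution.**  Under infinite sites (each mutation acquired
once, never reverted) every locus pair must pass the four-gamete test;
with the germline all-absent genotype implicitly present, a pair is
incompatible iff the patterns 01, 10 and 11 all occur among spots.  The
resolver searches for the minimum number of cell flips by
iterative-deepening branch and bound: at each node it picks the first
violating pair and branches over flips of cells in those two columns in
pattern-bearing rows (complete, since clearing any one pattern requires
such a flip).  Ties prefer present→absent flips at the lowest-VAF cell,
treating weak calls as the likelier false positives.  Exactness is
verified in tests against brute-force enumeration.

## Phylogeny

On a compatible matrix the perfect phylogeny is the unique
maximum-parsimony tree, so exact construction replaces heuristic
search: mutations with identical carrier sets share an edge, carrier
sets form a laminar family, and each set's parent is the smallest
strictly containing set (germline root).  A subclone whose genotype
equals an internal node's is attached there as a zero-length tip.
Parsimony length equals the number of distinct variant mutations.

`fitch_parsimony_length` scores arbitrary rooted trees by Sankoff
dynamic programming with unit costs (exact on polytomies), with the
root fixed to the all-absent state.  `exhaustive_parsimony_search`
enumerates rooted topologies (equivalently, all germline attachments of
the unrooted tree) for ≤ 9 tips, reports the number of co-optimal
topologies and breaks ties by lexicographic Newick order.  An
independent cross-check against the R `phangorn` parsimony ratchet runs
in the test suite.

**Bootstrap.**  Columns are resampled with replacement `bootstrap_n`
(default 1000) times; column subsets of a compatible matrix stay
compatible, so each replicate has a perfect phylogeny whose non-trivial
clades are exactly its carrier sets.  An internal edge's support is the
fraction of replicates containing the same tip clade.  The root edge is
excluded, and replicate polytomies contribute support only to the
clades they resolve — a convention this package fixes, since no
standard exists for multifurcating bootstrap comparison.

## Phylogeography

Migration is irreversible: superficial → invasive only.  Admissible
histories assign each node superficial or invaded, root superficial,
invaded nodes have only invaded descendants; purely invasive tips must
be invaded, purely superficial tips superficial.  A mixed (S-I) tip is
constrained to a superficial parent lineage with its own crossing
inside the tip, contributing exactly one event; this "superficial
parent" rule also means an S-I tip never shares a sister clade's
event.  The minimal transition count then has the closed form

    n_events = (# S-I tips) + (# maximal all-invasive clades),

which the test suite checks against exhaustive state enumeration on
1000 random instances.  Metastatic membership counts as invaded: a
metastasis-only subclone behaves like an invasive tip, and a
primary-superficial subclone with a metastatic member behaves like S-I.
Consequences: a tumor whose only invading lineage is the metastasis
reports one event, and a metastasis sharing a primary invasive
genotype merges into that clade's event.

A single invading subclone is reported monophyletic (by convention);
no invading subclone yields NA.  Multiclonal invasion is defined as
n_events ≥ 2.  Parsimony counts are conservative: two true crossings
that leave genotypically identical descendants collapse into one
reported event, so reported counts are a lower bound on the truth —
simulation tests treat them as such.

**Timing.**  A subclone "arose" where its branch attaches; its relative
root distance is attachment-node mutations divided by the maximum
root-to-tip mutation count, early iff ≤ 0.5.  The distance metric is a
config switch (`mutations`, default, or `nodes`).

## Statistics

* Gini–Simpson `GS = 1 − Σ nᵢ(nᵢ−1)/(N(N−1))` — the probability two
  spots drawn without replacement belong to different subclones;
  undefined for N < 2.
* Normalized adjacency distance: internal nodes on the tip-to-tip path
  minus 1, divided by (tree-wide maximum minus 1), so sister tips score
  0 and the most separated pair scores exactly 1.  The −1 shift is
  applied to both numerator and denominator to keep the normalization
  tight on every tree.
* Genetic distance between spots is the Hamming (L1) distance between
  dichotomized call vectors — the same CallMatrix the tree uses, not a
  separate cut-off.
* Spot adjacency (for contiguity and adjacent-subclone pairs) defaults
  to a 4 mm within-slide radius (≈ 1.4 × a typical nearest-neighbor
  spacing of ~3 mm); an explicit adjacency graph overrides it.
* The paired superficial-vs-invasive diversity comparison, the
  within/between-slide rank-sum and the KS uniformity test are computed
  and reported as descriptive statistics.

## Simulator

A 2D section lattice (default 40 × 30 gland units, 0.5 mm spacing) with
the muscularis mucosae at row 15.  Growth is Eden-style: a random gland
fissions into an adjacent empty site; with probability `mixing_prob`
(default 0.05) the daughter instead disperses to a random empty site
within a 3-unit radius — the "early mixing" that produces jigsaw
topographies.  Daughters inherit their parent's mutations plus
Poisson(`mutation_rate` = 0.06) new ones drawn without replacement from
the unused panel loci (infinite sites restricted to the panel, so the
truth is homoplasy-free by construction; the panel-exhaustion error
enforces it).  The founder starts 3 rows above the boundary with
`n_public` = 8 clonal mutations, the first two flagged as canonical
drivers.

Downward boundary crossings are gated by mode and logged as invasion
events; upward crossings are forbidden (irreversibility is built in):

* **bottleneck** — only lineages with ≥ `n_drivers_required` (1)
  acquired driver mutations may cross; `driver_prob` = 0.12 makes a
  driver clade arise in roughly half the runs, and when invasion
  happens all crossings trace to a single founding driver lineage.
* **multiclonal** — any boundary fission crosses with
  `invasion_prob` = 0.05, chosen so true crossing counts span 1–7 with
  a median near 3-4, the observed multiclonal range; runs with a single
  crossing (the bottleneck-like tail of the regime) occur and are kept.

Spots: 16 centers with minimum separation 2 units, each the center
gland plus nearest neighbors up to `glands_per_spot` = 3; spots
straddling clone boundaries become naturally admixed.  Phenotype is
geometric: S iff the center row is above the boundary.  Reads: depth ~
Poisson(9000), alt ~ Binomial(depth, f) with f = carrier-fraction × 0.5
× cellularity (0.95) and an error floor of 0.001 for absent loci;
`noise_free` replaces both with deterministic counts as a depth→∞
surrogate for recovery tests.  An optional early metastatic lineage
(sampled at `met_divergence_time` as a fraction of divisions, ~0.1 when
enabled) seeds 1–2 lymph-node spots carrying exactly its genotype at
divergence.

What the simulator does *not* emulate: 3D growth, stromal/vascular
architecture, copy-number changes distorting VAFs, selection beyond the
driver gate, panel design from exome data, and pathologist labeling
error.  Passing recovery tests therefore demonstrates correctness of
the inference chain under the stated read-noise and sampling model, not
robustness to those unmodeled features of real sections.

## Worked fixture

`make_worked_fixture()` is a handcrafted 14-spot, 20-locus tumor used
across tests and docs: five public mutations (two drivers), sister
mixed clones SC1/SC2, superficial clones SC4/SC5, and an invasive clone
SC3 carrying exactly the public genotype, shared with a lymph-node
metastasis — so the metastasis merges into SC3's invasion event and
the ground truth is 3 events (two S-I tips + one invasive clade).  One
spot is a 40:60 admixture of two clones, giving four-gamete violations
and a private/public VAF ratio of 0.4.  Read noise is emitted at fixed
seed; all expected values are stored alongside the data.

## Numerical and degenerate-input conventions

* Medians use the midpoint-of-two convention for even counts.
* A single-tip tree: the tip is early (relative distance 0); adjacency
  distances need ≥ 3 tips.
* Zero variance in either distance sample → correlation undefined
  (NaN) with a warning; < 2 invading subclones → monophyly True (one)
  or NA (none).
* All randomness flows through one `numpy` Generator per entry point,
  seeded from `rng_seed`; identical config + seed gives byte-identical
  output.

## Problem sizes used in checks

The randomized suites run 1000 invasion-count instances (≤ 8 tips), 500
random genealogies for tree recovery, 40–50 flip-repair instances
(5 × 8 matrices, where brute-force minimality is checkable), and 10
simulator seeds per growth mode at 450 glands / 16 spots — sizes at
which every exhaustive oracle remains exact and the whole suite runs in
well under a minute.
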