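# Methods

## Data model

A connectome here is three artifacts. The **edge table** is a directed,
weighted edge list: one row per (presynaptic neuron, postsynaptic neuron)
with an integer synapse count ≥ 1; raw exports that list individual synapses
are summed into one row per pair at load time, with a logged warning. The
**catalog** annotates each neuron: side (L/R, or M for unpaired midline
neurons, which are their own left–right homolog), segment (ordered
T1–T3, A1–A10), source type (nerve-cord interneuron, sensory neuron,
brain-or-SEZ neuron, or an untraceable fragment), optional sensory modality,
morphological class, lineage, hemilineage (Notch-ON/OFF), 1-based birth rank,
cohort label, and the left–right homolog's id. Homolog links must be
symmetric; birth ranks must be unique within (lineage, hemilineage, side).
**Skeletons** are SWC trees in the coordinate unit of the run (nanometres by
CATMAID convention, configurable); the soma is the first node carrying the
soma structure code and the neuropil-entry node comes from a companion CSV,
since SWC has no native way to mark it. Records without a side annotation
are excluded from pairing analyses and logged, never silently dropped;
fragments are kept as distinct input identities, since merging fragments of
one true neuron cannot be decided from the edge list.

## Input accounting

All summaries operate on the sub-table of inputs onto a named **target set**
(for example, every neuron of one lineage in one segment, left and right
copies, with their homolog pairing declared). Composition by source type and
by morphological class reports synapse counts and percentages of total input;
percentages always sum to exactly 100 before any rounding, and rounded
presentations keep the raw fractions alongside. Per-edge synapse-count
histograms use explicit labeled integer bins (1–9 then 10+ by default;
a 0–4/5–9/…/45+ variant for per-source pooled totals); values below the
lowest bin go to an explicit underflow bucket. Distribution comparisons use
the two-sample two-sided Kolmogorov–Smirnov test on the raw per-neuron
totals, never on binned counts, with the exact p-value when both samples
have n ≤ 25 and the asymptotic formula otherwise.

Two reliability filters address annotation noise. The **left–right pairing
filter** retains an interneuron pair {p, q} (p = q for a midline neuron) if
some homologous target pair (t_L, t_R) receives ≥ `thr_high` synapses from
one member and ≥ `thr_low` from the other member onto the opposite-side
target; defaults are 4 and 2. Either member may carry the high count — the
assignment is a logical OR over the four role/side combinations, since
nothing fixes which side is stronger. The **highly-connected filter** keeps
sensory neurons and interneurons whose left–right pair has at least one
member with ≥ `min_syn` (default 10) summed synapses onto the target set; it
returns both the pair-expanded member set and the strict set of individually
qualifying neurons, because the two counts answer different questions (who
belongs to a strongly connected pair vs. who is strongly connected). Both
filters are monotone in their thresholds and invariant to row order and to a
global swap of all L/R labels.

## Distance analysis

Input vectors are rows of a matrix whose columns are the union of presynaptic
partners observed onto the analyzed group (after any source-type dropout),
in sorted order — identical for every row, with no all-zero columns, which
cannot affect a Euclidean distance. Dropout variants restrict the universe to
sensory-only or interneuron-only sources to ask which input class drives an
observed similarity structure. The binary mode replaces counts with presence
bits; binarization is idempotent.

The null hypothesis is that partner *identity* is random given each neuron's
in-degree and count multiset. Each permutation round independently applies a
uniform random column permutation to every row — both members of every pair
are shuffled — and all pairwise distances are recomputed on the shuffled
matrix (one shuffled matrix per round, shared across pairs). Null mean and
standard deviation per pair use the n−1 sample estimator over `n_perm`
rounds (default 100, minimum 2). The significance threshold is derived from
α through the standard normal quantile rather than hard-coded, so non-default
α behaves consistently. Negative z means the real distance is smaller than
chance, i.e. similarity; positive z means difference. Pairs whose null sd is
zero (e.g. a single-column universe) are flagged undefined and never called
significant; the diagonal is excluded throughout. An exhaustive-enumeration
null (all joint row permutations, feasible for a handful of columns) serves
as the ground truth that the Monte-Carlo null is tested against.

Pair summaries pool the binary-mode z-scores — regardless of significance —
for left–right homolog pairs and for "following" pairs (consecutive birth
ranks within one lineage, hemilineage, side and segment), grouped by the
cohort shared by the pair's members. Midline self-homologs are degenerate
and excluded from left–right pairs; neurons without a birth rank are skipped
from following pairs and logged.

### Known limitation: calibration of the z cutoff

The ±1.96 cutoff treats the permutation distance distribution as normal. On
structureless data this is a good approximation when per-edge counts are
light-tailed (measured false-similarity rate 2.6–2.7% against the nominal
2.5% at the default problem size), but heavy-tailed counts skew the null
distance distribution left and make the count-mode call mildly
anticonservative (≈3% at skew ≈ −0.33), while the binary mode's discrete
overlap distribution makes it mildly conservative (≈1.5%). Users analyzing
edge lists with many 10+-synapse edges should prefer the binary mode for
similarity calls, or treat marginal |z| ≈ 2 calls with caution.

## Birth-order proxy

Cortex neurite length is the geodesic along the skeleton between the soma
node and the neuropil-entry node: the unique tree path is found by splicing
the two root paths at their lowest common ancestor, and its length is the sum
of 3-D Euclidean segment lengths. The proxy is summarized by Pearson's r
between birth rank and length (per side and for the side-average, falling
back to the available side when one is missing, flagged), with the two-sided
p from the t distribution on n − 2 degrees of freedom; r is unit-invariant,
absolute lengths are not, so the unit is carried in all outputs. The package
deliberately does not infer birth order from lengths — the correlation is
strong but rank-level inversions are common — it only quantifies the proxy.

## Synthetic generator

The generator emulates one segment's worth of structure: `n_lineages`
lineages of `n_neurons` neurons per side (default 10, cohort boundary after
rank 5, labels "early"/"late"), mirrored into left–right homolog pairs, wired
against a universe of `universe_size` partner units (default 200): unpaired
midline units (default 10, Ladder-style interneurons) and left–right paired
units, with source types in fixed fractions (61% interneuron, 19% sensory,
rest brain-or-SEZ) so dropout variants are exercised.

Wiring models. **sharp**: each cohort draws a dedicated pool of
`pool_size` = 30 partner units (disjoint between cohorts by default; a
`pool_overlap` fraction can soften this); members connect to pool units with
`p_within` = 0.8 and to all others with `p_across` = 0.05. The pool size is
chosen to echo the scale of shared partner classes a real cohort draws on
(tens of partners per cohort). **graded**: rank 1 draws a pool-sized partner
set; each subsequent rank inherits its predecessor's set with every partner
independently replaced with probability `drift_rate` = 0.2 — similarity then
decays smoothly with rank distance and no boundary exists. **null**: every
(partner neuron, target) edge is independent, on both sides, with a uniform
probability matched to the sharp model's expected in-degree; this is the
structureless control used for calibration, and it is deliberately wired at
the level of individual partner neurons so that no column subspace is shared
between any group of rows.

Mirroring. A right-side neuron inherits its left homolog's edges; each edge
is redrawn from the model with probability `mirror_noise` (per-cohort,
defaults 0.1 early / 0.6 late, reflecting that left–right wiring conservation
differs between cohorts in real lineages). An inherited edge is carried by
the *same* presynaptic neuron with per-cohort probability `p_bilateral`
(defaults 0.8 early / 0.2 late; always for midline partners) and by the
opposite-side homolog member otherwise. Bilateral carriers matter: without
some same-neuron sharing, left and right homologous targets would occupy
disjoint columns of the input matrix and left–right similarity would be
undetectable by construction, which contradicts how bilateral-dendrite
neurons actually receive input.

Synapse counts are drawn per edge from a truncated mixture: a single synapse
with probability 0.8, otherwise 1 + Geometric(`p_tail`), capped at 30. The
default `p_tail` = 0.8 makes the marginal exactly a truncated geometric —
light-tailed, which keeps the count-mode z calibrated (see the limitation
above). `CountLaw(p_tail=0.3)` reproduces the heavier tail of real edge
lists (a few edges at 10–30 synapses); the acceptance script uses it for the
pairing and highly-connected censuses, which are degenerate without
≥ 4-synapse edges. Skeletons are straight chains with cortex neurite length
`base + slope·rank + N(0, sd)` (defaults 5 + 2·rank ± 1, in the run's length
unit). Identical (config, seed) regenerates bit-identical systems, and every
generated catalog/edge table passes validation.

What passing tests on this generator do and do not show: the generator
reproduces the statistical skeleton of the problem — cohort-structured input
vectors over a shared universe, left–right homology with tunable
conservation, skewed synapse counts, birth-rank-correlated neurite lengths —
but not reconstruction artifacts (split/merged fragments, truncated arbors,
annotation errors), segment-to-segment repetition, or real partner
identities. Green tests demonstrate that the machinery detects the structure
it is designed to detect at realistic sizes and calls none on structureless
data; they cannot certify performance on any particular real reconstruction.

## Problem sizes and numerical choices

Statistical tests run at the study's stated conditions: recovery on 20
sharp-model replicates (universe 200, n_perm = 100, one hemisegment of 10
neurons in two cohorts of 5), calibration on 50 null-model replicates
(9,500 pairs), exhaustive-oracle comparisons on ≤ 3-neuron, ≤ 5-column
instances at n_perm = 10,000 with a 3-standard-error band. The whole suite
and the acceptance script each run in well under a minute on one CPU.
Matrices are float64; distances use scipy's `pdist`; all randomness flows
from named `numpy` Generators seeded explicitly, and reports embed seed,
n_perm, α, thresholds and a config hash. Ties and degenerate inputs are
resolved as follows: zero-input analyzed neurons get zero rows and a flag;
zero-variance correlation inputs and sub-3-point correlations are errors;
histogram underflow is explicit; undefined z is reported, never coerced.
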