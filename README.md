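# cohortwiring

Temporal-cohort connectivity analysis for synapse-resolution connectomes.

Neuroblast lineages in the *Drosophila* larval nerve cord produce neurons in a
fixed birth order, and neurons born within a tight time window (a *temporal
cohort*) often share circuit-level function. Given an EM-reconstructed wiring
diagram — a directed edge list of synapse counts plus an annotation catalog —
this package asks whether cohort membership is visible in wiring: do neurons
of the same cohort draw on the same presynaptic partners, and do cohort
boundaries mark sharp or graded transitions in input connectivity?

It is aimed at connectomics practitioners working with CATMAID-style exports
(edge tables, SWC skeletons) who want the full analysis battery as a tested,
scriptable library rather than a one-off notebook.

## The statistic at its core

Each analyzed neuron *i* gets an input vector **x**ᵢ over a shared, identically
ordered universe of presynaptic partners, with entries the synapse counts
(non-binary mode) or presence bits (binary mode). For every pair the Euclidean
distance

&nbsp;&nbsp;&nbsp;&nbsp;d(i, j) = ‖**x**ᵢ − **x**ⱼ‖₂

measures wiring dissimilarity. Chance is estimated by a shuffle null: each
neuron's vector is independently permuted across the universe (conserving its
in-degree and per-partner counts) n_perm = 100 times, distances are recomputed
each round, and the real distance is normalized per pair:

&nbsp;&nbsp;&nbsp;&nbsp;z(i, j) = (d − mean[d_shuffled]) / sd[d_shuffled].

At two-tailed α = 0.05, z < −1.96 calls a pair significantly **similar**
(closer than chance) and z > +1.96 significantly **different**. Around this
sit the standard accounting steps: input composition by source type, sensory
breakdown, per-edge synapse histograms with a two-sample Kolmogorov–Smirnov
comparison, the left–right pairing reliability filter (≥ 4 synapses on one
side and ≥ 2 on the hemisegmentally homologous side), the highly-connected
census (≥ 10 synapses), and a birth-order proxy: the along-skeleton geodesic
from soma to neuropil entry ("cortex neurite length") correlated with birth
rank via Pearson's r.

A seeded synthetic generator produces whole nervous systems under three
wiring models — **sharp** (cohort-specific partner pools), **graded**
(per-rank partner drift) and **null** (uniform, structureless) — so every
stage runs and is testable without external downloads.

## Worked example

Generate a sharp-model synthetic nervous cord and run the stages:

```bash
$ cohortwiring simulate --seed 17 --out demo
wrote 410 neurons, 643 edges, 20 skeletons to demo

$ cohortwiring account compose --edges demo/edges.csv \
    --catalog demo/catalog.csv --targets demo/targets.yaml
LIN1_A1LR: 825 synapses from 188 distinct sources
 source_type  synapses  percentage
 interneuron       532   64.484848
brain_or_SEZ       154   18.666667
     sensory       139   16.848485

$ cohortwiring distance --edges demo/edges.csv --catalog demo/catalog.csv \
    --analyzed demo/targets.yaml --n-perm 100 --seed 17 --out demo/nonbinary
64 similar / 34 different pairs at |z| > 1.96

$ cohortwiring birthorder --skeletons demo/skeletons --ranks demo/ranks.csv
L: r(8) = 0.985, p = 2.34e-07, n = 10
avg: r(8) = 0.985, p = 2.34e-07, n = 10
```

Reading the numbers: the 20 analyzed lineage neurons receive 825 synapses,
about 64% from other nerve-cord interneurons — the generator seeds the
universe with realistic source-type fractions. The 64 significantly similar
pairs concentrate inside the two generated cohorts (the sharp model's
dedicated partner pools), while the different calls separate the cohorts;
`demo/nonbinary.z.csv` holds the full z-matrix and
`demo/nonbinary.pairs.csv` the left–right and consecutive-birth pair
summaries. Cortex neurite length tracks birth rank at r ≈ 0.99 because the
generator draws skeleton lengths linear in rank with unit Gaussian noise.

`cohortwiring run --config run.yaml` executes everything end to end and
writes a consolidated, fully seeded `report.json`.

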