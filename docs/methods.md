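# Methods

## Problem setting

Each protein carries a non-empty set of functional categories drawn from
the 24 top-level FunCat classes (multi-label: on curated mouse corpora a
protein averages ~3 functions). Two information sources are modelled:
a weighted undirected PPI network whose edge weights are interaction
confidence scores, and the amino-acid sequence itself. Predictions are
full rankings of the 24 categories, evaluated at every order.

## Network method: inclined potential

For query *Q* with annotated neighbours *P\_i* and weights *w(Q, P\_i)*,

p\_μ(Q) = Σ\_i w(Q, P\_i) · 1[μ ∈ functions(P\_i)],  μ = 1..24.

Assumptions: function assortativity of interactions (neighbours tend to
share functions) and that confidence scores are monotone in interaction
reliability. The scorer is linear in the weights, so rankings are
invariant to any uniform positive rescaling — raw STRING 0–1000 combined
scores and normalized 0–1 confidences are accepted unchanged. There is
no self-interaction: w(Q, Q) = 0, and a query's own annotations are
never consulted while scoring it. Proteins whose neighbourhood carries
no annotations produce an all-zero profile and are flagged
unpredictable.

Ties in the descending ranking break to the ascending category index by
default (deterministic, reproducible reports); a seeded random tie rule
is available for fidelity with protocols that assign tied ranks
randomly.

## Sequence method: hybrid properties + nearest neighbour

### Descriptor (132 features, all percent-scaled)

Each sequence is translated, property by property, into a 2- or
3-letter group alphabet. The four sequence-intrinsic tripartitions are
the standard Dubchak-style groupings (shipped as data, overridable):

| property | groups |
|---|---|
| hydrophobicity | polar RKEDQN / neutral GASTPHY / hydrophobic CLVIMFW |
| van der Waals volume | GASCTPD / NVEQIL / MHKFRYW |
| polarity | LIFWCMVY / PATGS / HQRKNED |
| polarizability | GASDT / CPNVEQIL / KMHFRYW |

The hydrophobicity table is verified residue-by-residue against a
hand-translated 50-mer reference in the test suite; the other three are
the standard published tables and are not independently verifiable from
that example. Secondary structure (helix/sheet/coil) and solvent
accessibility (buried/exposed) are read from per-residue annotation
files (the output of external structure predictors). When none are
supplied, deterministic heuristics can stand in: per-residue argmax of
Chou–Fasman helix/sheet/turn propensities (turn read as coil; ties break
to coil), and buried-when-positive mean Kyte–Doolittle hydropathy over a
9-residue edge-truncated window. These are crude single-sequence rules,
clearly flagged at run time; features built on them should not be
compared against features built on real predictor output.

Per property: **C** = percent composition of each group; **T** = for
each unordered group pair, the percent of *differing* adjacent position
pairs that are that pair (denominator = number of differing adjacent
pairs, not sequence length − 1; the all-one-group case defines T = 0);
**D** = per group, the 1-based positions of the first occurrence and of
the ceil(q·n)-th occurrences (q = 25, 50, 75, 100 %) as percent of the
translated length, with (0,0,0,0,0) for absent groups. A three-group
property yields 3 + 3 + 15 = 21 features. The two-group solvent
accessibility contributes the buried group's C and D and the single
pair's T (1 + 1 + 5 = 7); which group's C/D to keep is not dictated by
the 1/1/5 dimensionality, and buried (the first group) was chosen. The
20 amino-acid composition percentages complete the 132.

Noncanonical residues (X, B, Z, U, O, J) are retained in records but
excluded from translated strings, AAC, and position numbering — a
deliberate convention, since including unknown residues in any group
would contaminate all three statistics.

Before training, coding vectors are filtered: groups of proteins with
identical vectors but differing function sets are removed entirely (the
representation cannot separate them), and of vector- and function-
identical groups one representative (smallest id) is kept.

### Feature selection

Mutual information uses the empirical plug-in estimate in nats on
discretized features — equal-frequency 3-bin coding with edges at the
tertiles of the data, duplicate edges collapsed (constant features get a
single state). mRMR relevance of a feature is the mean MI with the 24
binary category indicators (a `max` alternative is exposed); this
multi-label reduction is symmetric across categories and collapses to
single-target relevance when one label column is present. Redundancy is
the mean MI with already-selected features; greedy selection maximizes
relevance − redundancy, ties breaking to the earlier column for
determinism. IFS evaluates every nested prefix of the mRMR order with
the leave-one-out jackknife below and picks the *smallest* prefix
attaining the maximum first-order accuracy.

### Scoring

Similarity is the cosine of two feature vectors. Category μ scores the
maximum similarity among training proteins carrying μ (pure nearest-
neighbour reading); a similarity-sum over all carriers is available as
`agg="sum"`. The max rule is the larger interpretive choice in this
design: a multi-order ranking requires a per-category score that a plain
nearest-neighbour classifier does not define, and max-over-carriers is
the minimal generalization that reproduces nearest-neighbour behaviour
at order 1. Categories with no carrier score 0.

## Evaluation

Λ\_j = 100·N\_j/N, where N\_j counts proteins whose j-th ranked category
is a true function; m̄ = mean truth-set size; k = ⌈m̄⌉; Φ(k) = percent of
proteins whose entire truth set is within their top k. Since rankings
are permutations of the 24 categories, each true category is hit at
exactly one order, so Σ\_j N\_j equals the total annotation mass — a
conservation identity the tests assert on every run.

Jackknifing: the network harness hides only the held-out node's
annotations and keeps its edges — neighbours' labels, not the held-out
node's, drive the score, and removing edges would perturb every
neighbour's context as well. The hybrid harness holds the protein's
vector out of the training matrix. Unpredictable proteins stay in the
denominator N as misses at every order and are listed separately.

## Synthetic data

The generators emulate the statistical structure each method exploits,
not real biology:

* **Labels** are independent per-category Bernoulli indicators with
  empty sets redrawn, the rate calibrated by bisection so the
  post-rejection mean set size equals `label_rate` (default 3.14, a
  realistic curated-corpus mean). `label_rate = 1` is a degenerate
  boundary of that calibration (the conditional mean exceeds 1 for every
  positive rate) and draws exactly one uniform category instead.
* **Networks**: a target edge count of `edge_density` times all pairs;
  each edge joins a uniformly chosen function-sharing pair with
  probability `homophily`, else a uniform pair; weights uniform in
  `weight_range` (default 150–999, STRING-like). Isolated nodes receive
  one extra edge so every node is jackknifable.
* **Feature tables**: informative feature j is tied to category
  (j mod K) + 1 and shifts its carriers' mean by `effect_size` (unit
  noise); redundant features are informative columns plus N(0, 0.1);
  noise features are N(0, 1).
* **Sequences**: i.i.d. canonical residues with an optional hydrophobic
  sampling bias, lengths uniform in `seq_length_range`.

What the synthetics do *not* capture: STRING's evidence-channel score
composition, heavy-tailed degree distributions, correlated/hierarchical
category structure, phylogenetic relatedness of sequences, and real
structure-predictor output. Passing the synthetic calibrations therefore
demonstrates correctness of the machinery and sensitivity to planted
signal, not expected accuracy on curated corpora.

Calibration fixtures used by the acceptance tests: the homophily
calibration (200 proteins, homophily 0.95, density 0.05) uses
`label_rate = 2.0`. The fixture isolates edge homophily as the signal
under test; at higher label rates, multi-label co-annotation noise —
neighbours' non-shared labels accumulating weight — increasingly bounds
first-order accuracy regardless of homophily, which is a property of the
label model rather than of the scorer being calibrated. The hybrid
calibration uses a two-category single-label table (100 proteins,
10 informative / 5 redundant / 20 noise features) at separations of 5σ
and 0σ; chance for the balanced single-label design is ~50 %, and the
zero-homophily network control is compared to label_rate/24. Both
negative controls use a ±15-percentage-point band, generous enough for
binomial noise at n = 100–200 yet far below the calibrated positives.

## Numerical and degenerate-input conventions

* Percent values throughout; C sums to 100 per property, T sums to 100
  when any transition exists, D 5-tuples are non-decreasing.
* Empty translated sequences, all-noncanonical sequences and zero-norm
  vectors raise degenerate-input errors rather than returning silently
  wrong zeros.
* Duplicate annotation rows union; duplicate edges keep the maximum
  weight; both warn.
* All randomness (tie shuffles, generators) flows from explicit seeds;
  reports are byte-identical across runs with identical inputs and
  configuration.

## Known limitations

* The inclined potential is single-hop; no diffusion or module-assisted
  propagation.
* The heuristic structure/accessibility fallbacks are far weaker than
  real predictors and exist to keep the 132-feature contract satisfiable
  from sequence alone.
* mRMR discretization (equal-frequency, 3 bins) and the multi-label
  relevance reduction are reasonable defaults, not canonical choices;
  both are configurable.
* Jackknife cost is O(n²·d) for the hybrid method; IFS multiplies that
  by the number of prefixes, so full 132-feature IFS on thousands of
  proteins is expensive (the tests and examples use tens to hundreds).
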