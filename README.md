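# protfun

Multi-label protein function prediction over the 24 top-level FunCat
functional categories, combining two complementary predictors:

* **Network method — "inclined potential".** For a query protein *Q* in a
  weighted protein–protein interaction (PPI) network with STRING-style
  confidence scores *w(Q, P\_i)*, the potential toward category *μ* is

  *p\_μ(Q) = Σ\_i w(Q, P\_i) · [μ ∈ functions(P\_i)]*

  — guilt by association: functions of confidently interacting partners
  accumulate, and sorting the 24 scores in descending order yields the
  1st-order, 2nd-order, … predictions.

* **Sequence method — hybrid-property nearest neighbour.** Proteins with
  no interaction data are coded into a 132-dimensional descriptor built
  from six biochemical/physicochemical property alphabets (hydrophobicity,
  secondary structure, solvent accessibility, van der Waals volume,
  polarity, polarizability) via Composition/Transition/Distribution (CTD)
  statistics plus the 20 amino-acid composition percentages. Features are
  ordered by mRMR (maximum relevance to the 24 binary labels, minimum
  redundancy among features, via mutual information) and the best nested
  prefix is chosen by incremental feature selection (IFS); categories are
  then scored by cosine similarity to annotated training proteins.

Evaluation is by leave-one-out jackknifing with multi-order statistics:
Λ\_j (percent of proteins whose j-th ranked category is a true function),
m̄ (mean true functions per protein), and coverage Φ(k) (percent of
proteins whose whole function set lies in the top k = ⌈m̄⌉ predictions).

A seeded synthetic-data module generates annotated homophilous networks,
feature tables with planted informative/redundant/noise columns, and
random sequences, so the entire pipeline is testable without database
downloads.

Intended users: computational biologists prototyping or benchmarking
guilt-by-association and sequence-descriptor function predictors.

## Worked example

The CTD descriptor on a 50-residue sequence, using the three-group
hydrophobicity alphabet (P polar = RKEDQN, N neutral = GASTPHY,
H hydrophobic = CLVIMFW):

```python
from protfun import *

rec = read_fasta("ref.fasta")[0]   # MSDKPDMAEIEKFSKETIEQEKQAGESTQEKNPLPMLLPATDKSKLKKTE
t = translate_sequence(rec, HYDROPHOBICITY)
print(t)
print(composition_features(t, HYDROPHOBICITY))
print(transition_features(t, HYDROPHOBICITY))
print(distribution_features(t, HYDROPHOBICITY)[:5])
```

prints

```
HNPPNPHNPHPPHNPPNHPPPPPNNPNNPPPPNHNHHHNNNPPNPHPPNP
[20. 32. 48.]
[25.80645161 51.61290323 22.58064516]
[ 2. 20. 36. 74. 92.]
```

The translated string has 10 H, 16 N and 24 P, so composition C is
(20 %, 32 %, 48 %). Of its 49 adjacent position pairs, 31 differ — 8
H↔N, 16 N↔P, 7 H↔P — giving transitions T of (25.8 %, 51.6 %, 22.6 %).
The H residues sit at positions 1, 10, 18, 37, 46 (first and 25/50/75/
100 % occurrence landmarks), so distribution D(H) is (2 %, 20 %, 36 %,
74 %, 92 %) of the sequence length. `featurize(rec)` concatenates the
seven blocks (21+21+7+21+21+21+20) into the full 132-feature vector.

An end-to-end jackknife on a synthetic homophilous network:

```sh
protfun simulate --seed 1 --n-proteins 200 --out fixtures
protfun evaluate --method network \
    --edges fixtures/network.tsv \
    --annotations fixtures/network_annotations.tsv \
    --out report.tsv
```

prints

```
Lambda_1 = 86.00%  (N = 200, m_bar = 3.19, k = 4, Phi(k) = 35.00%)
```

i.e. with homophily 0.95 and a realistic mean of ~3.2 functions per
protein, the top-ranked category of 86 % of the 200 proteins is one of
their true functions, and for 35 % the whole function set is inside the
top 4. `report.tsv` lists all 24 orders; `report.detail.tsv` has the
per-protein rankings.

Other subcommands: `protfun featurize` (FASTA → 132-column matrix),
`protfun rank-features` (mRMR order), `protfun ifs` (IFS curve and
apogee), `protfun predict` (auto-dispatch between the two methods).

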