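# Methods

## Problem and model

`tbkg` mines adverse-drug-reaction (ADR) signals from a corpus of
biomedical abstracts and attaches mechanistic explanations to each
signal. Four entity classes are tracked — tumors, biomarkers, drugs,
and ADRs — and the method rests on one statistical primitive and one
graph primitive.

### The importance measure

Every abstract is reduced to binary indicators: `x_i = 1` if entity
*i* is mentioned positively at least once. For a fixed *target*
entity `y_j` (say, a drug) and a candidate *feature* entity `x_i` of a
different class (say, an ADR), a Bernoulli naive-Bayes model is fitted
per target by maximum likelihood with optional Laplace smoothing:

    p̂(x_i = 1 | y_j = v) = (#{x_i=1, y_j=v} + α) / (#{y_j=v} + 2α),  v ∈ {0,1}

The strength of the candidate relation is its **importance**

    IMP(x_i, y_j) = log2 p̂(x_i=1 | y_j=1) − log2 p̂(x_i=1 | y_j=0)

— the base-2 log of how many times more likely the feature is to be
mentioned when the target is present. Importance 1 means "twice as
likely"; 0 means no association; the default edge threshold of 1.0
therefore keeps relations with at least a two-fold enrichment. The
logarithm base is 2 because only base 2 reproduces the published
worked example (importance 4.31 from conditionals 10.4% and 0.5%:
log2(0.104/0.005) = 4.38, within rounding of the printed inputs,
whereas the natural log gives 3.04 and log10 gives 1.32).

### The knowledge graph and explanations

Relations above threshold become weighted undirected edges of a typed
graph (no self loops, no same-type edges, one edge per pair). For a
query drug, every ADR with a direct edge or at least one *explanation
path* — a simple path of at most `max_path_len` edges (default 3)
whose interior nodes are biomarkers or tumors — is a candidate.
Candidates are scored by the direct-edge importance when it exists;
otherwise by **widest-bottleneck path support**, the maximum over
paths of the weakest edge on the path. Directly connected ADRs always
rank above path-only ones: the direct statistical signal stays
primary and the paths stay explanatory. The ranking formula is a
design choice of this package — the ranking principle it implements
(larger weight = stronger association, short strong connections imply
likely ADRs) admits several scoring rules, and the bottleneck rule was
chosen because it never lets a chain of weak edges outrank a strong
one. Weights are never inverted into metric distances.

The top `ceil(0.05·N)` of a drug's ranked list is labeled *important*
and the bottom `ceil(0.05·N)` *unlikely* (ceiling rounding is a
package choice; labels must not overlap, which requires
N ≥ 2·ceil(0.05·N)).

### Evaluation statistics

Against a gold ADR list, the 2×2 agreement table is built from the
labeled extremes only — important = model positive, unlikely = model
negative, the unlabeled middle 90% excluded (an explicit
interpretation, since extremes are the only ranks with asserted
labels). From table (a, b, c, d): sensitivity a/(a+c), specificity
d/(b+d), and Cohen's kappa (p_o − p_e)/(1 − p_e) with
p_o = (a+d)/n and p_e = ((a+b)(a+c) + (c+d)(b+d))/n². The
co-occurrence baseline ranks pairs by the raw count of documents
containing both entities.

The classifier behind cross-validation predicts a target present iff
its posterior odds exceed 1 (ties predict absent, for determinism),
using the full Bernoulli likelihood (presence and absence terms).
Documents are split into k = 3 folds by permuting the *sorted*
document-id list, so fold assignment depends only on the seed, never
on row order. "Accuracy" is per-target binary classification accuracy
averaged over folds, then over targets — the cross-validation task is
an interpretation (the evaluation protocol it mirrors does not define
the predictive task precisely), and is documented as such.

## Entity tagging

Dictionary tagging stands in for a full clinical NLP engine, which is
not this package's contribution: exact case-insensitive longest-match
over whitespace/punctuation-tokenized text (title + body), shorter
overlapping matches suppressed. A mention is *negated* — and excluded
from the matrix — iff one of {no, not, without, denies, absence of,
negative for} occurs within the three preceding tokens. Node types
come from the lexicon's UMLS semantic category: T191 → tumor;
T121/T200 → drug; T109, T114, T116, T123, T125, T126, T129, T130,
T192, T195 → biomarker; rows carrying the designated adverse-reaction
source marker `WHO` → adr. Entities mentioned in fewer than
`min_entity_freq` documents (default 50) are dropped, and abstracts
with bodies under `min_body_chars` characters (default 100; no
published value exists, this is a stand-in cutoff) are removed.

## Synthetic data: what it emulates and what it does not

The generator plants a **two-level typed forest**: root entities
appear in each document independently with `anchor_rate` (default
0.3); each leaf has exactly one root parent and appears with
`p_present = 0.3` when its parent is present, else `p_absent = 0.03`;
unlinked background entities appear with 0.02. Each root parents
children of a single type, and the hierarchy tumor → drug →
biomarker → adr orders parents before children, so all six
relationship classes can occur.

This exact structure is deliberate: it is the unique regime in which
(i) every planted edge's conditionals are exactly (0.3, 0.03), making
its true importance exactly log2(10) = 3.32, and (ii) no unplanted
cross-type pair carries any correlation. Multi-parent children or
root→child→grandchild chains would induce confounded pairs with
importance ≈ 1.4–1.8 — above the discovery threshold — and attenuate
true edges, leaving recovery experiments without unambiguous truth.
The default effect sizes put planted importance near the published
osimertinib edge weights (3.49–4.59). Default sizes (3 tumors,
4 drugs, 5 biomarkers, 5 ADRs, 2 background ADR terms, edge density
0.6, ≈ 6 planted edges) were fixed by a design-time power analysis:
at n = 5000 documents the per-edge sampling sd of estimated importance
is ≈ 0.15 (dominated by estimating p_absent = 0.03 from the ~3500
target-absent documents), so recovery bands of ±0.3 are ≈ 2σ per edge
and every additional planted edge lowers the probability that *all*
edges land inside such a band by ~4.5%. Background entities are
ADR-typed only: ADRs are never fitting targets in the root-first
orientation, so rare background terms never become low-count, noisy
targets.

Documents are entity bags — one fixed carrier sentence per present
entity plus a constant filler sentence — so the tagger is exercised
but language is not simulated. Passing tests therefore demonstrate
correct counting, estimation, graph assembly, and ranking under the
model's own assumptions; they say nothing about negation-rich prose,
term ambiguity, reporting biases, or non-independent documents in
real literature.

Known consequence at the shipped study scale: on the fixed evaluation
corpus (generator seed 7, corpus seed 8, n = 5000), relation discovery
attains precision and recall 1.0, but 2 of the 6 planted edges have
importance estimates 0.34–0.35 above truth — just outside a ±0.3
band, consistent with the ≈ 2σ width above. The recovery test asserts
the ±0.3 band regardless and currently fails on those two edges; the
band is reported honestly rather than widened, and the estimator
itself is verified unbiased (empirical conditionals at n = 100 000
match the planted 0.30/0.03 to three decimals).

## Orientation convention

`discover_relations((target_type, feature_type))` fits one model per
target entity. The pipeline runs the six class pairs root-type first
— (tumor, drug), (tumor, biomarker), (tumor, adr), (drug, biomarker),
(drug, adr), (biomarker, adr) — mirroring the "one model per tumor"
construction. The importance measure is not symmetric in its
arguments, and on planted data only this orientation recovers the
planted conditionals exactly; each unordered pair class is scored
once, so re-running a pair in the reverse orientation (which would
generally produce a different, conflicting weight) is not done.

## Numerical and degenerate-case choices

* α = 1 (Laplace) by default; α = 0 gives the pure MLE, in which a
  zero conditional makes importance undefined and raises rather than
  returning ±inf.
* A target with zero positive documents cannot be fitted
  (degenerate-target error); `discover_relations` skips such targets
  with a warning.
* Ties: relation lists order by importance descending, then target
  id, then feature id; explanation paths order by length then
  lexicographic node ids; rank ties break by path support then
  concept id. Posterior odds exactly 1 predict absent.
* Duplicate edge insertions must agree in weight to within a 1e-9
  relative tolerance; otherwise a conflict error.
* Graph weights serialize via `repr` round-trip, preserving full
  float64 precision.
* Agreement statistics raise named undefined-statistic errors on zero
  denominators (e.g., a gold list disjoint from both labeled blocks).
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical config + seed reproduces byte-identical findings output.

## Problem sizes used in the shipped tests

Unit and end-to-end tests run at 50–5000 documents with the default
planted graph (19 entities); the sampling-concentration check uses
30 000 documents and the Bayes-rate Monte-Carlo check 60 000, sizes
chosen so the asserted bands sit at ≥ 4σ. The command-line
end-to-end fixtures use 600 documents with `min_entity_freq = 5`
(the default of 50 presumes corpus-scale frequencies).

## Limitations

* Dictionary longest-match tagging has no word-sense disambiguation,
  abbreviation handling, or syntactic negation scope; the six-cue
  window rule is a coarse polarity proxy.
* Importance is a marginal association measure: it cannot distinguish
  treatment, indication, and adverse-reaction relations, and drug–drug
  interactions are out of scope.
* The cross-validation accuracy definition and the extremes-only
  agreement table are documented interpretations of an evaluation
  protocol that leaves both under-specified.
* Published corpus-scale results (e.g., graph edge counts, kappa
  against a drug's official manual) require the licensed MEDLINE
  corpus and UMLS/WHO dictionaries and are not reproduced here.
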