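# Methods

## Task and data model

The unit of classification is the **CPI-pair**: one compound entity and one
protein entity annotated in the same sentence. Every co-occurring
compound x protein combination in a sentence is a candidate, including
long-form/abbreviation mentions as separate entities; each candidate is
labeled *functional* (the sentence describes direct interaction, regulation,
part-of or cofactor relations), *non-functional*, or *unknown*
(prediction-time corpora). Corpora are trees of documents -> sentences ->
entities/pairs with 0-based, end-exclusive character spans internally; the
XML dialect prints the inclusive offsets conventional for interaction
corpora and converts on the way in/out. PubTator ingestion joins title and
abstract with one space, sentence-splits with a rule-based splitter
(final punctuation + whitespace + capital, abbreviation guard), remaps
document offsets to sentence offsets, keeps Chemical/Gene/Protein
annotations only, and drops (with a warning) annotations that cross
sentence boundaries — candidate pairs are strictly sentence-bounded.

## Preprocessing

Tokenization is regex-based: decimal numbers and hyphenated terms
(`7-ketocholesterol`) stay single tokens, punctuation splits off. Each token
carries orthographic flags (capitalized / punctuation / numeral) and a
part-of-speech tag from a deterministic rule/lexicon tagger: punctuation and
numerals get their own tags, a closed function-word lexicon covers
determiners/prepositions/auxiliaries, and words whose suffix-stripped lemma
(s/es/ed/ing with e-restoration) appears in the interaction-verb lexicon get
verbal tags (VB/VBZ/VBD/VBG by suffix). This tagger cannot resolve
noun/verb homographs ("increase" as a noun); a richer tagger can be plugged
in, and reported numbers always depend on the linguistic backends used.

Dependency parses enter through a named-backend contract returning typed
head->dependent edges. The bundled `fixture` backend returns the
left-to-right token chain (type `next`): deterministic, connected, and
sufficient for testing the kernel machinery; it deliberately contains no
syntax. Prediction mode refuses fixture parses unless explicitly overridden.

Before feature extraction the candidate entities are **blinded**: each
candidate span collapses to a single `COMPOUND_C` / `PROTEIN_C` placeholder
(POS inherited from the span's last token), and by default every other
annotated entity collapses to `COMPOUND_O` / `PROTEIN_O`. Blinding prevents
the models from memorizing entity names. Edges are re-indexed; edges inside
a collapsed span vanish. Pairs whose two candidate spans share tokens are
flagged degenerate and excluded from kernels (logged, and reported as
unscored).

A pair **encloses an interaction verb** when at least one token strictly
between the two entity spans (surface token order, exclusive on both sides —
symmetric in entity order) has a verbal tag and a suffix-stripped lemma in
the verb list. The bundled `data/interaction_verbs.txt` is a curated default
lemma list; any list can be supplied (one lemma per line, `#` comments).

## Shallow linguistic kernel

For a blinded instance, three surface patterns are taken relative to the two
placeholders (first/second by position): fore-between (tokens before the
first placeholder plus tokens between), between, and between-after;
placeholders are excluded and surfaces lowercased. Each pattern is mapped to
a bag of contiguous k-grams, k = 1..n (order preserved inside a gram —
"unsorted patterns" refers to the bag, not to within-gram order, otherwise
n > 1 would be vacuous). The **global context kernel** is the sum over the
three patterns of cosine-normalized dot products, with 0 for empty patterns.

The **local context kernel** looks at windows of size w left and right of
each placeholder: for every in-bounds relative position it emits indicator
features for the neighbor's surface, POS tag and the three orthographic
flags, keyed by (side, entity, position, kind, value). Punctuation tokens
occupy window positions like any other token. The kernel is the
cosine-normalized dot of the left-side features plus that of the right-side
features. The full kernel is the sum of the five cosine-normalized blocks,
so K(x, x) <= 5 with equality when all patterns are non-empty. Per-block
cosine normalization keeps long sentences from dominating and makes decision
scores comparable across CV folds. All blocks are explicit sparse vectors;
Gram matrices are single sparse matrix products per block.

## All-paths graph kernel

Each instance becomes a weighted, vertex-labeled graph: one vertex per
blinded token, labels {lowercased surface or placeholder, `pos:TAG`,
`dep:TYPE` of the incoming dependency (configurable off)}. Every dependency
edge is inserted in **both orientations** — dependency direction would
otherwise disconnect entity pairs in trees. Edges on any shortest undirected
path between the two candidate entities get weight `w_sp` (default 0.9,
following the kernel's original lineage), all other edges `w_other`
(default 0.3).

The total weight of all directed walks of length >= 1 is
`M = sum_{k>=1} W^k`. When the spectral radius of W is below 1 this is the
closed form `(I - W)^-1 - I`; otherwise (common with both orientations at
weight 0.9) the series is truncated at `d_max` terms (default 2x vertex
count) and flagged — never silently rescaled, so the computation stays
deterministic and testable. The feature matrix is `G = L^T M L` with L the
binary vertex x label allocation matrix: entry (a, b) is the total walk
weight from any vertex labeled a to any vertex labeled b. The kernel between
two instances is the Frobenius inner product of their feature matrices over
the union label alphabet, cosine-normalized to unit diagonal. The
linear-order (surface sequence) subgraph of the original two-subgraph
formulation is not implemented: only the dependency graph is used.

## Classifiers

Both learners operate on precomputed kernel matrices and emit real decision
scores (signed distance to the decision boundary), which is what makes AUC
and threshold calibration possible.

* **SVC** (used with the SL kernel): soft-margin dual solution via libsvm
  (scikit-learn's precomputed-kernel interface), coefficients alpha_i y_i
  with 0 <= alpha_i <= C, sum alpha_i y_i = 0; default C = 1.
* **RLS** (used with the APG kernel): dual coefficients
  a = (K + lambda I)^-1 y, one linear solve, no quadratic programming.
  The regularization is parameterized as lambda = 1/c so that a larger c on
  the evaluated grid {0.25, 0.5, 1, 2} means weaker regularization; the
  mapping is explicit and can be bypassed by passing lambda directly.

Thresholding is strict (`score > t`; ties negative), which makes
precision-at-high-threshold well defined. Trained pipeline models serialize
to JSON together with the training instances' sparse feature vectors (needed
to evaluate the precomputed kernel against new instances) and a
preprocessing fingerprint (verb-list hash, parser backend, blinding mode,
kernel parameters) that prediction verifies before scoring.

## Evaluation protocol

Cross-validation is **document-wise**: documents are shuffled by a seeded
RNG and dealt round-robin into k folds, so all pairs of one abstract stay
together (instance-wise splits leak near-duplicate sentences and inflate
estimates). Each fold's pairs are scored by a model trained on the other
folds; scores are pooled across folds into a single report (unit-diagonal
kernel normalization keeps scores comparable; per-fold averaging is not
used). AUC is the Mann-Whitney statistic (ties count half), identical to
brute-force enumeration over (positive, negative) pairs. Undefined ratios
are reported as absent, never as 0; percentages are rounded half-up to one
decimal only at presentation.

Nested CV selects, per outer fold, the grid point with the highest pooled
inner (k-1)-fold AUC (ties: first in grid order) on the outer training
documents, then scores the outer fold with that setting.

The **co-occurrence baseline** labels every pair positive:
metrics(tp = positives, fp = negatives, tn = fn = 0). **Stratification**
recomputes pooled metrics separately on verb-enclosing (IV) and no-verb
(NIV) pairs. Label-verb independence is tested with the Pearson chi-squared
statistic n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 df, no continuity
correction. **Combination** is conjunction: positive only when both kernels
are positive, which provably cannot raise recall above either input nor
lower specificity below either. For a fair comparison,
`matched_precision_threshold` scans candidate thresholds (midpoints of
consecutive distinct scores plus +/-inf, ascending) and returns the one with
the most positive predictions whose precision still meets the target
(+inf with a warning if unreachable).

## Synthetic benchmark generator

The generator emulates the benchmark's statistical structure, not its
language: sentences of `filler* COMPOUND mid [marker] PROTEIN filler* .`
where `mid` is an inflected interaction verb with class-conditional
probability and a neutral function word otherwise, and positives carry an
adjacent marker token with probability 0.8. Defaults are the benchmark's
marginals: positive rate 0.527, verb rate 0.545 given functional and 0.482
given non-functional (derived from the published pair and stratum counts);
vocabulary 100 filler types, 2-5 fillers per side, one pair per sentence
(a multi-pair mode with 2x2 entities exercises candidate enumeration and
non-candidate blinding). One `random.Random(seed)` drives everything, so
corpora are byte-reproducible.

Passing signal-recovery tests on this generator shows the feature
extraction, kernels, classifiers and CV bookkeeping work end to end; it says
nothing about performance on real biomedical text, which depends on parser
and tagger quality and on annotation conventions the generator does not
model (negation, coordination, anaphora, nested entities).

## Problem sizes and numerical choices

Tests and the acceptance script run CV at 200 documents / 400 pairs
(10-fold) and the dependence test at 1,000 pairs — sizes chosen so the whole
suite completes in seconds while keeping binomial noise well inside the
asserted bands. Kernel PSD checks use tolerance 1e-8 on the smallest
eigenvalue; oracle equivalences are asserted at 1e-12 (feature-vector dot
products), 1e-9 (walk series), exact (AUC enumeration) and 1e-6 (RLS vs
numerical minimizer, SVC dual feasibility). Degenerate inputs: empty
patterns contribute 0 to cosine blocks; instances with overlapping
candidates or < 2 vertices are excluded and reported unscored; single-class
training folds are skipped with a warning and their pairs left unscored.

## Known limitations

* No bundled real dependency parser, POS tagger or lemmatizer — the rule
  backends are deterministic stand-ins with documented blind spots; accuracy
  on real text hinges on plugging in real ones.
* The verb list is a curated default, not the historical list used for the
  original benchmark annotation.
* The APG kernel implements the dependency subgraph only (no linear-order
  subgraph) and handles divergent walk series by truncation.
* No probability calibration, confidence intervals or learning curves;
  decision scores are uncalibrated margins.
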