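# Methods

## Problem setting

Online rehabilitation consultation communities accumulate question–answer
threads in which a patient describes symptoms and a doctor names a likely
disease and recommends (or advises against) rehabilitation measures. The
package turns such threads into structured knowledge in two stages: a
supervised relation-extraction stage producing (disease, entity, relation)
triples, and an unsupervised stage clustering the resulting per-disease
knowledge.

The relation inventory is fixed at four classes between a disease (DIS)
and a second entity: `DS` — the entity is a symptom (SYM) of the disease;
`SFD` / `NSFD` — the entity is a rehabilitation measure (TRE) that is
suitable / not suitable for the disease; `UKN` — the pair co-occurs but
the text does not commit to a relation. `UKN` exists so the classifier has
an explicit reject class; it is dropped when dictionaries are assembled.

## Instance construction

A classification instance is the whole record (question title + content +
answers, joined by a single space) with the two candidate entities replaced
in place by position markers: `#` for the disease, `*` for the second
entity. Marking by replacement rather than by flanking tags keeps the
sequence length unchanged and makes entity order unambiguous to the model.
Instances serialize as `LABEL@entity1$entity2$marked_text`; parsing splits
on the first `@` and first two `$` only, so surfaces may contain those
characters. Literal `#`, `*` and `\` in text are backslash-escaped on
write and restored on read — the line format reserves the bare markers for
positions. The legacy spelling `NSF` is accepted on read and normalised to
`NSFD`.

At prediction time candidate pairs are enumerated as all ordered
(DIS, SYM) and (DIS, TRE) mention pairs with disjoint spans in a record;
pairs the classifier labels `UKN` survive to the triple list (for auditing)
and are discarded at dictionary assembly.

### Stratified split

Instances are shuffled per class and split 6:2:2. Per class, training
receives round-half-up(0.6·n); the remainder is halved between validation
and test, and when it is odd the spare instance goes to whichever of the
two currently holds fewer instances (classes processed in the canonical
order DS, SFD, NSFD, UKN; ties to test). This balancing rule keeps the two
held-out partitions the same size overall — on the class counts
901/3602/497/235 it yields exactly 3141/1047/1047. Classes with fewer than
three instances cannot be split three ways and go wholly to training with
a warning.

## Encoding

Tokenization is pluggable: whitespace splitting (used for the synthetic
corpora) or per-character (for scripts without word boundaries); the
position markers always come out as single tokens, even glued to a word.
Text is NFC-normalised and otherwise untouched. Sequences are padded or
head-truncated to length L; if truncation would drop a marker the instance
is flagged and excluded from training/prediction, since the pair's
positions are gone.

The default backend is a trainable lookup table: rows drawn
N(0, 1/√D) from a seed, updated by gradient descent together with the
network (the analogue of fine-tuning the embedding layer). A frozen
pretrained contextual encoder (sequence length 200, width 768) can be
plugged in through an optional adapter; nothing else in the package
depends on it, so the default configuration needs no downloads. Padding
rows are exactly zero and carry a False mask bit; the attention layer
assigns them exactly zero weight.

## Classifier

Per direction a standard GRU (update/reset gates, candidate state
n = tanh(W_in x + r ∘ (W_hn h + b_hn) + b_in), h' = (1−z)∘n + z∘h) runs over
the unmasked positions with u = 32 hidden units; outputs are concatenated
to H ∈ R^(L×2u). Attention pooling computes M = tanh(H), scores ωᵀM with a
trainable ω ∈ R^(2u), masks padded positions additively with −1e9 before
the softmax (a finite stand-in for −∞ that cannot produce NaNs), and forms
c = Σₜ αₜHₜ ∈ R^64. A fully connected layer plus softmax yields class
probabilities; argmax ties break to the lowest label index.

Training minimises categorical cross-entropy by mini-batch gradient
descent. The optimiser is Adam (β = 0.9/0.999, ε = 1e-8) by default — the
de-facto choice for this architecture family — with plain SGD available
via configuration. Defaults: batch 16, 40 epochs, learning rate 5e-4,
dropout 0.2 applied to H (post-BiGRU, pre-attention) during training only.
Class imbalance is handled only by the stratified split; there is no loss
re-weighting. After every epoch the validation split is scored and the
parameters of the best weighted-F1 epoch (strictly better; earliest wins
among exact ties) are restored at the end, together with the embedding
table when it is being trained. All initialisation, shuffling and dropout
derive from one seed, so a run is exactly repeatable.

The forward and backward passes (BPTT through both GRU directions, the
attention softmax, dropout and the cross-entropy head) are hand-written in
NumPy; the test suite checks every gradient block against central finite
differences at 1e-7 tolerance. A mean-pooling variant (α uniform over
unmasked positions) is built in as the ablation partner for the attention
layer.

## Evaluation metrics

Per class (one-vs-rest): P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R), with any 0/0 defined as 0. The aggregate "Total" row is
the support-weighted mean of per-class values — the only common scheme in
which total P, R and F1 can all differ — with the micro average (equal to
accuracy for single-label data) reported alongside. ROC-AUC uses the rank
statistic; AUPR uses the step-wise average-precision rule, avoiding the
optimistic trapezoidal interpolation of PR points. Classes absent from the
truth get NaN areas and are excluded from the weighted aggregate.

## Dictionaries, graphs, contradictions

Triples are grouped by relation into DS/SFD/NSFD dictionaries mapping
disease → insertion-ordered unique value phrases. Bookkeeping guarantees
kept + dropped-UKN + dropped-duplicates = input size. Values match by
exact surface by default; an optional case-folding/whitespace-trimming
mode exists for noisier predictions, and the same switch governs the
SFD∩NSFD contradiction scan (measures recommended by some doctors and
advised against by others for one disease — a finding worth surfacing to
community moderators, not an error). Per-disease star graphs (disease
centre, one edge per value, edge attribute = relation kind) export to
GraphML via networkx and to DOT via a small built-in serializer.

## Clustering

Documents are diseases; the terms of a document are its value phrases.
Phrase-level terms are the default because dictionary values are short
curated phrases whose identity, not their word content, carries the
signal; a word-level mode is a flag. TF-IDF uses raw counts with smoothed
idf ln((1+N)/(1+df)) + 1 and L2 row normalisation, down-weighting phrases
that occur for most diseases. PCA (mean-centred, full SVD) keeps the
smallest component count explaining ≥ 95% variance, capped at
min(50, n−1) — unreported in the problem setting, fixed here once.

kmeans++ seeding samples each next centre with probability proportional to
squared distance from the nearest chosen centre (the probabilistic D²
rule, fully seeded); Lloyd iterations run to inertia change ≤ 1e-6 or 300
rounds, with a monotone-descent assertion each step and farthest-point
re-seeding of emptied clusters. Per k the procedure runs five times: the
silhouette coefficients are averaged across the repeats (mean-of-5, the
natural reading of "repeat five times and average"; best-of-5 is the other
reading and is not implemented) and the lowest-inertia run is kept as the
reported partition. Silhouette s = (b−a)/max(a,b) with singleton points
scored 0. Default cluster counts are DS 15, SFD 20, NSFD 6; a k-grid scan
maximising mean silhouette is available, with the caveat that silhouette
tends to rise with k, so grids should be capped. The largest cluster is
marked "residual" in the report when its members' mean silhouette is
negative — a catch-all of leftovers rather than a coherent group.

## Synthetic corpus

The generator emulates the discourse structure of consultation threads:
the question carries symptom mentions, the answer names a disease and a
measure with a relation cue drawn from the label's lexicon ("recommended",
"take", … for SFD; "avoid", "reduce", … for NSFD; "could_be", … for DS),
and UKN records put both entities in the question with a non-committal
answer and no cue. A configurable fraction of answers replaces the disease
name with the pronoun phrase "your condition" (the disease then appears in
the question), mimicking doctors' coreference. Noise sentences are
cue-free filler clauses inserted around the relation-bearing clause — they
exercise exactly the noise-filtering ability attention pooling claims.
Class proportions default to 901:3602:497:235 (the imbalance of an
annotated rehabilitation corpus, SFD ≈ 68.8%). The token alphabet is
synthetic (disN/symN/treN plus filler words) and deliberately
language-neutral: the pipeline under test must be script-agnostic.

What the generator does not emulate: real lexical variety, misspellings
and speech-to-text artifacts, polysemy (each token has one role), multiple
relations per record, and distractor cue words inside noise. Passing tests
therefore demonstrate that the pipeline recovers structure that is present
and separable — an implementation check, not a claim about performance on
real clinical text, where ceiling F1 would be far below the ≈1.0 observed
on noiseless synthetic data.

## Problem sizes used in tests and the acceptance script

Training runs use scaled conditions chosen once: the recovery run is 800
records, L = 64, D = 32 with the full default hyperparameters (batch 16,
40 epochs, lr 5e-4, u = 32, dropout 0.2); the attention-vs-mean ablation
uses 5 seeds × 300 records at noise rate 0.8, L = 48, 12 epochs. The
exhaustive-search equivalence check for kmeans uses n = 8, k = 2 with 50
seeded restarts (a 7–1 optimal split is a rare seeding event, so the
restart count is generous). Clustering recovery plants 3 symptom motifs
across 24 diseases.

## Known limitations

* The recurrent network is CPU NumPy; it is meant for method-scale
  experiments (thousands of instances), not production corpora.
* The pretrained-encoder adapter is frozen-features only; fine-tuning the
  contextual encoder end to end is out of scope.
* Entity mentions are assumed given (no named-entity recognition), and
  contradiction detection is surface-level string matching — synonymous
  measures are not unified.
* With `UKN` trained as a class rather than calibrated as a rejector,
  rare-class recall depends strongly on how much UKN data exists.
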