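# Methods

This note documents the models, parameters and design decisions behind
`riskstream`: what each component computes, which knobs matter, what the
synthetic data does and does not emulate, and where the package's behaviour
is a deliberate choice among defensible alternatives.

## 1. Execution-graph engine (`streamcore`)

The engine reproduces the observable semantics of a distributed
stream-processing platform — source/middle/leaf stages, queue-backed edges,
cycles, multi-input scheduling, per-stage instance scaling — inside one
deterministic process. A production deployment would put a message broker
between stages and run instances in containers; here the broker is an
in-process FIFO queue with the same per-edge ordering contract, and an
"instance" is a worker closure. This keeps every run bit-reproducible and
hardware-independent, which is what the test suite needs: the properties
being checked (ordering, scaling invariance, drain, dead-lettering) are
properties of the semantics, not of any transport.

Scheduling is tick-based: one tick is one message-delivery opportunity.
Nodes with several inbound edges choose a queue per tick through an input
policy:

* **parity** — round-robin over the inbound edges, skipping empty queues;
* **exponential** — each edge is granted a fraction
  $2^{p_e} / \sum_f 2^{p_f}$ of the ticks in a fixed window, where $p_e$ is
  the edge's non-negative integer priority. Grant counts within a window
  are apportioned by largest remainder, so whenever $\sum 2^p$ divides the
  window length the proportions are exact. The base 2 is the simplest
  function that grows exponentially with priority; the normalised form
  guarantees every edge at least one grant per window (no starvation of
  priority-0 inputs), which is a choice — an implementation that starves
  low-priority inputs under load would also be consistent with "fractions
  growing exponentially".

Stateful stages require keyed envelopes and route by
`crc32(key) mod instances`, so a given key always reaches the same instance
and per-key state never splits. Python's built-in `hash` is salted per
process and would break reproducibility. Stateless stages are scaled
round-robin; because the engine is sequential, their outputs are invariant
under any instance count (the tests assert multiset equality for 1/2/4).

A node function that raises sends the offending message to a dead-letter
record and the run continues: a monitoring pipeline must not halt on one
malformed document. Payloads crossing edges support JSON scalars, lists,
string-keyed maps, numpy arrays and 1×n CSR sparse vectors; serialisation
is tagged JSON + zlib and round-trips exactly (property-tested, including
NaN).

## 2. Text representation (`textrep`)

Tokens are lowercased maximal runs of Unicode letters/digits (underscores
split). No stemming, stop-listing or n-grams: the classifier downstream is
regularised, and a fixed, trivially reproducible tokenisation matters more
here than linguistic sophistication.

The vocabulary is built from the *training* split only, keeping terms with
document frequency ≥ `min_df` (default 2 — hapax terms carry no usable
signal for a per-user classifier and inflate the artifact), indexed in
lexicographic order so builds are deterministic.

Each user's accumulated representation is a sparse count vector merged
submission by submission. The merge is exact bag-of-words addition, so
streaming aggregation equals batch concatenation at the count layer — the
property that makes the replay graph and the offline incremental policy
provably agree. tf–idf is applied *on read*:

$$\mathrm{idf}_t = \ln\frac{1 + N}{1 + \mathrm{df}_t} + 1,$$

raw term count × idf, L2-normalised (the smoothed variant avoids division
by zero and matches the common default; the test suite cross-checks both
the idf vector and the transformed rows against scikit-learn's
`TfidfTransformer` to twelve decimals). idf statistics are fitted once from
the offline training corpus and frozen for streaming; because the stored
state is raw counts, a refreshed idf never requires re-ingesting users.

An optional per-user submission cap (`max_submissions_per_user`) exists for
emulating collections that truncate user histories; it is off by default.

## 3. Depression language classifier (`classifier`)

Each training user is one document — the concatenation of all their
writings — vectorised and tf–idf-transformed as above. The model is
L1-regularised logistic regression (scikit-learn's liblinear solver,
tolerance 1e-6), which zeroes uninformative term weights and keeps
per-message scoring cheap.

The regularisation strength C is selected from the grid
{0.01, 0.1, 1, 10, 100} by stratified 4-fold cross-validation maximising
mean positive-class F1; ties resolve to the smaller C (stronger
regularisation). Stratification matters because the class ratio is ~1:4 to
1:5; F1 is the selection metric because it is the headline classification
metric of the comparison table this package produces. The winner is
refitted on all training data. Folds are shuffled with the run seed, and
identical (corpus, grid, folds, seed) yields identical coefficients
(asserted to 1e-8). idf is fitted once on the full training corpus rather
than per fold; this slightly optimistic CV is acceptable because CV is used
only to pick C, not to report performance. Class weights are uniform.

The artifact bundles vocabulary, idf, sparse β, β₀, the chosen C and the
full CV table, so the topology and policy layers need nothing but the one
JSON file, and prediction is computed directly as σ(β·x + β₀).

## 4. Decision policies (`policies`)

* **Random** — Bernoulli(0.5) at k = 1. Baseline.
* **All-positive** — label 1 at k = 1. Recall 1, precision = prevalence.
* **First-n** — score the concatenation of the n oldest submissions once;
  positive iff p > 0.5 (the canonical logistic decision boundary; the
  method description leaves the cut implicit). Users with fewer than n
  submissions decide at exhaustion, so k = min(n, nᵢ) exactly. With n at
  least the longest stream this is the "All" method.
* **Incremental** — after each submission, merge and re-score; emit a
  positive at the first probability *strictly* greater than the threshold
  (consistent with the alert manager's "greater than" rule); if the stream
  ends without a crossing, negative at k = nᵢ. The method never emits an
  early negative — by the first-crossing construction, raising the
  threshold can only shrink the positive set and lengthen delays
  (property-tested at 0.5/0.75/0.9, the standard threshold set).

## 5. Evaluation (`evalmetrics`)

P, R and F1 use the 0/0 → 0 convention, so an all-negative baseline scores
zero everywhere. ERDE is implemented as in the README formula with
latency cost $lc_o(k) = \sigma(k - o)$ computed via `scipy.special.expit`
(numerically exact for any delay; the naive exponential overflows past
k − o ≈ 700). Cost constants: $c_{fn} = c_{tp} = 1$ fixed defaults,
$c_{fp}$ defaulting to the positive prevalence of the evaluated decision
set, all overridable through `ERDEParams` and recorded in reports. The
first submission counts as k = 1.

The implementation is validated three ways: closed-form corner cases
(all-TN → 0, single FN → c_fn, TP at the deadline → cost 0.5), an
independent brute-force per-user summation on random instances (agreement
to 1e-12), and order properties (monotone in every TP's delay, saturating
at the miss cost; ERDE₅ ≥ ERDE₅₀ for identical decisions). Published ERDE
values for real collections are *not* reproduction targets: they depend on
access-restricted data and on cost constants not recoverable from the
comparison tables alone.

## 6. Synthetic collections (`synthdata`)

The generator emulates the *structure* of early-risk benchmark
collections, not their content: train/test splits, a depressed and a
control group, per-user chronologies with ordered timestamps, and group
sizes 83/403 (train) and 52/349 (test) matching the 2017-style benchmark
shape. Submission counts per user are log-normal with group means 37.2
(depressed) and 65.6 (control) — the published per-group averages scaled
down ×10 so the full default collection generates in about a second —
with log-scale spread 0.6; words per submission are Poisson with the
published group means (27.6 / 21.3) kept unscaled. Tokens are drawn from a
Zipf distribution over an artificial 500-term vocabulary, giving the
natural-language-like sparsity that makes tf–idf and L1 selection behave
realistically.

The class signal is a planted vocabulary shift: 10 marker terms at Zipf
ranks 10–19 (moderately frequent — detectable but not dominant) have their
probability multiplied by (1 + δ) in the depressed group, after which the
distribution is renormalised. Two consequences worth knowing:

* Renormalisation necessarily *deflates* all non-marker terms in the
  depressed group (by ~5 % at δ = 0.5), so the most frequent terms become
  genuinely informative in the negative direction. A fitted L1 model
  therefore assigns them real negative weights that compete with the
  weakest markers in any "top coefficients" ranking. This is a property of
  the generative design, not an artefact of the fit.
* With the published per-group length profiles, the groups differ in
  volume as well as vocabulary, and document length alone is learnable
  (rare-term presence grows with tokens written). For experiments that
  isolate the vocabulary-shift parameter — exchangeability at δ = 0,
  signal monotonicity in δ, marker recovery — the package provides
  `parameter_recovery_config`, which gives both groups the control
  profile so δ is the only systematic group difference. At δ = 0 this
  design is exchangeable by construction and a trained classifier stays at
  chance AUC; with the default per-group profiles it would not.

The study sizes used by the tests and the acceptance script: 40/160
training users and 20/80 held-out users for the δ = 0.5 recovery study
(keeping the ~1:4 imbalance), 80/320 held-out users for the δ = 0 chance
check (AUC's sampling error at 100 users would be ±0.07 alone), and a
50-user test split (seed 42) for the streaming-equals-batch comparison.

Optionally the generator plants one explicit diagnosis submission
("i was diagnosed with depression") per depressed user;
`remove_diagnosis_posts` strips them, mirroring the curation step real
collections apply. The tests demonstrate the leak this prevents: with the
posts left in, the phrase's tokens enter the vocabulary and become a
perfect shortcut feature.

What the generator does **not** emulate: real English, topical community
structure, per-user drift over time, label noise, and any correlation
between text volume and content. Passing tests therefore show that the
pipeline's machinery is correct and that parameter recovery works under a
known generative model — they say nothing about classifier performance on
real social-media text.

## 7. Prediction topology (`topology`)

The wired graph scores every user after every submission:
replayer → text vectorisation → aggregator (stateful, keyed by user) →
tf–idf → model prediction → probability storer + alert manager. Default
instance proportions for the four scalable stages are 2-4-4-1
(vectorisation : tf–idf : aggregation : prediction), a workload-balancing
ratio for the stages' relative costs. The aggregator is the only stateful
stage; keying it by user is what makes it safe to scale — hash-partition
routing guarantees each user's state lives on exactly one instance.

The replayer emits submissions in global timestamp order (stable ties:
user, then input order), standing in for a live crawler. The alert manager
fires at most one alert per user, at the first probability strictly above
the threshold — the streaming mirror of the incremental policy, and the
acceptance suite asserts exact agreement (user sets and delays) at all
three standard thresholds under instance counts 1/2/4. Per-submission
scoring is the reference semantics; a loaded deployment might micro-batch,
which would only delay, never change, the first crossing.

Run statistics report counts only (submissions processed, users analysed,
alerts fired, dead letters); processing *speed* is deliberately excluded
from any report the tests depend on, being hardware-bound.

## 8. Known limitations

* The engine is single-threaded by design; it models concurrency semantics
  but measures nothing about throughput.
* Incremental scoring is O(total submissions × score cost); the replay
  rebuilds a tf–idf vector per submission rather than updating the dot
  product incrementally. Fine at desk scale; a deployment would cache.
* The classifier is a linear bag-of-words model; calibration beyond the
  logistic link, n-grams, embeddings and psycholinguistic lexicons are out
  of scope.
* ERDE's cost constants are configurable precisely because published
  values for real benchmarks cannot be reproduced desk-side; comparisons
  across papers should fix and report them.
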