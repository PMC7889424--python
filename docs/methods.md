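# Methods

## Scope and data model

`medsim` scores the semantic similarity of clinical sentence pairs on the
[0, 5] scale.  Corpora are plain TSV (`sentence_a<TAB>sentence_b[<TAB>score]`,
UTF-8, no header); sentences must be non-empty and scores, when present,
must lie in [0, 5].  Lines with any other field count are rejected —
clinical STS sentences contain no tabs, so no escaping scheme is needed.
Predictions are one `repr`-precision decimal per line, which round-trips
far below the 1e-9 comparison tolerance used throughout.

## Medication entity extraction

Prescription sentences follow a rigid template
(`<agent> [<BRAND>] <strength> <unit> <form> <n> <form>s by mouth <frequency> [as needed]`).
A single anchored regular expression extracts five entities: strength
amount and unit, dose amount and unit, and frequency.  Conventions:

* number words map to reals ("one-half" → 0.5, "two" → 2, … "twelve" → 12);
* "every H hours" yields frequency H and "N times a day" yields N — both
  feed the single ratio-scaled frequency feature, and once-daily phrasings
  ("one time daily", "every morning", "daily") yield 1.  The two phrasing
  families are deliberately *not* converted onto one events-per-day axis;
  the learned λ weight absorbs the scaling;
* bracketed brand names are stripped; agents and units are lowercased and
  a small synonym table collapses mg/milligram, tab/tablet, cap/capsule;
* a sentence that matches the template but lacks a dose or frequency is
  filled with sentinels (amount 0, unit "none") and a warning is logged,
  so the Δ vector is defined for every extracted pair.  Sentences that do
  not match at all yield "no record", and a pair counts as a medication
  pair only when *both* sentences parse.

The Δ vector is ordered (strength_amount, strength_unit, dose_amount,
dose_unit, frequency): squared difference for ratio-scaled entities,
exact-match indicator (0 equal / 1 different, after normalization) for
nominal ones.  Both forms are symmetric, so Δ(a, b) = Δ(b, a) and
Δ(a, a) = 0.

## Graph model

**Edge construction.**  For each agent pair observed together in training,
every observed score is shifted by `+tanh(λ0 + Σ λk Δk)` — removing the
estimated influence of the non-agent entities — clipped to [0, 5], then
averaged over the observation set, and finally floored at
`weight_floor = 1e-6` (keeps 1/w finite for zero-score edges).  Clipping
per observation *before* averaging was an open choice; it keeps every
contribution on the score scale.  Same-agent training pairs contribute
nodes but no edges.

**Sign convention.**  Edge construction *adds* the tanh adjustment and
inference *subtracts* it, making the two transformations exact algebraic
inverses: with a single observation and the same Δ at inference the
observed score is recovered to machine precision (absent clipping).  The
edge weight is thus an estimate of agent-only similarity; inference
re-applies the entity influence of the query pair.

**Shortest path.**  Queries between non-adjacent agents run Dijkstra with
edge length 1/max(w, weight_floor).  The selected path minimizes Σ 1/w,
and the reported similarity is the reciprocal of that sum — the
parallel-resistance aggregate.  Choosing the path by the same objective
that defines the aggregate makes "shortest" and "most similar chain" one
criterion; the alternative (hop-count shortest paths) can pick a chain
through a low-similarity edge even when a slightly longer high-similarity
chain exists.  Ties break by fewer hops, then lexicographic node
sequence, so results are deterministic.  The implementation carries
(resistance, hops, node sequence) in the priority queue; all three
components are prefix-monotone, so Dijkstra's optimality argument applies
to the full tuple.  The aggregate is bounded above by the smallest weight
on the path: low similarity anywhere in the chain caps the result.
A consequence worth knowing: where a *weak direct edge* coexists with a
strong two-hop chain, the query follows the chain and reports a higher
similarity than the direct observation.

**Disconnected or unseen agents.**  By default the graph reports "no
prediction" and callers keep the base predictor's score — replacement is
subset-only by design.  A numeric fallback can be configured instead.
Same-agent queries are not modeled by the graph (no self-edges); at the
sentence level a same-agent pair is scored from the maximal agent
similarity 5 before entity adjustment.

## Learning λ

λ = (λ0, λ1..λ5) is fitted by an accept-if-better random walk: split the
medication pairs into 10 seeded folds; at each of 50 steps pick one
coordinate uniformly, add a standard-normal draw, rebuild the per-fold
graphs, predict every held-out pair, concatenate predictions over all
folds and compute one MSE; accept iff it strictly decreases.  The
accepted-MSE trace is therefore strictly decreasing, and the whole
procedure is a pure function of its seed.  Held-out pairs whose agents
are unreachable in their fold's graph are excluded from the MSE; since
graph connectivity does not depend on λ, the exclusion set is constant
across proposals and the comparison stays fair.  λ is initialized from
N(0, 0.1²) with a fixed seed.  MSE rather than a correlation drives the
walk because closeness on the subset, not subset-internal ranking, is
what the replacement step needs.

The walk alternates twice with tuning of the fusion stage: an RBF-kernel
support vector regression over the two-feature rows (graph score, base
score), C ∈ {0.1, 1, 10, 100} and ε ∈ {0.01, 0.1, 0.5} chosen by 5-fold
cross-validated MSE, kernel bandwidth fixed by the median pairwise
squared-distance heuristic, and solver tolerance tightened to 1e-8 so the
fit is invariant to training-row order.  The fusion SVR is trained on all
training pairs, with the base score standing in for the graph score where
the graph is silent; replacement at prediction time still touches only
pairs where the graph actually produced a score.  After the final
iteration the graph is rebuilt from all training data with the final λ.

## M-Heads ensemble

The final affine regression layer over a (pluggable, deterministic)
pair-encoder is duplicated M times with distinct seeded initializations.
Training minimizes the responsibility-scaled loss
Σᵢ Σₘ α_im ℓ_im with ℓ_im the squared error of head m on example i and
α_im = softmax over heads of (−ℓ_im / T), recomputed each epoch and held
fixed within the gradient step — a soft winner-take-all scheme: heads
that already fit an example best receive most of its gradient, so heads
specialize on input regimes.  Temperature T defaults to 1.0 with an
optional per-epoch annealing factor.  With M = 1 the responsibilities are
identically 1 and training is *numerically identical* to plain MSE
gradient descent (asserted to 1e-9 against an independent loop).
Inference averages the heads (clipped to [0, 5]); a
responsibility-weighted mode using each head's average training
responsibility is available behind a flag.  The defaults (full-batch
gradient descent, learning rate 0.05, 200 epochs) are sized for the
low-dimensional similarity-feature encoder; transformer fine-tuning is
out of scope, and any encoder satisfying determinism can be plugged in.

## Similarity features and voting

The default registry: Jaccard and Dice on character n-gram sets for
n ∈ {2, 3, 4}, a normalized longest-common-substring ratio, and the
cosine of sentence embeddings.  Feature Sets I and II are two named
presets of this registry (I: the full set, concatenated to the encoder
vector; II: a leaner set for the stacking estimators); both are
user-overridable, and the feature-vector length is a pure function of the
config.  The default embedder hashes character trigrams into 128 signed
buckets (CRC32, stable across processes) and L2-normalizes — a
deterministic surface-overlap embedding, not a semantic one; InferSent-
or transformer-based embedders can be substituted through the same
contract.  Voting regression is the plain arithmetic mean of estimator
outputs; the default stacking registry (ridge, RBF-SVR,
gradient-boosted trees) is provided for convenience but only the
averaging contract is asserted.

## Evaluation protocol

Folds are a seeded uniform shuffle followed by contiguous chunking (no
stratification).  Each pair is held out exactly once; one Pearson r is
computed over the concatenated out-of-fold predictions in original pair
order — per-fold correlations are never computed, so the protocol yields
no variance estimate.  k defaults to 150 for protocol parity; the test
suite uses k ≤ 10 for runtime.  Test-time prediction averages the k fold
models (clipped to [0, 5]).  Subset MSE over a boolean mask serves as the
medication-subset metric.  Pearson on a constant vector raises rather
than returning NaN.

## Synthetic data

The generator emulates a clinical STS medication subset with fully known
latent structure:

* **Agents** get invented pronounceable names and 3-dimensional latent
  embeddings; similarity is 5·exp(−d/2) of the Euclidean distance
  (diagonal exactly 5).  Distance-derived similarities approximately
  satisfy the transitivity the graph model assumes, which is what makes
  shortest-path extrapolation meaningful on this data.
* **Sampling** draws agents with Zipf-like popularity weights
  (∝ rank^−0.8), mirroring the skewed drug frequencies of real
  prescription data and giving the graph realistic hub structure.
  Strengths come from a formulary-like list (4–500, mg with occasional
  mcg), doses from {½, 1, 2, 3} tablets/capsules, frequencies from 1–4
  times a day or every 4–12 hours.
* **Scores** follow the model the graph assumes:
  clip(sim(a, b) − tanh(λ*·(1, Δ)) + ε, 0, 5) with ε ~ N(0, noise_sd²).
  The default λ* = (0.1; 2e-5, 0.4, 0.15, 0.3, 0.02) puts each component
  on the scale of its feature (squared mg differences reach ~2.5e5, hence
  the small strength-amount weight) so the tanh argument spans roughly
  [0, 2] — effects are present but not always saturated.  Default
  noise_sd = 0.2 corresponds to the disagreement expected between human
  annotators after averaging.
* **Rendering** emits template sentences that re-parse to their
  generating record by construction (asserted at 100%); frequency phrasing
  is randomized between the two families.
* **Filler pairs** come from a small narrative template bank; their
  scores follow regime-dependent mappings from sentence overlap
  (alternating slope sign per regime) to provide the bimodal structure
  that head specialization needs.  They carry no medication content and
  exist for subset gating and regime diversity only.

What passing tests on this data do *not* show: robustness to free-text
prescription variants outside the template, real annotator behaviour,
EHR language statistics, or the transfer of a tuned λ to a corpus whose
entity effects are not tanh-bounded.  The generator shares its score
model with the graph (by design, to make λ identifiable); recovery
results are therefore a correctness check of the fitting machinery, not
evidence about model mismatch on real data.

## Problem sizes and numerics

The reference experiment (also run by `scripts/acceptance.py`) uses
30 agents, 600 medication pairs, a 450/150 train/test split, 10 folds,
two 50-step walk iterations — about ten seconds on one CPU, chosen so the
full pipeline including graph rebuilds per proposal stays interactive.
Tolerances: exact-inverse round trip 1e-9; path-oracle agreement 1e-12
relative; SVR order invariance 1e-6 (solver tolerance 1e-8).  Degenerate
inputs raise rather than guess: empty observation sets, self-similarity
queries, constant vectors for Pearson, empty masks, fewer pairs than
folds.

## Known limitations

* The extractor handles the rigid template only; free-text dose
  instructions ("take with food"), ranges ("1-2 tablets"), and routes
  other than oral are out of scope.  Externally extracted entities can be
  supplied instead of the built-in extractor.
* Edge weights collapse the observation multiset to (mean, count); raw
  per-observation data is not retained in the graph.
* The random walk is a local search; different seeds can end in different
  λ with comparable out-of-fold MSE, and on some corpora the tuned λ
  generalizes no better than λ = 0.
* Scores outside [0, 5], directed relations, and per-fold variance of the
  concatenated correlation are unsupported by design.
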