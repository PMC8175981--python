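# Methods

## Generative model

A labeling event is generated in four stages. A speaker's group *G* fixes a
characteristic knowledgeability θ_g ∈ [0, 1]; the speaker's own
knowledgeability is K ~ Bernoulli(θ_g). Given an object's true category *C*
from a finite label space of size *n*, the speaker commits to an intention
*I*: the delta function on *C* when K = 1, a single uniform draw over the
*n* labels when K = 0. Every token *D* the speaker produces equals *I*.

Two modeling commitments matter downstream:

* **Speaker consistency.** The intention is drawn once per speaker–object
  pair and then repeated. The likelihood of *t* identical tokens from one
  pair is therefore 1 (K = 1, tokens equal *C*) or 1/n (K = 0, tokens equal
  anything), independent of *t*; mixed tokens within a pair have likelihood
  zero under both K values, and such corpora are rejected at validation
  rather than silently zeroed, because no posterior exists over a
  zero-probability observation. The alternative reading — i.i.d. token
  draws — would make a lone speaker's seven repetitions almost conclusive
  (posterior on the repeated label ≈ 0.999) instead of the 2/3 the
  consistency reading yields, and would erase the single-vs-multiple speaker
  contrast the model exists to capture.
* **No production noise.** D ≡ I in this release. The two stages are kept
  distinct in the API (`intention_distribution`, `data_distribution`) so a
  confusion-matrix production model can be added without interface changes.

Labels are opaque, case-sensitive strings with no phonetic structure.
Deceptive (knowledgeable but wrong) informants are excluded by construction,
as is graded knowledgeability.

## Inference

**Knowledgeability from one event.** With the category known, Bayes' rule
over the two K values uses likelihoods (1, 1/n) for a correct token and
(0, 1/n) for an incorrect one. An incorrect token therefore pins K = 0; if
the group prior is θ = 1 the observation has zero prior probability and an
`ImpossibleObservationError` is raised. Event informativeness is the KL
divergence between posterior and prior, with 0·log(0/q) ≡ 0, and an
`UndefinedDivergenceError` (not +∞) when the posterior has mass where the
prior has none — the θ = 1, incorrect-token case. **All KL values are in
bits (base-2 logs).** The base is identified by the reported
incorrect-audio-speaker cell: 0.2345 = −log2(0.85).

**Reference parameters.** The word-recognition runner defaults to
θ_adult = 0.80, θ_audio = 0.15, n = 3. The source text for these simulations
states θ_adult = 0.85, but no label-space size reproduces the reported
informativeness table with 0.85 (the incorrect-adult cell is −log2(1 − θ),
giving 2.7370, vs. the reported 2.3219 = −log2(0.20)); all four reported
cells are reproduced to print precision by θ_adult = 0.80 with n = 3
(0.08453, 2.32193, 0.17013, 0.23447). We treat 0.85 as a typo, default to
0.80, and accept either via configuration. The reported correct-adult cell
0.0846 differs from direct evaluation (0.08453) in the last digit; we treat
this as rounding noise and compare at ±0.0002.

**Joint label + knowledgeability.** For a corpus from *m* speakers over *o*
objects, exact inference enumerates every (label assignment, K⃗) pair —
n^o · 2^m hypotheses, asserted before normalization — scoring each as the
product of per-speaker-object sequence likelihoods, per-speaker Bernoulli
priors on K, and the label prior (uniform by default; per-object
independent). For a single object this is the familiar n · 2^m space.
Multi-object corpora are enumerated jointly because the shared K couples
objects. Enumeration refuses above m = 20 speakers and directs callers to
the Gibbs sampler.

**Gibbs sampler.** The full conditionals follow from the joint: each
object's category is drawn from P(C | K⃗, D⃗) ∝ P(C) · Π_m P(D_m | C, K_m),
then each speaker's K_m from P(K_m | C, D⃗) ∝ P(K_m) · Π_obj P(D | C, K_m),
in a systematic scan. (The derivation is re-done from the joint; no
published sampler settings exist for this model.) The chain initializes at
all-K = 0, which is in the support for any category assignment, and samples
C first, so no repair step is ever exercised; the `support_repairs`
diagnostic records this (always 0). Defaults: 20,000 kept sweeps after
2,000 burn-in, one chain, seeded `numpy.random.default_rng`. Estimates are
raw post-burn-in state frequencies, mirroring the procedure the reported
multi-speaker posterior (0.9992 vs. the exact 0.999878) appears to reflect;
a Rao-Blackwellized label-marginal estimator (averaging the exact
conditional P(C | K⃗, D⃗) over kept sweeps) is available via
`GibbsSettings(rao_blackwell=True)` but off by default, and the sampler is
never tuned toward the reported Monte-Carlo figures. Diagnostics report
kept-sample counts and a batch-means effective sample size of the
modal-label indicator.

## Synthetic corpora

`sample_corpus` draws speakers exactly from the generative process:
K ~ Bernoulli(θ_g), one intention per object, tokens equal to the intention.
One child RNG is spawned per speaker from the design's root seed
(`numpy.random.SeedSequence`), so adding a speaker never perturbs others'
draws and corpora are bit-reproducible. Generated corpora satisfy the
consistency invariant by construction. What the generator does **not**
emulate: phonetic or acoustic variation, production errors, speaker
misattribution, or trial-by-trial belief updating — so passing recovery
tests show the inference machinery is correct under the model's own
assumptions, not that the model fits real infant data.

`recovery_experiment` runs exact inference with matched priors (each
speaker's K prior set to their group's θ) and reports MAP accuracy and mean
posterior mass on the truth; MAP ties break by label-space declaration
order so results are deterministic. Default study-like setting used in the
tests: θ = 0.9, 10 speakers, 3 labels, 200 replicates — small enough to run
in seconds while leaving the binomial noise on the accuracy estimate well
below the 0.95 acceptance floor.

## Simulation runners

* **Word recognition** (`run_simulation1`): the four informativeness cells
  for (adult, audio) × (correct, incorrect) at the reference parameters;
  requires θ < 1 and n ≥ 2. The parameter sweep evaluates the interaction
  statistic [KL(inc) − KL(cor)]_human − [KL(inc) − KL(cor)]_audio on a
  shared θ grid (default 19 points over [0.05, 0.95]; 1 is excluded because
  the incorrect-event divergence is undefined there). The statistic is
  exactly antisymmetric and zero on the diagonal by construction. The
  heatmap uses a diverging palette centered at zero so equal-prior cells
  read as neutral; axes are labeled θ_audio (x) vs. θ_adult (y).
* **Switch task** (`run_simulation2`): habituation corpora are built
  in-memory — `single`: one speaker × *t* identical tokens; `multiple`:
  *t* speakers × one token each — with defaults *t* = 7, labels
  {buk, puk, duk}, habituated label "buk", uniform label prior, per-speaker
  K prior 0.5 (maximal group uncertainty). With one token the two
  conditions coincide. Exact results are invariant to relabeling the
  habituated token.

## Numerical choices and degenerate inputs

Distributions validate to 1 within 1e-9 (categorical) and 1e-12
(Bernoulli). KL values are clamped at 0 from below to absorb float rounding
when posterior ≈ prior. θ = 0 and θ = 1 are legal priors; only the
(incorrect token, θ = 1) combination is an error. A single-label space is
legal and makes every distribution a point mass. Exact and Gibbs label
marginals are compared by total variation distance.

## Known limitations

The model is deliberately minimal: binary knowledgeability, no belief
carry-over across trials, no mapping from bits to seconds of looking (the
linkage is ordinal only), no estimation of θ_g from data, and no phonetic
representation. The Gibbs diagnostics are agreement-with-oracle checks and
a simple ESS, not multi-chain convergence analysis.
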