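# Methods

## Diagnostic model

The engine is a naive-Bayes ranker over a closed disease universe. Its only
parameters are the knowledge base: disease priors `π_d` and association
weights `w(s, d) ∈ [0, 1]`, read as `P(symptom present | disease)`. Three
modelling assumptions are built in and surface throughout the API:

1. **Objectifiable history.** Findings are pre-coded symptom identifiers
   with a present/absent polarity. Mapping free-text histories to codes is a
   separate NLP problem the package deliberately does not address; the
   JSON-lines vignette schema is the ingestion contract.
2. **Closed universe.** Every disease that can be diagnosed is in the KB, so
   the posterior normalizes over the declared set. Findings whose symptom
   code is unknown to the KB are skipped (and counted in the posterior's
   provenance) rather than raised, so a small KB can consume vignettes that
   mention out-of-scope findings.
3. **Single cause.** One disease explains the findings; comorbidity
   inference is out of scope.

Findings are assumed conditionally independent given the disease, which
makes evidence multiplicative and order-independent. The implementation
accumulates log-likelihoods in a canonical (sorted) symptom order and
normalizes via max-subtraction, so the posterior is exactly invariant to
finding permutation and immune to underflow. Duplicate findings with the
same polarity are collapsed to one piece of evidence; the same symptom
reported both present and absent is an error.

**Smoothing.** Weights are clamped to `[ε, 1−ε]`, `ε = 1e−6`, at likelihood
time. A hard clamp rather than pseudo-counts is appropriate because the KB
is expert-curated, not count-derived: a curated 0 means "no known
association", not "observed zero times". The clamp bounds the evidence any
single finding can carry at roughly `log((1−ε)/ε) ≈ 13.8` nats.

**Priors.** Non-negative priors are normalized to sum to one on load; a KB
that omits priors gets a uniform prior. Demographics (age band, sex) can
participate in inference only if encoded as symptoms of category
`demographic` with weights; otherwise they are metadata.

**Differentials.** The top-`k` posterior entries (default `k = 3`) are
renormalized and converted to integer percentage sureties by
largest-remainder (Hamilton) rounding — the standard method that guarantees
the sum-to-100 reporting convention. Rank ties are broken by disease id
ascending; rounding-remainder ties by rank.

## Evaluation battery

All metrics compare a source's 3-item differentials against gold vignettes,
overall and within each specificity stratum ("overall" is computed on the
full set, not by averaging strata):

* **Top-3 accuracy** — fraction of vignettes whose gold *primary* diagnosis
  appears anywhere in the predicted differential.
* **Precision / recall** are computed per disease on primary diagnoses only
  (TP: predicted primary = gold primary = d), then aggregated as a weighted
  mean with weights equal to each disease's gold-primary frequency. A
  disease that occurs in gold but is never predicted as primary has
  undefined (0/0) precision; the default policy scores it 0 at full weight
  (conservative — penalizes never-predicting), with an
  `exclude`-and-renormalize alternative behind a keyword. Diseases absent
  from both gold and predictions are excluded as vacuous.
* **Jaccard similarity** is intersection-over-union of the *unordered*
  3-sets of diagnoses — rank- and surety-blind. **Cosine similarity** embeds
  each differential as its surety vector over the disease universe — it
  rewards matching confidence allocations, not just matching sets. Keeping
  the two metrics on different representations makes them non-redundant.
* **Significance** is assessed with an upper-tailed two-sample Welch t test
  (unequal variances, Welch–Satterthwaite degrees of freedom). The unit of
  analysis is the per-vignette score: the binary top-3 hit indicator, and
  per-vignette Jaccard/cosine values; the model's vector is tested against
  the pooled non-model sources. Aggregate precision/recall have no
  per-vignette decomposition, so no t test is emitted for them. Degenerate
  inputs (both variances zero) return p = 0.5 for equal means by symmetry,
  flagged as degenerate. No multiple-testing correction is applied.

## Synthetic study generator

The generator produces data whose structure mimics a specificity-stratified
vignette study while keeping the ground truth known:

* **Knowledge base.** Each of `n_diseases` (default 15) owns
  `pathognomonic_per_disease` (default 2) markers with weight drawn from
  U[0.86, 0.99] for it and a faint background (U[0, 0.05]) elsewhere; at
  least one "leaning" sign per disease (owner weight U[0.55, 0.80], others
  U[0, 0.2]); and a shared constitutional pool (default 25% of the
  60-symptom vocabulary) with weights U[0.10, 0.45] for every disease.
  Priors are Dirichlet(3) draws, mildly non-uniform as real prevalence is.
  The bands were chosen once so that the three symptom roles are cleanly
  separated by the threshold policy below.
* **Stratum policies** are weight-threshold rules (configurable): a
  *high*-specificity vignette contains at least one symptom with
  `w ≥ 0.85` for its disease; *moderate* excludes those but includes at
  least one leaning symptom (`0.5 ≤ w < 0.85`); *low* samples only from the
  shared pool (all weights `< 0.5`). Within the allowed pool, each symptom
  is included by a Bernoulli draw with probability `w(s, d)` — i.e. findings
  are sampled from the generating disease's conditional symptom
  distribution — and one symptom is forced (weight-proportionally) if the
  draw comes up empty, since vignettes must contain findings.
* **Gold differentials** put the generating disease first and fill the two
  differential slots with the next-best diseases under the posterior on the
  sampled findings, with sureties from the same largest-remainder rule the
  engine uses — synthetic gold is therefore internally consistent with the
  planted generative model rather than invented.
* **Simulated raters** start from the engine's own differential and corrupt
  it: with probability `primary_error_rate` the primary is replaced by a
  uniformly random other disease (swapping positions if the replacement was
  already a differential), and each secondary slot is independently replaced
  with probability `differential_error_rate` by a disease not already
  listed. Slot sureties are retained, preserving the sum-100 contract. The
  default rates (0.3/0.3) are artifact parameters chosen to emulate a
  plausibly imperfect clinician, not estimates of real clinician error.
* **Determinism.** Every generator draws from `numpy` `default_rng` streams
  keyed by the config seed plus per-vignette indices, so studies regenerate
  identically and per-vignette sub-streams are stable.

A single-disease configuration cannot emit valid vignettes because gold
differentials require three entries; three diseases is the smallest
feasible universe.

### What the synthetic study does and does not show

Passing the planted-truth checks shows the pipeline is internally coherent:
the engine recovers the generating disease almost surely when pathognomonic
evidence is present, degrades monotonically as evidence becomes
nonspecific, and the comparison machinery detects injected accuracy gaps at
the expected significance. It does **not** show clinical accuracy: the
generator's conditional-independence sampling matches the engine's model
family (no model misspecification), its weights are cleanly separated by
construction, and its vignettes lack the narrative ambiguity, absent
findings and coding noise of expert-written cases. Real-world performance
depends entirely on the quality of a curated KB, which this package does
not provide.

## Numerical choices and problem sizes

* Posterior tolerance against the direct-product oracle: 1e−9 (observed
  agreement is at machine precision); prior normalization tolerance 1e−9;
  likelihood complement identity holds to 1e−12.
* Ranked outputs break all ties deterministically (disease id, then rank),
  so repeated runs are byte-identical.
* The planted-truth analyses in the test suite and acceptance script use
  15 diseases × 60 symptoms with 20 vignettes per (disease, stratum) cell —
  300 per stratum, 900 total — which gives stable stratum-level accuracy
  estimates (binomial standard error ≲ 3 points) while keeping a full run
  in seconds; the rater-comparison check uses 7 per cell (315 vignettes).

## Known limitations

* Association weights are interpreted as conditional symptom probabilities;
  curated scales that are odds-like or ordinal would need rescaling before
  use.
* No learning of weights from data, no physical-exam/lab findings, no
  comorbidity, no free-text ingestion, no calibration assessment of the
  surety values.
* The t-test choice (two-sample Welch on per-vignette scores) is one
  defensible reading of "upper-tailed t test"; a paired design over
  vignettes would be a reasonable alternative and is easy to compute from
  the exposed per-vignette scores.
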