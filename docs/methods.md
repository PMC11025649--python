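# Methods

## The evaluation framework

`embinfer` evaluates embedding spaces — static word-vector lexicons and
contextual text encoders — on four psycholinguistic protocols, and analyses
populations of such models. The unifying linking hypothesis is that the
cosine similarity between a context representation and a target-word
embedding varies inversely with the human difficulty measure for that
trial (N400 amplitude for the priming and discourse protocols, reaction
time for the word-order protocol). A model "performs" a task when its
similarity scores separate the task's conditions in the direction the
linking hypothesis requires; the size of that separation is summarized by
a t statistic across trials.

### Context representations

Static backends represent a multi-word text as the unweighted arithmetic
mean of its word vectors. Out-of-vocabulary context tokens are skipped
(excluded from both the sum and the denominator), which preserves the
mean's scale; a missing *target* word is always an error, because it
invalidates the trial. The resolved vectors are accumulated in sorted
token order, so permutation invariance of the average is exact at the bit
level rather than up to float-summation order. This order-blindness is not
an implementation detail but the mechanism under study: an averaged
representation cannot distinguish two sentences built from the same word
multiset. Contextual backends are any deterministic `text -> vector`
callable behind the `ContextualEncoder` contract; multi-sentence
discourses are passed as a single string and segmentation, pooling and
tokenization are the encoder's own business.

### The four task statistics

For one backend and one stimulus set:

* **Pairwise priming (`chwilla_sem`).** Per pair, the prime-target cosine.
  Performance is a two-sample t test (pooled variance by default; Welch
  behind a flag) of the related-pair similarities against the
  unrelated-pair similarities.
* **Sentence semantics (`metusalem_sem`).** Per item, with sentence vector
  S and expected/related/unrelated target embeddings E, R, U:
  `cos(S,E) - (cos(S,R) + cos(S,U)) / 2`. Performance is the paired t test
  of the expected similarity against the mean unexpected similarity, which
  is algebraically the one-sample t of the item scores against zero.
* **Discourse inference (`metusalem_inf`).** The *rescue* of the
  discourse-related word: with C the embedding of the discourse plus the
  final sentence (joined by one space) and S the sentence alone,
  `[cos(C,R) - cos(C,U)] - [cos(S,R) - cos(S,U)]`; paired t of the context
  difference against the sentence difference. The scorer also emits the
  six-condition similarity profile (S/D x E/R/U). Note that one prose
  description of this paired test in the source literature disagrees with
  the formula ("Sentence(Unexpected-Related)" rather than
  Sentence(Related - Unrelated)); this implementation follows the formula.
* **Word-order inference (`mckoon_inf`).** Per item,
  `cos(context, target) - cos(control, target)` where the two sentences are
  built from (near-)identical word multisets; paired t of context against
  control similarities. For an order-blind static backend with no OOV
  tokens, every item score is exactly zero.

All p values are two-sided; the sign of t carries direction (positive =
the direction the linking hypothesis requires). Degenerate trial-score
variance is an explicit error when the mean effect is nonzero (the t would
be unbounded and downstream correlations need finite points); when the
scores are identically zero — the exact word-order null — the result is
the honest t = 0, p = 1 with the usual df.

### Population analyses

Each scored model contributes one record (class label plus four t scores).
Two analyses operate on a population of records:

* **Correlation/regression** between a semantic task's and an inference
  task's t scores within one model class: Pearson r with two-sided p plus
  unweighted OLS slope and intercept. Both are always reported because a
  correlation can be significant while its slope is nearly flat, meaning
  semantic improvements buy almost no inference improvement; the
  "effective correlation" judgement therefore requires both p < 0.05 and
  |slope| above a configurable threshold (default 0.15).
* **2x2 mixed ANOVA** with model class as the between-models factor and
  task as the within-model (repeated) factor, computed by
  `pingouin.mixed_anova` and cross-checked in the test suite against a
  hand-coded balanced sum-of-squares decomposition. Cell means carry
  t-based 95% confidence intervals. Post hoc pairwise comparisons of the
  four cells use a paired t within a class and a Welch t between classes,
  each referred to the Scheffe criterion `t^2/(k-1) ~ F(k-1, df)` with
  k = 4 and the comparison's own df — a deliberately conservative choice
  that avoids picking one of the mixed design's two error terms for
  contrasts that straddle both.

The four-experiment suite reports: each semantic measure correlated with
each inference measure per class (experiments 1-2), the inference-pair
ANOVA (experiment 3) and the semantic-pair ANOVA (experiment 4), plus the
scatter data behind them. When a class has literally zero variance on a
task (order-blind models on matched multisets score exactly 0), the
Pearson r is undefined; the suite reports the OLS slope (well-defined and
zero) with an annotation instead of failing.

## The synthetic world generator

All tests run on generated worlds with planted, known effects; no
pretrained model is downloaded or shipped. Word vectors are unit-norm
normalized Gaussian draws; a planted cosine c between two unit vectors is
achieved exactly by `c*v + sqrt(1-c^2)*u` with u a random unit vector
orthogonal to v. Synthetic words are opaque generated tokens, so nothing
can depend on a real lexicon.

Planted effects and their construction:

* `related_gap` (default 0.3): related pairs get planted cosine
  `gap + noise`, unrelated pairs `0 + noise`. The same value doubles as
  the expected-word advantage of the discourse items (both are local
  semantic effects; the configuration deliberately has one semantics knob
  and one inference knob per mechanism).
* `rescue_delta` (default 0.3): each discourse item has an orthonormal
  frame (sentence anchor e1, related target e2, unrelated target e3,
  expected-residual e4). Sentence tokens sit near e1; discourse tokens sit
  near `cos(theta) e1 + sin(theta) e2`, with theta solved (Brent root
  find) so the context mean's cosine to the related target equals the
  planted rescue while the sentence alone separates nothing.
* `order_effect` (default 0.3): each word-order item's two sentences are
  permutations of one word multiset; one cue word leads the context
  sentence and trails the control sentence. The cue's projection onto the
  target is calibrated per item (Brent root find through the actual
  encoder arithmetic) so the order-aware encoder's context-minus-control
  cosine difference equals the planted per-item effect exactly, while the
  order-blind average cancels it exactly.

The synthetic order-aware encoder is a position-decay weighted word-vector
sum (weight `decay^i`, default decay 0.8) plus a small bigram-keyed
pseudo-random direction (scale 0.05, keyed by a stable hash of each
adjacent word pair) — the simplest deterministic mechanism that breaks
permutation invariance.

Trial counts default to the canonical sizes of the emulated human
protocols: 40 + 40 priming pairs, 72 discourse items, 32 word-order items.
Per-trial noise is `noise_sigma` (default 0.05) around each planted
cosine. `generate_world` raises with an explicit bound when the requested
geometry is infeasible (rescue beyond what the discourse/sentence token
ratio can express, order effects beyond the encoder's positional
contrast, dim < 5 for the four-anchor frame). Every world self-audits:
`SyntheticWorld.self_audit()` re-measures each planted effect on the
generated material through the ordinary scoring path.

### Deterministic-trials mode and model populations

`generate_model_population` draws latent (semantic quality, inference
quality) pairs from a bivariate normal with a configurable per-class
correlation (*coupling*), maps qualities to planted effects (the
word-order effect is scaled by 0.3 to stay inside the encoder's feasible
positional contrast), and builds one world per model. Static models expose
the order-blind lexicon; contextual models expose the order-aware encoder.
Two design choices keep class contrasts meaningful:

* The two classes share one *quality ladder*: the i-th static and the i-th
  contextual model receive the same latent qualities. Class differences in
  the 2x2 ANOVA therefore reflect architecture (order-blind vs
  order-aware), not the sampling luck of two independent quality draws.
* The word-order effect is geometrically capped well below the rescue
  effect, so with a single per-item heterogeneity an order-aware model's
  word-order t would sit an order of magnitude below its discourse t and
  the within-class task gap would be nearly equal for both classes,
  masking the architectural dissociation. Population worlds therefore use
  a tighter word-order heterogeneity (0.01 vs 0.05), giving order-aware
  models comparable t scales on the two inference tasks — the scenario the
  population emulates: order-aware models perform comparably on both
  inference tasks while order-blind models collapse (exactly to t = 0) on
  the word-order one.

Population worlds set `deterministic_trials=True`: per-trial deviations
around the planted effect are standardized to exact mean 0 and exact
sample sd `noise_sigma`, and token-level noise is turned off, so each
model's t statistic is an exact closed-form function of its latent
quality. This matters for correlation experiments: with i.i.d. trial
noise, the sampling error of each model's t (mostly the ~1/sqrt(2 df)
variability of the estimated denominator) attenuates the between-model
correlation below the planted coupling, so the generator would plant less
than it claims. In deterministic-trials mode the planted coupling *is* the
population correlation between task performances. The default mode (plain
i.i.d. noise) is kept for calibration studies, where honest trial-level
sampling noise is exactly what is being measured.

What the generator does **not** emulate: real lexical statistics
(frequency, polysemy, morphology), graded human cloze probabilities,
cross-item heterogeneity of effect sizes, and any training-corpus
signature shared across models of one family. Passing tests therefore
demonstrate that the scoring statistics, the exact order-blindness null,
and the population analyses behave correctly — not that any particular
real model family will show a particular effect size.

## Simulation sizes and numerical choices

* Null calibration: 1,000 replicate worlds with all effects 0, reduced
  per-protocol counts (20 + 20 pairs, 24 discourse items, 24 word-order
  items, dim 12) — large enough for the t approximations, small enough to
  keep the study quick. Each task's rejection rate at alpha = 0.05 is
  checked against the exact binomial 95% band [3.7%, 6.4%].
* Coupling recovery: 200 populations of 22 models with coupling 0.85;
  coverage of the planted value by the Fisher-z 95% CI around each
  estimated r is required to be at least 90%.
* Oracle agreement tolerances: per-trial scores 1e-12 against brute-force
  loops; t/r/slope/F 1e-8 against hand-coded formulas; rotation invariance
  1e-10; the word-order static null and permutation invariance exact.
* Cosines are clipped to [-1, 1] after division to absorb representation
  round-off; zero-norm vectors raise rather than propagating NaN.
* Root finds use Brent's method on sign-checked brackets; infeasible
  brackets raise with the achievable range in the message.
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning, so worlds, populations and reports
  are bit-identical across reruns.

## Known limitations

* Only toy/synthetic contextual encoders ship; the contextual-encoder
  contract is the integration point for real sentence encoders, and the
  published reference value for this pipeline (t = 4.14 on the discourse
  inference task for a wikipedia2vec static model on the original 72
  items) can only be checked by users who supply those vectors and items
  themselves — both are external and not redistributable here.
* The full 80-pair priming, 72-item discourse and 32-item word-order
  stimulus sets of the original human studies are likewise user-supplied
  files; the package ships the schema, the single worked example items,
  and synthetic sets.
* The mixed ANOVA reports the true degrees of freedom of whatever
  population it is given; unbalanced class sizes give the standard
  unbalanced df, and no attempt is made to force any particular df.
* Scheffe adjustment with per-comparison df (rather than a single pooled
  error term) is conservative by construction; it never undercuts the
  unadjusted p.
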