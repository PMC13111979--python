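# Methods

## The simulation in one paragraph

A fan design fixes 24 person–location study sentences: one category (the
*varied* category) has four groups at fan 2 and four at fan 4, the other
twelve groups all at fan 2.  Each sentence becomes one skip-gram training
item whose target token is the varied-category word and whose context
tokens are the other-category word and the article immediately preceding
the target.  After training SGNS on this tiny corpus, the shifted dot
product `t·c + log k` of each target–context pair estimates the pointwise
mutual information of the pair, which in the rational analysis of memory
*is* the spreading activation a cue sends to a chunk.  Higher fan spreads
the target's probability mass over more contexts, so fan-4 pairs converge
to lower activation than fan-2 pairs, and the ACT-R linking functions
translate that difference into slower, less accurate retrieval.

## Stimulus designs

The letter template (4 varied groups × fan 2, 4 × fan 4, 12 fixed groups
× 2) is fixed; lexical items are assigned to letters at random per seed.
In classic mode a group is a single repeated word; in semantic mode each
group is a list of semantically similar words and every sentence consumes
a distinct member, so all 24 person and 24 location words are unique.
Foils re-pair the target words (each word keeping its study multiplicity)
such that no foil pair ever co-occurred in a target sentence and no foil
repeats; re-pairing is rejection sampling over shuffled pools with a
1,000-draw budget, then exact backtracking.  A foil's fan condition is the
fan of its varied-category word's group — the analysis codes fan for foils,
and the varied category carries the manipulation.

Person words always take the article "de"; location articles come with the
lexicon and selections are balanced so the de/het counts among target
locations differ by at most 2.  In classic mode the balance is solved
exactly over the weight classes of the chosen words; in semantic mode the
design is redrawn (bounded retries) because single-use words leave no room
for local swaps.  When the person category is varied, the (constant)
sentence-initial "De" still enters as a context token; the per-target rule
is uniform and a constant context token is harmless.

## SGNS training

The trainer maximizes `log σ(t·c) + Σ_k log σ(−t·c′)` per observed pair
with k=5 noise contexts drawn from the unigram distribution of the edge
corpus raised to the 3/4 power (articles included — they are corpus words).
Vectors are 100-dimensional, initialized uniform(−1, 1) (or copied from a
pretrained store for targets, in which case they can be frozen), and
updated per-pair with Adam (lr 0.003, β₁ 0.9, β₂ 0.999, ε 1e-8) in
row-sparse fashion: only rows touched by a step advance, with bias
correction from the global step count.

Two corpus-level choices matter and are exposed as config flags:

- **Distinct-pair visits** (`dedupe_edges=True`).  An epoch visits every
  *distinct* (target, context-token) pair once, shuffled.  A fan-f target
  repeats its article pair in f sentences; collapsing the repeats gives it
  f+1 observed pairs, so the converged fan-2/fan-4 activation gap is
  log(5/3) ≈ 0.51 rather than log 2.  This is what places the classic
  simulation's condition means at ≈1.8 (fan 2) and ≈1.22 (fan 4); visiting
  repeated article pairs at full multiplicity (`dedupe_edges=False`)
  drives fan-4 pairs down to ≈0.9 instead.
- **No collision special-casing** (`resample_collisions=False`).  A noise
  draw that happens to equal the observed context simply contributes its
  negative gradient, as in implementations that sample negatives without
  filtering.  Resampling such draws removes the self-collision pressure
  and inflates both condition means by ≈0.15–0.2.

Training runs a fixed number of epochs (24 classic, 65 semantic) by
default; criterion-based stopping (`recall_stop_threshold`) stops at the
first epoch whose recall error reaches the threshold.  Recall error ranks,
for each target with f observed content contexts, all content-word
contexts by dot product and counts observed contexts outside the top f;
articles are excluded from the ranking because a single article co-occurs
with up to half the targets and would dominate, and the scorer is
pluggable.  Ties break lexicographically.  A non-finite epoch loss aborts
with learning-rate guidance.

Averaging "over models" for the three seeds happens on per-pair dot
products, not on vectors: dot products are the reported quantity, and
averaging vectors across independently initialized models is meaningless.

## Activation and linking

`shifted_dot` adds log k to the raw dot product (exact identity, tested to
1e-12).  `pmi_activation(P(i|j), P(i))` is the general spreading-activation
formula; with P(i|j)=1/fan and P(i)=1/M it reduces to `log M − log fan`.
`retrieval_time` and `retrieval_prob` are `F·exp(−A)` and
`1/(1+exp(−(A−T)/s))`; both are monotone in A, which is property-tested.
Activation tables carry one row per (target, content-context) pair —
article pairs are bookkeeping for training, not reported activations.  A
foil has no trained pair of its own; for synthesis its activation is the
mean of the trained pair activations involving either of its constituent
words.  This is an artifact convention: the underlying account offers no
generative story for foils.

## The binarized-cue comparison model

Sign-binarization maps every vector component to +1 if positive, else −1
(zeros to −1: the "otherwise" branch).  Every dimension is one cue; a
probe's cue fan is the number of study chunks whose same-category word
carries the probe's sign in that dimension, and the activation is the
cue-weighted sum of `S − log(fan_j)` with uniform weights W/d (total
W=100).  S defaults to log(number of study chunks), the log memory size
under a uniform need distribution, and is exposed as a free parameter; any
S or W only shifts/rescales activations and never reorders conditions, so
only the fan-2 > fan-4 ordering is asserted, not absolute magnitudes.  A
cue matched by no chunk is clamped to fan 1 with a logged warning.

## Synthetic generators

**Embedding spaces.** Group centroids are drawn isotropically at unit norm;
members add isotropic Gaussian noise with expected norm `within_spread`
(default 0.05, i.e. 5% of the centroid norm), and the space is regenerated
until every group satisfies the in-group > out-group cosine constraint.
Location members carry alternating de/het articles.  The spaces emulate
the *clustered-neighborhood* property of pretrained embeddings, not their
geometry: real in-group neighbors have cosines around 0.5–0.8, while
spread 0.05 gives near-duplicates.  One consequence is that with frozen
near-duplicate targets the recall criterion is partly unlearnable (nearly
identical targets cannot rank four different contexts first), so semantic
runs are validated by the fan-2 > fan-4 ordering and the pre-training null
(no systematic dot difference between conditions before training), not by
recall.  Passing tests on these spaces shows the mechanism, not that real
pretrained vectors would yield the same magnitudes.

**Behavior.** RT = `shift + exp(log(F·e^−A) + u_p + w_i + ε)` with
participant/item effects and residual on the log scale; accuracy is
Bernoulli with logit `(A−T)/s + u′_p + w′_i`.  Defaults (F=3000 ms,
T=0.5, s=0.4, shift=500 ms, σ_log=0.25, participant sd 0.15, item sd 0.05,
100 participants × 3 rounds × 48 sentences) put RTs and accuracies in the
1–2 s / 0.8–0.95 ranges typical of fan experiments.  The generator omits
base-level (familiarity) activation, learning across rounds, and speed–
accuracy trade-offs; the additive shift also attenuates log-scale effects
(d log RT/dA ≈ 0.65 at the defaults), so recovered log-RT effects are
smaller than the generating activation contrast — by design, recovery is
judged by sign and CI behavior, not by magnitude.

## Cleaning, coding, estimation

RT cleaning removes trials outside [200 ms, 90 s], then trials outside
mean ± 3 sd computed once, globally, on the survivors (a per-participant
option exists but is off: the trimming rule is stated "from the mean"
without grouping).  Participant exclusion (mean accuracy strictly below
0.6 classic / 0.65 semantic) runs before RT cleaning on all trials.
Contrast codes nest fan in stimulus type: fan_target ∈ {−1,0,+1},
fan_foil ∈ {−1,0,+1}, stimulus_type ∈ {−1,+1}.  Condition summaries report
trial-level SEs; the fan-2 row is identical across person/location/
combined labels because fan 2 means both categories at fan 2.

`recover_fan_effect` is the parameter-recovery statistic: the across-
participant mean of each participant's fan-4 − fan-2 mean log RT, with a
seeded percentile bootstrap (2,000 replicates).  The bootstrap resamples
participants *and* the fan-2/fan-4 item sets, because the generator (like
real data) has item-level variability that a participant-only interval
would treat as fixed, undercovering badly under a zero contrast;
resampled item-margin deviations are inflated by √(n/(n−1)) to correct the
n-out-of-n variance shrinkage of the small item clusters (8 and 16).
Calibration at 100 participants: zero-contrast CIs cover 0 in ≈94% of
seeded runs, positive-contrast CIs exclude 0 in ≈100%.

## Problem sizes and numerical choices

The test suite and the reproduction script run at the study's native
scale — 24-sentence designs, 100-dimensional vectors, 24/65 epochs, 3
seeds — since one training run takes well under a second.  Seed-sensitive
checks aggregate: the shifted-dot means average over several independently
seeded replicates (8 in `scripts/acceptance.py`), ordering properties use
20 seeded runs, null checks 50, and recovery calibration 40 per condition.
All randomness flows through `numpy.random.default_rng` with explicit
seeds; design, initialization, and training streams are separated so that
identical seeds give bit-identical designs, models, and trial tables.
Degenerate inputs are handled explicitly: zero residual noise generates
noise-free RTs, zero RT spread disables the sd trim, all-identical dot
products collapse the median split to a single warned group, and empty
summary cells report n=0 with null statistics.

## Known limitations

- The SGNS equilibrium analysis (and hence the printed condition means)
  depends on the edge-corpus conventions documented above; both flags are
  exposed so either convention can be run.
- Synthetic embedding spaces do not reproduce the norms, anisotropy, or
  frequency structure of real pretrained vectors; reproducing the semantic
  experiment's absolute dot-product levels requires the original
  pretrained vectors and stimulus lists, which are external inputs.
- Hierarchical Bayesian estimation (and Bayes-factor model comparison) of
  the behavioral data is out of scope; the bootstrap estimator is a
  recovery harness, not a replacement for a mixed-effects analysis.
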