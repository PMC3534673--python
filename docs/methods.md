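# Methods

## The generative model

A language is a lexicon of `n_types` word types (default 1000) realized
as `total_tokens` word tokens (default 60,000).

**Type frequencies.** Token counts follow a floored Zipfian law
`f_r = max(round(C/r), floor)` over frequency rank `r`, with the scale
constant `C` found by bisection so the counts sum exactly to the token
total; the rounding residual (usually 0–2 tokens) is absorbed at rank 1.
The floor (default 10) is a hard constraint: an unfloored `C/r` law at
this scale would leave the rarest types with ~8 tokens, whereas the
design calls for a minimum of 10.  Under the default configuration the
solve gives `C = 7987`, so the most frequent type carries 7,987 tokens
and exactly 7 types exceed 1,000 tokens.

**Word forms.** The syllable inventory is the full Cartesian product of
the consonant and vowel label lists (default 24 × 14 = 336 CV
syllables), in consonant-major order.  Word lengths are i.i.d.
`1 + Poisson(length_mean − 1)` (default mean 3 syllables; the shift
avoids zero-length words), drawn independently of rank, so there is no
built-in bias for frequent words to be short.  Forms are uniform random
syllable sequences, resampled on collision until pairwise distinct.

**Corpus arrangement.** The default *exact-count* mode realizes every
type at precisely its allocation count: the token multiset is shuffled
and repaired by conflict-free swaps until no word is immediately
repeated anywhere in the stream (including across sentence breaks — the
conservative reading of the no-repetition constraint; a within-sentence
flag and an i.i.d.-multinomial mode are available).  For
feasibility-tight multisets where random swap repair cannot succeed
(e.g. two equally frequent types, whose only valid arrangement strictly
alternates), a deterministic round-robin interleave takes over.  The
stream is then cut into sentences with lengths
`2 + Poisson(sentlen_mean − 2)` (default mean 4 words, hence ≈12
syllables); the final sentence is trimmed to hit the exact token total,
or merged with its predecessor if trimming would leave a single word.
Boundary positions between syllables are indexed 1..L−1 ("gaps");
utterance edges are not gaps.

Note one subtlety: the mean sentence length *in syllables* is the mean
words-per-sentence times the **token-weighted** mean word length.  The
weighting concentrates on the few top-rank types, so this statistic has
a per-seed standard deviation of about one syllable around 12 even
though its expectation is exact; quantities derived from it should be
averaged over seeds.

**Test blocks.** Novel-sentence test blocks are sampled by the same
process (type probabilities proportional to allocation counts, no
immediate repetition), and each sentence is verified absent, as a word
sequence, from the training corpus.  100 sentences carry ≈400 word
tokens.

**Timing export.** Corpora serialize to MBROLA-style `.pho` text: 250 ms
per syllable (split 125/125 ms over consonant and vowel — the even split
is a package choice; only the syllable total is part of the design),
constant 100 Hz pitch, and a 200 ms pause line between sentences.  Files
chunk into ≈5-minute batches and never split a sentence.  Audio
rendering is out of scope.

## Synthetic participants

No human data enter the pipeline; responders with known parameters make
every downstream estimate checkable by parameter recovery.

- **Noisy oracle** (the canonical harness): marks each true boundary with
  probability `hit_rate` (default 0.55) and each word-internal gap with
  probability `false_alarm_rate` (default 0.08), independently.  The
  defaults give F ≈ 0.6 with precision above recall, the qualitative
  regime of interest for trained learners.
- **TP segmenter**: estimates forward transitional probabilities
  P(s₂|s₁) from syllable bigrams *within* sentences (the inter-sentence
  silence breaks the chain) and marks any test gap whose TP falls below
  `tp_threshold` (default 0.1).  Unseen bigrams count as TP 0, favouring
  boundary insertion at novel junctures.
- **Yoked control**: the TP segmenter trained on the ~400-token test
  block alone — what an untrained participant could learn during the
  test session itself.  Its F reliably lands between the permutation
  null and the trained learner.
- **Periodic segmenter**: a boundary every k syllables regardless of
  content — the degenerate strategy that warrants exclusion.
- **Chunk segmenter** (optional third mechanism): greedy
  leftmost-longest parse against the most frequent attested syllable
  n-grams.
- **2AFC responder**: chooses the target with probability
  `0.5 + 0.5·σ(β₀ + β₁·ln f)` (defaults β₀ = −4.0, β₁ = 0.8, giving
  near-chance accuracy at the 10-token floor and near-perfect accuracy
  at the ≈8000-token ceiling).

A mechanism note: the TP segmenter at its default threshold
over-segments next to high-frequency words.  Its decision regression
therefore shows strong positive log-frequency and boundary main effects
but a *negative* frequency-by-boundary interaction — word-internal
accuracy rises steeply with frequency while boundary-gap accuracy
declines slightly.  Which response mechanism best mimics human
asymmetries is an open empirical question; the simulators here are
harnesses, not cognitive claims, and passing tests demonstrate that the
scoring and inference machinery recovers known ground truth, not that
real learners behave like any of these mechanisms.

## Scoring and the permutation null

Scoring is strict gap matching with counts pooled over sentences
(micro-average) before precision, recall and F are formed; 0/0 is
defined as 0.  The micro-average is the natural companion of the
permutation baseline, which is defined on whole-test F: each of
`n_reps` replicates (default 10,000) independently re-draws every
sentence's m marks uniformly without replacement from its G gaps,
preserving per-sentence mark counts, and the corpus F of each replicate
forms the empirical null.  The expected per-sentence hit count under
this null is m·k/G (k = true boundaries), which the tests verify by
exhaustive enumeration for small sentences.  The reported p-value uses
the add-one correction (b+1)/(n+1), so it is never exactly zero.

Degenerate responses are detected as exact fixed-period lattices: one
period p such that every sentence's marks are exactly the consecutive
multiples of p up to its last marked gap (all-empty responses count as
degenerate with period ∞).  This generalizes the observed
every-two-syllables strategy to any constant period, which carries the
same interpretability failure.

## Location analysis and inference

Each gap of each test sentence yields one decision record: whether a
boundary is truly present, whether it was marked, and the token
frequency of the governing word — at a boundary, the higher frequency of
the two adjacent words; inside a word, the containing word's frequency.
Accuracy is binned in equal-width bins of log frequency with equal-tailed
95% Beta-posterior intervals (Jeffreys (½, ½) prior by default,
uniform (1, 1) by option; zero-trial cells return the prior's own
quantiles, flagged).  A windowed moving average over log frequency is
provided as a plot aid.

The decision model is `correct ~ log(freq) × bound`.  With only a
handful of simulated participants, a maximal crossed random-effects
structure is not estimable; the pooled fit instead uses participant
fixed effects, complemented by fully independent per-participant fits,
with z-approximation p-values.  The logistic family is the default for
the binary outcome; a linear-probability option is provided, and the two
agree in sign on homogeneous data.

## The 2AFC retention test

Targets come from language A: every word above `freq_cutoff` (default
1000) tokens is obligatory (7 words under the default allocation), and
the remaining slots of the `n_trials` = 64 trials are sampled uniformly
on the log-frequency range (nearest available frequency, without
replacement).  Each target is paired with a distractor from language B
that has the same syllable count, contains only syllables present in
both inventories, is not itself a word of language A, and is nearest in
log frequency — preferring |Δln f| ≤ 0.25, with ties broken by raw
frequency difference and then a seeded draw.  Because word length is
independent of frequency, a high-frequency target can lack any
length-matched high-frequency candidate; matching then degrades
gracefully with a warning rather than failing, and sampled (but not
obligatory) targets with no length-matched candidate at all are skipped.

The psychometric model is the chance-floored ("half-logit") curve
p = ½ + ½·σ(β₀ + β₁·ln f), fit by maximum likelihood with a
deterministic L-BFGS-B start at (0, 0) and box bounds at |β| = 25; Wald
CIs come from the numerical Hessian.  Complete separation (e.g. a
ceiling responder) drives the fit to the bound, which is flagged and
reported with infinite standard errors rather than masked.

## Numerical and design choices

- All randomness flows from one master seed through named substreams
  (CRC-tagged `SeedSequence` children), so any stage — a participant's
  language, one session's responses, one permutation run — reproduces in
  isolation.
- The Zipf solve bisects 200 times on a step function; ties in the
  distractor search and chunk parsing break deterministically
  (leftmost-longest; closest-length-then-frequency).
- Scale defaults in the test suite: full 60,000-token languages are used
  where the contract demands them (generator, interim tests,
  permutation nulls at 10,000 reps); parameter-recovery studies use
  5,000-trial simulations over 20–30 seeds, sizes at which Wald
  coverage is accurate to a few percent.

## Limitations

- No prosody, coarticulation, sub-syllabic structure, semantics or audio;
  the `.pho` export is timing metadata only.
- The simulated learners are response harnesses, not cognitive models;
  no claim that any of them reproduces human precision/recall
  asymmetries or retention curves.
- The regression replaces random effects with fixed effects — adequate
  for recovering known simulated structure, not a general mixed-model
  engine.
- Frequency matching in the 2AFC is limited by the joint availability of
  length and frequency in the distractor lexicon (see above); the
  matching tolerance is reported per trial rather than enforced.
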