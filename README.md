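# seglab

Simulation and evaluation of **large-scale artificial-language word
segmentation** experiments, for researchers in statistical learning and
computational psycholinguistics.

In a statistical-learning segmentation study, listeners hear a stream of
synthesized nonsense sentences with no acoustic cues to word boundaries
and must recover the words from distributional structure alone.  `seglab`
simulates every stage of a large-scale version of this paradigm:

- **Language generation** — a unique language per simulated participant:
  1000 word types over a 336-syllable CV inventory (24 consonants × 14
  vowels), type frequencies following a floored Zipfian law
  *f<sub>r</sub> = max(round(C/r), 10)* with *C* solved so the counts sum
  to exactly 60,000 tokens; word lengths 1 + Poisson(2) syllables
  (mean 3), sentence lengths 2 + Poisson(2) words (mean 4, ≈12
  syllables), and no word ever repeated immediately after itself.
- **Synthetic participants** — segmentation responders with known
  generative parameters (a hit/false-alarm noisy oracle, a
  transitional-probability learner, a yoked control trained on the test
  block alone, a frequency-chunk parser, and the degenerate fixed-period
  strategy), plus a 2AFC chooser whose accuracy follows a half-logit law
  in log word frequency.
- **Scoring** — strict boundary precision, recall and F
  (P = hits/(hits+FA), R = hits/(hits+misses)), with a permutation-null
  chance baseline that reshuffles each sentence's own boundary marks
  while preserving their count, and a location-level analysis of
  accuracy by the log frequency of the word governing each gap.
- **Inference** — the `correct ~ log(freq) × bound` decision regression
  (logistic or linear-probability, with participant fixed effects),
  Jeffreys Beta-posterior binomial intervals, and maximum-likelihood
  fits of the 2AFC psychometric curve
  *p(correct) = ½ + ½·σ(β₀ + β₁·ln f)*.

## Worked example

```python
from seglab import *
from seglab.langgen import default_phonology
from seglab.learners import ResponderParams, estimate_tp, tp_segmenter

inventory  = build_syllable_inventory(default_phonology())
allocation = allocate_zipf_counts(n_types=1000, total_tokens=60_000, floor=10)
lexicon    = build_lexicon(inventory, allocation, seed=1)
training   = generate_corpus(lexicon, seed=1)
test       = generate_test_block(lexicon, training, n_sentences=100, seed=1)
print(f"types={len(lexicon)}  tokens={training.token_total}  "
      f"max_freq={allocation.counts[0]}  min_freq={allocation.counts[-1]}")
print(f"test sentences={len(test)}  test tokens={test.token_total}")

params   = ResponderParams(tp_threshold=0.1)
response = tp_segmenter(test, estimate_tp(training), params)
score    = score_segmentation(response, test)
null     = permutation_baseline(response, test, n_reps=10_000, seed=1)
print(f"precision={score.precision:.3f}  recall={score.recall:.3f}  "
      f"F={score.f_score:.3f}")
print(f"chance F 95% CI=({null.ci_low:.3f}, {null.ci_high:.3f})  "
      f"p={null.p_value:.2e}")
```

prints

```
types=1000  tokens=60000  max_freq=7987  min_freq=10
test sentences=100  test tokens=397
precision=0.647  recall=0.946  F=0.769
chance F 95% CI=(0.260, 0.337)  p=1.00e-04
```

The generated language hits the design exactly (1000 types, 60,000
tokens, most frequent word ≈8000 tokens, rarest 10).  The
transitional-probability learner, trained on the full corpus and tested
on 100 novel sentences, segments far above chance: its F of 0.77 sits
well outside the (0.26, 0.34) interval that its own reshuffled boundary
marks would produce by luck.

The full experiment — several participants, two interim tests, yoked
controls, permutation baselines, location-level frequency analyses, and
the 2AFC retention test with half-logit fits — runs from one config:

```sh
seglab run --config config.yaml --seed 1 --out results/
seglab report --out results/
```

Subcommands `generate`, `respond`, `score` and `twoafc` expose the
individual stages; `generate` also writes MBROLA-style `.pho` timing
files and orthographic glosses via `seglab.export`.

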