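"""Scoring, permutation nulls, location analysis, degeneracy detection."""

import itertools

import numpy as np
import pytest

from seglab.langgen import Corpus
from seglab.learners import (
    ResponderParams,
    SegmentationResponse,
    oracle_noisy_segmenter,
    periodic_segmenter,
)
from seglab.segeval import (
    bin_by_log_frequency,
    classify_locations,
    detect_degenerate_strategy,
    permutation_baseline,
    score_segmentation,
)
from seglab.util import substream

from conftest import make_sentence, toy_two_word_language


def response_for(test: Corpus, gap_sets) -> SegmentationResponse:
    return SegmentationResponse(gaps=tuple(frozenset(g) for g in gap_sets))


class TestScoring:
    def test_identity_scores_one(self, small_language):
        _, _, test = small_language
        resp = response_for(test, [s.gold_gaps for s in test.sentences])
        score = score_segmentation(resp, test)
        assert (score.precision, score.recall, score.f_score) == (1.0, 1.0, 1.0)

    def test_hand_counted_sentence(self):
        """Gold {2,4}, predicted {2,5}: 1 hit, 1 miss, 1 false alarm."""
        lexicon = toy_two_word_language()
        test = Corpus(sentences=(make_sentence(lexicon, [1, 2, 1]),))
        score = score_segmentation(response_for(test, [{2, 5}]), test)
        assert (score.hits, score.misses, score.false_alarms) == (1, 1, 1)
        assert score.precision == score.recall == score.f_score == 0.5

    def test_empty_response_zero_f(self, small_language):
        _, _, test = small_language
        score = score_segmentation(
            response_for(test, [set() for _ in test.sentences]), test)
        assert score.hits == 0
        assert score.recall == 0.0 and score.f_score == 0.0

    def test_count_identities(self, small_language):
        """hits + misses = gold boundaries; hits + false alarms = marks."""
        _, _, test = small_language
        resp = oracle_noisy_segmenter(
            test, ResponderParams(hit_rate=0.5, false_alarm_rate=0.2, seed=3))
        score = score_segmentation(resp, test)
        assert score.hits + score.misses == \
            sum(len(s.gold_gaps) for s in test.sentences)
        assert score.hits + score.false_alarms == resp.n_marks

    def test_sentence_count_mismatch_rejected(self, small_language):
        _, _, test = small_language
        with pytest.raises(ValueError):
            score_segmentation(response_for(test, [set()]), test)

    def test_out_of_range_gap_rejected(self, small_language):
        _, _, test = small_language
        gaps = [set() for _ in test.sentences]
        gaps[0] = {10_000}
        with pytest.raises(ValueError):
            score_segmentation(response_for(test, gaps), test)


class TestLocationAnalysis:
    def test_boundary_gets_higher_adjacent_frequency(self):
        lexicon = toy_two_word_language()  # freqs 10 and 10 -> use custom ranks
        test = Corpus(sentences=(make_sentence(lexicon, [1, 2]),))
        resp = response_for(test, [{2}])
        decs = classify_locations(resp, test, lexicon)
        boundary = [d for d in decs if d.is_boundary]
        assert len(boundary) == 1
        assert boundary[0].freq_label == max(lexicon.frequency_of(1),
                                             lexicon.frequency_of(2))

    def test_internal_gaps_take_containing_word(self, small_language):
        lexicon, _, test = small_language
        resp = response_for(test, [s.gold_gaps for s in test.sentences])
        for d in classify_locations(resp, test, lexicon):
            s = test.sentences[d.sentence]
            if not d.is_boundary:
                # the gap's containing word frequency is one of the member words'
                assert d.freq_label in {lexicon.frequency_of(r) for r in s.words}
            assert d.correct == (d.marked == d.is_boundary)

    def test_internal_gaps_outnumber_boundaries(self, paper_language):
        """Mean word length 3 > 2: more within-word gaps than boundary gaps."""
        lexicon, _, test = paper_language
        resp = response_for(test, [set() for _ in test.sentences])
        decs = classify_locations(resp, test, lexicon)
        n_bound = sum(d.is_boundary for d in decs)
        assert len(decs) - n_bound > n_bound

    def test_binned_accuracy_all_correct(self, small_language):
        lexicon, _, test = small_language
        resp = response_for(test, [s.gold_gaps for s in test.sentences])
        table = bin_by_log_frequency(
            classify_locations(resp, test, lexicon), n_bins=4)
        assert (table.prop_correct == 1.0).all()
        assert ((table.ci_low > 0) & (table.ci_high < 1)).all()

    def test_oracle_boundary_accuracy_flat_in_frequency(self, paper_language):
        lexicon, _, test = paper_language
        h = 0.6
        resp = oracle_noisy_segmenter(
            test, ResponderParams(hit_rate=h, false_alarm_rate=0.1, seed=2))
        table = bin_by_log_frequency(
            classify_locations(resp, test, lexicon), n_bins=4)
        bound = table[table.is_boundary & (table.n >= 30)]
        for _, row in bound.iterrows():
            assert abs(row.prop_correct - h) < 3 * np.sqrt(h * (1 - h) / row.n)


def enumerate_null_hits(G: int, k: int, m: int) -> float:
    """Oracle: mean hits over all C(G, m) equally likely mark placements."""
    gold = set(range(k))  # boundary identity is exchangeable
    hits = [len(gold & set(marks))
            for marks in itertools.combinations(range(G), m)]
    return float(np.mean(hits))


class TestPermutationBaseline:
    @pytest.mark.parametrize("G,k,m", [(4, 2, 2), (6, 3, 2), (8, 3, 5),
                                       (5, 1, 4), (7, 6, 1)])
    def test_expected_hits_match_exhaustive_enumeration(self, G, k, m):
        """Mean permuted hits equals m*k/G, checked against full enumeration."""
        exact = enumerate_null_hits(G, k, m)
        assert exact == pytest.approx(m * k / G)
        # build a single synthetic sentence with G gaps and k boundaries
        from seglab.langgen import Sentence
        stream = tuple(f"s{i}" for i in range(G + 1))
        sent = Sentence(words=tuple(range(1, k + 2)),
                        syllable_stream=stream,
                        gold_gaps=frozenset(range(1, k + 1)))
        test = Corpus(sentences=(sent,))
        resp = response_for(test, [set(range(1, m + 1))])
        n_reps = 4000
        baseline = permutation_baseline(resp, test, n_reps=n_reps, seed=9)
        # with one sentence, F = 2h/(m+k) inverts exactly to per-replicate hits
        hits = baseline.f_samples * (m + k) / 2
        se = np.sqrt(m * (k / G) * (1 - k / G) / n_reps)
        assert abs(hits.mean() - exact) < 3 * se + 0.02

    def test_mark_counts_preserved_and_mean_f_consistent(self, small_language):
        """The null F distribution from the engine matches an independent
        per-sentence hypergeometric simulation of the same statistic."""
        _, _, test = small_language
        resp = oracle_noisy_segmenter(
            test, ResponderParams(hit_rate=0.7, false_alarm_rate=0.15, seed=4))
        baseline = permutation_baseline(resp, test, n_reps=3000, seed=5)
        # independent oracle: hits ~ sum of hypergeometrics
        rng = np.random.default_rng(123)
        total_k = sum(len(s.gold_gaps) for s in test.sentences)
        total_m = resp.n_marks
        hits = np.zeros(3000)
        for marks, s in zip(resp.gaps, test.sentences):
            k, G, m = len(s.gold_gaps), s.n_gaps, len(marks)
            if m:
                hits += rng.hypergeometric(k, G - k, m, size=3000)
        prec = hits / total_m
        rec = hits / total_k
        f = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0)
        assert abs(baseline.f_samples.mean() - f.mean()) < \
            4 * f.std() / np.sqrt(3000) + 1e-3

    def test_no_marks_gives_zero_null(self, small_language):
        _, _, test = small_language
        resp = response_for(test, [set() for _ in test.sentences])
        baseline = permutation_baseline(resp, test, n_reps=200, seed=0)
        assert np.all(baseline.f_samples == 0.0)

    def test_perfect_oracle_above_null(self, paper_language):
        """Observed F = 1 sits above the 97.5th percentile of the null."""
        _, _, test = paper_language
        resp = response_for(test, [s.gold_gaps for s in test.sentences])
        baseline = permutation_baseline(resp, test, n_reps=2000, seed=1)
        assert baseline.observed_f == 1.0
        assert baseline.observed_f > baseline.ci_high
        assert baseline.p_value < 0.01

    def test_random_segmenter_is_calibrated(self, small_language):
        """A uniformly random segmenter's p-value against its own null is
        roughly uniform: across runs the p-values span the unit interval."""
        _, _, test = small_language
        pvals = []
        for seed in range(20):
            rng = substream(seed, "rand-seg")
            gaps = []
            for s in test.sentences:
                m = int(rng.integers(0, s.n_gaps + 1))
                gaps.append(set(1 + rng.choice(s.n_gaps, size=m, replace=False)))
            resp = response_for(test, gaps)
            pvals.append(permutation_baseline(resp, test, n_reps=400,
                                              seed=seed).p_value)
        pvals = np.array(pvals)
        assert 0.2 < pvals.mean() < 0.8
        assert (pvals < 0.05).mean() < 0.3


class TestDegeneracyDetection:
    @pytest.mark.parametrize("period", [1, 2, 3])
    def test_flags_fixed_period(self, small_language, period):
        _, _, test = small_language
        resp = periodic_segmenter(test, period=period)
        flagged, diag = detect_degenerate_strategy(resp)
        assert flagged and diag["period"] == period

    def test_does_not_flag_noisy_oracle(self, paper_language):
        _, _, test = paper_language
        resp = oracle_noisy_segmenter(
            test, ResponderParams(hit_rate=0.6, false_alarm_rate=0.1, seed=8))
        flagged, _ = detect_degenerate_strategy(resp)
        assert not flagged

    def test_flags_all_empty_response(self, small_language):
        _, _, test = small_language
        resp = response_for(test, [set() for _ in test.sentences])
        flagged, diag = detect_degenerate_strategy(resp)
        assert flagged and diag["period"] is None
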