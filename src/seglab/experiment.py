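"""End-to-end experiment simulation.

Composes all pipeline stages under a single configuration: per simulated
participant, generate a unique language, run two interim segmentation
tests (the second without further exposure), score against gold with a
permutation-null baseline, run the location-level frequency analysis,
and — pairing each participant's language with the next participant's
as distractor source — build and score the 2AFC retention test with a
half-logit fit.  Yoked controls take each participant's first interim
test without training.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import langgen, learners, segeval, stats, twoafc
from .export import write_language_bundle
from .util import substream_seed

__all__ = ["ExperimentConfig", "ParticipantResult", "run_experiment"]

log = logging.getLogger("seglab")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of a simulated experiment.

    Defaults are the study conditions the package emulates: four
    participants, 1000-type / 60,000-token Zipfian languages with a
    10-token floor, 24x14 CV phonology, mean word length 3 and sentence
    length 4, 100-sentence interim tests, 10,000-replicate permutation
    baselines, and a 64-trial 2AFC with frequency cutoff 1000.
    """

    n_participants: int = 4
    n_types: int = 1000
    total_tokens: int = 60_000
    floor: int = 10
    length_mean: float = 3.0
    sentlen_mean: float = 4.0
    consonants: tuple[str, ...] = tuple(langgen.DEFAULT_CONSONANTS)
    vowels: tuple[str, ...] = tuple(langgen.DEFAULT_VOWELS)
    test_sentences: int = 100
    permutation_reps: int = 10_000
    twoafc_trials: int = 64
    freq_cutoff: int = 1000
    learner: str = "tp"                # "tp", "oracle" or "chunk"
    hit_rate: float = 0.55
    false_alarm_rate: float = 0.08
    tp_threshold: float = 0.1
    beta0: float = -4.0
    beta1: float = 0.8
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["consonants"] = list(d["consonants"])
        d["vowels"] = list(d["vowels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "consonants" in d:
            d["consonants"] = tuple(d["consonants"])
        if "vowels" in d:
            d["vowels"] = tuple(d["vowels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class ParticipantResult:
    participant_id: str
    scores: dict[str, segeval.ScoreReport]
    baselines: dict[str, segeval.PermutationBaseline]
    decisions: dict[str, list[segeval.LocationDecision]]
    twoafc_results: pd.DataFrame | None = None
    twoafc_fit: twoafc.HalfLogitFit | None = None


def _build_language(config: ExperimentConfig, seed: int):
    phonology = langgen.PhonologyConfig(config.consonants, config.vowels)
    inventory = langgen.build_syllable_inventory(phonology)
    allocation = langgen.allocate_zipf_counts(config.n_types,
                                              config.total_tokens, config.floor)
    lexicon = langgen.build_lexicon(inventory, allocation,
                                    length_mean=config.length_mean, seed=seed)
    training = langgen.generate_corpus(lexicon, sentlen_mean=config.sentlen_mean,
                                       seed=seed)
    test = langgen.generate_test_block(lexicon, training,
                                       n_sentences=config.test_sentences,
                                       sentlen_mean=config.sentlen_mean,
                                       seed=seed)
    return lexicon, training, test


def _trained_response(config: ExperimentConfig, lexicon, training, test,
                      pid: str, session: str) -> learners.SegmentationResponse:
    params = learners.ResponderParams(
        hit_rate=config.hit_rate, false_alarm_rate=config.false_alarm_rate,
        tp_threshold=config.tp_threshold,
        seed=substream_seed(config.master_seed, f"{pid}-{session}"))
    if config.learner == "oracle":
        return learners.oracle_noisy_segmenter(test, params, participant_id=pid)
    if config.learner == "chunk":
        return learners.chunk_segmenter(test, training, participant_id=pid)
    table = learners.estimate_tp(training)
    return learners.tp_segmenter(test, table, params, participant_id=pid)


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the full simulated experiment; return the combined report table.

    The report has one row per participant x condition x session with
    precision, recall, F, and the permutation-null 95% interval — the
    layout of the interim-test results figure.  With ``out_dir`` set,
    language bundles, per-location decision CSVs, 2AFC fits and the
    report are written beneath it.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    participants: list[ParticipantResult] = []
    languages = []
    rows = []
    for p in range(config.n_participants):
        pid = f"P{p + 1}"
        lang_seed = substream_seed(config.master_seed, f"language-{pid}")
        log.info("generating language for %s (seed %d)", pid, lang_seed)
        lexicon, training, test = _build_language(config, lang_seed)
        languages.append((lexicon, training, test))
        if out is not None:
            write_language_bundle(out / pid, lexicon, training, test,
                                  config.to_dict())

        result = ParticipantResult(pid, scores={}, baselines={}, decisions={})
        # two interim sessions on the same test block (no further exposure),
        # plus a yoked control who never saw the training corpus
        sessions = {
            "immediate": _trained_response(config, lexicon, training, test,
                                           pid, "immediate"),
            "followup": _trained_response(config, lexicon, training, test,
                                          pid, "followup"),
            "yoked": learners.yoked_control_segmenter(
                test,
                learners.ResponderParams(
                    tp_threshold=config.tp_threshold,
                    seed=substream_seed(config.master_seed, f"{pid}-yoked")),
                participant_id=f"{pid}-yoked"),
        }
        for session, response in sessions.items():
            score = segeval.score_segmentation(response, test)
            baseline = segeval.permutation_baseline(
                response, test, n_reps=config.permutation_reps,
                seed=substream_seed(config.master_seed, f"{pid}-{session}-perm"))
            result.scores[session] = score
            result.baselines[session] = baseline
            result.decisions[session] = segeval.classify_locations(
                response, test, lexicon)
            rows.append({
                "participant": pid, "session": session,
                "condition": response.condition,
                "precision": score.precision, "recall": score.recall,
                "f_score": score.f_score,
                "null_ci_low": baseline.ci_low, "null_ci_high": baseline.ci_high,
                "p_value": baseline.p_value,
            })
        participants.append(result)

    # 2AFC retention: distractors from the next participant's language
    for p, result in enumerate(participants):
        if config.n_participants < 2:
            break
        lexA = languages[p][0]
        lexB = languages[(p + 1) % config.n_participants][0]
        trials = twoafc.build_twoafc_trials(
            lexA, lexB, n_trials=config.twoafc_trials,
            freq_cutoff=config.freq_cutoff,
            seed=substream_seed(config.master_seed, f"{result.participant_id}-2afc"))
        responder = learners.ResponderParams(
            beta0=config.beta0, beta1=config.beta1,
            seed=substream_seed(config.master_seed,
                                f"{result.participant_id}-2afc-resp"))
        choices = learners.twoafc_responder(trials, responder,
                                            participant_id=result.participant_id)
        result.twoafc_results = twoafc.score_twoafc(trials, choices)
        result.twoafc_fit = twoafc.fit_half_logit(result.twoafc_results)
        if out is not None:
            pdir = out / result.participant_id
            result.twoafc_results.to_csv(pdir / "twoafc_results.csv", index=False)
            fit = result.twoafc_fit
            (pdir / "twoafc_fit.json").write_text(json.dumps({
                "beta0": fit.beta0, "beta1": fit.beta1,
                "log_likelihood": fit.log_likelihood,
                "ci_beta0": list(fit.ci_beta0), "ci_beta1": list(fit.ci_beta1),
                "boundary": fit.boundary}, indent=1))

    report = pd.DataFrame(rows)
    if out is not None:
        report.to_csv(out / "report.csv", index=False)
        for result in participants:
            pdir = out / result.participant_id
            for session, decs in result.decisions.items():
                pd.DataFrame([{
                    "sentence": d.sentence, "gap": d.gap,
                    "is_boundary": d.is_boundary, "marked": d.marked,
                    "correct": d.correct, "freq_label": d.freq_label,
                } for d in decs]).to_csv(pdir / f"locations_{session}.csv",
                                         index=False)
    return report
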