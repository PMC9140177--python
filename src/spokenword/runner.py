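"""Experiment orchestration: train, decode, decide, tabulate.

Ties the pipeline together: synthesize or load stimuli, train the phone
models from labelled data, run identification or lexical-decision trials,
and write per-trial and summary result tables.  All randomness flows from
explicit seeds, so a run is fully reproducible from its inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acoustic import ModelSet, init_models
from .acoustic import train_models as _train_models
from .activation import DecoderConfig, compute_activation_traces
from .decision import DecisionConfig, Response, decide_identification, decide_lexical
from .frontend import extract_features, read_wav, write_wav
from .lexicon import (
    CohortTree,
    LanguageModel,
    LexiconEntry,
    PseudoWordNetwork,
    build_pseudoword_network,
    compile_cohort_tree,
    entry_keys,
    read_lexicon,
)
from .synth import GroundTruth, Trial, make_training_data, synthesize_word_waveform

__all__ = [
    "ExperimentResult",
    "train_from_synth",
    "run_trials",
    "run_experiment",
    "write_results",
    "read_results",
    "write_manifest",
    "read_manifest",
]

RECORD_COLUMNS = [
    "stimulus_id",
    "task",
    "label",
    "truth",
    "correct",
    "decided_before_offset",
    "decision_ms",
    "choice_ms",
    "exec_ms",
    "rt_ms",
    "entropy_bits",
]


@dataclass
class ExperimentResult:
    """Per-trial responses joined with trial truth, plus a summary row."""

    records: pd.DataFrame

    @property
    def summary(self) -> pd.DataFrame:
        df = self.records
        if len(df) == 0:
            return pd.DataFrame(
                columns=["n_trials", "accuracy", "mean_rt_ms", "median_rt_ms"]
            )
        return pd.DataFrame(
            [
                {
                    "n_trials": len(df),
                    "accuracy": float(df["correct"].mean()),
                    "mean_rt_ms": float(df["rt_ms"].mean()),
                    "median_rt_ms": float(df["rt_ms"].median()),
                }
            ]
        )

    @property
    def accuracy(self) -> float:
        return float(self.records["correct"].mean())

    @property
    def mean_rt_ms(self) -> float:
        return float(self.records["rt_ms"].mean())


def train_from_synth(
    gt: GroundTruth,
    lexicon: list[LexiconEntry],
    n_tokens_per_word: int = 5,
    n_iter: int = 5,
    seed: int = 0,
) -> tuple[ModelSet, list[float]]:
    """Train a context-dependent model set on synthesized labelled tokens."""
    labeled = make_training_data(gt, lexicon, n_tokens_per_word, seed=seed)
    keys = []
    for e in lexicon:
        for key in entry_keys(e.phones):
            if key not in keys:
                keys.append(key)
    ms = init_models(keys, labeled)
    return _train_models(ms, labeled, n_iter=n_iter)


def _one_response(
    trial: Trial,
    gt: GroundTruth,
    ms: ModelSet,
    tree: CohortTree,
    pw: PseudoWordNetwork | None,
    lm: LanguageModel,
    dec_cfg: DecoderConfig,
    decision_cfg: DecisionConfig,
    task: str,
) -> Response:
    w = synthesize_word_waveform(trial.spec, gt)
    ft = extract_features(w)
    tr = compute_activation_traces(ft, tree, ms, pw=pw, lm=lm, cfg=dec_cfg)
    if task == "identification":
        return decide_identification(tr, decision_cfg)
    if task == "lexical_decision":
        return decide_lexical(tr, decision_cfg)
    raise ValueError(f"unknown task {task!r}")


def run_trials(
    trials: list[Trial],
    gt: GroundTruth,
    ms: ModelSet,
    lexicon: list[LexiconEntry],
    task: str = "identification",
    decoder_cfg: DecoderConfig | None = None,
    decision_cfg: DecisionConfig | None = None,
    with_pseudo: bool | None = None,
) -> ExperimentResult:
    """Run a list of synthetic trials through the full pipeline.

    Pseudo-word hypotheses are decoded whenever the task is lexical
    decision or any trial is a pseudo-word (overridable via with_pseudo).
    """
    decoder_cfg = decoder_cfg or DecoderConfig()
    decision_cfg = decision_cfg or DecisionConfig()
    tree = compile_cohort_tree(lexicon, ms)
    lm = LanguageModel.from_entries(lexicon)
    if with_pseudo is None:
        with_pseudo = task == "lexical_decision" or any(
            not t.spec.is_word for t in trials
        )
    pw = build_pseudoword_network(
        lexicon, pseudo_prior=decoder_cfg.pseudo_prior
    ) if with_pseudo else None

    rows = []
    for trial in trials:
        resp = _one_response(
            trial, gt, ms, tree, pw, lm, decoder_cfg, decision_cfg, task
        )
        if task == "identification":
            correct = trial.spec.is_word and resp.label == trial.truth_label
        else:
            truth = "word" if trial.spec.is_word else "pseudo-word"
            correct = resp.label == truth
        rows.append(
            {
                "stimulus_id": trial.stimulus_id,
                "task": resp.task,
                "label": resp.label,
                "truth": trial.truth_label,
                "correct": bool(correct),
                "decided_before_offset": resp.decided_before_offset,
                "decision_ms": resp.decision_ms,
                "choice_ms": resp.choice_ms,
                "exec_ms": resp.exec_ms,
                "rt_ms": resp.rt_ms,
                "entropy_bits": resp.entropy_bits,
            }
        )
    return ExperimentResult(pd.DataFrame(rows, columns=RECORD_COLUMNS))


MANIFEST_COLUMNS = [
    "stimulus_id",
    "wav",
    "phones",
    "is_word",
    "noise_start_ms",
    "noise_end_ms",
    "snr_db",
    "seed",
]


def write_manifest(trials: list[Trial], gt: GroundTruth, out_dir: str) -> str:
    """Write stimuli as WAV files plus a trial manifest CSV."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for trial in trials:
        wav_path = os.path.join(out_dir, f"{trial.stimulus_id}.wav")
        write_wav(wav_path, synthesize_word_waveform(trial.spec, gt))
        noise = trial.spec.noise
        rows.append(
            {
                "stimulus_id": trial.stimulus_id,
                "wav": wav_path,
                "phones": " ".join(trial.spec.target),
                "is_word": trial.spec.is_word,
                "noise_start_ms": noise.start_ms if noise else "",
                "noise_end_ms": noise.end_ms if noise else "",
                "snr_db": noise.snr_db if noise else "",
                "seed": trial.spec.seed,
            }
        )
    path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def run_experiment(
    manifest_path: str,
    models_path: str,
    lexicon_path: str,
    task: str = "identification",
    decoder_cfg: DecoderConfig | None = None,
    decision_cfg: DecisionConfig | None = None,
) -> ExperimentResult:
    """File-level entry point: WAV stimuli + trained models + lexicon in,
    per-trial response records out."""
    decoder_cfg = decoder_cfg or DecoderConfig()
    decision_cfg = decision_cfg or DecisionConfig()
    manifest = read_manifest(manifest_path)
    ms = ModelSet.from_json(models_path)
    lexicon = read_lexicon(lexicon_path)
    tree = compile_cohort_tree(lexicon, ms)
    lm = LanguageModel.from_entries(lexicon)
    need_pseudo = task == "lexical_decision" or (~manifest["is_word"]).any()
    pw = build_pseudoword_network(
        lexicon, pseudo_prior=decoder_cfg.pseudo_prior
    ) if need_pseudo else None

    by_phones = {}
    for e in lexicon:
        by_phones.setdefault(e.phones, e.orthography)
    rows = []
    for rec in manifest.itertuples(index=False):
        ft = extract_features(read_wav(rec.wav))
        tr = compute_activation_traces(ft, tree, ms, pw=pw, lm=lm, cfg=decoder_cfg)
        if task == "identification":
            resp = decide_identification(tr, decision_cfg)
        else:
            resp = decide_lexical(tr, decision_cfg)
        phones = tuple(str(rec.phones).split())
        if task == "identification":
            truth = by_phones.get(phones, "pseudo-word")
            correct = bool(rec.is_word) and resp.label == truth
        else:
            truth = "word" if bool(rec.is_word) else "pseudo-word"
            correct = resp.label == truth
        rows.append(
            {
                "stimulus_id": rec.stimulus_id,
                "task": resp.task,
                "label": resp.label,
                "truth": truth,
                "correct": bool(correct),
                "decided_before_offset": resp.decided_before_offset,
                "decision_ms": resp.decision_ms,
                "choice_ms": resp.choice_ms,
                "exec_ms": resp.exec_ms,
                "rt_ms": resp.rt_ms,
                "entropy_bits": resp.entropy_bits,
            }
        )
    return ExperimentResult(pd.DataFrame(rows, columns=RECORD_COLUMNS))


def write_results(res: ExperimentResult, out_dir: str) -> tuple[str, str]:
    """Write records.csv and summary.csv with fixed float precision."""
    os.makedirs(out_dir, exist_ok=True)
    rec_path = os.path.join(out_dir, "records.csv")
    sum_path = os.path.join(out_dir, "summary.csv")
    res.records.to_csv(rec_path, index=False, float_format="%.6f")
    res.summary.to_csv(sum_path, index=False, float_format="%.6f")
    return rec_path, sum_path


def read_results(rec_path: str) -> ExperimentResult:
    df = pd.read_csv(rec_path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{rec_path}: records missing columns {sorted(missing)}")
    return ExperimentResult(df)
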