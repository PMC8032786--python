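"""The four gaze-similarity designs, back-sorted by subsequent memory.

For each participant, studied trials carry a motivation cue (remember /
control / forget) and a later memory outcome (hit / miss).  Four similarity
measures are computed over the encoded scanpaths:

* ``enc_test`` — each image's encoding scanpath vs. the same image's
  test-phase scanpath (gaze reinstatement at retrieval).
* ``enc_reg`` — each image's encoding scanpath vs. the scanpath on the
  blurred image that immediately follows it in the regulation phase.
* ``global_enc_reg`` — each hit's (miss's) encoding scanpath vs. the
  regulation scanpaths of all *other* hits (misses), averaged; an
  across-stimulus measure in the style of neural global-reinstatement
  analyses.
* ``global_enc_enc`` — the same, with encoding scanpaths on both sides.

Global comparisons pool across motivation cues by default (each per-trial
global score is then averaged into the cell of its own trial's cue); a
``within_motivation`` switch restricts comparison partners to the same cue.
Per-trial scores are reduced to unweighted per-participant cell means for
the 3 (motivation) x 2 (outcome) repeated-measures design; empty cells are
flagged, never imputed.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .config import StudyConfig
from .scanpath import (GridSpec, Scanpath, build_substitution_matrix,
                       encode_sequence, similarity)

__all__ = [
    "MEASURES",
    "encode_fixation_table",
    "encoding_test_similarity",
    "encoding_regulation_similarity",
    "global_cross_similarity",
    "cell_means",
    "participants_with_empty_cells",
]

MEASURES = ("enc_test", "enc_reg", "global_enc_reg", "global_enc_enc")


def encode_fixation_table(fixations: pd.DataFrame, config: StudyConfig) -> dict:
    """Encode every (participant, trial, phase) record into a symbol sequence.

    Returns a dict keyed by ``(participant_id, trial_index, phase)``.
    Fixations are assumed onset-sorted within a record (the reader
    guarantees this).
    """
    grid = GridSpec.from_config(config)
    encoded = {}
    for key, grp in fixations.groupby(
        ["participant_id", "trial_index", "phase"], observed=True, sort=False
    ):
        sp = Scanpath(key[0], key[1], key[2],
                      grp["x_px"].to_numpy(), grp["y_px"].to_numpy(),
                      grp["duration_ms"].to_numpy())
        encoded[key] = encode_sequence(sp, grid, config.temporal_bin_ms,
                                       config.max_sequence_length)
    return encoded


def _studied_with_outcome(trials: pd.DataFrame) -> pd.DataFrame:
    mask = trials["studied"].astype(bool) & trials["outcome"].isin(["hit", "miss"])
    return trials[mask]


def _paired_phase_similarity(encoded: dict, trials: pd.DataFrame,
                             config: StudyConfig, target_phase: str,
                             measure: str) -> pd.DataFrame:
    grid = GridSpec.from_config(config)
    sub = build_substitution_matrix(grid, config.substitution_threshold)
    rows = []
    for rec in _studied_with_outcome(trials).itertuples():
        a = encoded.get((rec.participant_id, rec.trial_index, "encoding"))
        b = encoded.get((rec.participant_id, rec.trial_index, target_phase))
        if a is None or b is None:
            continue  # phase record missing or excluded; trial skipped
        score = similarity(a, b, sub, config.substitution_threshold,
                           config.gap_penalty)
        rows.append((rec.participant_id, rec.trial_index, rec.motivation,
                     rec.outcome, measure, score))
    return pd.DataFrame(rows, columns=["participant_id", "trial_index",
                                       "motivation", "outcome", "measure",
                                       "score"])


def encoding_test_similarity(encoded: dict, trials: pd.DataFrame,
                             config: StudyConfig) -> pd.DataFrame:
    """Per-trial encoding-vs-test similarity; foils have no encoding record."""
    return _paired_phase_similarity(encoded, trials, config, "test", "enc_test")


def encoding_regulation_similarity(encoded: dict, trials: pd.DataFrame,
                                   config: StudyConfig) -> pd.DataFrame:
    """Per-trial encoding-vs-regulation similarity (trial i with blurred i)."""
    return _paired_phase_similarity(encoded, trials, config, "regulation",
                                    "enc_reg")


def global_cross_similarity(encoded: dict, trials: pd.DataFrame,
                            config: StudyConfig, source_phase: str,
                            target_phase: str, measure: str | None = None,
                            within_motivation: bool | None = None) -> pd.DataFrame:
    """Across-stimulus global similarity, separately for hits and misses.

    For trial *i* with outcome *c*, the global score is the arithmetic mean
    of ``similarity(source_i, target_j)`` over all other trials *j* with
    the same outcome (never the same trial).  An outcome class with fewer
    than 2 trials yields no scores for that class.
    """
    if within_motivation is None:
        within_motivation = config.global_within_motivation
    if measure is None:
        measure = f"global_{source_phase[:3]}_{target_phase[:3]}"
    grid = GridSpec.from_config(config)
    sub = build_substitution_matrix(grid, config.substitution_threshold)
    T, gap = config.substitution_threshold, config.gap_penalty
    symmetric = source_phase == target_phase

    rows = []
    studied = _studied_with_outcome(trials)
    group_cols = ["participant_id", "outcome"]
    if within_motivation:
        group_cols.append("motivation")
    for _, grp in studied.groupby(group_cols, observed=True, sort=False):
        recs = [r for r in grp.itertuples()
                if (r.participant_id, r.trial_index, source_phase) in encoded
                and (r.participant_id, r.trial_index, target_phase) in encoded]
        k = len(recs)
        if k < 2:
            continue
        src = [encoded[(r.participant_id, r.trial_index, source_phase)] for r in recs]
        tgt = [encoded[(r.participant_id, r.trial_index, target_phase)] for r in recs]
        sims = np.zeros((k, k))
        if symmetric:
            for i, j in itertools.combinations(range(k), 2):
                sims[i, j] = sims[j, i] = similarity(src[i], tgt[j], sub, T, gap)
        else:
            for i in range(k):
                for j in range(k):
                    if i != j:
                        sims[i, j] = similarity(src[i], tgt[j], sub, T, gap)
        g = sims.sum(axis=1) / (k - 1)  # diagonal (same-trial pair) excluded
        for r, gi in zip(recs, g):
            rows.append((r.participant_id, r.trial_index, r.motivation,
                         r.outcome, measure, gi))
    return pd.DataFrame(rows, columns=["participant_id", "trial_index",
                                       "motivation", "outcome", "measure",
                                       "score"])


def cell_means(scores: pd.DataFrame,
               motivations=("remember", "control", "forget"),
               outcomes=("hit", "miss")) -> pd.DataFrame:
    """Unweighted per-participant cell means over the full 3 x 2 design.

    Every (participant, motivation, outcome) cell appears exactly once per
    measure; cells with no contributing trials have ``n_trials`` 0 and a
    missing mean.
    """
    if scores.empty:
        return pd.DataFrame(columns=["participant_id", "measure", "motivation",
                                     "outcome", "n_trials", "mean_score"])
    agg = (
        scores.groupby(["participant_id", "measure", "motivation", "outcome"],
                       observed=True)["score"]
        .agg(n_trials="size", mean_score="mean")
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [scores["participant_id"].unique(), scores["measure"].unique(),
         motivations, outcomes],
        names=["participant_id", "measure", "motivation", "outcome"],
    ).to_frame(index=False)
    out = full.merge(agg, how="left",
                     on=["participant_id", "measure", "motivation", "outcome"])
    out["n_trials"] = out["n_trials"].fillna(0).astype(int)
    return out


def participants_with_empty_cells(cells: pd.DataFrame) -> list:
    """Participants with any empty motivation x outcome cell (per measure)."""
    empty = cells[cells["n_trials"] == 0]
    return sorted(empty["participant_id"].unique().tolist())
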