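"""Readers and writers for the pipeline's tabular artifacts.

Fixation tables and trial manifests are plain delimited files (comma or
tab, sniffed from the header line).  Fixation coordinates on disk are in
the *screen* frame; the reader translates them into the stimulus frame
using the configured offsets (defaults place a 1024 x 768 stimulus
centered on a 1920 x 1080 screen).  SCR traces are two-column
(time_s, conductance_uS) CSVs accompanied by an events CSV
(trial_index, onset_s, movement_flag).
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "FormatError",
    "ValidationError",
    "read_fixation_table",
    "read_trial_manifest",
    "read_scr_trace",
    "read_scr_events",
]

log = logging.getLogger("gazesim")

FIXATION_COLUMNS = ("participant_id", "trial_index", "phase",
                    "x_px", "y_px", "onset_ms", "duration_ms")
MANIFEST_COLUMNS = ("participant_id", "trial_index", "image_id",
                    "motivation", "studied", "test_response")


class FormatError(ValueError):
    """A file does not have the expected columns or delimiter."""


class ValidationError(ValueError):
    """A file parses but violates an invariant of its table."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def read_fixation_table(path: str | Path, config: StudyConfig,
                        frame: str = "screen") -> pd.DataFrame:
    """Read, validate and stimulus-align a fixation table.

    Rows come back grouped and sorted by (participant, trial, phase,
    onset).  ``frame`` says which frame the file's coordinates are in;
    ``"screen"`` (the default) applies the configured screen offsets,
    ``"stimulus"`` reads them as-is.
    """
    df = _read_delimited(path)
    _require_columns(df, FIXATION_COLUMNS, path)
    if (df["duration_ms"] <= 0).any():
        bad = df[df["duration_ms"] <= 0].iloc[0]
        raise ValidationError(
            f"{path}: non-positive duration in trial {bad['trial_index']} "
            f"({bad['participant_id']})")
    df = df.sort_values(["participant_id", "trial_index", "phase",
                         "onset_ms"], kind="stable").reset_index(drop=True)
    for key, grp in df.groupby(["participant_id", "trial_index", "phase"],
                               observed=True, sort=False):
        onsets = grp["onset_ms"].to_numpy()
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError(
                f"{path}: non-monotone fixation onsets in participant "
                f"{key[0]}, trial {key[1]}, phase {key[2]}")
    if frame == "screen":
        df["x_px"] = df["x_px"] - config.screen_offset_x_px
        df["y_px"] = df["y_px"] - config.screen_offset_y_px
    elif frame != "stimulus":
        raise ValueError("frame must be 'screen' or 'stimulus'")
    return df


def read_trial_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial manifest; foils are flagged studied=False."""
    df = _read_delimited(path)
    if df.empty:
        log.warning("%s: empty trial manifest", path)
        return pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    _require_columns(df, MANIFEST_COLUMNS, path)
    df["studied"] = df["studied"].astype(bool)
    dup = df.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (participant, trial) key "
            f"({bad['participant_id']}, {bad['trial_index']})")
    studied = df[df["studied"]]
    missing_mot = studied["motivation"].isna() | \
        ~studied["motivation"].isin(["remember", "control", "forget"])
    if missing_mot.any():
        bad = studied[missing_mot].iloc[0]
        raise ValidationError(
            f"{path}: studied trial without a valid motivation cue "
            f"({bad['participant_id']}, trial {bad['trial_index']})")
    return df


def read_scr_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_delimited(path)
    _require_columns(df, ("time_s", "conductance_uS"), path)
    return df["time_s"].to_numpy(), df["conductance_uS"].to_numpy()


def read_scr_events(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    _require_columns(df, ("trial_index", "onset_s", "movement_flag"), path)
    df["movement_flag"] = df["movement_flag"].astype(bool)
    return df
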