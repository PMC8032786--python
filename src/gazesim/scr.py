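"""Skin-conductance response (SCR) extraction and reduction.

The per-trial SCR amplitude is the maximal increase in skin conductance in
a window 1-5 s after stimulus onset, implemented as the largest
trough-to-peak rise inside the window (an alternative baseline — the
conductance value at stimulus onset — is available via
``StudyConfig.scr_baseline``).  Reduction follows a single pass in the
order standardize -> filter -> nonresponder detection:

1. amplitudes are z-scored within (participant, phase, block), where the
   two blocks are the trials before and after the session break
   (minimizing habituation effects in the standardization);
2. trials with |z| > 5, and trials with a movement annotation whose z is
   strictly positive, are removed;
3. a block whose retained amplitudes have a standard deviation below
   0.01 uS is nonresponsive and dropped; if both blocks of a phase are
   nonresponsive the participant's SCR data for that phase are dropped
   entirely.

Raw (not standardized) amplitudes feed the downstream ANOVAs; the z-scores
exist only to identify outliers and movement-contaminated trials.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "extract_scr_amplitude",
    "extract_features",
    "standardize_within_block",
    "filter_scr_trials",
    "detect_nonresponders",
    "reduce_features",
    "RULE_SCR_OUTLIER",
    "RULE_SCR_MOVEMENT",
    "RULE_NONRESPONDER",
]

RULE_SCR_OUTLIER = "scr_outlier"
RULE_SCR_MOVEMENT = "scr_movement"
RULE_NONRESPONDER = "scr_nonresponder"


def extract_scr_amplitude(time_s: np.ndarray, conductance_uS: np.ndarray,
                          onset_s: float, window: tuple[float, float] = (1.0, 5.0),
                          baseline: str = "trough_to_peak") -> float:
    """Largest rise in conductance within ``[onset+w0, onset+w1]``.

    With the default trough-to-peak baseline the amplitude is
    ``max_t (s(t) - min_{t' <= t} s(t'))`` over the window — non-negative
    by construction, invariant to constant shifts and robust to slow
    downward drift.  Returns NaN when the window extends past the trace.
    """
    t = np.asarray(time_s, dtype=float)
    s = np.asarray(conductance_uS, dtype=float)
    lo, hi = onset_s + window[0], onset_s + window[1]
    if lo < t[0] or hi > t[-1]:
        return float("nan")
    mask = (t >= lo) & (t <= hi)
    seg = s[mask]
    if seg.size == 0:
        return float("nan")
    if baseline == "onset_value":
        base = np.interp(onset_s, t, s)
        return float(max(seg.max() - base, 0.0))
    running_min = np.minimum.accumulate(seg)
    return float((seg - running_min).max())


def extract_features(time_s: np.ndarray, conductance_uS: np.ndarray,
                     events: pd.DataFrame, participant_id: str, phase: str,
                     config: StudyConfig) -> pd.DataFrame:
    """Score every annotated trial of one participant-phase trace.

    ``events`` rows: (trial_index, onset_s, movement_flag).  Block is the
    pre/post-break half of the trial sequence unless the events table
    already carries a ``block`` column.
    """
    ev = events.sort_values("trial_index").reset_index(drop=True)
    if "block" in ev.columns:
        block = ev["block"].to_numpy()
    else:
        half = (ev["trial_index"].max() + 1) / 2
        block = np.where(ev["trial_index"] < half, 1, 2)
    amps = [
        extract_scr_amplitude(time_s, conductance_uS, onset,
                              config.scr_window_s, config.scr_baseline)
        for onset in ev["onset_s"]
    ]
    return pd.DataFrame({
        "participant_id": participant_id,
        "trial_index": ev["trial_index"],
        "phase": phase,
        "block": block,
        "amplitude_uS": amps,
        "movement_flag": ev["movement_flag"].astype(bool),
    })


def standardize_within_block(features: pd.DataFrame) -> pd.DataFrame:
    """z-score amplitudes within (participant, phase, block); sample SD (n-1).

    A block with zero SD leaves z undefined there; such blocks fall through
    to the nonresponder check.
    """
    out = features.copy()

    def _z(x):
        sd = x.std(ddof=1)
        # guard the degenerate all-equal block against rounding noise
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(x.abs().max())):
            return pd.Series(np.nan, index=x.index)
        return (x - x.mean()) / sd

    out["z"] = (
        out.groupby(["participant_id", "phase", "block"], observed=True)
        ["amplitude_uS"].transform(_z)
    )
    return out


def filter_scr_trials(features: pd.DataFrame, outlier_z: float = 5.0
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag outlier and movement-contaminated trials.

    Removal fires when |z| > ``outlier_z``, or when a movement occurred and
    z is strictly greater than 0 (a movement trial with z <= 0 is kept).
    """
    out = features.copy()
    z = out["z"]
    outlier = z.abs() > outlier_z
    movement = out["movement_flag"] & (z > 0)
    out["retained"] = ~(outlier.fillna(False) | movement.fillna(False))
    out["drop_rule"] = None
    out.loc[outlier.fillna(False), "drop_rule"] = RULE_SCR_OUTLIER
    out.loc[movement.fillna(False) & ~outlier.fillna(False),
            "drop_rule"] = RULE_SCR_MOVEMENT
    dropped = out[~out["retained"]]
    report = pd.DataFrame({
        "participant_id": dropped["participant_id"],
        "rule_id": dropped["drop_rule"],
        "detail": [
            f"phase {p} trial {t}: z={z:.2f}" + (" movement" if m else "")
            for p, t, z, m in zip(dropped["phase"], dropped["trial_index"],
                                  dropped["z"], dropped["movement_flag"])
        ],
        "stage": "scr_trial_filter",
    })
    return out, report


def detect_nonresponders(features: pd.DataFrame, sd_threshold_uS: float = 0.01
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop nonresponsive blocks and participants, after single-item removal.

    Within each (participant, phase): if the retained amplitudes of both
    blocks have SD below the threshold, all SCR data of that participant-
    phase are dropped; if only one block is below, only that block is
    dropped.
    """
    out = features.copy()
    report_rows = []
    for (pid, phase), grp in out.groupby(["participant_id", "phase"],
                                         observed=True):
        kept = grp[grp["retained"]]
        sds = kept.groupby("block")["amplitude_uS"].std(ddof=1)
        low = {b: (b in sds.index and np.isfinite(sds[b])
                   and sds[b] < sd_threshold_uS)
               or (b in sds.index and not np.isfinite(sds[b]))
               for b in (1, 2)}
        # a block absent from the retained data is vacuously nonresponsive
        for b in (1, 2):
            if b not in sds.index:
                low[b] = True
        if low[1] and low[2]:
            idx = grp.index[grp["retained"]]
            out.loc[idx, "retained"] = False
            out.loc[idx, "drop_rule"] = RULE_NONRESPONDER
            report_rows.append((pid, RULE_NONRESPONDER,
                                f"phase {phase}: both blocks SD < "
                                f"{sd_threshold_uS} uS", "scr_participant_filter"))
        else:
            for b in (1, 2):
                if low[b]:
                    idx = grp.index[grp["retained"] & (grp["block"] == b)]
                    out.loc[idx, "retained"] = False
                    out.loc[idx, "drop_rule"] = RULE_NONRESPONDER
                    report_rows.append((pid, RULE_NONRESPONDER,
                                        f"phase {phase}: block {b} SD < "
                                        f"{sd_threshold_uS} uS",
                                        "scr_block_filter"))
    report = pd.DataFrame(report_rows, columns=["participant_id", "rule_id",
                                                "detail", "stage"])
    return out, report


def reduce_features(features: pd.DataFrame, config: StudyConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass reduction: standardize, filter, then nonresponder check."""
    feats = standardize_within_block(features)
    feats, rep1 = filter_scr_trials(feats, config.scr_outlier_z)
    feats, rep2 = detect_nonresponders(feats, config.nonresponder_sd_uS)
    return feats, pd.concat([rep1, rep2], ignore_index=True)
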