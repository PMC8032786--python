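"""Study and generator configuration.

Two dataclasses hold every tunable of the pipeline:

* :class:`StudyConfig` — analysis parameters (grid geometry, temporal bin,
  substitution threshold, SCR window and reduction thresholds, exclusion
  thresholds, alpha, Bayes-factor prior scale).
* :class:`GeneratorConfig` — synthetic-dataset parameters (design size,
  fixation statistics, reinstatement probabilities, interference strength,
  SCR bump amplitudes).

Both round-trip through plain YAML mappings whose keys mirror the field
names exactly.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "GeneratorConfig", "load_config", "save_config"]


@dataclass
class StudyConfig:
    """Analysis-side parameters.

    Defaults follow the study design: a 12 x 8 region-of-interest grid over a
    1024 x 768 stimulus, 50 ms temporal bins, substitution-matrix threshold 4,
    zero gap penalty, SCR scoring window 1-5 s post onset, |z| > 5 outlier
    cut, 0.01 uS nonresponder criterion, minimum 3 fixations per record and a
    20% regulation-phase removal cap per participant.
    """

    grid_nx: int = 12
    grid_ny: int = 8
    stim_width_px: int = 1024
    stim_height_px: int = 768
    # screen -> stimulus translation; default: 1024x768 centered on 1920x1080
    screen_offset_x_px: int = 448
    screen_offset_y_px: int = 156
    temporal_bin_ms: float = 50.0
    substitution_threshold: float = 4.0
    gap_penalty: float = 0.0
    max_sequence_length: int = 200
    scr_window_s: tuple[float, float] = (1.0, 5.0)
    scr_outlier_z: float = 5.0
    scr_baseline: str = "trough_to_peak"  # or "onset_value"
    nonresponder_sd_uS: float = 0.01
    min_fixations: int = 3
    max_removed_fraction: float = 0.20
    global_within_motivation: bool = False
    drop_encoding_of_excluded_regulation: bool = False
    alpha: float = 0.05
    bf_prior_scale: float = math.sqrt(2) / 2
    gg_always: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid_nx and grid_ny must be >= 1")
        if self.temporal_bin_ms <= 0:
            raise ValueError("temporal_bin_ms must be > 0")
        if not 0.0 <= self.max_removed_fraction <= 1.0:
            raise ValueError("max_removed_fraction must lie in [0, 1]")
        self.scr_window_s = tuple(self.scr_window_s)  # yaml gives a list
        if self.scr_window_s[0] >= self.scr_window_s[1]:
            raise ValueError("scr_window_s must be an increasing pair")
        if self.scr_baseline not in ("trough_to_peak", "onset_value"):
            raise ValueError("scr_baseline must be 'trough_to_peak' or 'onset_value'")

    @property
    def bin_width_px(self) -> float:
        return self.stim_width_px / self.grid_nx

    @property
    def bin_height_px(self) -> float:
        return self.stim_height_px / self.grid_ny


@dataclass
class GeneratorConfig:
    """Synthetic-study parameters.

    The defaults emulate the study design: 36 participants, 90 studied trials
    each (30 per motivation cue) plus 90 foils, 3000 ms viewing per phase,
    fixation durations ~ N(250, 80) ms truncated at 60 ms, and per-motivation
    base hit rates of .70 / .60 / .59 (remember / control / forget).

    ``template_share_prob`` and ``interference_beta`` build the
    across-stimulus interference structure: a trial whose encoding scanpath
    derives from the participant-level template both resembles other template
    trials and is pushed toward a miss outcome.  ``reg_rho_by_motivation``
    and ``test_rho_by_outcome`` control gaze reinstatement during the
    regulation and test phases.  SCR bump amplitudes default to the
    condition means the analyses are meant to recover (encoding: misses
    larger; test: hits larger).
    """

    n_participants: int = 36
    n_trials: int = 90  # studied trials; 30 per motivation cue
    n_foils: int = 90
    viewing_ms: float = 3000.0
    fixation_duration_mean_ms: float = 250.0
    fixation_duration_sd_ms: float = 80.0
    fixation_duration_min_ms: float = 60.0
    central_bias_sd_px: float = 150.0
    template_length: int = 24
    template_share_prob: float = 0.4
    template_jitter_sd_px: float = 40.0
    reg_rho_by_motivation: dict = field(
        default_factory=lambda: {"remember": 0.55, "control": 0.45, "forget": 0.35}
    )
    test_rho_by_outcome: dict = field(default_factory=lambda: {"hit": 0.6, "miss": 0.3})
    interference_beta: float = 2.0
    base_hit_rates: dict = field(
        default_factory=lambda: {"remember": 0.70, "control": 0.60, "forget": 0.59}
    )
    false_alarm_rate: float = 0.15
    short_record_prob: float = 0.023
    scr_fs_hz: float = 1000.0
    scr_trial_spacing_s: float = 9.0
    scr_latency_s: float = 1.0
    scr_rise_s: float = 0.75
    scr_decay_s: float = 2.0
    scr_amp_by_phase_outcome: dict = field(
        default_factory=lambda: {
            "encoding": {"hit": 0.14, "miss": 0.17},
            "regulation": {"hit": 0.12, "miss": 0.12},
            "test": {"hit": 0.12, "miss": 0.09},
        }
    )
    scr_amp_trial_sd_uS: float = 0.08
    scr_tonic_uS: float = 2.0
    scr_drift_uS: float = 0.05
    scr_noise_sd_uS: float = 0.005
    movement_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("template_share_prob", "false_alarm_rate", "short_record_prob",
                     "movement_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for m, r in self.reg_rho_by_motivation.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"reg_rho_by_motivation[{m}] must lie in [0, 1]")
        for o, r in self.test_rho_by_outcome.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"test_rho_by_outcome[{o}] must lie in [0, 1]")
        for name in ("fixation_duration_sd_ms", "central_bias_sd_px",
                     "template_jitter_sd_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_trials % 3:
            raise ValueError("n_trials must be divisible by the 3 motivation cues")


def load_config(path: str | Path, kind: str = "study") -> StudyConfig | GeneratorConfig:
    """Load a YAML config whose keys mirror the dataclass field names."""
    cls = StudyConfig if kind == "study" else GeneratorConfig
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(**payload)


def save_config(config: StudyConfig | GeneratorConfig, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["scr_window_s"] = list(payload.get("scr_window_s", [])) or None
    if payload["scr_window_s"] is None:
        payload.pop("scr_window_s")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
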