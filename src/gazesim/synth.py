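"""Synthetic study generator with known ground truth.

Emulates the structure of a two-session directed-forgetting experiment:
each participant encodes 90 scene images (3000 ms each) cued post-stimulus
to remember, forget, or neither (30 trials per cue), views a blurred
version during a regulation phase, and later takes an old/new recognition
test over the 90 studied images plus 90 foils.  Skin conductance is
recorded continuously at 1000 Hz in every phase.

The gaze model is a template + central-bias mixture, built so the
analyses' target effects exist by construction:

* **Across-stimulus interference** — with probability
  ``template_share_prob`` a trial's encoding scanpath derives from a
  participant-level template (with positional jitter); template trials are
  pushed toward miss outcomes with log-odds increment
  ``interference_beta``.  Misses therefore share gaze structure, raising
  global encoding-encoding (and encoding-regulation) similarity for misses
  over hits.
* **Gaze reinstatement** — each regulation / test fixation is, with
  probability rho, a jittered copy of the positionally corresponding
  encoding fixation (fresh central-bias draw otherwise).  Regulation rho
  varies by motivation cue (remember > control > forget) and test rho by
  outcome (hits > misses), mirroring the motivational modulation and the
  encoding-test memory benefit.

SCR traces are tonic level + slow sinusoidal drift + per-trial phasic
bumps (bi-exponential, rise 0.75 s / decay 2 s, onset latency 1 s so the
rise falls inside the 1-5 s scoring window) with condition-dependent
mean amplitudes, trial-level amplitude jitter, and white noise.  Everything is reproducible from the
config seed; SCR traces are regenerated on demand from per-(participant,
phase) child seeds rather than held in memory.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import GeneratorConfig

__all__ = [
    "MOTIVATIONS",
    "ParticipantState",
    "SyntheticDataset",
    "draw_fixation_durations",
    "generate_encoding_scanpath",
    "generate_followup_scanpath",
    "generate_outcomes",
    "generate_scr_trace",
    "generate_dataset",
    "write_dataset",
]

MOTIVATIONS = ("remember", "control", "forget")
PHASES = ("encoding", "regulation", "test")


@dataclass
class ParticipantState:
    """Per-participant latent state: the shared scanpath template."""

    participant_id: str
    template_xy: np.ndarray  # (template_length, 2)


def draw_fixation_durations(config: GeneratorConfig, rng: np.random.Generator
                            ) -> np.ndarray:
    """Renewal sequence of truncated-normal durations filling the viewing time.

    Durations ~ N(mean, sd) truncated below at the minimum; fixations are
    appended until their total covers ``viewing_ms`` and the last one is
    trimmed to fit, so the sequence sums to the viewing time.
    """
    durations = []
    total = 0.0
    while total < config.viewing_ms:
        d = rng.normal(config.fixation_duration_mean_ms,
                       config.fixation_duration_sd_ms)
        d = max(d, config.fixation_duration_min_ms)
        if total + d > config.viewing_ms:
            d = config.viewing_ms - total
            if d < 1.0:  # negligible remainder; fold into previous fixation
                break
        durations.append(d)
        total += d
    if not durations:
        durations = [config.viewing_ms]
    return np.asarray(durations)


def _central_bias_xy(n: int, config: GeneratorConfig,
                     rng: np.random.Generator) -> np.ndarray:
    w, h = 1024.0, 768.0
    xy = rng.normal([w / 2, h / 2], config.central_bias_sd_px, size=(n, 2))
    return np.clip(xy, 0.0, [w - 1e-6, h - 1e-6])


def generate_encoding_scanpath(config: GeneratorConfig, state: ParticipantState,
                               is_template: bool, rng: np.random.Generator
                               ) -> tuple[np.ndarray, np.ndarray]:
    """One encoding viewing episode: (n, 2) locations and (n,) durations.

    Template trials reuse the participant template (cycled if the trial
    has more fixations than the template holds) with Gaussian jitter;
    non-template trials draw fresh central-bias locations.
    """
    durations = draw_fixation_durations(config, rng)
    n = len(durations)
    if is_template:
        base = np.resize(state.template_xy, (n, 2))
        xy = base + rng.normal(0.0, config.template_jitter_sd_px, size=(n, 2))
        xy = np.clip(xy, 0.0, [1024 - 1e-6, 768 - 1e-6])
    else:
        xy = _central_bias_xy(n, config, rng)
    return xy, durations


def generate_followup_scanpath(encoding_xy: np.ndarray, rho: float,
                               config: GeneratorConfig,
                               rng: np.random.Generator
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Regulation- or test-phase episode reinstating the encoding gaze.

    Each fixation is, with probability ``rho``, a jittered copy of the
    positionally corresponding encoding fixation (the last one if the new
    episode is longer); otherwise a fresh central-bias draw.
    """
    durations = draw_fixation_durations(config, rng)
    n = len(durations)
    reinstate = rng.random(n) < rho
    idx = np.minimum(np.arange(n), len(encoding_xy) - 1)
    fresh = _central_bias_xy(n, config, rng)
    copied = encoding_xy[idx] + rng.normal(
        0.0, config.template_jitter_sd_px, size=(n, 2))
    xy = np.where(reinstate[:, None], copied, fresh)
    return np.clip(xy, 0.0, [1024 - 1e-6, 768 - 1e-6]), durations


def generate_outcomes(motivations: np.ndarray, template_flags: np.ndarray,
                      config: GeneratorConfig, rng: np.random.Generator
                      ) -> np.ndarray:
    """Hit/miss outcomes: template trials are pushed toward misses.

    P(miss) = logistic(logit(1 - base_hit_rate[cue]) +
    interference_beta * template_flag).
    """
    base_miss = np.array([1.0 - config.base_hit_rates[m] for m in motivations])
    lp = logit(np.clip(base_miss, 1e-9, 1 - 1e-9)) \
        + config.interference_beta * template_flags.astype(float)
    miss = rng.random(len(motivations)) < expit(lp)
    return np.where(miss, "miss", "hit")


def _bump_kernel(config: GeneratorConfig, fs: float) -> np.ndarray:
    t = np.arange(0.0, 8.0, 1.0 / fs)
    h = np.exp(-t / config.scr_decay_s) - np.exp(-t / config.scr_rise_s)
    return h / h.max()


def generate_scr_trace(amplitudes_uS: np.ndarray, config: GeneratorConfig,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous conductance trace with one phasic bump per trial.

    Returns ``(time_s, conductance_uS, onsets_s)``.  Stimulus onsets are
    evenly spaced; each bump starts ``scr_latency_s`` after its onset so
    the trough-to-peak rise lands in the 1-5 s scoring window.
    """
    fs = config.scr_fs_hz
    n_trials = len(amplitudes_uS)
    onsets = 2.0 + np.arange(n_trials) * config.scr_trial_spacing_s
    total_s = onsets[-1] + 8.0
    t = np.arange(0.0, total_s, 1.0 / fs)
    phase0 = rng.uniform(0, 2 * np.pi)
    cond = config.scr_tonic_uS + config.scr_drift_uS * np.sin(
        2 * np.pi * t / 120.0 + phase0)
    kernel = _bump_kernel(config, fs)
    for onset, amp in zip(onsets, amplitudes_uS):
        i0 = int(round((onset + config.scr_latency_s) * fs))
        i1 = min(i0 + len(kernel), len(cond))
        cond[i0:i1] += amp * kernel[: i1 - i0]
    if config.scr_noise_sd_uS > 0:
        cond = cond + rng.normal(0.0, config.scr_noise_sd_uS, size=len(cond))
    return t, cond, onsets


@dataclass
class SyntheticDataset:
    """In-memory synthetic study plus deterministic SCR regeneration."""

    config: GeneratorConfig
    fixations: pd.DataFrame
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    participant_ids: list = field(default_factory=list)

    def scr_trace(self, participant_id: str, phase: str
                  ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Regenerate the (trace, events) pair for one participant-phase.

        Deterministic given the dataset seed; traces are not stored.
        """
        p = self.participant_ids.index(participant_id)
        k = PHASES.index(phase)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.config.seed, 7919, p, k]))
        gt = self.ground_truth
        rows = gt[gt["participant_id"] == participant_id].sort_values("trial_index")
        amps = rows[f"scr_amp_{phase}_uS"].to_numpy()
        t, cond, onsets = generate_scr_trace(amps, self.config, rng)
        movement = rng.random(len(onsets)) < self.config.movement_rate
        events = pd.DataFrame({
            "trial_index": rows["trial_index"].to_numpy(),
            "onset_s": onsets,
            "movement_flag": movement,
        })
        return t, cond, events


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full synthetic study (gaze + manifest + ground truth)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    n_per_cue = config.n_trials // 3
    fix_rows = []
    man_rows = []
    gt_rows = []
    pids = [f"p{p:03d}" for p in range(config.n_participants)]

    for pid in pids:
        state = ParticipantState(pid, _central_bias_xy(
            config.template_length, config, rng))
        motivations = np.array(
            [m for m in MOTIVATIONS for _ in range(n_per_cue)])
        rng.shuffle(motivations)
        template_flags = rng.random(config.n_trials) < config.template_share_prob
        outcomes = generate_outcomes(motivations, template_flags, config, rng)

        for trial in range(config.n_trials):
            mot, outcome = motivations[trial], outcomes[trial]
            enc_xy, enc_dur = generate_encoding_scanpath(
                config, state, template_flags[trial], rng)
            reg_rho = config.reg_rho_by_motivation[mot]
            test_rho = config.test_rho_by_outcome[outcome]
            reg_xy, reg_dur = generate_followup_scanpath(
                enc_xy, reg_rho, config, rng)
            test_xy, test_dur = generate_followup_scanpath(
                enc_xy, test_rho, config, rng)
            for phase, xy, dur in (("encoding", enc_xy, enc_dur),
                                   ("regulation", reg_xy, reg_dur),
                                   ("test", test_xy, test_dur)):
                n = len(dur)
                if rng.random() < config.short_record_prob:
                    n = int(rng.integers(1, 3))  # degraded record, < 3 fixations
                onset = np.concatenate([[0.0], np.cumsum(dur[:n])[:-1]])
                for i in range(n):
                    fix_rows.append((pid, 1, trial, phase, i,
                                     xy[i, 0], xy[i, 1], onset[i], dur[i]))
            man_rows.append((pid, trial, f"img{trial:03d}", mot, True,
                             "yes" if outcome == "hit" else "no"))
            gt_rows.append({
                "participant_id": pid, "trial_index": trial,
                "motivation": mot, "template": bool(template_flags[trial]),
                "outcome": outcome, "reg_rho": reg_rho, "test_rho": test_rho,
                # per-trial phasic amplitude: condition mean + trial jitter
                **{f"scr_amp_{ph}_uS": max(
                    config.scr_amp_by_phase_outcome[ph][outcome]
                    + rng.normal(0.0, config.scr_amp_trial_sd_uS), 0.0)
                   for ph in PHASES},
            })
        fa = rng.random(config.n_foils) < config.false_alarm_rate
        for j in range(config.n_foils):
            man_rows.append((pid, config.n_trials + j, f"foil{j:03d}", None,
                             False, "yes" if fa[j] else "no"))

    fixations = pd.DataFrame(fix_rows, columns=[
        "participant_id", "session", "trial_index", "phase", "fix_index",
        "x_px", "y_px", "onset_ms", "duration_ms"])
    manifest = pd.DataFrame(man_rows, columns=[
        "participant_id", "trial_index", "image_id", "motivation", "studied",
        "test_response"])
    return SyntheticDataset(config, fixations, manifest,
                            pd.DataFrame(gt_rows), pids)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path,
                  scr_participants: int | None = 0,
                  screen_offset: tuple[float, float] = (448.0, 156.0)) -> None:
    """Write the dataset in the pipeline's input formats.

    Fixation coordinates are written in the screen frame (stimulus frame
    plus ``screen_offset``, matching a centered 1024 x 768 stimulus on a
    1920 x 1080 screen), which is what the reader expects.
    ``scr_participants`` limits how many participants get trace CSVs
    written (they are large; ``None`` writes all, 0 writes none).  The
    ground truth goes to ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = dataset.fixations.copy()
    fx["x_px"] = fx["x_px"] + screen_offset[0]
    fx["y_px"] = fx["y_px"] + screen_offset[1]
    fx.to_csv(outdir / "fixations.csv", index=False)
    dataset.manifest.to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(dataset.ground_truth.to_dict(orient="records"), fh, indent=1)
    pids = dataset.participant_ids
    if scr_participants is not None:
        pids = pids[:scr_participants]
    for pid in pids:
        for phase in PHASES:
            t, cond, events = dataset.scr_trace(pid, phase)
            pd.DataFrame({"time_s": t, "conductance_uS": cond}).to_csv(
                outdir / f"scr_{pid}_{phase}_trace.csv", index=False,
                float_format="%.5f")
            events.to_csv(outdir / f"scr_{pid}_{phase}_events.csv", index=False)
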