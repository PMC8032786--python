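"""Synthetic-study generator: determinism, structure, ground-truth effects."""
import numpy as np
import pandas as pd
import pytest

from gazesim.config import GeneratorConfig, StudyConfig
from gazesim.scanpath import GridSpec, build_substitution_matrix, similarity
from gazesim.synth import (ParticipantState, draw_fixation_durations,
                           generate_dataset, generate_encoding_scanpath,
                           generate_followup_scanpath, generate_outcomes)


CFG = GeneratorConfig()


def encode_xy(xy, durations, study=StudyConfig()):
    from gazesim.scanpath import Scanpath, encode_sequence
    sp = Scanpath("p", 0, "encoding", xy[:, 0], xy[:, 1], durations)
    return encode_sequence(sp, GridSpec.from_config(study),
                           study.temporal_bin_ms)


class TestScanpathGeneration:
    def test_expected_fixation_count(self):
        rng = np.random.default_rng(0)
        counts = [len(draw_fixation_durations(CFG, rng)) for _ in range(1000)]
        # 3000 ms viewing / 250 ms mean duration ~ 12 fixations
        assert np.mean(counts) == pytest.approx(12, abs=1.0)

    def test_durations_fill_viewing_time(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = draw_fixation_durations(CFG, rng)
            assert d.sum() <= CFG.viewing_ms + 1e-9
            assert d.sum() >= CFG.viewing_ms - CFG.fixation_duration_min_ms

    def test_zero_jitter_template_trial_replays_template(self):
        cfg = GeneratorConfig(template_jitter_sd_px=1e-9)
        rng = np.random.default_rng(2)
        state = ParticipantState("p", np.tile([[512.0, 384.0]],
                                              (cfg.template_length, 1)))
        xy, dur = generate_encoding_scanpath(cfg, state, True, rng)
        assert np.allclose(xy, [512.0, 384.0], atol=1e-6)

    def test_small_central_bias_concentrates_centrally(self):
        cfg = GeneratorConfig(central_bias_sd_px=1.0)
        rng = np.random.default_rng(3)
        state = ParticipantState("p", np.tile([[512.0, 384.0]], (24, 1)))
        xy, dur = generate_encoding_scanpath(cfg, state, False, rng)
        seq = encode_xy(xy, dur)
        central = {5 * 12 + 5, 5 * 12 + 6, 4 * 12 + 5, 4 * 12 + 6,
                   3 * 12 + 5, 3 * 12 + 6}
        assert set(seq.tolist()) <= central


class TestReinstatement:
    @pytest.fixture(scope="class")
    def sub(self):
        grid = GridSpec(12, 8, 1024, 768)
        return grid, build_substitution_matrix(grid, 4.0)

    def sim_of_pair(self, rho, seed, sub):
        grid, mat = sub
        cfg = GeneratorConfig()
        rng = np.random.default_rng(seed)
        state = ParticipantState("p", np.random.default_rng(99).uniform(
            [200, 150], [800, 600], (24, 2)))
        enc_xy, enc_dur = generate_encoding_scanpath(cfg, state, False, rng)
        reg_xy, reg_dur = generate_followup_scanpath(enc_xy, rho, cfg, rng)
        return similarity(encode_xy(enc_xy, enc_dur),
                          encode_xy(reg_xy, reg_dur), mat, 4.0)

    def test_full_reinstatement_zero_jitter_scores_one(self):
        cfg = GeneratorConfig(template_jitter_sd_px=1e-9)
        rng = np.random.default_rng(4)
        state = ParticipantState("p", np.random.default_rng(98).uniform(
            [200, 150], [800, 600], (24, 2)))
        enc_xy, enc_dur = generate_encoding_scanpath(cfg, state, False, rng)
        reg_xy, _ = generate_followup_scanpath(enc_xy, 1.0, cfg, rng)
        idx = np.minimum(np.arange(len(reg_xy)), len(enc_xy) - 1)
        assert np.allclose(reg_xy, enc_xy[idx], atol=1e-5)

    def test_similarity_monotone_in_rho(self, sub):
        lo = np.mean([self.sim_of_pair(0.2, s, sub) for s in range(150)])
        hi = np.mean([self.sim_of_pair(0.8, s, sub) for s in range(150)])
        assert hi > lo + 0.02


class TestOutcomes:
    def test_base_rates_recovered_without_interference(self):
        cfg = GeneratorConfig(interference_beta=0.0)
        rng = np.random.default_rng(5)
        mots = np.repeat(["remember", "control", "forget"], 2000)
        flags = rng.random(6000) < 0.4
        outcomes = generate_outcomes(mots, flags, cfg, rng)
        for m in ("remember", "control", "forget"):
            rate = (outcomes[mots == m] == "hit").mean()
            base = cfg.base_hit_rates[m]
            se = np.sqrt(base * (1 - base) / 2000)
            assert abs(rate - base) < 3 * se

    def test_large_beta_makes_template_trials_misses(self):
        cfg = GeneratorConfig(interference_beta=10.0)
        rng = np.random.default_rng(6)
        mots = np.array(["control"] * 4000)
        flags = np.array([True] * 2000 + [False] * 2000)
        outcomes = generate_outcomes(mots, flags, cfg, rng)
        assert (outcomes[:2000] == "miss").mean() > 0.99
        assert (outcomes[2000:] == "miss").mean() < 0.5

    def test_degenerate_all_hits_leaves_empty_miss_cells(self):
        cfg = GeneratorConfig(n_participants=2, seed=1, interference_beta=0.0,
                              base_hit_rates={"remember": 1.0, "control": 1.0,
                                              "forget": 1.0})
        ds = generate_dataset(cfg)
        assert (ds.ground_truth["outcome"] == "hit").all()


class TestDataset:
    def test_same_seed_identical_distinct_seeds_differ(self):
        a = generate_dataset(GeneratorConfig(n_participants=2, seed=5))
        b = generate_dataset(GeneratorConfig(n_participants=2, seed=5))
        c = generate_dataset(GeneratorConfig(n_participants=2, seed=6))
        pd.testing.assert_frame_equal(a.fixations, b.fixations)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        assert not a.fixations["x_px"].equals(c.fixations["x_px"])

    def test_bookkeeping_counts(self, small_dataset):
        cfg = small_dataset.config
        groups = small_dataset.fixations.groupby(
            ["participant_id", "trial_index", "phase"])
        assert len(groups) == cfg.n_participants * cfg.n_trials * 3
        per_p = small_dataset.manifest.groupby("participant_id").size()
        assert (per_p == cfg.n_trials + cfg.n_foils).all()
        mots = small_dataset.manifest[small_dataset.manifest.studied]
        counts = mots.groupby(["participant_id", "motivation"]).size()
        assert (counts == cfg.n_trials // 3).all()

    def test_scr_trace_deterministic_and_annotated(self, small_dataset):
        t1, c1, e1 = small_dataset.scr_trace("p000", "encoding")
        t2, c2, e2 = small_dataset.scr_trace("p000", "encoding")
        np.testing.assert_array_equal(c1, c2)
        pd.testing.assert_frame_equal(e1, e2)
        assert len(e1) == small_dataset.config.n_trials

    def test_zero_amplitude_everywhere_triggers_nonresponder(self):
        from gazesim.pipeline import analyze_scr, scr_features_from_dataset
        from gazesim.exclusion import code_recognition
        cfg = GeneratorConfig(
            n_participants=1, seed=2, scr_noise_sd_uS=0.0,
            scr_amp_trial_sd_uS=1e-12,
            scr_amp_by_phase_outcome={ph: {"hit": 0.0, "miss": 0.0}
                                      for ph in ("encoding", "regulation",
                                                 "test")})
        ds = generate_dataset(cfg)
        feats = scr_features_from_dataset(ds, StudyConfig(),
                                          phases=("encoding",))
        res = analyze_scr(feats, code_recognition(ds.manifest), StudyConfig())
        assert not res["features"]["retained"].any()
        assert (res["exclusions"]["rule_id"] == "scr_nonresponder").any()
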