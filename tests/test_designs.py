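"""The four similarity designs and their reduction to cell means."""
import numpy as np
import pandas as pd
import pytest

from gazesim.config import StudyConfig
from gazesim.designs import (cell_means, encode_fixation_table,
                             encoding_regulation_similarity,
                             encoding_test_similarity,
                             global_cross_similarity,
                             participants_with_empty_cells)
from gazesim.scanpath import GridSpec, build_substitution_matrix, similarity


def trials_frame(rows):
    df = pd.DataFrame(rows, columns=["participant_id", "trial_index",
                                     "motivation", "outcome"])
    df["studied"] = True
    return df


def encoded_from(paths):
    """paths: {(pid, trial, phase): list of bin symbols}."""
    return {k: np.asarray(v, dtype=np.int64) for k, v in paths.items()}


CFG = StudyConfig()


class TestPairedDesigns:
    def test_exact_replay_scores_one(self):
        enc = encoded_from({
            ("p0", 0, "encoding"): [3, 3, 7],
            ("p0", 0, "test"): [3, 3, 7],
        })
        trials = trials_frame([("p0", 0, "remember", "hit")])
        scores = encoding_test_similarity(enc, trials, CFG)
        assert scores["score"].iloc[0] == 1.0

    def test_foils_and_missing_phases_skipped(self):
        enc = encoded_from({
            ("p0", 0, "encoding"): [1], ("p0", 0, "test"): [1],
            ("p0", 1, "encoding"): [2], ("p0", 1, "test"): [2],
            ("p0", 2, "encoding"): [3],  # no test record
        })
        trials = trials_frame([("p0", 0, "remember", "hit"),
                               ("p0", 1, "control", "miss"),
                               ("p0", 2, "forget", "hit")])
        foil = pd.DataFrame([{"participant_id": "p0", "trial_index": 9,
                              "motivation": None, "outcome": pd.NA,
                              "studied": False}])
        scores = encoding_test_similarity(
            enc, pd.concat([trials, foil], ignore_index=True), CFG)
        assert len(scores) == 2

    def test_opposite_corner_regulation_scores_zero(self):
        enc = encoded_from({
            ("p0", 0, "encoding"): [0, 0, 0],
            ("p0", 0, "regulation"): [95, 95, 95],
        })
        trials = trials_frame([("p0", 0, "forget", "miss")])
        scores = encoding_regulation_similarity(enc, trials, CFG)
        assert scores["score"].iloc[0] == 0.0


class TestGlobalSimilarity:
    def test_two_identical_hits_score_one(self):
        enc = encoded_from({
            ("p0", 0, "encoding"): [5, 5, 9],
            ("p0", 1, "encoding"): [5, 5, 9],
        })
        trials = trials_frame([("p0", 0, "remember", "hit"),
                               ("p0", 1, "forget", "hit")])
        g = global_cross_similarity(enc, trials, CFG, "encoding", "encoding",
                                    "global_enc_enc")
        assert g["score"].tolist() == [1.0, 1.0]

    def test_micro_example_matches_hand_computation(self):
        """Three misses on a 3x2 grid: g_i is the mean of its two pair scores."""
        cfg = StudyConfig(grid_nx=3, grid_ny=2, stim_width_px=300,
                          stim_height_px=200)
        grid = GridSpec(3, 2, 300, 200)
        sub = build_substitution_matrix(grid, cfg.substitution_threshold)
        seqs = {0: [0, 1, 2], 1: [0, 0, 5], 2: [3, 4, 4]}
        enc = encoded_from({("p0", t, "encoding"): s for t, s in seqs.items()})
        trials = trials_frame([("p0", 0, "remember", "miss"),
                               ("p0", 1, "control", "miss"),
                               ("p0", 2, "forget", "miss")])
        g = global_cross_similarity(enc, trials, cfg, "encoding", "encoding",
                                    "global_enc_enc")
        pair = {(i, j): similarity(np.array(seqs[i]), np.array(seqs[j]), sub,
                                   cfg.substitution_threshold)
                for i in seqs for j in seqs if i != j}
        for t in seqs:
            others = [pair[(t, j)] for j in seqs if j != t]
            expected = np.mean(others)
            got = g[g["trial_index"] == t]["score"].iloc[0]
            assert got == pytest.approx(expected)

    def test_outcome_class_below_two_trials_has_no_scores(self):
        enc = encoded_from({("p0", t, "encoding"): [t] for t in range(3)})
        trials = trials_frame([("p0", 0, "remember", "hit"),
                               ("p0", 1, "control", "hit"),
                               ("p0", 2, "forget", "miss")])
        g = global_cross_similarity(enc, trials, CFG, "encoding", "encoding")
        assert set(g["outcome"]) == {"hit"}

    def test_permutation_invariance(self, small_dataset, study_config):
        fx = small_dataset.fixations
        fx = fx[fx["participant_id"] == "p000"]
        trials = small_dataset.manifest.merge(
            small_dataset.ground_truth[["participant_id", "trial_index",
                                        "outcome"]],
            on=["participant_id", "trial_index"], how="left")
        trials = trials[trials["participant_id"] == "p000"]
        enc = encode_fixation_table(fx, study_config)
        g1 = global_cross_similarity(enc, trials, study_config,
                                     "encoding", "encoding")
        shuffled = trials.sample(frac=1.0, random_state=3)
        g2 = global_cross_similarity(enc, shuffled, study_config,
                                     "encoding", "encoding")
        m1 = g1.set_index("trial_index")["score"].sort_index()
        m2 = g2.set_index("trial_index")["score"].sort_index()
        pd.testing.assert_series_equal(m1, m2)

    def test_removing_trial_touches_only_same_outcome_scores(self):
        rng = np.random.default_rng(8)
        enc = encoded_from({("p0", t, "encoding"):
                            rng.integers(0, 96, 10) for t in range(8)})
        trials = trials_frame(
            [("p0", t, "remember", "hit" if t < 4 else "miss")
             for t in range(8)])
        g_full = global_cross_similarity(enc, trials, CFG,
                                         "encoding", "encoding")
        g_drop = global_cross_similarity(enc, trials[trials.trial_index != 0],
                                         CFG, "encoding", "encoding")
        full = g_full.set_index("trial_index")["score"]
        drop = g_drop.set_index("trial_index")["score"]
        for t in range(4, 8):  # miss trials unaffected by dropping hit 0
            assert drop[t] == pytest.approx(full[t])


class TestCellMeans:
    def test_unweighted_mean_per_cell(self):
        scores = pd.DataFrame({
            "participant_id": "p0", "trial_index": [0, 1],
            "motivation": "remember", "outcome": "hit",
            "measure": "enc_test", "score": [0.2, 0.4]})
        cells = cell_means(scores)
        cell = cells[(cells.motivation == "remember") &
                     (cells.outcome == "hit")]
        assert cell["mean_score"].iloc[0] == pytest.approx(0.3)
        assert cell["n_trials"].iloc[0] == 2

    def test_empty_cell_flagged_not_imputed(self):
        scores = pd.DataFrame({
            "participant_id": "p0", "trial_index": [0],
            "motivation": "remember", "outcome": "hit",
            "measure": "enc_test", "score": [0.5]})
        cells = cell_means(scores)
        assert len(cells) == 6
        empty = cells[(cells.motivation == "forget") &
                      (cells.outcome == "miss")]
        assert empty["n_trials"].iloc[0] == 0
        assert pd.isna(empty["mean_score"].iloc[0])
        assert participants_with_empty_cells(cells) == ["p0"]

    def test_constant_scores_give_constant_cells(self):
        rows = [("p0", t, m, o, "enc_test", 0.42)
                for t, (m, o) in enumerate(
                    (m, o) for m in ("remember", "control", "forget")
                    for o in ("hit", "miss"))]
        scores = pd.DataFrame(rows, columns=["participant_id", "trial_index",
                                             "motivation", "outcome",
                                             "measure", "score"])
        cells = cell_means(scores)
        assert np.allclose(cells["mean_score"], 0.42)
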