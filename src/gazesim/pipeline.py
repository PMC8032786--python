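"""End-to-end orchestration: exclusions, similarity designs, SCR, stats.

``run_pipeline`` drives the file-based route (fixation table + manifest
[+ SCR trace/event files] in, results bundle out); ``analyze_gaze`` /
``analyze_scr`` are the in-memory work-horses the drivers, tests and the
synthetic route share.  Every exclusion is accumulated into one report
with its rule identifier; any stage failure aborts with the stage name
and the underlying cause.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import designs, exclusion, scr, stats
from .config import StudyConfig
from .io import read_fixation_table, read_scr_events, read_scr_trace, \
    read_trial_manifest

__all__ = [
    "PipelineError",
    "analyze_gaze",
    "analyze_scr",
    "scr_features_from_dataset",
    "run_pipeline",
    "run_from_dataset",
    "write_bundle",
]

log = logging.getLogger("gazesim")

PHASES = ("encoding", "regulation", "test")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _measure_stats(cells: pd.DataFrame, config: StudyConfig) -> dict:
    """Per-measure empty-cell exclusion, ANOVA and post hocs."""
    excluded = designs.participants_with_empty_cells(cells)
    complete = cells[~cells["participant_id"].isin(excluded)]
    out = {"excluded_participants": excluded, "n_participants":
           complete["participant_id"].nunique(), "anova": None, "posthoc": None}
    if out["n_participants"] >= 3:
        out["anova"] = stats.rm_anova_3x2(
            complete, alpha=config.alpha, gg_always=config.gg_always)
        out["posthoc"] = stats.posthoc_motivation(
            complete, dv="mean_score", prior_scale=config.bf_prior_scale)
    return out


@_stage("gaze_analysis")
def analyze_gaze(fixations: pd.DataFrame, manifest: pd.DataFrame,
                 config: StudyConfig,
                 measures: tuple = designs.MEASURES) -> dict:
    """Exclusion cascade, recognition coding and the similarity designs.

    ``measures`` can be narrowed (e.g. to ``("global_enc_enc",)``) to skip
    the alignments the caller does not need.
    """
    reports = []

    retained, rep_trials, reg_fraction = exclusion.exclude_trials_few_fixations(
        fixations, config.min_fixations)
    reports.append(rep_trials)
    dropped_pids, rep_pids = exclusion.exclude_participants(
        reg_fraction, config.max_removed_fraction)
    reports.append(rep_pids)
    retained = retained[~retained["participant_id"].isin(dropped_pids)]

    coded = exclusion.code_recognition(manifest)
    missing = coded[coded["outcome"].isna()]
    if len(missing):
        reports.append(pd.DataFrame({
            "participant_id": missing["participant_id"],
            "rule_id": exclusion.RULE_MISSING_RESPONSE,
            "detail": [f"trial {t}: no test response"
                       for t in missing["trial_index"]],
            "stage": "recognition_coding"}))
    hit_rates, fa_rates = exclusion.recognition_rates(coded)
    recog = {"hit_rates": hit_rates, "fa_rates": fa_rates,
             "anova": None, "posthoc": None}
    if hit_rates["participant_id"].nunique() >= 3:
        recog["anova"] = stats.rm_anova_oneway(
            hit_rates, dv="hit_rate", within="motivation",
            alpha=config.alpha, gg_always=config.gg_always)
        recog["posthoc"] = stats.posthoc_motivation(
            hit_rates, dv="hit_rate", prior_scale=config.bf_prior_scale)

    trials = coded[coded["studied"]].copy()
    trials = trials[~trials["participant_id"].isin(dropped_pids)]
    encoded = designs.encode_fixation_table(retained, config)

    score_frames = []
    if "enc_test" in measures:
        score_frames.append(designs.encoding_test_similarity(
            encoded, trials, config))
    if "enc_reg" in measures:
        score_frames.append(designs.encoding_regulation_similarity(
            encoded, trials, config))
    if "global_enc_reg" in measures:
        score_frames.append(designs.global_cross_similarity(
            encoded, trials, config, "encoding", "regulation",
            "global_enc_reg"))
    if "global_enc_enc" in measures:
        score_frames.append(designs.global_cross_similarity(
            encoded, trials, config, "encoding", "encoding",
            "global_enc_enc"))
    scores = pd.concat(score_frames, ignore_index=True) if score_frames \
        else pd.DataFrame()

    cells = designs.cell_means(scores) if len(scores) else pd.DataFrame()
    measure_results = {}
    for m in measures:
        cells_m = cells[cells["measure"] == m] if len(cells) else pd.DataFrame(
            columns=["participant_id", "n_trials"])
        res = _measure_stats(cells_m, config) if len(cells_m) else {
            "excluded_participants": [], "n_participants": 0,
            "anova": None, "posthoc": None}
        if res["excluded_participants"]:
            reports.append(pd.DataFrame({
                "participant_id": res["excluded_participants"],
                "rule_id": exclusion.RULE_EMPTY_CELL,
                "detail": f"empty motivation x outcome cell for {m}",
                "stage": f"measure_{m}"}))
        measure_results[m] = res

    return {
        "exclusions": pd.concat(reports, ignore_index=True) if reports
        else pd.DataFrame(columns=["participant_id", "rule_id", "detail",
                                   "stage"]),
        "recognition": recog,
        "coded_manifest": coded,
        "scores": scores,
        "cells": cells,
        "measures": measure_results,
    }


@_stage("scr_analysis")
def analyze_scr(features: pd.DataFrame, coded_manifest: pd.DataFrame,
                config: StudyConfig) -> dict:
    """Reduce raw SCR features and run the per-phase 3 x 2 ANOVAs."""
    feats, report = scr.reduce_features(features, config)
    labels = coded_manifest[["participant_id", "trial_index", "motivation",
                             "outcome"]]
    merged = feats[feats["retained"]].merge(
        labels, on=["participant_id", "trial_index"], how="inner")
    merged = merged[merged["outcome"].isin(["hit", "miss"])]
    phase_results = {}
    all_cells = []
    for phase in sorted(merged["phase"].unique()):
        sub = merged[merged["phase"] == phase]
        scores = sub.rename(columns={"amplitude_uS": "score"}).assign(
            measure=f"scr_{phase}")
        cells = designs.cell_means(
            scores[["participant_id", "measure", "motivation", "outcome",
                    "score"]])
        all_cells.append(cells)
        res = _measure_stats(cells, config)
        if res["excluded_participants"]:
            report = pd.concat([report, pd.DataFrame({
                "participant_id": res["excluded_participants"],
                "rule_id": exclusion.RULE_EMPTY_CELL,
                "detail": f"empty motivation x outcome cell for scr_{phase}",
                "stage": f"measure_scr_{phase}"})], ignore_index=True)
        phase_results[phase] = res
    return {
        "features": feats,
        "exclusions": report,
        "cells": pd.concat(all_cells, ignore_index=True) if all_cells
        else pd.DataFrame(),
        "phases": phase_results,
    }


def scr_features_from_dataset(dataset, config: StudyConfig,
                              phases: tuple = PHASES) -> pd.DataFrame:
    """Extract raw SCR features from a synthetic dataset, trace by trace."""
    frames = []
    for pid in dataset.participant_ids:
        for phase in phases:
            t, cond, events = dataset.scr_trace(pid, phase)
            frames.append(scr.extract_features(t, cond, events, pid, phase,
                                               config))
    return pd.concat(frames, ignore_index=True)


@_stage("scr_io")
def _read_scr_features(scr_dir: str | Path, config: StudyConfig) -> pd.DataFrame:
    scr_dir = Path(scr_dir)
    frames = []
    for trace_path in sorted(scr_dir.glob("scr_*_trace.csv")):
        stem = trace_path.name[len("scr_"):-len("_trace.csv")]
        pid, phase = stem.rsplit("_", 1)
        events_path = scr_dir / f"scr_{stem}_events.csv"
        if not events_path.exists():
            log.warning("no events file for %s; trace skipped", trace_path)
            continue
        t, cond = read_scr_trace(trace_path)
        events = read_scr_events(events_path)
        frames.append(scr.extract_features(t, cond, events, pid, phase,
                                           config))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: StudyConfig, fixation_path, manifest_path,
                 scr_dir=None, outdir=None) -> dict:
    """File-based end-to-end run; returns (and optionally writes) the bundle."""
    try:
        fixations = read_fixation_table(fixation_path, config)
        manifest = read_trial_manifest(manifest_path)
    except Exception as exc:
        raise PipelineError(f"stage 'input' failed: {exc}") from exc
    results = analyze_gaze(fixations, manifest, config)
    if scr_dir is not None:
        features = _read_scr_features(scr_dir, config)
        if len(features):
            results["scr"] = analyze_scr(features, results["coded_manifest"],
                                         config)
            results["exclusions"] = pd.concat(
                [results["exclusions"], results["scr"]["exclusions"]],
                ignore_index=True)
        else:
            log.warning("no SCR traces found in %s; SCR stage skipped",
                        scr_dir)
            results["scr"] = None
    else:
        results["scr"] = None
    if outdir is not None:
        write_bundle(results, outdir)
    return results


def run_from_dataset(dataset, config: StudyConfig, with_scr: bool = True,
                     measures: tuple = designs.MEASURES,
                     outdir=None) -> dict:
    """In-memory end-to-end run on a synthetic dataset."""
    results = analyze_gaze(dataset.fixations, dataset.manifest, config,
                           measures=measures)
    if with_scr:
        features = scr_features_from_dataset(dataset, config)
        results["scr"] = analyze_scr(features, results["coded_manifest"],
                                     config)
        results["exclusions"] = pd.concat(
            [results["exclusions"], results["scr"]["exclusions"]],
            ignore_index=True)
    else:
        results["scr"] = None
    if outdir is not None:
        write_bundle(results, outdir)
    return results


def _stats_payload(results: dict) -> dict:
    def df_records(df):
        return None if df is None else json.loads(df.to_json(orient="records"))

    payload = {"recognition": {
        "anova": df_records(results["recognition"]["anova"]),
        "posthoc": df_records(results["recognition"]["posthoc"]),
    }, "similarity": {}, "scr": {}, "anova_bayes_factors": "not computed"}
    for m, res in results["measures"].items():
        payload["similarity"][m] = {
            "n_participants": int(res["n_participants"]),
            "excluded_participants": list(res["excluded_participants"]),
            "anova": df_records(res["anova"]),
            "posthoc": df_records(res["posthoc"]),
        }
    if results.get("scr"):
        for phase, res in results["scr"]["phases"].items():
            payload["scr"][phase] = {
                "n_participants": int(res["n_participants"]),
                "excluded_participants": list(res["excluded_participants"]),
                "anova": df_records(res["anova"]),
                "posthoc": df_records(res["posthoc"]),
            }
    return payload


def _format_anova_block(title: str, res: dict) -> list[str]:
    lines = [title, "-" * len(title),
             f"n = {res['n_participants']}"]
    if res["anova"] is not None:
        for r in res["anova"].itertuples():
            eps = f", eps = {r.epsilon:.2f}" if r.gg_applied else ""
            lines.append(
                f"  {r.effect}: F({r.df1},{r.df2}) = {r.F:.2f}, "
                f"p = {r.p:.4f}{eps}, f = {r.cohen_f:.2f}")
    if res["posthoc"] is not None:
        for r in res["posthoc"].itertuples():
            lines.append(
                f"  post hoc {r.contrast}: t({r.df}) = {r.t:.2f}, "
                f"p_bonf = {r.p_bonferroni:.4f}, d = {r.cohen_d:.2f}, "
                f"BF10 = {r.bf10:.1f}")
    lines.append("")
    return lines


def write_bundle(results: dict, outdir: str | Path) -> None:
    """Write the results bundle: tables, exclusion report and stats report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(results["scores"]):
        results["scores"].to_csv(outdir / "similarity_scores.csv", index=False)
    if len(results["cells"]):
        results["cells"].to_csv(outdir / "similarity_cells.csv", index=False)
    results["exclusions"].to_csv(outdir / "exclusions.csv", index=False)
    results["recognition"]["hit_rates"].to_csv(outdir / "hit_rates.csv",
                                               index=False)
    if results.get("scr"):
        results["scr"]["features"].to_csv(outdir / "scr_features.csv",
                                          index=False)
        if len(results["scr"]["cells"]):
            results["scr"]["cells"].to_csv(outdir / "scr_cells.csv",
                                           index=False)
    payload = _stats_payload(results)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    lines = []
    lines += _format_anova_block(
        "Recognition (hit rate by motivation)",
        {"n_participants":
         results["recognition"]["hit_rates"]["participant_id"].nunique(),
         "anova": results["recognition"]["anova"],
         "posthoc": results["recognition"]["posthoc"]})
    for m, res in results["measures"].items():
        lines += _format_anova_block(f"Gaze similarity: {m}", res)
    if results.get("scr"):
        for phase, res in results["scr"]["phases"].items():
            lines += _format_anova_block(f"SCR ({phase} phase)", res)
    lines.append("ANOVA-level Bayes factors: not computed")
    (outdir / "stats.txt").write_text("\n".join(lines) + "\n")
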