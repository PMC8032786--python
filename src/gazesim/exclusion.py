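"""Recognition coding and the gaze-data exclusion cascade.

Recognition responses are back-sorted into hits ("yes" to a studied item),
misses ("no" to a studied item), false alarms and correct rejections.
Gaze records are then filtered in two stages: phase-records with fewer
than ``min_fixations`` fixations are dropped, and participants losing more
than ``max_removed_fraction`` of their regulation-phase records are
excluded entirely.  A further, per-measure exclusion removes participants
with an empty motivation x outcome cell; that one lives with the cell
tables (see :func:`gazesim.designs.participants_with_empty_cells`).

Every removal is logged as a row (participant, rule_id, detail, stage) so
the exclusion report can account for each decision exactly once.
"""
from __future__ import annotations

import pandas as pd

__all__ = [
    "code_recognition",
    "recognition_rates",
    "exclude_trials_few_fixations",
    "exclude_participants",
    "RULE_FEW_FIXATIONS",
    "RULE_REMOVED_FRACTION",
    "RULE_EMPTY_CELL",
    "RULE_MISSING_RESPONSE",
]

RULE_FEW_FIXATIONS = "few_fixations"
RULE_REMOVED_FRACTION = "regulation_removed_fraction"
RULE_EMPTY_CELL = "empty_cell"
RULE_MISSING_RESPONSE = "missing_response"


def code_recognition(manifest: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``outcome`` column: hit/miss for studied items, FA/CR for foils.

    Trials with a missing test response get outcome NaN and a log entry;
    they contribute to no rate or cell.
    """
    out = manifest.copy()
    studied = out["studied"].astype(bool)
    yes = out["test_response"].eq("yes")
    no = out["test_response"].eq("no")
    out["outcome"] = pd.NA
    out.loc[studied & yes, "outcome"] = "hit"
    out.loc[studied & no, "outcome"] = "miss"
    out.loc[~studied & yes, "outcome"] = "false_alarm"
    out.loc[~studied & no, "outcome"] = "correct_rejection"
    return out


def recognition_rates(coded: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant hit rate by motivation, and overall false-alarm rate.

    Foils carry no motivation cue, so the false-alarm rate is a single
    per-participant number.
    """
    studied = coded[coded["studied"].astype(bool) & coded["outcome"].notna()]
    hit = (
        studied.assign(is_hit=studied["outcome"].eq("hit"))
        .groupby(["participant_id", "motivation"], observed=True)["is_hit"]
        .agg(hit_rate="mean", n_trials="size")
        .reset_index()
    )
    foils = coded[~coded["studied"].astype(bool) & coded["outcome"].notna()]
    fa = (
        foils.assign(is_fa=foils["outcome"].eq("false_alarm"))
        .groupby("participant_id")["is_fa"]
        .agg(fa_rate="mean", n_foils="size")
        .reset_index()
    )
    return hit, fa


def exclude_trials_few_fixations(
    fixations: pd.DataFrame, min_fixations: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop phase-records with fewer than ``min_fixations`` fixations.

    The rule is strict ("less than"), so a record with exactly
    ``min_fixations`` fixations is kept.  Each phase-record of a trial is
    judged independently: a trial dropped in the regulation phase can still
    contribute its encoding record elsewhere.

    Returns ``(retained fixations, exclusion report, regulation removal
    fractions per participant)``.
    """
    counts = (
        fixations.groupby(["participant_id", "trial_index", "phase"], observed=True)
        .size()
        .rename("n_fix")
        .reset_index()
    )
    bad = counts[counts["n_fix"] < min_fixations]
    report = pd.DataFrame(
        {
            "participant_id": bad["participant_id"],
            "rule_id": RULE_FEW_FIXATIONS,
            "detail": [
                f"trial {t} phase {p}: {n} fixations < {min_fixations}"
                for t, p, n in zip(bad["trial_index"], bad["phase"], bad["n_fix"])
            ],
            "stage": "gaze_trial_filter",
        }
    )
    keys = ["participant_id", "trial_index", "phase"]
    merged = fixations.merge(bad[keys].assign(_drop=True), on=keys, how="left")
    retained = merged[merged["_drop"].isna()].drop(columns="_drop")

    reg = counts[counts["phase"] == "regulation"]
    reg_removed = (
        reg.assign(removed=reg["n_fix"] < min_fixations)
        .groupby("participant_id")["removed"]
        .mean()
        .rename("removed_fraction")
        .reset_index()
    )
    return retained.reset_index(drop=True), report, reg_removed


def exclude_participants(
    removal_fractions: pd.DataFrame, max_removed_fraction: float = 0.20
) -> tuple[list, pd.DataFrame]:
    """Exclude participants losing more than the allowed regulation fraction.

    Strict "more than": a participant at exactly the cap is kept.
    """
    over = removal_fractions[
        removal_fractions["removed_fraction"] > max_removed_fraction
    ]
    report = pd.DataFrame(
        {
            "participant_id": over["participant_id"],
            "rule_id": RULE_REMOVED_FRACTION,
            "detail": [
                f"regulation removal fraction {f:.3f} > {max_removed_fraction}"
                for f in over["removed_fraction"]
            ],
            "stage": "participant_filter",
        }
    )
    return over["participant_id"].tolist(), report
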