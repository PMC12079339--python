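"""Rating-stratified forced-choice classification.

Tests whether a pairwise signature discriminates two conditions at
matched subjective-intensity levels: if classification survives (or
strengthens) when the two conditions are compared only within trials
given the same 1-5 rating, the discrimination cannot be explained by
rating intensity alone.

Per subject and rating level, the subject's same-rating trial images
are averaged per condition (an approximation of per-level parametric
beta images), and the averaged pair enters the forced-choice test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import ForcedChoiceReport, LinearPatternModel, _score_forced_choice, pattern_response
from .stack import MaskedImageStack

__all__ = ["RatingStratifiedReport", "stratified_forced_choice"]

RATING_LEVELS = (1, 2, 3, 4, 5)


@dataclass
class RatingStratifiedReport:
    """Per-rating-level forced-choice reports and usable-trial counts.

    ``reports`` maps level -> ForcedChoiceReport (absent if no subject
    contributed the level in both conditions); ``trial_counts`` is a
    level x condition table of trial counts; ``flagged_levels`` lists
    levels with fewer than 2 usable subjects (kept, not dropped).
    """

    reports: dict[int, ForcedChoiceReport] = field(default_factory=dict)
    trial_counts: pd.DataFrame | None = None
    flagged_levels: list[int] = field(default_factory=list)
    missing_levels: list[int] = field(default_factory=list)
    n_usable_subjects: dict[int, int] = field(default_factory=dict)


def stratified_forced_choice(
    model: LinearPatternModel,
    trial_stack: MaskedImageStack,
    cond_a: str,
    cond_b: str,
    levels: tuple[int, ...] = RATING_LEVELS,
) -> RatingStratifiedReport:
    """Forced choice between two conditions at matched rating levels.

    For each level r, each subject's rating-r trials are averaged per
    condition; subjects lacking level r in either condition are
    excluded at that level. The fixed ``model`` is applied single-pass
    (no retraining). Levels empty in all subjects are reported missing.
    """
    meta = trial_stack.obs_meta
    if "rating" not in meta.columns or meta["rating"].isna().all():
        raise ValueError("trial stack carries no rating metadata")
    for cond in (cond_a, cond_b):
        if cond not in set(meta["condition"]):
            raise ValueError(f"condition {cond!r} absent from trial stack")
    counts = (
        meta[meta["condition"].isin([cond_a, cond_b])]
        .groupby(["rating", "condition"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(levels), fill_value=0)
    )
    counts.index.name = "rating"
    report = RatingStratifiedReport(trial_counts=counts)
    for level in levels:
        ra, rb = [], []
        for subject in trial_stack.subjects:
            sub = meta[(meta["subject"] == subject) & (meta["rating"] == level)]
            rows_a = sub.index[sub["condition"] == cond_a]
            rows_b = sub.index[sub["condition"] == cond_b]
            if len(rows_a) == 0 or len(rows_b) == 0:
                continue
            xa = trial_stack.data[rows_a].mean(axis=0)
            xb = trial_stack.data[rows_b].mean(axis=0)
            ra.append(float(xa @ model.weights))
            rb.append(float(xb @ model.weights))
        n_usable = len(ra)
        report.n_usable_subjects[level] = n_usable
        if n_usable == 0:
            report.missing_levels.append(level)
            continue
        if n_usable < 2:
            report.flagged_levels.append(level)
        report.reports[level] = _score_forced_choice(np.array(ra), np.array(rb))
    return report


def accuracy_profile(report: RatingStratifiedReport) -> pd.DataFrame:
    """Long-format per-level accuracy table for TSV export."""
    rows = []
    for level, fc in sorted(report.reports.items()):
        rows.append(
            {
                "rating": level,
                "accuracy_pct": fc.accuracy_mean,
                "accuracy_sd_pct": fc.accuracy_sd,
                "p_value": fc.p_value,
                "auc": fc.auc,
                "cohens_d": fc.cohens_d,
                "n_subjects": fc.n_subjects,
                "flagged": level in report.flagged_levels,
            }
        )
    return pd.DataFrame(rows)
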