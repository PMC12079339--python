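"""Multilevel two-path mediation with bootstrap inference.

Tests whether a mediator signal M accounts for the relation between a
predictor X and trial-level ratings Y. Paths are estimated per subject
by OLS (a: X->M; b and c': Y ~ X + M; c: Y ~ X), so the identity
c = c' + a*b holds exactly within every subject. Group inference is a
summary-statistics multilevel approach: bootstrap resampling of
subjects, taking the mean of per-subject coefficients per sample, with
percentile confidence intervals and two-tailed bootstrap p-values. The
mediation is declared significant when a, b and the indirect effect
a*b are all significant; partial vs complete mediation is labelled by
whether the direct path c' remains significant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import LinearPatternModel, pattern_response
from .stack import MaskedImageStack

__all__ = ["MediationResult", "mediate", "signature_mediation"]

PATHS = ("a", "b", "ab", "c", "cprime")


@dataclass
class MediationResult:
    """Per-subject path coefficients and bootstrap group inference."""

    per_subject: pd.DataFrame
    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    n_boot: int
    n_subjects: int
    dropped_subjects: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def significant(self) -> dict[str, bool]:
        return {k: self.p[k] < self.alpha for k in PATHS}

    @property
    def mediation_significant(self) -> bool:
        s = self.significant
        return s["a"] and s["b"] and s["ab"]

    @property
    def mediation_type(self) -> str:
        if not self.mediation_significant:
            return "none"
        return "partial" if self.significant["cprime"] else "complete"


def _subject_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """OLS paths for one subject; raises on collinear x, m."""
    X1 = np.column_stack([np.ones_like(x), x])
    a = np.linalg.lstsq(X1, m, rcond=None)[0][1]
    c = np.linalg.lstsq(X1, y, rcond=None)[0][1]
    X2 = np.column_stack([np.ones_like(x), x, m])
    if np.linalg.matrix_rank(X2) < 3:
        raise ValueError("x and m are collinear within a subject; c' unidentifiable")
    coef = np.linalg.lstsq(X2, y, rcond=None)[0]
    cprime, b = coef[1], coef[2]
    return {"a": a, "b": b, "ab": a * b, "c": c, "cprime": cprime}


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    standardize: bool = True,
    alpha: float = 0.05,
) -> MediationResult:
    """Two-path mediation on per-trial scalars grouped by subject.

    ``x``/``m`` are z-scored within subject by default (for numerical
    conditioning; disable with ``standardize=False`` to keep raw
    units); ``y`` (ratings) is always used raw. Subjects with
    zero-variance x or m are dropped with a warning; more than 30%
    dropped is an error. Requires >= 10 subjects and >= 10 trials per
    subject.
    """
    x, m, y = (np.asarray(v, dtype=float).ravel() for v in (x, m, y))
    subjects = np.asarray(subjects)
    if not (len(x) == len(m) == len(y) == len(subjects)):
        raise ValueError("x, m, y and subjects must have equal length")
    uniq = pd.unique(subjects)
    if len(uniq) < 10:
        raise ValueError(f"need at least 10 subjects, got {len(uniq)}")
    rows, dropped = [], []
    for s in uniq:
        idx = subjects == s
        if idx.sum() < 10:
            raise ValueError(f"subject {s!r} has fewer than 10 trials")
        xs, ms, ys = x[idx], m[idx], y[idx]
        if xs.std() == 0 or ms.std() == 0:
            dropped.append(str(s))
            continue
        if standardize:
            xs = (xs - xs.mean()) / xs.std(ddof=1)
            ms = (ms - ms.mean()) / ms.std(ddof=1)
        paths = _subject_paths(xs, ms, ys)
        paths["subject"] = s
        rows.append(paths)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} subject(s) with zero-variance x or m: {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(dropped) > 0.3 * len(uniq):
        raise ValueError(
            f"{len(dropped)}/{len(uniq)} subjects dropped for zero variance"
        )
    per_subject = pd.DataFrame(rows).set_index("subject")
    coefs = per_subject[list(PATHS)].to_numpy()
    n_subj = coefs.shape[0]
    rng = np.random.default_rng(seed)
    samples = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boot_means = coefs[samples].mean(axis=1)  # n_boot x paths
    means = {k: float(coefs[:, i].mean()) for i, k in enumerate(PATHS)}
    ci_low, ci_high, pvals = {}, {}, {}
    for i, k in enumerate(PATHS):
        dist = boot_means[:, i]
        lo, hi = np.percentile(dist, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        ci_low[k], ci_high[k] = float(lo), float(hi)
        # two-tailed percentile bootstrap p with small-sample correction
        p_le = (np.sum(dist <= 0) + 1) / (n_boot + 1)
        p_ge = (np.sum(dist >= 0) + 1) / (n_boot + 1)
        pvals[k] = float(min(1.0, 2.0 * min(p_le, p_ge)))
    return MediationResult(
        per_subject=per_subject,
        means=means,
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        n_boot=n_boot,
        n_subjects=n_subj,
        dropped_subjects=dropped,
        alpha=alpha,
    )


def signature_mediation(
    stack: MaskedImageStack,
    sig_x: LinearPatternModel,
    sig_m: LinearPatternModel,
    n_boot: int = 2000,
    seed: int = 0,
    standardize: bool = True,
) -> dict[str, MediationResult]:
    """Mediation between two signatures' responses and trial ratings.

    X and M are the dot products of the two signatures with each
    single-trial image, Y the trial's rating. Both directions are
    returned: ``"x_to_m"`` (sig_x predictor, sig_m mediator) and
    ``"m_to_x"`` (roles swapped), as both orderings are of interest.
    """
    meta = stack.obs_meta
    if "rating" not in meta.columns or meta["rating"].isna().any():
        raise ValueError("every trial needs a rating for mediation")
    x = pattern_response(sig_x, stack)
    m = pattern_response(sig_m, stack)
    y = meta["rating"].to_numpy(dtype=float)
    subjects = meta["subject"].to_numpy()
    return {
        "x_to_m": mediate(x, m, y, subjects, n_boot=n_boot, seed=seed,
                          standardize=standardize),
        "m_to_x": mediate(m, x, y, subjects, n_boot=n_boot, seed=seed,
                          standardize=standardize),
    }
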