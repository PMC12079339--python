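"""Core-system identification: bootstrap weight maps, Haufe encoding
maps, and their conjunction.

The "core system" of a signature is the set of voxels that both (1)
carry reliably non-zero classifier weights under subject-level
bootstrap resampling (the backward model) and (2) show a reliable
forward-model relationship with the signature's response across
subjects after the Haufe transformation into structure coefficients.
Both maps are thresholded with Benjamini-Hochberg FDR; the core map is
their intersection. The core map exists for interpretation and display
only - classification always uses the full, unthresholded weights.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, ttest_1samp
from sklearn.svm import SVC

from .decoder import LinearPatternModel, pattern_response
from .stack import MaskedImageStack
from .stats import bh_fdr

__all__ = [
    "BootstrapMap",
    "EncodingMap",
    "CoreSystemMap",
    "bootstrap_weights",
    "haufe_encode",
    "conjunction_core",
]


@dataclass
class BootstrapMap:
    """Voxelwise bootstrap summary of signature weights."""

    mean: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    q: float
    n_boot: int
    n_redraws: int = 0


@dataclass
class EncodingMap:
    """Per-subject Haufe structure coefficients and group inference."""

    coefficients: np.ndarray  # subjects x voxels
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    q: float
    excluded_subjects: list[str]


@dataclass
class CoreSystemMap:
    """Conjunction of the backward and forward significance masks."""

    mask: np.ndarray
    core_weights: np.ndarray  # full weights zeroed outside the mask


def bootstrap_weights(
    stack: MaskedImageStack,
    positive: list[str] | str,
    negative: list[str] | str,
    C: float = 1.0,
    n_boot: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> BootstrapMap:
    """Bootstrap the SVM weight map by resampling subjects.

    Subjects are drawn with replacement (all of a subject's images
    travel together - images within a subject are dependent), the SVM
    is retrained per sample, and each voxel's weight distribution is
    summarized as z = mean/SD with a normal-theory two-tailed p, then
    BH-FDR thresholded at ``q``. Samples in which one class is absent
    are redrawn (at most 50 consecutive times). The reference protocol
    uses 10 000 samples; 1000 is the desk-scale default.
    """
    positive = [positive] if isinstance(positive, str) else list(positive)
    negative = [negative] if isinstance(negative, str) else list(negative)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    subjects = np.asarray(stack.subjects)
    conds = stack.obs_meta["condition"].to_numpy()
    subj_col = stack.obs_meta["subject"].to_numpy()
    keep = np.isin(conds, positive + negative)
    y_all = np.where(np.isin(conds, positive), 1, -1)
    rows_by_subject = {
        s: np.flatnonzero(keep & (subj_col == s)) for s in subjects
    }
    rng = np.random.default_rng(seed)
    weights = np.empty((n_boot, stack.n_voxels))
    n_redraws = 0
    for b in range(n_boot):
        consecutive = 0
        while True:
            sample = rng.choice(subjects, size=len(subjects), replace=True)
            rows = np.concatenate([rows_by_subject[s] for s in sample])
            y = y_all[rows]
            if (y == 1).any() and (y == -1).any():
                break
            n_redraws += 1
            consecutive += 1
            if consecutive >= 50:
                raise RuntimeError(
                    "50 consecutive bootstrap samples lacked a class; "
                    "the design cannot be resampled"
                )
        svm = SVC(kernel="linear", C=C)
        svm.fit(stack.data[rows], y)
        weights[b] = svm.coef_[0]
    mean = weights.mean(axis=0)
    sd = weights.std(axis=0, ddof=1)
    z = np.zeros_like(mean)
    ok = sd > 0
    z[ok] = mean[ok] / sd[ok]
    p = np.ones_like(mean)
    p[ok] = 2.0 * norm.sf(np.abs(z[ok]))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    sig, _ = bh_fdr(p, q)
    return BootstrapMap(
        mean=mean, sd=sd, z=z, p=p, significant=sig, q=q,
        n_boot=n_boot, n_redraws=n_redraws,
    )


def haufe_encode(
    stack: MaskedImageStack,
    model: LinearPatternModel,
    q: float = 0.05,
    per_subject: bool = True,
) -> EncodingMap:
    """Haufe transformation of a backward model into structure
    coefficients, with group inference.

    For each subject the signature response r = w.x is computed over
    that subject's observations and the structure coefficient of voxel
    v is cov(x_v, r) across those observations (the forward model
    A ~ Sigma_x w). A one-sample t-test across subjects per voxel is
    BH-FDR thresholded at ``q``. Subjects with zero response variance
    are excluded with a warning.

    With ``per_subject=False`` a single group-level covariance map is
    computed over all observations pooled (no t-test; ``t``/``p`` are
    NaN and the significance mask is all-True).
    """
    if per_subject:
        coefs, excluded = [], []
        for subject in stack.subjects:
            sub = stack.select(subject=subject)
            if sub.n_obs < 2:
                raise ValueError(
                    f"subject {subject!r} has fewer than 2 observations"
                )
            r = pattern_response(model, sub)
            if r.std(ddof=1) == 0:
                excluded.append(str(subject))
                continue
            xc = sub.data - sub.data.mean(axis=0)
            rc = r - r.mean()
            coefs.append(xc.T @ rc / (sub.n_obs - 1))
        if excluded:
            warnings.warn(
                f"excluded {len(excluded)} subject(s) with zero response "
                f"variance: {excluded}",
                RuntimeWarning,
                stacklevel=2,
            )
        coefs = np.array(coefs)
        if coefs.shape[0] < 3:
            raise ValueError("need at least 3 usable subjects for the group t-test")
        t, p = ttest_1samp(coefs, 0.0, axis=0)
        p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
        sig, _ = bh_fdr(p, q)
        return EncodingMap(
            coefficients=coefs, t=t, p=p, significant=sig, q=q,
            excluded_subjects=excluded,
        )
    r = pattern_response(model, stack)
    xc = stack.data - stack.data.mean(axis=0)
    rc = r - r.mean()
    A = xc.T @ rc / (stack.n_obs - 1)
    nan = np.full(stack.n_voxels, np.nan)
    return EncodingMap(
        coefficients=A[None, :], t=nan, p=nan,
        significant=np.ones(stack.n_voxels, dtype=bool), q=q,
        excluded_subjects=[],
    )


def conjunction_core(
    bmap: BootstrapMap, emap: EncodingMap, model: LinearPatternModel
) -> CoreSystemMap:
    """Intersect the backward and forward significance masks.

    Weights outside the conjunction are zeroed for display; an empty
    intersection is a valid (empty) core map and only warns. The core
    map is never used for classification.
    """
    if bmap.significant.shape != emap.significant.shape:
        raise ValueError("bootstrap and encoding maps live in different voxel spaces")
    mask = bmap.significant & emap.significant
    if not mask.any():
        warnings.warn("empty core-system conjunction", RuntimeWarning, stacklevel=2)
    core = np.where(mask, model.weights, 0.0)
    return CoreSystemMap(mask=mask, core_weights=core)
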