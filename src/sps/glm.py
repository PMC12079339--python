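"""First-level GLM: design construction and OLS estimation.

Three design variants are supported, mirroring common practice for
task fMRI:

* ``condition`` - one HRF-convolved boxcar per condition;
* ``rating_parametric`` - condition boxcars plus mean-centered
  trial-rating modulators;
* ``single_trial`` - one regressor per trial (all trials estimated in a
  single simultaneous design), producing per-trial beta images.

Every design carries a 24-column motion-derived nuisance block (6
parameters, their squares, their temporal derivatives, and the squared
derivatives), a discrete-cosine high-pass basis with a 128 s cutoff,
and per-run intercepts. Estimation is ordinary least squares without
prewhitening - a deliberate simplification; serial-correlation
modelling would not change any downstream contract.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import MaskedImageStack

__all__ = [
    "hrf_double_gamma",
    "validate_events",
    "DesignMatrix",
    "build_design",
    "GLMResult",
    "fit_glm",
    "make_condition_contrasts",
]

#: default high-pass cutoff (seconds)
HIGHPASS_CUTOFF_S = 128.0


def hrf_double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function.

    The conventional parameterization: a gamma density with shape 6
    (response peaking ~5 s) minus a shape-16 undershoot gamma scaled by
    1/6. Normalized to unit peak. ``t`` is in seconds.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, peak_delay / dispersion, scale=dispersion) - gamma.pdf(
        t, undershoot_delay / dispersion, scale=dispersion
    ) / ratio
    peak = h.max()
    return h / peak if peak > 0 else h


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check a BIDS-flavoured event table (onset, duration, trial_type)."""
    for col in ("onset", "duration", "trial_type"):
        if col not in events.columns:
            raise ValueError(f"events missing column {col!r}")
    ev = events.sort_values("onset").reset_index(drop=True)
    if (ev["onset"] < 0).any():
        raise ValueError("onsets must be non-negative")
    if (ev["duration"] <= 0).any():
        raise ValueError("durations must be positive")
    return ev


@dataclass
class DesignMatrix:
    """Time x regressor matrix with named, role-tagged columns."""

    matrix: np.ndarray
    names: list[str]
    task_idx: np.ndarray
    nuisance_idx: np.ndarray
    highpass_idx: np.ndarray
    tr_s: float
    run_lengths: list[int] = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def task_names(self) -> list[str]:
        return [self.names[i] for i in self.task_idx]


def _convolved_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr_s: float,
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved boxcar sampled at scan acquisition times."""
    dt = tr_s / oversample
    n_fine = n_scans * oversample
    neural = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        if i0 >= n_fine:
            raise ValueError(f"event onset {onset:.1f}s beyond scan duration")
        neural[i0 : min(i1, n_fine)] += amp
    hrf = hrf_double_gamma(np.arange(0, 32.0, dt))
    signal = np.convolve(neural, hrf)[:n_fine]
    return signal[::oversample]


def _dct_highpass_basis(n_scans: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff_s``."""
    order = int(np.floor(2.0 * n_scans * tr_s / cutoff_s))
    t = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_scans))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.zeros((n_scans, 0))


def _nuisance_block(motion: np.ndarray) -> np.ndarray:
    """6 motion parameters -> 24 columns (m, m^2, dm, dm^2)."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {motion.shape}")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    return np.column_stack([motion, motion**2, deriv, deriv**2])


def _task_block(
    events: pd.DataFrame, n_scans: int, tr_s: float, model: str, rating_col: str
) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if model == "single_trial":
        for i, row in events.iterrows():
            cols.append(
                _convolved_regressor(
                    np.array([row["onset"]]), np.array([row["duration"]]),
                    np.array([1.0]), n_scans, tr_s,
                )
            )
            trial_id = row.get("trial", i + 1)
            names.append(f"trial_{int(trial_id):03d}_{row['trial_type']}")
    else:
        for cond in events["trial_type"].unique():
            sub = events[events["trial_type"] == cond]
            cols.append(
                _convolved_regressor(
                    sub["onset"].to_numpy(), sub["duration"].to_numpy(),
                    np.ones(len(sub)), n_scans, tr_s,
                )
            )
            names.append(str(cond))
        if model == "rating_parametric":
            for cond in events["trial_type"].unique():
                sub = events[events["trial_type"] == cond]
                if rating_col not in sub.columns or sub[rating_col].isna().all():
                    continue
                mod = sub[rating_col].to_numpy(dtype=float)
                mod = mod - mod.mean()  # mean-centered, not orthogonalized
                if np.allclose(mod, 0):
                    continue
                cols.append(
                    _convolved_regressor(
                        sub["onset"].to_numpy(), sub["duration"].to_numpy(),
                        mod, n_scans, tr_s,
                    )
                )
                names.append(f"{cond}_x_rating")
    return np.column_stack(cols), names


def build_design(
    events: pd.DataFrame,
    motion: pd.DataFrame | np.ndarray,
    n_scans: int | list[int],
    tr_s: float,
    model: str = "condition",
    hp_cutoff_s: float = HIGHPASS_CUTOFF_S,
    rating_col: str = "rating",
) -> DesignMatrix:
    """Build a first-level design matrix.

    Multiple runs are supported by passing a list in ``n_scans`` and a
    ``run`` column in ``events``; runs are concatenated with
    run-specific intercepts, nuisance blocks and high-pass bases, while
    task conditions share columns across runs.

    Raises if the task block is rank-deficient, naming the collinear
    columns.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if model not in ("condition", "rating_parametric", "single_trial"):
        raise ValueError(f"unknown model {model!r}")
    events = validate_events(events)
    motion_arr = np.asarray(motion, dtype=float)
    run_lengths = [int(n_scans)] if np.isscalar(n_scans) else [int(n) for n in n_scans]
    n_total = sum(run_lengths)
    if motion_arr.shape[0] != n_total:
        raise ValueError(
            f"motion table has {motion_arr.shape[0]} rows, expected {n_total} scans"
        )
    n_runs = len(run_lengths)
    if n_runs > 1 and "run" not in events.columns:
        raise ValueError("multi-run designs need a 'run' column in events")

    # Task block: per run, stacked vertically; conditions share columns.
    if model == "single_trial":
        # every trial gets its own column; runs just offset the rows
        all_names: list[str] = []
        blocks = []
        offset_rows = 0
        col_count = 0
        per_run = []
        for r, n_r in enumerate(run_lengths, start=1):
            ev_r = events[events["run"] == r] if n_runs > 1 else events
            blk, names = _task_block(ev_r, n_r, tr_s, model, rating_col)
            per_run.append(blk)
            all_names += names
            col_count += blk.shape[1]
        task = np.zeros((n_total, col_count))
        row0, col0 = 0, 0
        for blk, n_r in zip(per_run, run_lengths):
            task[row0 : row0 + n_r, col0 : col0 + blk.shape[1]] = blk
            row0 += n_r
            col0 += blk.shape[1]
        task_names = all_names
    else:
        run_blocks, task_names = [], []
        for r, n_r in enumerate(run_lengths, start=1):
            ev_r = events[events["run"] == r] if n_runs > 1 else events
            blk, names = _task_block(ev_r, n_r, tr_s, model, rating_col)
            run_blocks.append((blk, names))
        task_names = []
        for _, names in run_blocks:
            for n in names:
                if n not in task_names:
                    task_names.append(n)
        task = np.zeros((n_total, len(task_names)))
        row0 = 0
        for (blk, names), n_r in zip(run_blocks, run_lengths):
            for j, name in enumerate(names):
                task[row0 : row0 + n_r, task_names.index(name)] = blk[:, j]
            row0 += n_r

    rank = np.linalg.matrix_rank(task)
    if rank < task.shape[1]:
        # identify columns that add no rank, greedily
        collinear = []
        kept: list[int] = []
        for j in range(task.shape[1]):
            cand = task[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept):
                collinear.append(task_names[j])
            else:
                kept.append(j)
        raise ValueError(f"task design block is rank-deficient; collinear columns: {collinear}")

    # Nuisance + high-pass + intercepts, block-diagonal per run.
    nuis_cols, nuis_names = [], []
    hp_cols, hp_names = [], []
    row0 = 0
    nuis = np.zeros((n_total, 24 * n_runs))
    for r, n_r in enumerate(run_lengths, start=1):
        nuis[row0 : row0 + n_r, (r - 1) * 24 : r * 24] = _nuisance_block(
            motion_arr[row0 : row0 + n_r]
        )
        row0 += n_r
    nuis_names = [
        f"run{r}_{kind}{i+1}"
        for r in range(1, n_runs + 1)
        for kind in ("motion", "motion_sq", "motion_deriv", "motion_deriv_sq")
        for i in range(6)
    ]
    hp_blocks = [_dct_highpass_basis(n_r, tr_s, hp_cutoff_s) for n_r in run_lengths]
    n_hp = sum(b.shape[1] for b in hp_blocks)
    hp = np.zeros((n_total, n_hp))
    row0, col0 = 0, 0
    for b, n_r in zip(hp_blocks, run_lengths):
        hp[row0 : row0 + n_r, col0 : col0 + b.shape[1]] = b
        row0 += n_r
        col0 += b.shape[1]
    hp_names = [
        f"run{r}_dct{k+1}"
        for r, b in enumerate(hp_blocks, start=1)
        for k in range(b.shape[1])
    ]
    intercepts = np.zeros((n_total, n_runs))
    row0 = 0
    for r, n_r in enumerate(run_lengths):
        intercepts[row0 : row0 + n_r, r] = 1.0
        row0 += n_r
    icpt_names = [f"run{r}_intercept" for r in range(1, n_runs + 1)]

    matrix = np.column_stack([task, nuis, hp, intercepts])
    names = list(task_names) + nuis_names + hp_names + icpt_names
    n_task = task.shape[1]
    return DesignMatrix(
        matrix=matrix,
        names=names,
        task_idx=np.arange(n_task),
        nuisance_idx=np.arange(n_task, n_task + nuis.shape[1]),
        highpass_idx=np.arange(n_task + nuis.shape[1], n_task + nuis.shape[1] + hp.shape[1]),
        tr_s=tr_s,
        run_lengths=run_lengths,
    )


@dataclass
class GLMResult:
    """Task-column betas plus residual variance per voxel."""

    betas: MaskedImageStack
    sigma2: np.ndarray
    dof: int
    zero_voxels: np.ndarray


def fit_glm(
    series: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    subject: str = "sub-001",
    drop_initial: int = 0,
) -> GLMResult:
    """Voxelwise OLS fit of a 4-D series against a design matrix.

    ``drop_initial`` removes the first volumes of the series (and the
    matching design rows) before fitting, as is done to let image
    intensity stabilize. All-zero voxel time courses yield zero betas
    with a warning rather than failure.
    """
    import warnings

    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, t)")
    if series.shape[:3] != mask.shape:
        raise ValueError("series grid does not match mask")
    X = design.matrix
    Y = series[mask].T  # time x voxels
    if drop_initial:
        X = X[drop_initial:]
        Y = Y[drop_initial:]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"design has {X.shape[0]} rows but series has {Y.shape[0]} volumes"
        )
    zero_voxels = ~Y.any(axis=0)
    if zero_voxels.any():
        warnings.warn(
            f"{int(zero_voxels.sum())} all-zero voxel time courses; betas set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    pinv = np.linalg.pinv(X)
    B = pinv @ Y  # regressors x voxels
    resid = Y - X @ B
    dof = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / max(dof, 1)
    B[:, zero_voxels] = 0.0
    task_betas = B[design.task_idx]
    if affine is None:
        affine = np.eye(4)
    meta = pd.DataFrame(
        {"subject": subject, "condition": design.task_names}
    )
    stack = MaskedImageStack(data=task_betas, mask=mask, affine=affine, obs_meta=meta)
    return GLMResult(betas=stack, sigma2=sigma2, dof=dof, zero_voxels=zero_voxels)


def make_condition_contrasts(
    betas: MaskedImageStack, scheme: dict[str, tuple[str, str]]
) -> MaskedImageStack:
    """Per-subject condition-difference images.

    ``scheme`` maps contrast name -> (minuend condition, subtrahend
    condition); one contrast image is produced per subject per pair.
    """
    present = set(betas.obs_meta["condition"])
    needed = {c for pair in scheme.values() for c in pair}
    missing = sorted(needed - present)
    if missing:
        raise ValueError(f"conditions absent from beta stack: {missing}")
    rows, meta = [], []
    for subject in betas.subjects:
        sub = betas.select(subject=subject)
        by_cond = {
            c: sub.select(condition=c).data.mean(axis=0) for c in needed
        }
        for name, (minuend, subtrahend) in scheme.items():
            rows.append(by_cond[minuend] - by_cond[subtrahend])
            meta.append({"subject": subject, "condition": name})
    return MaskedImageStack(
        data=np.array(rows),
        mask=betas.mask,
        affine=betas.affine,
        obs_meta=pd.DataFrame(meta),
    )
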