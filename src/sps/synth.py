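"""Synthetic multi-subject beta-map generator with known ground truth.

The generator emulates the data structure that the signature-development
pipeline assumes: a cohort of subjects, each contributing one
control-subtracted contrast image per condition (exclusion, inclusion,
separation, company) plus per-trial images with 1-5 intensity ratings
for the two "pain" tasks. Condition patterns are unit-norm voxel
vectors built from a shared component and condition-specific components
with an analytically known pairwise cosine, so that recovery and
calibration tests can be scored against the truth.

Defaults mirror the discovery-cohort structure: 65 subjects x 4
conditions (260 contrast images), 60 + 60 trials per subject, a 16^3
grid with an ellipsoidal in-brain mask of ~1400 voxels, and a latent
Gaussian rating link whose round-and-clip discretization reproduces the
heavy rating-1 skew seen in trial-count tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import MaskedImageStack, Parcellation

__all__ = [
    "SyntheticTruth",
    "ellipsoid_mask",
    "generate_contrast_stack",
    "generate_trial_stack",
    "generate_parcellation",
    "generate_timeseries",
]

CONDITIONS = ("exclusion", "inclusion", "separation", "company")
PAIN_CONDITIONS = ("exclusion", "separation")


def ellipsoid_mask(
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    semi_axes: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Ellipsoidal in-brain mask centred on the grid.

    Default semi-axes scale with the grid (0.47, 0.44, 0.41 of each
    extent); on the default 16^3 grid this gives ~1400 in-mask voxels.
    """
    if semi_axes is None:
        semi_axes = (0.47 * grid_shape[0], 0.44 * grid_shape[1], 0.41 * grid_shape[2])
    idx = np.indices(grid_shape).astype(float)
    centre = (np.array(grid_shape) - 1) / 2.0
    d2 = sum(
        ((idx[k] - centre[k]) / semi_axes[k]) ** 2 for k in range(3)
    )
    mask = d2 <= 1.0
    if not mask.any():
        raise ValueError("ellipsoid mask is empty; enlarge the semi-axes")
    return mask


@dataclass
class SyntheticTruth:
    """Ground-truth configuration for the synthetic cohort.

    ``rho_shared`` mixes a shared component g into every condition
    pattern: pattern_c = rho*g + sqrt(1-rho^2)*u_c with g and the u_c
    orthonormal, so cos(pattern_a, pattern_b) = rho^2 exactly.
    Amplitudes are positive (mean ``pattern_amplitude_mean``) for the
    pain conditions and zero for their positive counterparts.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    mask: np.ndarray | None = None
    rho_shared: float = 0.5
    pattern_amplitude_mean: float = 1.0
    pattern_amplitude_sd: float = 0.25
    noise_sd: float = 0.2
    subject_count: int = 65
    trial_counts: dict[str, int] = field(
        default_factory=lambda: {"exclusion": 60, "separation": 60}
    )
    trial_amplitude_sd: float = 0.5
    rating_intercept: float = 0.0
    rating_slope: float = 1.5
    rating_noise_sd: float = 0.8
    mediator_overlap: float = 0.5
    subject_pattern_jitter: float = 0.0
    seed: int = 0

    # populated in __post_init__
    condition_patterns: dict[str, np.ndarray] = field(init=False, repr=False)
    shared_component: np.ndarray = field(init=False, repr=False)
    specific_components: dict[str, np.ndarray] = field(init=False, repr=False)
    mediator_pattern: np.ndarray = field(init=False, repr=False)
    affine: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_shared <= 1.0:
            raise ValueError("rho_shared must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.subject_count < 2:
            raise ValueError("need at least 2 subjects")
        if self.mask is None:
            self.mask = ellipsoid_mask(self.grid_shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid_shape):
            raise ValueError("mask shape does not match grid_shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        self.affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm iso, RAS+

        v = int(self.mask.sum())
        n_dirs = len(CONDITIONS) + 2  # shared + specifics + mediator residual
        if v < n_dirs:
            raise ValueError("mask too small to embed the condition patterns")
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0)))
        raw = rng.standard_normal((v, n_dirs))
        basis, _ = np.linalg.qr(raw)  # orthonormal columns
        self.shared_component = basis[:, 0]
        self.specific_components = {
            c: basis[:, 1 + i] for i, c in enumerate(CONDITIONS)
        }
        rho = self.rho_shared
        self.condition_patterns = {
            c: rho * self.shared_component
            + np.sqrt(1.0 - rho**2) * self.specific_components[c]
            for c in CONDITIONS
        }
        ov = self.mediator_overlap
        self.mediator_pattern = (
            ov * self.condition_patterns["exclusion"]
            + np.sqrt(1.0 - ov**2) * basis[:, n_dirs - 1]
        )

    # -- helpers -------------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def condition_amplitude_mean(self, condition: str) -> float:
        return self.pattern_amplitude_mean if condition in PAIN_CONDITIONS else 0.0

    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:03d}" for i in range(self.subject_count)]

    def _subject_rngs(self, namespace: int) -> list[np.random.Generator]:
        root = np.random.SeedSequence((self.seed, namespace))
        return [np.random.default_rng(s) for s in root.spawn(self.subject_count)]

    def subject_pattern(
        self, condition: str, rng: np.random.Generator
    ) -> np.ndarray:
        """Condition pattern, optionally jittered per subject (unit norm)."""
        p = self.condition_patterns[condition]
        if self.subject_pattern_jitter > 0:
            noise = rng.standard_normal(self.n_voxels)
            p = p + self.subject_pattern_jitter * noise / np.linalg.norm(noise)
            p = p / np.linalg.norm(p)
        return p

    def discriminative_direction(self, positive: str) -> np.ndarray:
        """pattern_positive minus the mean of the other amplitude-weighted
        patterns - the direction an ideal one-vs-all decoder recovers."""
        others = [c for c in CONDITIONS if c != positive]
        mean_other = np.mean(
            [self.condition_amplitude_mean(c) * self.condition_patterns[c] for c in others],
            axis=0,
        )
        return (
            self.condition_amplitude_mean(positive) * self.condition_patterns[positive]
            - mean_other
        )


def generate_contrast_stack(truth: SyntheticTruth) -> MaskedImageStack:
    """One control-subtracted contrast image per subject x condition.

    Each image is amplitude_s * pattern_c + N(0, noise_sd) per voxel,
    where amplitude_s ~ N(mean, sd) clipped at zero for the pain
    conditions and 0 for the others. Deterministic under a fixed seed.
    """
    rows, meta = [], []
    for sid, rng in zip(truth.subject_ids(), truth._subject_rngs(1)):
        amp_base = truth.pattern_amplitude_mean + truth.pattern_amplitude_sd * rng.standard_normal()
        amp_base = max(amp_base, 0.0)
        for cond in CONDITIONS:
            amp = amp_base if cond in PAIN_CONDITIONS else 0.0
            pattern = truth.subject_pattern(cond, rng)
            img = amp * pattern + truth.noise_sd * rng.standard_normal(truth.n_voxels)
            rows.append(img)
            meta.append({"subject": sid, "condition": cond})
    return MaskedImageStack(
        data=np.array(rows),
        mask=truth.mask,
        affine=truth.affine,
        obs_meta=pd.DataFrame(meta),
    )


def _rating_from_expression(
    expression: float, truth: SyntheticTruth, rng: np.random.Generator
) -> int:
    latent = (
        truth.rating_intercept
        + truth.rating_slope * expression
        + truth.rating_noise_sd * rng.standard_normal()
    )
    return int(np.clip(np.round(latent), 1, 5))


def generate_trial_stack(
    truth: SyntheticTruth, coupling: str = "amplitude"
) -> MaskedImageStack:
    """Per-trial images with trial-level amplitude jitter and ratings.

    ``coupling`` selects what the rating tracks:

    * ``"amplitude"`` (default) - the condition pattern's expression
      scales with the per-trial amplitude and the rating tracks that
      same amplitude, so the between-condition difference signal grows
      with the rated intensity;
    * ``"pattern"`` - the condition-specific component has constant
      expression while the rating tracks a shared-intensity component,
      so the between-condition difference is rating-independent.
    """
    if coupling not in ("amplitude", "pattern"):
        raise ValueError("coupling must be 'amplitude' or 'pattern'")
    if not truth.trial_counts:
        raise ValueError("trial_counts is empty")
    for cond, n in truth.trial_counts.items():
        if n <= 0:
            raise ValueError(f"zero trials configured for condition {cond!r}")
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
    rows, meta = [], []
    for sid, rng in zip(truth.subject_ids(), truth._subject_rngs(2)):
        amp_base = truth.pattern_amplitude_mean + truth.pattern_amplitude_sd * rng.standard_normal()
        amp_base = max(amp_base, 0.0)
        for cond, n_trials in truth.trial_counts.items():
            pattern = truth.subject_pattern(cond, rng)
            for t in range(n_trials):
                amp_t = max(
                    amp_base + truth.trial_amplitude_sd * rng.standard_normal(), 0.0
                )
                if coupling == "amplitude":
                    signal = amp_t * pattern
                else:
                    signal = (
                        amp_t * truth.shared_component
                        + truth.pattern_amplitude_mean
                        * np.sqrt(1.0 - truth.rho_shared**2)
                        * truth.specific_components[cond]
                    )
                img = signal + truth.noise_sd * rng.standard_normal(truth.n_voxels)
                rating = _rating_from_expression(amp_t, truth, rng)
                rows.append(img)
                meta.append(
                    {"subject": sid, "condition": cond, "trial": t + 1, "rating": rating}
                )
    return MaskedImageStack(
        data=np.array(rows),
        mask=truth.mask,
        affine=truth.affine,
        obs_meta=pd.DataFrame(meta),
    )


def generate_parcellation(
    truth: SyntheticTruth, n_rois: int = 24, n_networks: int = 7
) -> Parcellation:
    """Contiguous-block labelling of in-mask voxels into ROIs and networks.

    In-mask voxels (C-order) are split into ``n_rois`` nearly equal
    contiguous blocks; ROIs map many-to-one onto ``n_networks``
    networks. Every in-mask voxel is labelled exactly once.
    """
    if not (n_rois >= n_networks >= 1):
        raise ValueError("need n_rois >= n_networks >= 1")
    v = truth.n_voxels
    if n_rois > v:
        raise ValueError(f"n_rois={n_rois} exceeds the {v} in-mask voxels")
    labels = np.empty(v, dtype=np.int64)
    for r, chunk in enumerate(np.array_split(np.arange(v), n_rois), start=1):
        labels[chunk] = r
    roi_to_network = 1 + (np.arange(n_rois) * n_networks) // n_rois
    return Parcellation(roi_labels=labels, roi_to_network=roi_to_network)


def generate_timeseries(
    truth: SyntheticTruth,
    events: pd.DataFrame,
    tr_s: float = 2.0,
    n_scans: int | None = None,
    drift_amplitude: float = 0.0,
    motion_sd: float = 0.02,
    subject_index: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raw 4-D series for one subject: HRF-convolved condition signals
    plus optional slow drift and Gaussian noise, with a 6-column motion
    table.

    The convolved regressor for each condition in ``events`` multiplies
    that condition's amplitude and voxel pattern. ``noise_sd`` and
    amplitudes come from ``truth``; ``drift_amplitude`` adds a slow
    cosine drift. Deterministic under a fixed seed.
    """
    from .glm import _convolved_regressor, validate_events

    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    events = validate_events(events)
    end = float((events["onset"] + events["duration"]).max())
    if n_scans is None:
        n_scans = int(np.ceil((end + 16.0) / tr_s))
    if end > n_scans * tr_s:
        raise ValueError("events extend beyond the scan duration")
    rng = np.random.default_rng(
        np.random.SeedSequence((truth.seed, 3, subject_index))
    )
    v = truth.n_voxels
    signal = np.zeros((n_scans, v))
    for cond in events["trial_type"].unique():
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r} in events")
        sub = events[events["trial_type"] == cond]
        reg = _convolved_regressor(
            sub["onset"].to_numpy(), sub["duration"].to_numpy(),
            np.ones(len(sub)), n_scans, tr_s,
        )
        amp = truth.condition_amplitude_mean(cond)
        signal += np.outer(reg, amp * truth.condition_patterns[cond])
    if drift_amplitude:
        t = np.arange(n_scans) * tr_s
        drift = drift_amplitude * np.cos(2 * np.pi * t / (n_scans * tr_s))
        signal += drift[:, None]
    signal += truth.noise_sd * rng.standard_normal((n_scans, v))
    series = np.zeros(truth.grid_shape + (n_scans,))
    series[truth.mask] = signal.T
    motion = pd.DataFrame(
        np.cumsum(motion_sd * rng.standard_normal((n_scans, 6)), axis=0),
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    return series, motion
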