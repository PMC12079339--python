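"""In-memory containers: masked image stacks and parcellations.

A :class:`MaskedImageStack` is the package's canonical container for
beta / contrast / single-trial images: an ``observations x voxels``
matrix restricted to an in-brain mask, tied to the 3-D grid it came
from (mask + affine) and to per-observation metadata (subject,
condition, trial, rating).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MaskedImageStack", "Parcellation"]


@dataclass
class MaskedImageStack:
    """Observations x in-mask-voxels matrix tied to a 3-D voxel grid.

    Parameters
    ----------
    data : ndarray, shape (n_obs, n_voxels)
        One flattened masked image per row, in beta units.
    mask : ndarray of bool, shape ``grid_shape``
        In-brain mask; ``mask.sum()`` must equal ``data.shape[1]``.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (RAS+) affine.
    obs_meta : DataFrame
        One row per observation. Required columns: ``subject``,
        ``condition``. Optional: ``trial``, ``rating`` (integers 1-5,
        NaN where absent).
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    obs_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.obs_meta = self.obs_meta.reset_index(drop=True)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.mask.shape}")
        n_mask = int(self.mask.sum())
        if n_mask == 0:
            raise ValueError("mask is empty: no in-brain voxels")
        if self.data.shape[1] != n_mask:
            raise ValueError(
                f"data has {self.data.shape[1]} voxel columns but the mask "
                f"contains {n_mask} voxels"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            raise ValueError(
                f"non-finite values in data at (obs, voxel) {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(self.obs_meta) != self.data.shape[0]:
            raise ValueError(
                f"obs_meta has {len(self.obs_meta)} rows but data has "
                f"{self.data.shape[0]} observations"
            )
        for col in ("subject", "condition"):
            if col not in self.obs_meta.columns:
                raise ValueError(f"obs_meta missing required column {col!r}")
        if "rating" in self.obs_meta.columns:
            r = self.obs_meta["rating"].dropna()
            if len(r) and not (
                np.allclose(r, np.round(r)) and r.min() >= 1 and r.max() <= 5
            ):
                raise ValueError("ratings must be integers in [1, 5]")

    # -- basic geometry ------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def voxel_index(self) -> np.ndarray:
        """Flat (C-order) grid indices of the in-mask voxels."""
        return np.flatnonzero(self.mask.ravel())

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject identifiers, in order of first appearance."""
        return self.obs_meta["subject"].unique()

    def same_space(self, other: "MaskedImageStack", atol: float = 1e-4) -> bool:
        return (
            self.mask.shape == other.mask.shape
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.affine, other.affine, atol=atol)
        )

    # -- views ---------------------------------------------------------
    def select(self, **criteria) -> "MaskedImageStack":
        """Subset observations by metadata equality (scalar or list).

        ``stack.select(condition="exclusion", subject=["sub-001"])``
        """
        keep = np.ones(self.n_obs, dtype=bool)
        for col, value in criteria.items():
            values = value if isinstance(value, (list, tuple, set, np.ndarray)) else [value]
            keep &= self.obs_meta[col].isin(list(values)).to_numpy()
        return MaskedImageStack(
            data=self.data[keep],
            mask=self.mask,
            affine=self.affine,
            obs_meta=self.obs_meta.loc[keep],
        )

    def unmask(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a voxel vector back into a 3-D volume."""
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (self.n_voxels,):
            raise ValueError(
                f"vector has shape {vector.shape}, expected ({self.n_voxels},)"
            )
        vol = np.full(self.grid_shape, fill, dtype=np.float64)
        vol[self.mask] = vector
        return vol


@dataclass
class Parcellation:
    """Integer labelling of in-mask voxels into ROIs grouped into networks.

    ``roi_labels`` assigns every in-mask voxel a ROI id in ``1..R``;
    ``roi_to_network`` maps each ROI (index ``roi-1``) onto a network id
    in ``1..N`` (many-to-one).
    """

    roi_labels: np.ndarray
    roi_to_network: np.ndarray
    roi_names: list[str] = field(default_factory=list)
    network_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.roi_labels = np.asarray(self.roi_labels, dtype=np.int64)
        self.roi_to_network = np.asarray(self.roi_to_network, dtype=np.int64)
        if self.roi_labels.ndim != 1:
            raise ValueError("roi_labels must be a flat per-voxel vector")
        if self.roi_labels.min() < 1 or self.roi_labels.max() > self.n_rois:
            raise ValueError("every voxel must carry a ROI label in 1..R")
        if self.roi_to_network.min() < 1:
            raise ValueError("network ids start at 1")
        if not self.roi_names:
            self.roi_names = [f"ROI_{r:02d}" for r in range(1, self.n_rois + 1)]
        if not self.network_names:
            self.network_names = [
                f"NET_{n}" for n in range(1, int(self.roi_to_network.max()) + 1)
            ]

    @property
    def n_rois(self) -> int:
        return len(self.roi_to_network)

    @property
    def n_networks(self) -> int:
        return int(self.roi_to_network.max())

    @property
    def network_labels(self) -> np.ndarray:
        """Per-voxel network id derived from the ROI labelling."""
        return self.roi_to_network[self.roi_labels - 1]

    def labels(self, level: str) -> tuple[np.ndarray, list[str]]:
        """Per-voxel labels and names at ``level`` ('roi' or 'network')."""
        if level == "roi":
            return self.roi_labels, list(self.roi_names)
        if level == "network":
            return self.network_labels, list(self.network_names)
        raise ValueError("level must be 'roi' or 'network'")

    def to_table(self) -> pd.DataFrame:
        """Label table (columns: label, roi_name, network_name)."""
        return pd.DataFrame(
            {
                "label": np.arange(1, self.n_rois + 1),
                "roi_name": self.roi_names,
                "network_name": [
                    self.network_names[n - 1] for n in self.roi_to_network
                ],
            }
        )
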