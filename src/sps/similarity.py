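"""Atlas-based spatial decomposition of pattern maps.

Quantifies where a signature's (core) weight map lives relative to a
parcellation: per-ROI / per-network cosine similarity of the rectified
map with the region indicator, ribbon values normalized to the global
maximum, and the relative contribution of competing maps to each region
as the percentage of region voxels on which each map has the largest
rectified value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import Parcellation

__all__ = ["SimilarityDecomposition", "regional_cosine", "contribution_shares"]


@dataclass
class SimilarityDecomposition:
    """Tabular result of a regional similarity analysis.

    ``cosines`` has one row per region with one column per map
    (NaN for empty regions); ``ribbons`` are the same values divided by
    the global maximum; ``shares`` (percent, per region summing to 100)
    is present only for contribution analyses.
    """

    level: str
    cosines: pd.DataFrame | None = None
    ribbons: pd.DataFrame | None = None
    shares: pd.DataFrame | None = None


def _as_map_dict(maps) -> dict[str, np.ndarray]:
    if isinstance(maps, dict):
        return {k: np.asarray(v, dtype=float).ravel() for k, v in maps.items()}
    return {"map": np.asarray(maps, dtype=float).ravel()}


def regional_cosine(
    maps, parc: Parcellation, level: str = "roi"
) -> SimilarityDecomposition:
    """Per-region cosine similarity of rectified maps with region
    indicators.

    The input map is rectified to absolute values before comparison
    (all voxels maintained as positive for interpretation). For region
    r with m voxels the cosine is
    ``sum(|x|_r) / (||x_r|| * sqrt(m))`` - the cosine between the map
    restricted to r and the all-ones indicator of r. A region where the
    map is identically zero scores 0; a region with no voxels is
    reported as missing (NaN). Ribbons divide by the maximum cosine
    across all regions and maps.
    """
    map_dict = _as_map_dict(maps)
    labels, names = parc.labels(level)
    for name, vec in map_dict.items():
        if vec.shape[0] != labels.shape[0]:
            raise ValueError(
                f"map {name!r} has {vec.shape[0]} voxels, parcellation has {labels.shape[0]}"
            )
    records = {}
    for name, vec in map_dict.items():
        rect = np.abs(vec)
        cos = []
        for r in range(1, len(names) + 1):
            in_r = labels == r
            m = int(in_r.sum())
            if m == 0:
                cos.append(np.nan)
                continue
            norm_r = np.linalg.norm(rect[in_r])
            cos.append(0.0 if norm_r == 0 else float(rect[in_r].sum() / (norm_r * np.sqrt(m))))
        records[name] = cos
    cosines = pd.DataFrame(records, index=pd.Index(names, name=level))
    global_max = np.nanmax(cosines.to_numpy()) if np.isfinite(cosines.to_numpy()).any() else np.nan
    ribbons = cosines / global_max if global_max and global_max > 0 else cosines * np.nan
    return SimilarityDecomposition(level=level, cosines=cosines, ribbons=ribbons)


def contribution_shares(
    maps: dict[str, np.ndarray], parc: Parcellation, level: str = "roi"
) -> SimilarityDecomposition:
    """Relative contribution of competing maps to each region.

    Every voxel of a region is assigned to the map with the highest
    rectified value there; a map's share of the region is the percent
    of voxels it wins. Ties split their credit equally, so shares sum
    to 100% per region. Regions on which all maps are identically zero
    are reported as missing rather than 0 (every voxel there is an
    uninformative all-way tie).
    """
    map_dict = _as_map_dict(maps)
    if len(map_dict) < 2:
        raise ValueError("contribution shares need at least 2 maps")
    labels, names = parc.labels(level)
    rect = np.vstack([np.abs(v) for v in map_dict.values()])  # maps x voxels
    if rect.shape[1] != labels.shape[0]:
        raise ValueError("maps and parcellation have different voxel counts")
    top = rect.max(axis=0)
    winners = rect == top  # maps x voxels boolean; ties share
    credit = winners / winners.sum(axis=0)  # columns sum to 1
    map_names = list(map_dict)
    records = {}
    all_zero_voxel = top == 0
    for r in range(1, len(names) + 1):
        in_r = labels == r
        m = int(in_r.sum())
        if m == 0 or bool(all_zero_voxel[in_r].all()):
            records[names[r - 1]] = [np.nan] * len(map_names)
            continue
        records[names[r - 1]] = [
            100.0 * credit[i, in_r].sum() / m for i in range(len(map_names))
        ]
    shares = pd.DataFrame(records, index=pd.Index(map_names, name="model")).T
    shares.index.name = level
    return SimilarityDecomposition(level=level, shares=shares)
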