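"""Voxel weight maps and region importance from a linear whole-brain SVM.

The primal weight vector of a linear SVM trained on all in-brain voxels
assigns each voxel a weight whose magnitude reflects its contribution to the
separating hyperplane.  Region importance is the arithmetic mean of those
per-voxel weights over the region's voxels,

    w_r = (1 / N_r) * sum_{x_i in r} w_{x_i},

computed here on |w| so that opposite-signed voxels cannot cancel within a
region (the signed variant is available behind a flag).  The top-k regions
by importance drive the region selection of the multi-kernel classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parcellation import region_voxel_mask
from .svm import SVMModel, weight_vector
from .volumes import Atlas, Volume


@dataclass
class WeightMap:
    """Per-voxel weights rearranged into brain form; zero outside the mask."""

    volume: Volume
    mask: np.ndarray
    normalized: bool


def voxel_weight_map(
    model: SVMModel,
    X_train: np.ndarray,
    voxel_index: np.ndarray,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray | None = None,
    normalize: bool = True,
    signed: bool = False,
) -> WeightMap:
    """Rearrange |w| (or signed w) of a linear model into a brain volume.

    ``voxel_index`` gives the grid coordinate of each feature column.  With
    ``normalize`` the in-mask values are min-max scaled to [0, 1]; a constant
    |w| map degenerates to all zeros by convention.
    """
    w = weight_vector(model, X_train)
    if voxel_index.shape != (w.size, 3):
        raise ValueError("voxel index does not match the feature columns")
    vals = w if signed else np.abs(w)
    if normalize:
        lo, hi = float(vals.min()), float(vals.max())
        vals = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo)
    data = np.zeros(grid_shape)
    data[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = vals
    mask = np.zeros(grid_shape, dtype=bool)
    mask[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = True
    vol = Volume(data=data, affine=np.eye(4) if affine is None else affine)
    return WeightMap(volume=vol, mask=mask, normalized=normalize)


def region_weight(wmap: WeightMap, atlas: Atlas, region: str, merge_lr: bool = True) -> float:
    """Mean weight over the region's voxels (restricted to the feature mask)."""
    rmask = region_voxel_mask(atlas, region, merge_lr) & wmap.mask
    n = int(rmask.sum())
    if n == 0:
        raise ValueError(f"region {region!r} is empty within the feature mask")
    return float(wmap.volume.data[rmask].sum() / n)


def region_weights(
    wmap: WeightMap,
    atlas: Atlas,
    regions: list[str],
    merge_lr: bool = True,
) -> dict[str, float]:
    return {r: region_weight(wmap, atlas, r, merge_lr) for r in regions}


def select_top_regions(rw: dict[str, float], k: int = 5) -> list[str]:
    """The k regions with the largest importance, descending; ties go
    alphabetically."""
    if k > len(rw):
        raise ValueError(f"k={k} exceeds the {len(rw)} scored regions")
    ordered = sorted(rw.items(), key=lambda item: (-item[1], item[0]))
    return [name for name, _ in ordered[:k]]


def write_region_weights(rw: dict[str, float], path) -> None:
    """Delimited text (region, weight), sorted by descending weight."""
    from pathlib import Path

    lines = [f"{name}\t{w:.10g}" for name, w in sorted(rw.items(), key=lambda x: (-x[1], x[0]))]
    Path(path).write_text("\n".join(lines) + "\n")
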