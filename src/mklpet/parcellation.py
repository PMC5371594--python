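"""Atlas-driven feature extraction: volumes -> per-region intensity matrices.

Voxels of each atlas region are read out in fixed lexicographic grid order,
giving one ``n_subjects x n_voxels`` block per (modality, region).  Left and
right homologous structures (e.g. ``putamen-L`` / ``putamen-R``) are merged
into a single named region by default, and ``striatum`` is available as the
union of putamen and caudate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import SubjectRecord
from .volumes import Atlas, BrainMask, Volume

#: convenience alias: the striatum is the union of putamen and caudate
ALIASES = {"striatum": ("putamen", "caudate")}


def merged_region_names(atlas: Atlas) -> list[str]:
    """Atlas region names with -L/-R pairs pooled, sorted alphabetically."""
    base = {n[:-2] if n.endswith(("-L", "-R")) else n for n in atlas.names.values()}
    return sorted(base)


def region_voxel_mask(atlas: Atlas, region: str, merge_lr: bool = True) -> np.ndarray:
    """Boolean grid for a region name, resolving L/R merging and aliases."""
    names = set(atlas.names.values())
    if region in names:
        return atlas.region_mask(region)
    if region in ALIASES:
        mask = np.zeros(atlas.labels.shape, dtype=bool)
        for part in ALIASES[region]:
            mask |= region_voxel_mask(atlas, part, merge_lr=True)
        return mask
    if merge_lr:
        parts = [f"{region}-L", f"{region}-R"]
        if any(p in names for p in parts):
            mask = np.zeros(atlas.labels.shape, dtype=bool)
            for p in parts:
                if p in names:
                    mask |= atlas.region_mask(p)
            return mask
    raise KeyError(f"region {region!r} not found in atlas")


def region_voxel_index(atlas: Atlas, region: str, merge_lr: bool = True) -> np.ndarray:
    """Voxel coordinates of a region, (n_voxels, 3), lexicographic grid order."""
    mask = region_voxel_mask(atlas, region, merge_lr)
    coords = np.argwhere(mask)  # argwhere is lexicographic in C order
    if coords.shape[0] == 0:
        raise ValueError(f"region {region!r} is empty")
    return coords


def extract_region_features(v: Volume, atlas: Atlas, region: str, merge_lr: bool = True) -> np.ndarray:
    """Intensities of one region's voxels, in fixed lexicographic grid order."""
    if v.shape != atlas.labels.shape:
        raise ValueError("volume and atlas grids differ")
    coords = region_voxel_index(atlas, region, merge_lr)
    return v.data[coords[:, 0], coords[:, 1], coords[:, 2]]


def whole_brain_features(v: Volume, mask: BrainMask) -> np.ndarray:
    """In-mask intensities in fixed lexicographic grid order."""
    if v.shape != mask.data.shape:
        raise ValueError("volume and mask grids differ")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    coords = np.argwhere(mask.data)
    return v.data[coords[:, 0], coords[:, 1], coords[:, 2]]


@dataclass
class FeatureSet:
    """Ordered subjects x per-region voxel-intensity blocks.

    ``blocks`` maps (modality, region) -> matrix of shape
    (n_subjects, n_region_voxels); ``voxel_index`` records the grid
    coordinates defining each block's column order.
    """

    subject_ids: list[str]
    labels: list[str]
    blocks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    voxel_index: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(self.labels) != n:
            raise ValueError("labels and subject_ids lengths differ")
        for key, block in self.blocks.items():
            if block.shape[0] != n:
                raise ValueError(f"block {key} row count != number of subjects")
            if np.isnan(block).any():
                raise ValueError(f"block {key} contains NaN")
            if key in self.voxel_index and block.shape[1] != self.voxel_index[key].shape[0]:
                raise ValueError(f"block {key} column count != voxel index length")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def block(self, modality: str, region: str) -> np.ndarray:
        return self.blocks[(modality, region)]

    def save(self, prefix: str | Path) -> None:
        """Cache to <prefix>.npz with a JSON sidecar describing the blocks."""
        prefix = Path(prefix)
        arrays = {}
        meta = {"subject_ids": self.subject_ids, "labels": self.labels, "blocks": []}
        for i, (key, block) in enumerate(sorted(self.blocks.items())):
            arrays[f"block_{i}"] = block
            arrays[f"index_{i}"] = self.voxel_index[key]
            meta["blocks"].append(
                {"modality": key[0], "region": key[1], "shape": list(block.shape)}
            )
        np.savez(prefix.with_suffix(".npz"), **arrays)
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureSet":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        data = np.load(prefix.with_suffix(".npz"))
        blocks, index = {}, {}
        for i, b in enumerate(meta["blocks"]):
            key = (b["modality"], b["region"])
            blocks[key] = data[f"block_{i}"]
            index[key] = data[f"index_{i}"]
        return cls(
            subject_ids=list(meta["subject_ids"]),
            labels=list(meta["labels"]),
            blocks=blocks,
            voxel_index=index,
        )


def build_feature_sets(
    subjects: list[SubjectRecord],
    atlas: Atlas,
    regions: list[str],
    modalities: list[str],
    merge_lr: bool = True,
) -> FeatureSet:
    """One block per (modality, region); subject order is the input order."""
    blocks: dict[tuple[str, str], np.ndarray] = {}
    index: dict[tuple[str, str], np.ndarray] = {}
    for modality in modalities:
        for rec in subjects:
            if modality not in rec.volumes:
                raise KeyError(f"subject {rec.id} is missing modality {modality!r}")
        for region in regions:
            coords = region_voxel_index(atlas, region, merge_lr)
            mat = np.empty((len(subjects), coords.shape[0]))
            for i, rec in enumerate(subjects):
                v = rec.volumes[modality]
                if v.shape != atlas.labels.shape:
                    raise ValueError("volume and atlas grids differ")
                mat[i] = v.data[coords[:, 0], coords[:, 1], coords[:, 2]]
            blocks[(modality, region)] = mat
            index[(modality, region)] = coords
    return FeatureSet(
        subject_ids=[r.id for r in subjects],
        labels=[r.diagnosis for r in subjects],
        blocks=blocks,
        voxel_index=index,
    )
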