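"""Synthetic PET-like phantoms: toy atlas + cohorts with seeded group effects.

The generator emulates the structure of a dopaminergic-imaging study of
parkinsonism: three diagnostic groups (idiopathic PD and the two atypical
syndromes MSA and PSP), striatal regions roughly ten times brighter than
extrastriatal tissue, group-specific multiplicative reductions of regional
uptake, spatially smooth noise, and (optionally) affine misalignment.  Every
downstream stage -- registration, parcellation, classification, t-maps -- can
therefore be exercised end to end without clinical data.

Uptake effects are multiplicative factors on a per-region baseline, matching
tracer-binding semantics: a factor of 0.65 on the putamen means 35% loss of
specific binding there.  Noise is i.i.d. Gaussian added before smoothing, so
the smoothed phantom carries spatially correlated noise like reconstructed
emission data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import Atlas, Volume, gaussian_smooth, write_volume, read_volume, write_atlas

GROUPS = ("PD", "MSA", "PSP")

#: default group sizes, mirroring the emulated three-group cohort
DEFAULT_GROUP_SIZES = {"PD": 39, "MSA": 24, "PSP": 24}


@dataclass(frozen=True)
class RegionSpec:
    """A spherical region: center (voxel coords), radius (voxels), baseline."""

    center: tuple[float, float, float]
    radius: float
    baseline: float


def _default_regions() -> dict[str, RegionSpec]:
    # Geometry for the default 40 x 48 x 34 grid (2 mm voxels).  Striatal
    # baselines ~10x extrastriatal tissue; filler regions carry no group
    # effect and act as negative controls for selection and t-maps.
    return {
        "putamen-L": RegionSpec((13.0, 26.0, 17.0), 4.0, 10.0),
        "putamen-R": RegionSpec((26.0, 26.0, 17.0), 4.0, 10.0),
        "caudate-L": RegionSpec((14.0, 33.0, 20.0), 2.5, 10.0),
        "caudate-R": RegionSpec((25.0, 33.0, 20.0), 2.5, 10.0),
        "thalamus": RegionSpec((19.5, 20.0, 17.0), 3.5, 2.0),
        "olfactory": RegionSpec((19.5, 41.0, 7.0), 2.5, 1.5),
        "supplementary-motor-area": RegionSpec((19.5, 30.0, 28.0), 3.5, 1.5),
        "frontal-filler-L": RegionSpec((8.0, 38.0, 20.0), 3.0, 1.5),
        "frontal-filler-R": RegionSpec((31.0, 38.0, 20.0), 3.0, 1.5),
        "occipital-filler": RegionSpec((19.5, 6.0, 16.0), 3.5, 1.5),
        "temporal-filler-L": RegionSpec((7.0, 16.0, 9.0), 3.0, 1.5),
        "temporal-filler-R": RegionSpec((32.0, 16.0, 9.0), 3.0, 1.5),
    }


def _default_effects() -> dict[str, dict[str, float]]:
    # Multiplicative uptake factors by (group, region); regions not listed
    # keep factor 1.  Keys may name a merged structure ("putamen" covers
    # putamen-L and putamen-R).  The pattern emulates postsynaptic D2/3
    # imaging: atypical syndromes lose striatal binding while idiopathic PD
    # shows extrastriatal (olfactory) involvement.
    return {
        "PD": {"olfactory": 0.70},
        "MSA": {"putamen": 0.65, "caudate": 0.75, "thalamus": 0.85},
        "PSP": {
            "putamen": 0.70,
            "caudate": 0.75,
            "thalamus": 0.90,
            "supplementary-motor-area": 0.80,
        },
    }


def _strong_effects() -> dict[str, dict[str, float]]:
    # Pronounced-effect variant used for discrimination checks.
    return {
        "PD": {"olfactory": 0.45},
        "MSA": {"putamen": 0.40, "caudate": 0.50, "thalamus": 0.70},
        "PSP": {
            "putamen": 0.45,
            "caudate": 0.50,
            "thalamus": 0.80,
            "supplementary-motor-area": 0.55,
        },
    }


@dataclass
class PhantomSpec:
    """Full description of a synthetic cohort; a pure function of this + seed."""

    shape: tuple[int, int, int] = (40, 48, 34)
    voxel_size_mm: float = 2.0
    regions: dict[str, RegionSpec] = field(default_factory=_default_regions)
    group_effects: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    noise_sd: float = 0.4
    smooth_fwhm_mm: float = 4.0
    brain_baseline: float = 0.5
    #: extrastriatal baseline scale applied for DaTSCAN-like phantoms, whose
    #: signal is almost entirely striatal
    datscan_extrastriatal_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in self.regions.items():
            if r.baseline <= 0 or r.radius <= 0:
                raise ValueError(f"region {name}: baseline and radius must be positive")
        for g, eff in self.group_effects.items():
            for reg, f in eff.items():
                if f <= 0:
                    raise ValueError(f"effect ({g},{reg}) must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @classmethod
    def strong(cls, **kw) -> "PhantomSpec":
        """Pronounced group effects and lower noise (discrimination checks)."""
        kw.setdefault("group_effects", _strong_effects())
        kw.setdefault("noise_sd", 0.3)
        return cls(**kw)

    @classmethod
    def small(cls, **kw) -> "PhantomSpec":
        """Compact 24 x 28 x 20 grid (3 mm voxels) with the same anatomy.

        Keeps registration and template experiments fast while preserving
        the full region layout and intensity contrast.
        """
        regions = {
            "putamen-L": RegionSpec((7.8, 15.2, 10.0), 2.4, 10.0),
            "putamen-R": RegionSpec((15.6, 15.2, 10.0), 2.4, 10.0),
            "caudate-L": RegionSpec((8.4, 19.3, 11.8), 1.5, 10.0),
            "caudate-R": RegionSpec((15.0, 19.3, 11.8), 1.5, 10.0),
            "thalamus": RegionSpec((11.7, 11.7, 10.0), 2.1, 2.0),
            "olfactory": RegionSpec((11.7, 23.9, 4.1), 1.5, 1.5),
            "supplementary-motor-area": RegionSpec((11.7, 17.5, 16.5), 2.1, 1.5),
            "frontal-filler-L": RegionSpec((4.8, 22.2, 11.8), 1.8, 1.5),
            "frontal-filler-R": RegionSpec((18.6, 22.2, 11.8), 1.8, 1.5),
            "occipital-filler": RegionSpec((11.7, 3.5, 9.4), 2.1, 1.5),
            "temporal-filler-L": RegionSpec((4.2, 9.3, 5.3), 1.8, 1.5),
            "temporal-filler-R": RegionSpec((19.2, 9.3, 5.3), 1.8, 1.5),
        }
        kw.setdefault("shape", (24, 28, 20))
        kw.setdefault("voxel_size_mm", 3.0)
        kw.setdefault("regions", regions)
        return cls(**kw)

    @classmethod
    def null(cls, **kw) -> "PhantomSpec":
        """No group effects at all: every group shares one expected image."""
        kw.setdefault("group_effects", {g: {} for g in GROUPS})
        return cls(**kw)

    def with_effects(self, effects: dict[str, dict[str, float]]) -> "PhantomSpec":
        return replace(self, group_effects=effects)

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size_mm": self.voxel_size_mm,
            "regions": {
                n: {"center": list(r.center), "radius": r.radius, "baseline": r.baseline}
                for n, r in self.regions.items()
            },
            "group_effects": {g: dict(e) for g, e in self.group_effects.items()},
            "noise_sd": self.noise_sd,
            "smooth_fwhm_mm": self.smooth_fwhm_mm,
            "brain_baseline": self.brain_baseline,
            "datscan_extrastriatal_scale": self.datscan_extrastriatal_scale,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "regions" in d:
            d["regions"] = {
                n: RegionSpec(tuple(r["center"]), float(r["radius"]), float(r["baseline"]))
                for n, r in d["regions"].items()
            }
        return cls(**d)


@dataclass
class SubjectRecord:
    """One simulated (or loaded) subject: id, diagnosis, per-modality volumes."""

    id: str
    diagnosis: str
    volumes: dict[str, Volume]

    def __post_init__(self) -> None:
        if self.diagnosis not in GROUPS:
            raise ValueError(f"diagnosis must be one of {GROUPS}, got {self.diagnosis!r}")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) > 1:
            raise ValueError("all volumes of a subject must share one grid shape")


def _sphere_mask(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    grid = np.indices(shape, dtype=np.float64)
    d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


def make_toy_atlas(spec: PhantomSpec) -> Atlas:
    """Deterministic toy parcellation: labelled spheres on an empty grid.

    Raises if any two regions overlap or a region does not fit in the grid.
    """
    labels = np.zeros(spec.shape, dtype=np.int32)
    names: dict[int, str] = {}
    for lab, (name, reg) in enumerate(sorted(spec.regions.items()), start=1):
        for a in range(3):
            if reg.center[a] - reg.radius < 0 or reg.center[a] + reg.radius > spec.shape[a] - 1:
                raise ValueError(f"region {name} does not fit inside grid {spec.shape}")
        mask = _sphere_mask(spec.shape, reg.center, reg.radius)
        if np.any(labels[mask] != 0):
            raise ValueError(f"region {name} overlaps a previously placed region")
        labels[mask] = lab
        names[lab] = name
    return Atlas(labels=labels, names=names, affine=spec.affine)


def brain_envelope(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoidal 'brain' support enclosing all regions (boolean grid)."""
    c = [(s - 1) / 2.0 for s in spec.shape]
    semi = [0.46 * s for s in spec.shape]
    grid = np.indices(spec.shape, dtype=np.float64)
    d2 = sum(((grid[a] - c[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def effect_factor(spec: PhantomSpec, group: str, region: str) -> float:
    """Multiplicative uptake factor for (group, region); 1.0 if unspecified.

    Merged keys apply to both hemispheres: an effect on "putamen" covers
    putamen-L and putamen-R.
    """
    eff = spec.group_effects.get(group)
    if eff is None:
        raise KeyError(f"unknown group {group!r}")
    if region in eff:
        return eff[region]
    base = region[:-2] if region.endswith(("-L", "-R")) else region
    return eff.get(base, 1.0)


def _is_striatal(region: str) -> bool:
    return region.startswith(("putamen", "caudate"))


def expected_image(
    atlas: Atlas, spec: PhantomSpec, group: str, modality: str = "DMFP"
) -> np.ndarray:
    """Noise-free pre-smoothing intensity map for a group/modality."""
    img = np.zeros(spec.shape, dtype=np.float64)
    extrastriatal_scale = 1.0
    brain_base = spec.brain_baseline
    if modality == "DaTSCAN":
        extrastriatal_scale = spec.datscan_extrastriatal_scale
        brain_base = spec.brain_baseline * spec.datscan_extrastriatal_scale
    img[brain_envelope(spec)] = brain_base
    for lab, name in atlas.names.items():
        reg = spec.regions[name]
        base = reg.baseline if _is_striatal(name) else reg.baseline * extrastriatal_scale
        img[atlas.labels == lab] = base * effect_factor(spec, group, name)
    return img


def simulate_subject(
    atlas: Atlas,
    spec: PhantomSpec,
    group: str,
    seed: int,
    modality: str = "DMFP",
) -> Volume:
    """One phantom volume: (baseline x group effect) + white noise, smoothed."""
    img = expected_image(atlas, spec, group, modality)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = Volume(data=img, affine=spec.affine)
    if spec.smooth_fwhm_mm > 0:
        vol = gaussian_smooth(vol, spec.smooth_fwhm_mm)
    return vol


def simulate_cohort(
    spec: PhantomSpec,
    n_per_group: dict[str, int] | None = None,
    seed: int | None = None,
    modalities: tuple[str, ...] = ("DMFP",),
    atlas: Atlas | None = None,
) -> list[SubjectRecord]:
    """Reproducible cohort: per-subject seeds derive from the master seed.

    Default group sizes are PD 39, MSA 24, PSP 24.
    """
    if n_per_group is None:
        n_per_group = dict(DEFAULT_GROUP_SIZES)
    if not n_per_group:
        raise ValueError("empty group list")
    if any(n < 1 for n in n_per_group.values()):
        raise ValueError("group counts must be >= 1")
    if seed is None:
        seed = spec.seed
    if atlas is None:
        atlas = make_toy_atlas(spec)
    records: list[SubjectRecord] = []
    idx = 0
    for group in sorted(n_per_group):
        for k in range(n_per_group[group]):
            vols = {}
            for m, modality in enumerate(modalities):
                child = np.random.SeedSequence([int(seed), idx, m]).generate_state(1)[0]
                vols[modality] = simulate_subject(atlas, spec, group, int(child), modality)
            records.append(SubjectRecord(id=f"sub-{idx:03d}", diagnosis=group, volumes=vols))
            idx += 1
    return records


def apply_random_affine(
    v: Volume,
    max_shift_mm: float,
    max_rot_deg: float,
    seed: int,
    max_scale: float = 0.0,
) -> tuple[Volume, "np.ndarray"]:
    """Resample a volume under a random rigid(+scale) perturbation.

    Returns the moved volume and the true 12-parameter vector
    (tx ty tz rx ry rz sx sy sz hxy hxz hyz) for recovery testing.
    """
    from .preprocess import AffineParams, transform_volume

    if max_shift_mm < 0 or max_rot_deg < 0 or max_scale < 0:
        raise ValueError("perturbation bounds must be >= 0")
    rng = np.random.default_rng(seed)
    t = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
    r = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg, size=3))
    s = 1.0 + rng.uniform(-max_scale, max_scale, size=3)
    params = AffineParams(np.concatenate([t, r, s, np.zeros(3)]))
    return transform_volume(v, params), params.as_vector()


# ---------------------------------------------------------------------------
# cohort <-> disk (NIfTI volumes + delimited manifest)

def write_cohort(
    records: list[SubjectRecord],
    outdir: str | Path,
    atlas: Atlas | None = None,
) -> Path:
    """Write volumes as NIfTI and a tab-delimited manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    modalities = sorted({m for r in records for m in r.volumes})
    rows = []
    for rec in records:
        row: dict[str, str] = {"subject_id": rec.id, "diagnosis": rec.diagnosis}
        for modality in modalities:
            fname = f"{rec.id}_{modality}.nii.gz"
            write_volume(rec.volumes[modality], outdir / fname)
            row[modality] = fname
        rows.append(row)
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if atlas is not None:
        write_atlas(atlas, outdir / "atlas.nii.gz", outdir / "atlas_names.txt")
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "diagnosis"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must contain columns {sorted(required)}")
    modalities = [c for c in df.columns if c not in required]
    base = manifest_path.parent
    records = []
    for _, row in df.iterrows():
        vols = {m: read_volume(base / row[m]) for m in modalities}
        records.append(
            SubjectRecord(id=str(row["subject_id"]), diagnosis=str(row["diagnosis"]), volumes=vols)
        )
    return records
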