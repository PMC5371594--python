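"""Spatial and intensity normalization.

Spatial normalization uses a plain 12-parameter affine model (3 translations,
3 rotations, 3 zooms, 3 shears) fitted by minimizing the mean squared
intensity difference (MSD) between the transformed source and a reference,
with derivative-free Nelder-Mead search run at three resolutions (volumes
smoothed at 8, 4 and 0 mm FWHM).  Translations are initialized from the
center-of-mass offset.  This is a deliberately simple similarity-optimizing
registration: no Bayesian priors on zooms or shears, no nonlinear warping.

Templates are built by registering a set of volumes to one of them, averaging
the registered images together with their left-right midplane reflections,
and smoothing; the result is made bit-exactly symmetric.

Intensity normalization divides each image by the mean of its top 0.1%
voxel intensities (computed within a brain mask by default), a robust
surrogate for a global uptake scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volumes import BrainMask, Volume, gaussian_smooth, reflect_midplane

PARAM_NAMES = (
    "tx", "ty", "tz",      # translations, mm
    "rx", "ry", "rz",      # rotations, radians
    "sx", "sy", "sz",      # zooms (scales)
    "hxy", "hxz", "hyz",   # shears
)


@dataclass
class AffineParams:
    """12-parameter affine: tx ty tz (mm), rx ry rz (rad), zooms, shears."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (12,):
            raise ValueError("expected 12 parameters")
        if np.any(self.values[6:9] <= 0):
            raise ValueError("zoom parameters must be positive")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=np.float64))

    @property
    def translation_mm(self) -> np.ndarray:
        return self.values[:3]

    @property
    def rotation_rad(self) -> np.ndarray:
        return self.values[3:6]

    @property
    def zooms(self) -> np.ndarray:
        return self.values[6:9]

    @property
    def shears(self) -> np.ndarray:
        return self.values[9:12]

    def as_vector(self) -> np.ndarray:
        return self.values.copy()

    def to_text(self) -> str:
        return " ".join(f"{v:.10g}" for v in self.values)

    @classmethod
    def from_text(cls, text: str) -> "AffineParams":
        return cls(np.array([float(t) for t in text.split()], dtype=np.float64))

    def linear_matrix(self) -> np.ndarray:
        """3x3 linear part: rotation . zoom . shear."""
        rx, ry, rz = self.rotation_rad
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        Z = np.diag(self.zooms)
        hxy, hxz, hyz = self.shears
        H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
        return Rx @ Ry @ Rz @ Z @ H


def transform_volume(v: Volume, params: AffineParams) -> Volume:
    """Resample a volume under the affine, about the grid center.

    The output at voxel p takes the source value at M (p - c) + c + t, with
    translations given in mm and converted to voxels; trilinear
    interpolation, zero fill outside the source.
    """
    M = params.linear_matrix()
    c = (np.array(v.shape, dtype=np.float64) - 1.0) / 2.0
    t_vox = params.translation_mm / v.voxel_size
    offset = c - M @ c + t_vox
    out = ndimage.affine_transform(v.data, M, offset=offset, order=1, mode="constant", cval=0.0)
    return v.copy_with(out)


@dataclass
class RegistrationOptions:
    """Tunables of the multi-resolution MSD registration."""

    fwhm_levels_mm: tuple[float, ...] = (8.0, 4.0, 0.0)
    maxfev_per_level: int = 1200
    xatol: float = 1e-3
    fatol: float = 1e-10
    init_from_center_of_mass: bool = True
    #: natural parameter steps used to scale the Nelder-Mead simplex
    param_scales: np.ndarray = field(
        default_factory=lambda: np.array(
            [2, 2, 2, 0.02, 0.02, 0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01]
        )
    )


@dataclass
class RegistrationResult:
    params: AffineParams
    resampled: Volume
    improved: bool
    msd: float


def _msd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.mean(d * d))


def _center_of_mass(data: np.ndarray) -> np.ndarray:
    w = np.clip(data, 0, None)
    s = w.sum()
    if s <= 0:
        return (np.array(data.shape, dtype=np.float64) - 1) / 2.0
    return np.array(ndimage.center_of_mass(w), dtype=np.float64)


def affine_register(
    source: Volume,
    reference: Volume,
    opts: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Find the 12-parameter affine minimizing MSD(transform(source), reference).

    Derivative-free Nelder-Mead search over three resolutions (source and
    reference smoothed at 8/4/0 mm).  If the optimum does not improve on the
    identity transform, the identity is returned with ``improved=False`` and
    a warning.
    """
    if source.shape != reference.shape:
        raise ValueError("source and reference must share a grid shape")
    opts = opts or RegistrationOptions()
    scales = np.asarray(opts.param_scales, dtype=np.float64)

    x0 = AffineParams.identity().as_vector()
    if opts.init_from_center_of_mass:
        com_s = _center_of_mass(source.data)
        com_r = _center_of_mass(reference.data)
        x0[:3] = (com_s - com_r) * source.voxel_size

    identity_msd = _msd(source.data, reference.data)
    u = (x0 - AffineParams.identity().as_vector()) / scales

    for fwhm in opts.fwhm_levels_mm:
        if fwhm > 0:
            src_l = gaussian_smooth(source, fwhm)
            ref_l = gaussian_smooth(reference, fwhm)
        else:
            src_l, ref_l = source, reference
        ref_data = ref_l.data

        def cost(uu: np.ndarray) -> float:
            vec = AffineParams.identity().as_vector() + uu * scales
            if np.any(vec[6:9] <= 0.1):
                return np.inf
            moved = transform_volume(src_l, AffineParams(vec))
            return _msd(moved.data, ref_data)

        n = u.size
        simplex = np.vstack([u] + [u + 0.5 * np.eye(n)[i] for i in range(n)])
        res = optimize.minimize(
            cost,
            u,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": opts.maxfev_per_level,
                "xatol": opts.xatol,
                "fatol": opts.fatol,
            },
        )
        u = res.x

    best = AffineParams(AffineParams.identity().as_vector() + u * scales)
    resampled = transform_volume(source, best)
    best_msd = _msd(resampled.data, reference.data)
    if best_msd < identity_msd:
        return RegistrationResult(best, resampled, True, best_msd)
    if identity_msd <= 1e-30:  # already perfectly aligned
        return RegistrationResult(AffineParams.identity(), source, True, identity_msd)
    warnings.warn("registration failed to improve over identity", stacklevel=2)
    return RegistrationResult(AffineParams.identity(), source, False, identity_msd)


def build_template(
    volumes: list[Volume],
    reference_index: int = 0,
    fwhm_mm: float = 8.0,
    opts: RegistrationOptions | None = None,
) -> Volume:
    """Symmetric template: register, pool with midplane reflections, smooth.

    All volumes are registered to ``volumes[reference_index]``; the mean of
    the registered images and their left-right reflections is smoothed and
    then symmetrized, so the result satisfies
    ``template[x, y, z] == template[X-1-x, y, z]`` exactly.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    if not 0 <= reference_index < len(volumes):
        raise IndexError("reference_index out of range")
    ref = volumes[reference_index]
    registered = []
    for i, v in enumerate(volumes):
        if i == reference_index:
            registered.append(v)
        else:
            registered.append(affine_register(v, ref, opts).resampled)
    stack = [r.data for r in registered] + [reflect_midplane(r).data for r in registered]
    mean = Volume(data=np.mean(stack, axis=0), affine=ref.affine)
    if fwhm_mm > 0:
        mean = gaussian_smooth(mean, fwhm_mm)
    sym = 0.5 * (mean.data + mean.data[::-1, :, :])
    return Volume(data=sym, affine=ref.affine)


def spatially_normalize(
    v: Volume,
    template: Volume,
    opts: RegistrationOptions | None = None,
) -> Volume:
    """Register a volume onto the template grid (template-matching approach)."""
    return affine_register(v, template, opts).resampled


def normalize_intensity(
    v: Volume,
    mask: BrainMask | None = None,
    top_frac: float = 0.001,
) -> Volume:
    """Divide by the mean of the top ``top_frac`` highest (in-mask) intensities.

    The top-set size is ``ceil(top_frac * N)`` with a minimum of one voxel,
    over the in-mask voxel population (whole volume if no mask is given).
    After normalization the mean of that same top set equals 1 exactly, and
    the operation is invariant to any positive rescaling of the input.
    """
    vals = v.data[mask.data] if mask is not None else v.data.ravel()
    n = vals.size
    if n == 0:
        raise ValueError("empty mask")
    n_top = max(1, math.ceil(top_frac * n))
    top = np.partition(vals, n - n_top)[n - n_top:]
    i_max = float(top.mean())
    if i_max <= 0:
        raise ValueError("nonpositive normalization constant")
    return v.copy_with(v.data / i_max)
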