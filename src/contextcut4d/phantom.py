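"""Synthetic 4-D phantoms with exact ground truth.

The phantom emulates the salient features of a lung 4D-CT tumor study: a
bright ellipsoidal "tumor" inside darker "lung" parenchyma, translating
smoothly along the respiratory cycle; an adjacent "chest wall" slab of
near-tumor intensity (configurable up to exact equality, the adhesion
situation where the regional model alone cannot separate the two);
additive Gaussian noise; and,
optionally, a weak-edge scenario in chosen phases, where the tumor
boundary is selectively blurred within an angular sector so the edge
information lost in one phase is still present in its neighbours.

Ground-truth masks are the exact per-phase ellipsoid voxel sets, fixed
before noise and degradation are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .datamodel import Labeling4D, SeedSet, Volume4D
from .errors import ValidationError

_CROSS3D = ndimage.generate_binary_structure(3, 1)


@dataclass
class PhantomParams:
    """Geometry, intensities and corruption of one synthetic study.

    Defaults give a 48x64x64 grid at 1 mm isotropic spacing with k = 6
    phases (the phase count of routine clinical acquisitions), a tumor of
    semi-axes (6, 8, 8) mm at intensity 0.65 inside lung background 0.25,
    a low-contrast chest-wall slab (0.55, three noise sigmas below the
    tumor) on the +x side, 6 mm of sinusoidal cranio-caudal motion and
    additive noise of sigma 0.03.
    """

    grid_shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase_count: int = 6
    tumor_semiaxes_mm: tuple[float, float, float] = (6.0, 8.0, 8.0)
    tumor_center: tuple[float, float, float] = (20.0, 32.0, 40.0)  # (z, y, x) voxels
    tumor_intensity: float = 0.65
    background_intensity: float = 0.25
    wall_x_start: int | None = 56      # slab occupies x >= this index; None = no wall
    wall_intensity: float = 0.55
    motion_amplitude_mm: float = 6.0
    noise_sigma: float = 0.03
    degraded_phases: tuple[int, ...] = ()
    degrade_radius_mm: float = 4.5   # ~3/4 of the smallest tumor semi-axis
    degrade_sector: tuple[float, float] = (0.0, math.pi)  # (start angle, extent), x-y plane
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_count < 1:
            raise ValidationError("phase_count must be >= 1")
        if any(n < 4 for n in self.grid_shape):
            raise ValidationError("grid too small")
        for v in (self.tumor_intensity, self.background_intensity, self.wall_intensity):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("intensities must lie in [0, 1]")
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValidationError("tumor semi-axes must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if any(not 0 <= p < self.phase_count for p in self.degraded_phases):
            raise ValidationError("degraded phase index out of range")

    def to_dict(self) -> dict:
        return asdict(self)

    def phase_centers(self) -> np.ndarray:
        """Tumor center (z, y, x, voxels) per phase along the breathing cycle.

        Cranio-caudal displacement follows (A/2)(1 - cos(2 pi i / k)):
        zero at end-exhale (phase 0), maximal at mid-cycle, periodic.
        """
        k = self.phase_count
        centers = np.tile(np.asarray(self.tumor_center, float), (k, 1))
        dz_mm = 0.5 * self.motion_amplitude_mm * (1.0 - np.cos(2.0 * np.pi * np.arange(k) / k))
        centers[:, 0] += dz_mm / self.spacing[0]
        return centers


@dataclass
class PhantomTruth:
    """A generated phantom: the 4-D volume, its exact masks, and the params."""

    volume: Volume4D
    masks: Labeling4D
    params: PhantomParams


def _ellipsoid_mask(grid_shape, spacing, center_vox, semiaxes_mm) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in grid_shape), indexing="ij")
    q = np.zeros(grid_shape)
    for coord, c, r, sp in zip((zz, yy, xx), center_vox, semiaxes_mm, spacing):
        q += ((coord - c) * sp / r) ** 2
    return q <= 1.0


def generate_phantom(params: PhantomParams) -> PhantomTruth:
    """Build the phantom volume and its exact ground-truth masks.

    Per phase: truth mask = ellipsoid at that phase's center; image =
    background + tumor + wall, then sector blur on the degraded phases,
    then Gaussian noise.  Deterministic given ``params.rng_seed``.
    """
    shape = params.grid_shape
    k = params.phase_count
    centers = params.phase_centers()
    # tumor must stay strictly inside the grid at every phase
    for c in centers:
        for ax in range(3):
            r_vox = params.tumor_semiaxes_mm[ax] / params.spacing[ax]
            if c[ax] - r_vox < 0 or c[ax] + r_vox > shape[ax] - 1:
                raise ValidationError("tumor leaves the grid during the motion cycle")

    masks = np.zeros((k, *shape), dtype=np.uint8)
    vol = np.full((k, *shape), params.background_intensity, dtype=np.float64)
    for i in range(k):
        m = _ellipsoid_mask(shape, params.spacing, centers[i], params.tumor_semiaxes_mm)
        masks[i] = m
        vol[i][m] = params.tumor_intensity
        if params.wall_x_start is not None:
            vol[i][:, :, params.wall_x_start:] = params.wall_intensity

    for i in params.degraded_phases:
        vol[i] = degrade_boundary(vol[i], masks[i].astype(bool), params.degrade_sector,
                                  params.degrade_radius_mm, params.spacing)

    rng = np.random.default_rng(params.rng_seed)
    if params.noise_sigma > 0:
        vol += rng.normal(0.0, params.noise_sigma, vol.shape)
    np.clip(vol, 0.0, 1.0, out=vol)
    return PhantomTruth(Volume4D(vol, params.spacing), Labeling4D(masks), params)


def degrade_boundary(phase: np.ndarray, mask: np.ndarray,
                     sector: tuple[float, float], radius_mm: float,
                     spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Weaken the tumor edge within an angular sector of the boundary shell.

    Voxels within ``radius_mm`` of the mask boundary whose x-y azimuth
    around the mask centroid falls in ``sector = (start, extent)`` are
    replaced by a Gaussian-blurred copy of the phase; everything else is
    untouched.  A zero-extent sector leaves the phase unchanged.
    """
    if radius_mm <= 0:
        raise ValidationError("degrade radius must be > 0")
    start, extent = float(sector[0]), float(sector[1])
    if not 0.0 <= start < 2.0 * math.pi or not 0.0 <= extent <= 2.0 * math.pi:
        raise ValidationError("sector start must be in [0, 2*pi), extent in [0, 2*pi]")
    out = np.array(phase, dtype=np.float64, copy=True)
    if extent == 0.0 or not mask.any():
        return out
    sampling = np.asarray(spacing, dtype=np.float64)
    dist_out = ndimage.distance_transform_edt(~mask, sampling=sampling)
    dist_in = ndimage.distance_transform_edt(mask, sampling=sampling)
    shell = np.where(mask, dist_in, dist_out) <= radius_mm

    centroid = np.argwhere(mask).mean(axis=0)
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in mask.shape), indexing="ij")
    theta = np.mod(np.arctan2(yy - centroid[1], xx - centroid[2]), 2.0 * math.pi)
    in_sector = np.mod(theta - start, 2.0 * math.pi) <= extent

    sigma_vox = (radius_mm / 2.0) / sampling
    blurred = ndimage.gaussian_filter(out, sigma=sigma_vox)
    sel = shell & in_sector
    out[sel] = blurred[sel]
    return out


def weak_edge_params(rng_seed: int = 0, degraded_phase: int = 3) -> PhantomParams:
    """Phantom preset for the weak-edge study: one blurred-boundary phase.

    The tumor edge of one mid-cycle phase is washed out over half its
    circumference, while the same edge stays sharp in the neighbouring
    phases — the situation where inter-phase context information should
    rescue the degraded phase.  The chest wall is omitted so the
    experiment isolates the weak-edge failure mode from the (separate)
    adhesion failure mode: wall intensities would otherwise populate the
    background histogram exactly where the blur ramp lives, masking the
    effect under study.
    """
    return PhantomParams(rng_seed=rng_seed, degraded_phases=(degraded_phase,),
                         wall_x_start=None)


def seeds_from_truth(truth: PhantomTruth, phase_index: int = 0,
                     n_object: int = 300, n_background: int = 2000,
                     rng_seed: int = 0) -> SeedSet:
    """Emulate a user's brush annotation from the ground truth of one phase.

    Object seeds are sampled from the eroded tumor mask (a brush stays
    well inside the tumor).  Background seeds are sampled from the whole
    surround of the tumor on the slices it occupies — lung, the dark gap,
    and the chest wall alike — the way an annotator strokes "not tumor"
    generously across the slice.  Covering nearby confusable structures
    is essential: the background histogram must assign mass to every
    intensity that occurs outside the tumor.
    """
    rng = np.random.default_rng(rng_seed)
    mask = truth.masks.labels[phase_index].astype(bool)
    core = ndimage.binary_erosion(mask, structure=_CROSS3D, iterations=2, border_value=0)
    if not core.any():
        core = mask
    z_any = np.flatnonzero(mask.any(axis=(1, 2)))
    z_lo = max(0, z_any.min() - 2)
    z_hi = min(mask.shape[0], z_any.max() + 3)
    surround = np.zeros_like(mask)
    surround[z_lo:z_hi] = True
    surround &= ~ndimage.binary_dilation(mask, structure=_CROSS3D, iterations=2, border_value=0)
    obj = np.argwhere(core)
    bkg = np.argwhere(surround)
    obj = obj[rng.choice(len(obj), size=min(n_object, len(obj)), replace=False)]
    bkg = bkg[rng.choice(len(bkg), size=min(n_background, len(bkg)), replace=False)]
    return SeedSet(phase_index, obj, bkg)
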