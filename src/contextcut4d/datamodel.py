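"""4-D image, seed and label containers plus volume I/O.

A 4D-CT study is represented as ``k`` co-registered 3-D grids sharing one
voxel spacing.  Intensities are stored window-normalized to [0, 1]: raw
values are clipped to a CT display window (default [-1000, 400] HU, the
usual lung/mediastinum compromise) and mapped affinely onto the unit
interval.  All energy parameters (``sigma1``, ``tau``) are therefore
scale-free.  Coordinates are (z, y, x), 0-based, voxel-center convention;
spacing is (dz, dy, dx) in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, IOFailure, ValidationError

DEFAULT_WINDOW = (-1000.0, 400.0)

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class Volume4D:
    """k respiratory phases of one 4D-CT, normalized intensities in [0, 1].

    Attributes
    ----------
    phases : ndarray, shape (k, Z, Y, X)
        Normalized intensity of every voxel in every phase.
    spacing : tuple of float
        Voxel spacing (dz, dy, dx) in mm, shared by all phases.
    """

    phases: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if self.phases.ndim != 4:
            raise FormatError(f"expected a (k, Z, Y, X) array, got shape {self.phases.shape}")
        if self.phases.shape[0] < 1:
            raise FormatError("need at least one phase")
        if not np.all(np.isfinite(self.phases)):
            raise FormatError("non-finite intensities")
        if self.phases.min() < -1e-12 or self.phases.max() > 1 + 1e-12:
            raise FormatError("intensities must be normalized to [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def phase_count(self) -> int:
        return self.phases.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.phases.shape[1:]


@dataclass
class SeedSet:
    """User-marked object (O) and background (B) voxels in one phase.

    Seeds may span several slices but must all live in ``phase_index``;
    that single annotation drives the segmentation of every phase.
    """

    phase_index: int
    object_voxels: np.ndarray   # (n, 3) int (z, y, x)
    background_voxels: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.object_voxels = np.atleast_2d(np.asarray(self.object_voxels, dtype=np.intp))
        self.background_voxels = np.atleast_2d(np.asarray(self.background_voxels, dtype=np.intp))
        for name, arr in (("object", self.object_voxels), ("background", self.background_voxels)):
            if arr.size and arr.shape[1] != 3:
                raise ValidationError(f"{name} seeds must be (n, 3) (z, y, x) coordinates")

    def validate_for(self, volume: Volume4D) -> None:
        if not (0 <= self.phase_index < volume.phase_count):
            raise ValidationError(
                f"seed phase {self.phase_index} outside [0, {volume.phase_count})")
        if self.object_voxels.size == 0 or self.background_voxels.size == 0:
            raise ValidationError("both object and background seeds are required")
        shape = np.asarray(volume.grid_shape)
        for name, arr in (("object", self.object_voxels), ("background", self.background_voxels)):
            if arr.min() < 0 or np.any(arr >= shape):
                raise ValidationError(f"{name} seed coordinates outside the grid")
        o = {tuple(c) for c in self.object_voxels}
        b = {tuple(c) for c in self.background_voxels}
        if o & b:
            raise ValidationError(f"{len(o & b)} voxels marked both object and background")


@dataclass
class Labeling4D:
    """Binary segmentation per voxel per phase: 0 = background, 1 = object."""

    labels: np.ndarray  # (k, Z, Y, X) uint8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise FormatError(f"expected a (k, Z, Y, X) label array, got {self.labels.shape}")
        if not np.isin(self.labels, (0, 1)).all():
            raise FormatError("labels must be 0 or 1")
        self.labels = self.labels.astype(np.uint8)

    @property
    def phase_count(self) -> int:
        return self.labels.shape[0]


def _read_image(path: Path) -> sitk.Image:
    try:
        return sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on unreadable files
        raise IOFailure(f"cannot read volume {path}: {exc}") from exc


def _spacing_zyx(img: sitk.Image) -> tuple[float, ...]:
    return tuple(reversed(img.GetSpacing()))


def read_volume4d(paths: Sequence[str | Path],
                  window: tuple[float, float] = DEFAULT_WINDOW) -> Volume4D:
    """Load per-phase volumes (NIfTI or MetaImage) into one Volume4D.

    Intensities are clipped to ``window`` and mapped affinely to [0, 1];
    phase order follows the input order.  All files must share grid shape
    and spacing.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValidationError(f"window low must be < high, got {window}")
    if not paths:
        raise ValidationError("no phase files given")
    arrays = []
    spacing = None
    for p in paths:
        img = _read_image(Path(p))
        arr = sitk.GetArrayFromImage(img).astype(np.float64)
        if arr.ndim != 3:
            raise FormatError(f"{p}: expected a 3-D volume, got {arr.ndim}-D")
        sp = _spacing_zyx(img)
        if spacing is None:
            spacing, shape0 = sp, arr.shape
        else:
            if arr.shape != shape0:
                raise FormatError(f"{p}: grid {arr.shape} differs from first phase {shape0}")
            if not np.allclose(sp, spacing, rtol=1e-4):
                raise FormatError(f"{p}: spacing {sp} differs from first phase {spacing}")
        arrays.append(np.clip(arr, lo, hi))
    normalized = (np.stack(arrays) - lo) / (hi - lo)
    return Volume4D(normalized, spacing)


def load_manifest(path: str | Path) -> tuple[list[Path], dict]:
    """Read a phase manifest (JSON or YAML): {"phases": [...], ...}.

    Relative phase paths are resolved against the manifest directory.
    Returns the ordered phase paths and the full manifest dict.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOFailure(f"cannot read manifest {path}: {exc}") from exc
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict) or "phases" not in data:
        raise FormatError(f"manifest {path} must be a mapping with a 'phases' list")
    phases = [path.parent / p if not Path(p).is_absolute() else Path(p) for p in data["phases"]]
    return phases, data


def read_seeds(path: str | Path, volume: Volume4D,
               phase_index: int | None = None) -> SeedSet:
    """Load a seed annotation for exactly one phase.

    Two formats are accepted:

    * a JSON coordinate list ``{"phase_index": i, "object": [[z,y,x],...],
      "background": [[z,y,x],...]}``;
    * a same-grid label volume (0 = unmarked, 1 = object, 2 = background),
      with the phase given by ``phase_index`` (3-D mask) or inferred from
      the single non-empty phase of a 4-D mask.
    """
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"seed file not found: {path}")
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        try:
            seeds = SeedSet(int(data["phase_index"]),
                            np.asarray(data["object"], dtype=np.intp).reshape(-1, 3),
                            np.asarray(data["background"], dtype=np.intp).reshape(-1, 3))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"malformed seed JSON {path}: {exc}") from exc
    else:
        arr = sitk.GetArrayFromImage(_read_image(path))
        if arr.ndim == 4:
            nonzero_phases = np.flatnonzero(arr.reshape(arr.shape[0], -1).any(axis=1))
            if len(nonzero_phases) != 1:
                raise ValidationError(
                    f"seed volume must mark exactly one phase, found {len(nonzero_phases)}")
            phase_index = int(nonzero_phases[0])
            arr = arr[phase_index]
        elif arr.ndim == 3:
            if phase_index is None:
                raise ValidationError("a 3-D seed mask needs an explicit phase index")
        else:
            raise FormatError(f"seed volume must be 3-D or 4-D, got {arr.ndim}-D")
        if arr.shape != volume.grid_shape:
            raise ValidationError(
                f"seed grid {arr.shape} does not match volume grid {volume.grid_shape}")
        seeds = SeedSet(int(phase_index),
                        np.argwhere(arr == 1),
                        np.argwhere(arr == 2))
    seeds.validate_for(volume)
    return seeds


def write_labeling(labeling: Labeling4D, spacing: Sequence[float],
                   out_dir: str | Path, prefix: str = "mask_phase",
                   suffix: str = ".nii.gz") -> list[Path]:
    """Write one binary mask volume per phase; returns the paths written."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create {out_dir}: {exc}") from exc
    paths = []
    for i in range(labeling.phase_count):
        img = sitk.GetImageFromArray(labeling.labels[i])
        img.SetSpacing(tuple(float(s) for s in reversed(spacing)))
        p = out_dir / f"{prefix}{i:02d}{suffix}"
        try:
            sitk.WriteImage(img, str(p))
        except Exception as exc:
            raise IOFailure(f"cannot write {p}: {exc}") from exc
        paths.append(p)
    return paths


def write_volume4d(volume: Volume4D, out_dir: str | Path,
                   prefix: str = "phase", suffix: str = ".nii.gz",
                   window: tuple[float, float] | None = None) -> list[Path]:
    """Write per-phase volumes plus a ``manifest.json`` listing them.

    With ``window`` the normalized intensities are mapped back to raw
    units (e.g. HU) so the files round-trip through :func:`read_volume4d`.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create {out_dir}: {exc}") from exc
    paths = []
    for i in range(volume.phase_count):
        arr = volume.phases[i]
        if window is not None:
            lo, hi = window
            arr = arr * (hi - lo) + lo
        img = sitk.GetImageFromArray(arr.astype(np.float32))
        img.SetSpacing(tuple(float(s) for s in reversed(volume.spacing)))
        p = out_dir / f"{prefix}{i:02d}{suffix}"
        try:
            sitk.WriteImage(img, str(p))
        except Exception as exc:
            raise IOFailure(f"cannot write {p}: {exc}") from exc
        paths.append(p)
    manifest = {
        "phases": [p.name for p in paths],
        "spacing": list(volume.spacing),
        "window": list(window) if window is not None else None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths
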