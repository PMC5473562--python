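"""Segmentation accuracy metrics: Dice coefficient and average symmetric
surface distance, computed in 3-D per phase.

DSC = 2|A∩G| / (|A|+|G|) measures volumetric overlap in [0, 1].
ASSD averages, over the border voxels of both surfaces, the Euclidean
distance (mm, voxel-center convention) to the nearest border voxel of the
other surface:

    ASSD = ( sum_{a in S_A} min_b d(a,b) + sum_{b in S_G} min_a d(a,b) )
           / (N_A + N_G)

Border voxels are mask voxels with at least one 6-neighbor outside the
mask; voxels on the grid boundary count as border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .datamodel import Labeling4D
from .errors import ValidationError

_CROSS3D = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class SurfaceSet:
    """Border voxel positions (mm) of one binary mask."""

    positions_mm: np.ndarray  # (N, 3) float

    @property
    def count(self) -> int:
        return len(self.positions_mm)


@dataclass
class MetricReport:
    """Per-phase and aggregate DSC/ASSD of a 4-D labeling vs ground truth."""

    dsc_per_phase: list[float]
    assd_per_phase: list[float]

    @property
    def dsc_mean(self) -> float:
        return float(np.mean(self.dsc_per_phase))

    @property
    def assd_mean(self) -> float:
        return float(np.mean(self.assd_per_phase))

    def to_records(self) -> list[dict]:
        rows = [
            {"phase": i, "dsc": d, "assd_mm": a}
            for i, (d, a) in enumerate(zip(self.dsc_per_phase, self.assd_per_phase))
        ]
        rows.append({"phase": "aggregate", "dsc": self.dsc_mean, "assd_mm": self.assd_mean})
        return rows


def dsc(a_mask: np.ndarray, g_mask: np.ndarray) -> float:
    """Dice similarity coefficient of two same-shape binary masks."""
    a = np.asarray(a_mask, bool)
    g = np.asarray(g_mask, bool)
    if a.shape != g.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {g.shape}")
    denom = int(a.sum()) + int(g.sum())
    if denom == 0:
        raise ValidationError("DSC undefined: both masks are empty")
    return 2.0 * int((a & g).sum()) / denom


def extract_surface(mask: np.ndarray, spacing: Sequence[float]) -> SurfaceSet:
    """Border voxels of a 3-D mask as voxel-center positions in mm.

    A mask voxel is border if any of its 6 neighbors is outside the mask
    (outside-grid counts as outside).
    """
    m = np.asarray(mask, bool)
    if m.ndim != 3:
        raise ValidationError(f"expected a 3-D mask, got {m.ndim}-D")
    if not m.any():
        raise ValidationError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(m, structure=_CROSS3D, border_value=0)
    coords = np.argwhere(m & ~interior)
    return SurfaceSet(coords * np.asarray(spacing, dtype=np.float64))


def assd(a_mask: np.ndarray, g_mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Average symmetric surface distance in mm between two binary masks."""
    a = np.asarray(a_mask, bool)
    g = np.asarray(g_mask, bool)
    if a.shape != g.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {g.shape}")
    sa = extract_surface(a, spacing)
    sg = extract_surface(g, spacing)
    d_ag, _ = cKDTree(sg.positions_mm).query(sa.positions_mm)
    d_ga, _ = cKDTree(sa.positions_mm).query(sg.positions_mm)
    return float((d_ag.sum() + d_ga.sum()) / (sa.count + sg.count))


def assd_bruteforce(a_mask: np.ndarray, g_mask: np.ndarray,
                    spacing: Sequence[float]) -> float:
    """All-pairs ASSD, an independent O(N_A * N_G) oracle for testing."""
    sa = extract_surface(np.asarray(a_mask, bool), spacing)
    sg = extract_surface(np.asarray(g_mask, bool), spacing)
    d = np.linalg.norm(sa.positions_mm[:, None, :] - sg.positions_mm[None, :, :], axis=2)
    return float((d.min(axis=1).sum() + d.min(axis=0).sum()) / (sa.count + sg.count))


def evaluate_labeling(result: Labeling4D, truth: Labeling4D,
                      spacing: Sequence[float]) -> MetricReport:
    """Per-phase 3-D DSC/ASSD of a segmentation against ground truth.

    The 4-D aggregate is the mean over phases of the per-phase 3-D values.
    """
    if result.labels.shape != truth.labels.shape:
        raise ValidationError(
            f"labeling shapes differ: {result.labels.shape} vs {truth.labels.shape}")
    ds, ad = [], []
    for i in range(result.phase_count):
        ds.append(dsc(result.labels[i], truth.labels[i]))
        ad.append(assd(result.labels[i], truth.labels[i], spacing))
    return MetricReport(ds, ad)
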