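"""Cost terms of the global segmentation energy.

Three families of costs enter the global energy:

* regional: negative log-likelihood of a voxel's intensity under
  object/background histograms fitted from the user seeds, with hard
  (infinite) overrides at the seeds themselves;
* boundary: an edge-preserving Gaussian similarity weight between
  6-neighbors within one phase, divided by their physical distance;
* context: a two-level Potts penalty on label disagreement between
  corresponding voxels of neighbouring phases — twice as expensive to
  disagree when the two intensities are similar (|dI| <= tau).

All intensities are window-normalized to [0, 1] (see datamodel), so the
Gaussian width sigma1, the Potts level sigma2 and the threshold tau are
dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .datamodel import SeedSet, Volume4D
from .errors import ValidationError

#: tau follows the classic interactive graph-cut default of 5 grey levels
#: on an 8-bit scale, re-expressed on normalized intensities.
DEFAULT_TAU = 5.0 / 255.0


@dataclass
class EnergyParams:
    """All knobs of the energy.

    lambda1, sigma1 shape the intra-phase boundary term; lambda2, sigma2
    and tau shape the inter-phase context term.  The neighborhood is the
    fixed 6-connected system.  ``chain`` selects linear (phase i <-> i+1)
    or cyclic (additionally last <-> first) phase adjacency.
    ``hard_weight`` realizes the infinite seed penalty; None means
    "compute per problem instance as 1 + sum of all finite weights",
    which is provably uncuttable.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    sigma1: float = 0.5
    sigma2: float = 0.1
    tau: float = DEFAULT_TAU
    n_bins: int = 64
    prob_floor: float = 1e-6
    chain: str = "linear"
    hard_weight: float | None = None

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("lambda1 and lambda2 must be >= 0")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValidationError("sigma1 and sigma2 must be > 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if self.chain not in ("linear", "cyclic"):
            raise ValidationError(f"chain must be 'linear' or 'cyclic', got {self.chain!r}")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if not 0 < self.prob_floor * self.n_bins < 1:
            raise ValidationError("prob_floor must satisfy 0 < n_bins*floor < 1")
        if self.hard_weight is not None and self.hard_weight <= 0:
            raise ValidationError("hard_weight must be positive when given")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IntensityModel:
    """Histogram likelihoods Pr(I|O), Pr(I|B) over equal-width bins of [0, 1].

    Both histograms are floor-regularized (every bin probability >= floor)
    and renormalized, so regional costs are always finite.
    """

    bin_edges: np.ndarray
    p_object: np.ndarray
    p_background: np.ndarray
    floor: float

    @property
    def n_bins(self) -> int:
        return len(self.p_object)

    def bin_of(self, intensity: np.ndarray | float) -> np.ndarray:
        """Bin index of normalized intensities; the right edge maps to the last bin."""
        i = np.floor(np.asarray(intensity, dtype=np.float64) * self.n_bins).astype(np.intp)
        return np.clip(i, 0, self.n_bins - 1)


def fit_intensity_model(volume: Volume4D, seeds: SeedSet,
                        n_bins: int = 64, floor: float = 1e-6) -> IntensityModel:
    """Fit object/background intensity histograms from the seed voxels.

    The seed-phase intensities at the marked voxels are histogrammed over
    ``n_bins`` equal-width bins of [0, 1]; each histogram is then mixed
    with the uniform floor (p <- p*(1 - n_bins*floor) + floor) so every
    bin has probability >= floor and the histogram still sums to one.
    """
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    if not 0 < floor * n_bins < 1:
        raise ValidationError("floor must satisfy 0 < n_bins*floor < 1")
    seeds.validate_for(volume)
    phase = volume.phases[seeds.phase_index]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = []
    for coords in (seeds.object_voxels, seeds.background_voxels):
        vals = phase[coords[:, 0], coords[:, 1], coords[:, 2]]
        hist, _ = np.histogram(vals, bins=edges)
        p = hist / hist.sum()
        out.append(p * (1.0 - n_bins * floor) + floor)
    return IntensityModel(edges, out[0], out[1], floor)


def regional_cost(model: IntensityModel, intensity: np.ndarray | float,
                  label: int) -> np.ndarray | float:
    """-ln Pr(I|O) for label 1, -ln Pr(I|B) for label 0 (elementwise)."""
    if label not in (0, 1):
        raise ValidationError(f"label must be 0 or 1, got {label}")
    p = model.p_object if label == 1 else model.p_background
    cost = -np.log(p[model.bin_of(intensity)])
    return float(cost) if np.isscalar(intensity) else cost


def seed_hard_costs(seeds: SeedSet, params: EnergyParams) -> dict[tuple[int, int, int], dict[int, float]]:
    """Per-label regional-cost overrides realizing the hard seed constraints.

    An object seed must not be labelled background, so its cost for label 0
    is the hard weight (and symmetrically for background seeds).  Overrides
    apply only in ``seeds.phase_index``.  When ``params.hard_weight`` is
    None the override is ``math.inf`` and is replaced by the per-instance
    finite bound at graph-build time.
    """
    w = params.hard_weight if params.hard_weight is not None else math.inf
    overrides: dict[tuple[int, int, int], dict[int, float]] = {}
    for v in map(tuple, seeds.object_voxels):
        overrides[v] = {0: w}
    for v in map(tuple, seeds.background_voxels):
        overrides[v] = {1: w}
    return overrides


def boundary_cost(i_v: np.ndarray | float, i_w: np.ndarray | float,
                  distance: np.ndarray | float, params: EnergyParams) -> np.ndarray | float:
    """Edge weight lambda1 * exp(-(i_v - i_w)^2 / (2 sigma1^2)) / distance.

    ``distance`` is the physical voxel-center distance in mm (the spacing
    along the connecting axis for 6-neighbors).
    """
    distance = np.asarray(distance, dtype=np.float64)
    if np.any(distance <= 0):
        raise ValidationError("neighbor distance must be > 0")
    di = np.asarray(i_v, dtype=np.float64) - np.asarray(i_w, dtype=np.float64)
    w = params.lambda1 * np.exp(-(di * di) / (2.0 * params.sigma1 ** 2)) / distance
    return float(w) if w.ndim == 0 else w


def context_cost(i_a: np.ndarray | float, i_b: np.ndarray | float,
                 params: EnergyParams) -> np.ndarray | float:
    """Potts disagreement penalty between corresponding voxels of adjacent phases.

    2*lambda2*sigma2 when the intensities agree to within tau (disagreeing
    labels are then doubly implausible), lambda2*sigma2 otherwise.
    """
    d = np.abs(np.asarray(i_a, dtype=np.float64) - np.asarray(i_b, dtype=np.float64))
    w = np.where(d <= params.tau, 2.0 * params.lambda2 * params.sigma2,
                 params.lambda2 * params.sigma2)
    return float(w) if w.ndim == 0 else w
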