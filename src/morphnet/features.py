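"""Vertex-wise morphometric maps and per-ROI summaries.

A subject's surface morphometry arrives as one value per vertex (cortical
thickness CT and sulcal depth SD in mm; fractal dimension FD and
gyrification index GI dimensionless) together with a vertex-to-ROI
parcellation.  Two summaries are derived per region:

* the regional mean, which is the quantity tested in regional
  between-group statistics, and
* a discrete probability distribution of the vertex values (a Gaussian
  kernel density estimate evaluated on a fixed grid and renormalized),
  which is the object compared across regions when building similarity
  networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FEATURES",
    "VertexFeatureMap",
    "RoiDensity",
    "MissingRegionError",
    "regional_mean",
    "regional_means",
    "silverman_bandwidth",
    "estimate_density",
    "kernel_mass",
]

#: The four surface-based morphometric features handled by the pipeline.
FEATURES = ("CT", "FD", "GI", "SD")


class MissingRegionError(KeyError):
    """A referenced ROI has no labelled vertices."""


@dataclass
class VertexFeatureMap:
    """Per-subject, per-feature vertex values with ROI labels.

    Labels are integers ``1..n_roi``; label ``0`` marks unlabelled
    vertices (e.g. the medial wall) which are excluded from every
    computation.  Labelled vertex values must be finite.
    """

    subject_id: str
    feature: str
    values: np.ndarray
    roi_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_labels = np.asarray(self.roi_labels, dtype=int)
        if self.values.shape != self.roi_labels.shape or self.values.ndim != 1:
            raise ValueError("values and roi_labels must be 1-D arrays of equal length")
        labelled = self.roi_labels > 0
        if not np.all(np.isfinite(self.values[labelled])):
            raise ValueError(
                f"non-finite vertex values in labelled vertices of "
                f"{self.subject_id}/{self.feature}"
            )

    @property
    def roi_ids(self) -> np.ndarray:
        """Sorted ids of ROIs present in the parcellation (label 0 excluded)."""
        ids = np.unique(self.roi_labels)
        return ids[ids > 0]

    def roi_values(self, roi_id: int) -> np.ndarray:
        """Vertex values belonging to ``roi_id``; raises if the ROI is empty."""
        vals = self.values[self.roi_labels == roi_id]
        if vals.size == 0:
            raise MissingRegionError(
                f"ROI {roi_id} has no labelled vertices in "
                f"{self.subject_id}/{self.feature}"
            )
        return vals


@dataclass
class RoiDensity:
    """Discrete probability distribution of one ROI's vertex values.

    ``mass`` is a nonnegative vector on a strictly increasing evaluation
    ``grid``; it sums to one (within 1e-12) so that information-theoretic
    divergences are well defined.
    """

    grid: np.ndarray
    mass: np.ndarray
    roi_id: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.size < 2:
            raise ValueError("density grid needs at least 2 points")
        if self.grid.shape != self.mass.shape:
            raise ValueError("grid and mass must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mass < 0) or abs(self.mass.sum() - 1.0) > 1e-12:
            raise ValueError("mass must be nonnegative and sum to 1")


def regional_mean(vmap: VertexFeatureMap, roi_id: int) -> float:
    """Arithmetic mean of the ROI's vertex values (the regionally tested quantity)."""
    return float(np.mean(vmap.roi_values(roi_id)))


def regional_means(vmap: VertexFeatureMap, roi_ids=None) -> np.ndarray:
    """Regional means for every requested ROI (default: all present)."""
    ids = vmap.roi_ids if roi_ids is None else np.asarray(roi_ids, int)
    return np.array([regional_mean(vmap, r) for r in ids])


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's normal-reference bandwidth ``(4 / 3n)^(1/5) * sd``.

    Returns 0.0 for degenerate samples (fewer than two distinct values),
    which callers treat as the point-mass case.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0.0:
        return 0.0
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return 0.0
    return sd * (4.0 / (3.0 * v.size)) ** 0.2


def kernel_mass(values: np.ndarray, bandwidth: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel density on ``grid``, renormalized to a probability vector.

    With zero bandwidth (all values identical) the entire mass is placed on
    the grid cell nearest to the common value — the documented degenerate
    policy, so that identical regions still compare as maximally similar.
    """
    v = np.asarray(values, dtype=float)
    if bandwidth <= 0.0:
        mass = np.zeros(grid.size)
        mass[int(np.argmin(np.abs(grid - v[0])))] = 1.0
        return mass
    # kernel sum; the 1/(n h sqrt(2 pi)) prefactor cancels in the
    # renormalization and is omitted
    z = (grid[:, None] - v[None, :]) / bandwidth
    f = np.exp(-0.5 * z * z).sum(axis=1)
    total = f.sum()
    if total <= 0.0:  # grid disjoint from data; only possible with a fixed range
        raise ValueError("density grid carries no mass; check grid_range")
    return f / total


def estimate_density(
    values,
    grid_size: int = 28,
    bandwidth="silverman",
    grid_range: tuple[float, float] | None = None,
    roi_id: int | None = None,
) -> RoiDensity:
    """Discrete KDE of ``values`` on ``grid_size`` equally spaced points.

    Parameters
    ----------
    values
        Finite vertex values of one ROI.
    grid_size
        Number of evaluation points (the study default is 28).
    bandwidth
        ``"silverman"`` for the normal-reference rule, or a positive number
        for a fixed bandwidth.
    grid_range
        Optional ``(lo, hi)`` evaluation range; by default the data range.
        When all values coincide the grid spans a unit interval centred on
        the common value and the mass is a point mass (degenerate policy).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot estimate a density from zero values")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values passed to estimate_density")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")

    if bandwidth == "silverman":
        h = silverman_bandwidth(v)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("fixed bandwidth must be positive")
        if v.size < 2 or np.ptp(v) == 0.0:
            h = 0.0  # degenerate sample overrides any fixed bandwidth

    if grid_range is None:
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi <= lo:  # all values identical: centred unit span
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = float(grid_range[0]), float(grid_range[1])
        if hi <= lo:
            raise ValueError("grid_range must satisfy lo < hi")
    grid = np.linspace(lo, hi, grid_size)
    mass = kernel_mass(v, h, grid)
    mass = mass / mass.sum()
    return RoiDensity(grid=grid, mass=mass, roi_id=roi_id)
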