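"""Proximity map: fingerprint-shape similarity across parameter space.

The data fingerprint is compared with every one of the 1,681 synthetic
fingerprints through the mean Euclidean distance between their nonzero
points (in grid-index units, one cell = 5 ms along AT = 5 % along Con).
Each cell of the proximity map stores the reciprocal of that mean distance,
so cells whose cohort blob sits near — and is shaped like — the data blob
light up.  Unlike the binary fingerprint, the map is graded: it encodes how
the non-uniform blob geometry of the parameter space distorts a naive
cohort average, which is what the enhanced extraction exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DomainError, EmptyFingerprintError
from .fingerprint import Fingerprint
from .parameter_space import ParameterGrid

__all__ = ["ProximityMap", "DEFAULT_DISTANCE_FLOOR", "mean_point_distance", "proximity_map"]

#: Mean distances are floored at half a grid cell before inverting, so a
#: data fingerprint identical to a synthetic one maps to a finite intensity.
DEFAULT_DISTANCE_FLOOR = 0.5


@dataclass
class ProximityMap:
    """Non-negative intensity image ``intensity[con_index, at_index]``."""

    intensity: np.ndarray
    grid: ParameterGrid
    d_min: float = DEFAULT_DISTANCE_FLOOR
    data_source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (self.grid.n_con, self.grid.n_at):
            raise DomainError(
                f"intensity shape {arr.shape} does not match grid "
                f"({self.grid.n_con}, {self.grid.n_at})"
            )
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DomainError("intensity must be finite and non-negative")
        self.intensity = arr


def mean_point_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean Euclidean distance over all point pairs of two binary masks.

    Points are the (row, col) indices of nonzero cells; the mean runs over
    all ``|A| * |B|`` ordered pairs, making the statistic symmetric.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    pa = np.argwhere(a)
    pb = np.argwhere(b)
    if pa.size == 0 or pb.size == 0:
        raise DomainError("mean_point_distance requires two nonempty masks")
    return float(cdist(pa.astype(float), pb.astype(float)).mean())


def proximity_map(
    data_fp: Fingerprint,
    synthetic_masks: np.ndarray,
    d_min: float = DEFAULT_DISTANCE_FLOOR,
) -> ProximityMap:
    """Reciprocal mean point distance between the data blob and every cell's blob.

    ``synthetic_masks`` is the (n_cells, n_con, n_at) stack from
    :func:`strainprint.fingerprint.build_synthetic_fingerprints`, flat index
    in library-row (AT-major) order.  ``intensity[i, j] =
    1 / max(mean_point_distance(synthetic, data), d_min)``; a cell whose
    synthetic fingerprint is empty gets intensity 0 (cannot occur when
    synthetic fingerprints include their own cell).

    The per-cell means are computed by first averaging the distance from
    each grid point to the data points, then averaging those over each
    synthetic mask — algebraically identical to the full pairwise mean.
    """
    if data_fp.is_empty:
        raise EmptyFingerprintError(
            "the data fingerprint is empty; raise the similarity threshold "
            "or check that the trace is on the library time grid"
        )
    grid = data_fp.grid
    n_cells = grid.n_cells
    if synthetic_masks.shape != (n_cells, grid.n_con, grid.n_at):
        raise DomainError(
            f"synthetic mask stack has shape {synthetic_masks.shape}, "
            f"expected {(n_cells, grid.n_con, grid.n_at)}"
        )
    data_pts = data_fp.points().astype(float)
    rows, cols = np.indices((grid.n_con, grid.n_at))
    all_pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    # mean distance from every single grid point to the data point set
    point_to_data = cdist(all_pts, data_pts).mean(axis=1).reshape(grid.n_con, grid.n_at)

    flat_masks = synthetic_masks.reshape(n_cells, -1)
    counts = flat_masks.sum(axis=1)
    sums = flat_masks @ point_to_data.ravel()
    intensity_flat = np.zeros(n_cells)
    nonempty = counts > 0
    mean_d = sums[nonempty] / counts[nonempty]
    intensity_flat[nonempty] = 1.0 / np.maximum(mean_d, d_min)
    # flat index is AT-major -> image axes [con, at]
    intensity = intensity_flat.reshape(grid.n_at, grid.n_con).T
    return ProximityMap(
        intensity=intensity,
        grid=grid,
        d_min=d_min,
        data_source=data_fp.source,
        meta={"n_data_points": int(data_pts.shape[0])},
    )
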