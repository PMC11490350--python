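"""Similarity statistic and binary fingerprints in parameter space.

Two strain patterns are compared by their root-mean-square difference over
the analysis window — from mitral valve closure to two-thirds of systole
(speckle-tracking drift makes late systole unreliable)::

    S(p, i) = sqrt( sum_t (E_p[t] - E_i[t])^2 / N )

A *fingerprint* of a reference pattern is the binary 41 × 41 image marking
the cohort of library simulations whose similarity to the reference is
within the strain measurement error (S <= 0.03 by default).  A fingerprint
built from a library row always contains its own cell (self-similarity is
zero); the blob's shape encodes how uniquely that region of parameter space
maps to a strain pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.spatial.distance import cdist
from skimage import measure

from .errors import AlignmentError, ConfigurationError
from .model_core import StrainTrace, TensionWaveform
from .parameter_space import ParameterGrid, StrainLibrary

__all__ = [
    "AnalysisWindow",
    "Fingerprint",
    "DEFAULT_THRESHOLD",
    "similarity",
    "analysis_window",
    "build_fingerprint",
    "connected_components",
    "pairwise_similarity",
    "build_synthetic_fingerprints",
]

#: Cohort inclusion threshold: the realistic strain measurement error.
DEFAULT_THRESHOLD = 0.03


@dataclass(frozen=True)
class AnalysisWindow:
    """Inclusive sample-index window [start_index, end_index] for Eq-style RMS.

    ``n`` is the number of samples entering the similarity statistic.
    """

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ConfigurationError(
                f"window must contain >= 2 samples, got "
                f"[{self.start_index}, {self.end_index}]"
            )

    @property
    def n(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)


def analysis_window(waveform: TensionWaveform, dt: float | None = None) -> AnalysisWindow:
    """Window from MVC to two-thirds of systole, floored to the sampling grid.

    Systole runs from mitral valve closure to mitral valve opening; the
    window endpoint is ``t_mvc + (2/3) (t_mvo - t_mvc)`` rounded *down* to
    the nearest output sample (both endpoints inclusive).
    """
    if waveform.t_mvo <= waveform.t_mvc:
        raise ConfigurationError(
            f"t_mvo={waveform.t_mvo} must exceed t_mvc={waveform.t_mvc}"
        )
    dt = waveform.dt if dt is None else dt
    start = int(round((waveform.t_mvc - waveform.t[0]) / dt))
    end_time = waveform.t_mvc + (2.0 / 3.0) * (waveform.t_mvo - waveform.t_mvc)
    end = int(math.floor((end_time - waveform.t[0]) / dt + 1e-9))
    return AnalysisWindow(start_index=start, end_index=end)


def similarity(p: np.ndarray, i: np.ndarray, window: AnalysisWindow) -> float:
    """RMS difference of two strain patterns over the analysis window.

    Symmetric and non-negative; zero iff the patterns agree on every window
    sample.  Both arrays must already live on the same sampling grid.
    """
    p = np.asarray(p, dtype=float)
    i = np.asarray(i, dtype=float)
    if p.shape != i.shape:
        raise AlignmentError(
            f"strain arrays have different lengths ({p.size} vs {i.size}); "
            "resample onto a common grid first"
        )
    if p.size <= window.end_index:
        raise AlignmentError(
            f"arrays of length {p.size} do not cover the window "
            f"ending at index {window.end_index}"
        )
    d = p[window.slice] - i[window.slice]
    return float(np.sqrt(np.mean(d * d)))


@dataclass
class Fingerprint:
    """Binary cohort image in parameter space, ``mask[con_index, at_index]``."""

    mask: np.ndarray            # (n_con, n_at) of 0/1
    grid: ParameterGrid
    source: str = ""
    threshold: float = DEFAULT_THRESHOLD
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.shape != (self.grid.n_con, self.grid.n_at):
            raise ConfigurationError(
                f"mask shape {mask.shape} does not match grid "
                f"({self.grid.n_con}, {self.grid.n_at})"
            )
        self.mask = mask.astype(bool)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def n_members(self) -> int:
        return int(self.mask.sum())

    def points(self) -> np.ndarray:
        """(row, col) = (con_index, at_index) coordinates of cohort members."""
        return np.argwhere(self.mask)


def build_fingerprint(
    reference: StrainTrace | np.ndarray,
    library: StrainLibrary,
    window: AnalysisWindow,
    threshold: float = DEFAULT_THRESHOLD,
    source: str = "",
) -> Fingerprint:
    """Mark every library cell whose strain is within ``threshold`` of the reference.

    The comparison is inclusive (``S <= threshold``).  An empty cohort is
    returned with a warning rather than raised: measured data may simply lie
    outside the model's coverage, and the caller decides how to proceed.
    """
    ref = reference.Ef if isinstance(reference, StrainTrace) else np.asarray(reference)
    if ref.shape[0] != library.traces.shape[1]:
        raise AlignmentError(
            "reference is not on the library time grid; resample first "
            f"({ref.shape[0]} vs {library.traces.shape[1]} samples)"
        )
    d = library.traces[:, window.slice] - ref[window.slice]
    sims = np.sqrt(np.mean(d * d, axis=1))
    mask_flat = sims <= threshold
    # flat rows are AT-major -> reshape (n_at, n_con), then image axes are
    # [con, at].
    mask = mask_flat.reshape(library.grid.n_at, library.grid.n_con).T
    fp = Fingerprint(
        mask=mask,
        grid=library.grid,
        source=source,
        threshold=threshold,
        meta={"n_members": int(mask.sum())},
    )
    if fp.is_empty:
        warnings.warn(
            f"empty cohort for source '{source}': no library pattern within "
            f"similarity {threshold}; raise the threshold or check the data",
            stacklevel=2,
        )
    return fp


def connected_components(fp: Fingerprint) -> Tuple[int, np.ndarray]:
    """Count and label the 8-connected components of a fingerprint mask."""
    labels, count = measure.label(
        fp.mask.astype(np.uint8), connectivity=2, return_num=True
    )
    return count, labels


def pairwise_similarity(library: StrainLibrary, window: AnalysisWindow) -> np.ndarray:
    """Dense (n_cells, n_cells) matrix of windowed RMS similarities.

    Row ``p`` is the similarity of library pattern ``p`` to every other
    pattern; the matrix is symmetric with a zero diagonal.
    """
    X = library.traces[:, window.slice]
    return cdist(X, X, metric="euclidean") / math.sqrt(window.n)


def build_synthetic_fingerprints(
    library: StrainLibrary,
    window: AnalysisWindow,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """All per-cell cohort masks as a boolean (n_cells, n_con, n_at) stack.

    Element ``[grid.cell_to_row(i, j)]`` is the mask of the fingerprint built
    from the library trace at cell ``(i, j)``; every mask contains its own
    cell (self-similarity is exactly zero).
    """
    S = pairwise_similarity(library, window)
    flat = S <= threshold                                  # (n_cells, n_cells)
    n_at, n_con = library.grid.n_at, library.grid.n_con
    return flat.reshape(-1, n_at, n_con).transpose(0, 2, 1)
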