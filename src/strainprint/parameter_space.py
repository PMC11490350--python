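"""The (AT, Con) parameter lattice and the library of simulated strains.

The inverse problem is solved by exhaustive scan: a 41 × 41 grid of
activation times (−100 … 100 ms, 5 ms step) and contractilities
(2 … 202 %, 5 % step) is simulated once, yielding 1,681 strain traces.
Every downstream object — fingerprints, proximity maps, extraction results
— lives on this lattice.

Conventions fixed here and relied on everywhere else:

* library rows are flattened **AT-major**: ``flat = at_index * n_con + con_index``;
* parameter-space images are indexed ``[con_index, at_index]`` (rows = Con
  ascending, columns = AT ascending), so rendered with ``origin='lower'``
  Con increases upward and AT rightward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .errors import ConfigurationError
from .model_core import (
    ModelConfig,
    TensionWaveform,
    simulate_strain_batch,
)

__all__ = ["ParameterGrid", "StrainLibrary", "default_grid", "build_library"]


@dataclass(frozen=True)
class ParameterGrid:
    """The rectangular (AT, Con) lattice scanned by the library build."""

    at_values: np.ndarray   # ms, ascending, uniform step
    con_values: np.ndarray  # %, ascending, uniform step

    def __post_init__(self) -> None:
        for name, v in (("at_values", self.at_values), ("con_values", self.con_values)):
            v = np.asarray(v, dtype=float)
            if v.ndim != 1 or v.size < 2:
                raise ConfigurationError(f"{name} must be a 1-D array with >= 2 values")
            steps = np.diff(v)
            if not np.allclose(steps, steps[0]):
                raise ConfigurationError(f"{name} must be uniformly spaced")
            object.__setattr__(self, name, v)

    @property
    def n_at(self) -> int:
        return self.at_values.size

    @property
    def n_con(self) -> int:
        return self.con_values.size

    @property
    def n_cells(self) -> int:
        return self.n_at * self.n_con

    def cell_to_row(self, at_index: int, con_index: int) -> int:
        """Flat library-row index of a grid cell (AT-major order)."""
        if not (0 <= at_index < self.n_at and 0 <= con_index < self.n_con):
            raise IndexError(f"cell ({at_index}, {con_index}) outside the grid")
        return at_index * self.n_con + con_index

    def row_to_cell(self, row: int) -> Tuple[int, int]:
        """Inverse of :meth:`cell_to_row`."""
        if not 0 <= row < self.n_cells:
            raise IndexError(f"row {row} outside 0..{self.n_cells - 1}")
        return divmod(row, self.n_con)

    def flat_at(self) -> np.ndarray:
        """AT value of every library row, in row order."""
        return np.repeat(self.at_values, self.n_con)

    def flat_con(self) -> np.ndarray:
        """Con value of every library row, in row order."""
        return np.tile(self.con_values, self.n_at)

    def to_dict(self) -> dict:
        return {
            "at_values": self.at_values.tolist(),
            "con_values": self.con_values.tolist(),
            "ordering": "at_major",
            "image_axes": "rows=con, cols=at",
        }


def default_grid() -> ParameterGrid:
    """The standard 41 × 41 scan: AT −100…100 ms and Con 2…202 % in 5-unit steps.

    Con never reaches 0 — the 2 % floor stands for total loss of
    contractility while keeping the model well-posed.
    """
    return ParameterGrid(
        at_values=np.arange(-100.0, 100.0 + 2.5, 5.0),
        con_values=np.arange(2.0, 202.0 + 2.5, 5.0),
    )


@dataclass
class StrainLibrary:
    """All simulated strain traces of a grid scan, one row per (AT, Con) cell.

    ``traces[grid.cell_to_row(i, j)]`` is bitwise-identical to the strain
    returned by :func:`strainprint.model_core.simulate_strain` at
    ``(at_values[i], con_values[j])`` with the same waveform and config.
    """

    grid: ParameterGrid
    t: np.ndarray                 # ms, shared output time grid
    traces: np.ndarray            # (n_cells, n_samples) strain matrix
    config_digest: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.traces.shape[0] != self.grid.n_cells:
            raise ConfigurationError(
                f"library has {self.traces.shape[0]} rows for a "
                f"{self.grid.n_cells}-cell grid"
            )
        if self.traces.shape[1] != self.t.size:
            raise ConfigurationError("trace length does not match the time grid")

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    def row(self, at_index: int, con_index: int) -> np.ndarray:
        """Strain trace of one grid cell."""
        return self.traces[self.grid.cell_to_row(at_index, con_index)]


def build_library(
    grid: ParameterGrid,
    waveform: TensionWaveform,
    config: ModelConfig,
) -> StrainLibrary:
    """Simulate every grid cell and assemble the strain library.

    The whole scan is one vectorised integration (the sarcomere dynamics are
    elementwise across cells), so the default 1,681-trace build takes seconds
    rather than minutes and is fully deterministic.
    """
    at_flat = grid.flat_at()
    con_flat = grid.flat_con()
    traces = simulate_strain_batch(at_flat, con_flat, waveform, config)
    t = config.t_mvc + config.dt_out * np.arange(traces.shape[1])
    return StrainLibrary(
        grid=grid,
        t=t,
        traces=traces,
        config_digest=config.digest(),
        meta={"grid": grid.to_dict()},
    )
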