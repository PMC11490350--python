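"""Pseudo-measurement strain traces for end-to-end pipeline testing.

The patient strain recordings the method targets (six longitudinal traces
around the left-ventricular circumference of a left-bundle-branch-block
heart) are not publicly deposited, so this module fabricates stand-ins:
model-generated traces at chosen (AT, Con) with additive i.i.d. Gaussian
noise.  Because the generator's ground truth is known, round-trip recovery
becomes an exact, assertable property — something real speckle-tracking
data can never provide.

The default noise sd (0.01 strain units) is one third of the 0.03 cohort
threshold, keeping a noisy trace inside its own cohort with high
probability; raise it toward or past 0.03 for stress tests.  An optional
low-frequency wobble (off by default) mimics the intermediate shortening /
stretching dynamics that real measurements show and the model lacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .model_core import (
    ModelConfig,
    StrainTrace,
    TensionWaveform,
    simulate_strain,
)

__all__ = ["NoiseModel", "make_measurement", "make_lbbb_like_set", "LBBB_SET_PARAMS"]

#: (AT ms, Con %) of the six LBBB-like segments: an early-activated septal
#: wall (negative AT), near-synchronous mid segments, and a late-activated
#: lateral wall, all at near-uniform contractility (conduction block shifts
#: timing, not contractile strength).
LBBB_SET_PARAMS: Tuple[Tuple[float, float], ...] = (
    (-60.0, 100.0),
    (-25.0, 95.0),
    (-5.0, 105.0),
    (0.0, 100.0),
    (5.0, 95.0),
    (20.0, 100.0),
)


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian per-sample strain noise, reproducible from a seed."""

    sd: float = 0.01      # strain units
    seed: int = 0
    wobble_amp: float = 0.0     # optional low-frequency model-misfit term
    wobble_period_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("noise sd must be non-negative")
        if self.wobble_amp < 0:
            raise ConfigurationError("wobble amplitude must be non-negative")


def make_measurement(
    at: float,
    con: float,
    noise: NoiseModel,
    waveform: TensionWaveform,
    config: ModelConfig,
    label: Optional[str] = None,
) -> StrainTrace:
    """Simulate (at, con) and corrupt it like a measurement.

    Noise is added per sample, then the trace is re-zeroed at the MVC sample
    (strain is by definition relative to MVC, and real post-processing pins
    it there too).  With ``sd = 0`` and ``wobble_amp = 0`` the output equals
    the noiseless simulation exactly.  Deterministic for a given seed.
    """
    clean = simulate_strain(at, con, waveform, config)
    rng = np.random.default_rng(noise.seed)
    Ef = clean.Ef.copy()
    if noise.wobble_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        Ef = Ef + noise.wobble_amp * np.sin(
            2.0 * np.pi * clean.t / noise.wobble_period_ms + phase
        )
    if noise.sd > 0:
        Ef = Ef + rng.normal(0.0, noise.sd, size=Ef.shape)
    i_mvc = int(round((config.t_mvc - clean.t[0]) / config.dt_out))
    Ef = Ef - Ef[i_mvc]
    return StrainTrace(
        t=clean.t, Ef=Ef, at=float(at), con=float(con), Ls0=clean.Ls0, label=label
    )


def make_lbbb_like_set(
    seed: int,
    waveform: TensionWaveform,
    config: ModelConfig,
    sd: float = 0.01,
    params: Sequence[Tuple[float, float]] = LBBB_SET_PARAMS,
) -> List[StrainTrace]:
    """Six noisy traces spanning early to late activation, labeled ``"1"``–``"6"``.

    The most early-activated member shortens immediately (negative initial
    strain slope); the most late-activated member is first stretched by the
    already-contracting remote wall (positive initial slope).
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(params))
    out = []
    for k, ((at, con), s) in enumerate(zip(params, seeds), start=1):
        noise = NoiseModel(sd=sd, seed=int(s % (2**31)))
        out.append(
            make_measurement(at, con, noise, waveform, config, label=str(k))
        )
    return out
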