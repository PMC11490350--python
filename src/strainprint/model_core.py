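"""Tension-driven Hill-type sarcomere model of myocardial fiber strain.

The simulated sarcomere is a three-element Hill arrangement: a contractile
element ``Cs`` in series with a spring ``Ks`` (the active branch), and a
parallel spring ``Kp`` representing passive tissue stiffness.  The sarcomere
is loaded by a prescribed external wall tension ``G(t)`` that is identical
for every simulation — the sarcomere is a vanishingly small patch of the
ventricular wall, so its own behaviour does not feed back on the load.  Two
local tissue properties are varied:

* **activation time (AT)** — the delay (ms) between contractile-element
  activation and the onset of the external tension pulse.  Negative values
  mean the patch activates early (before the wall loads it), positive values
  late.
* **contractility (Con)** — a percentage scaling of the contractile
  element's maximum isometric tension; 100% is baseline, 2% is essentially
  a passive patch.

The force balance is solved algebraically for the sarcomere length ``Ls``
given the contractile-element length ``Lc``::

    G(t) = Ks * (Ls - Lc) + Kp * (Ls - Ls_ref)

and the contractile element evolves with first-order, tension-imbalance
dynamics (a lumped force–velocity relation)::

    dLc/dt = -visc * (T_iso(t) - T_s),    T_s = Ks * (Ls - Lc)

where the isometric capacity ``T_iso`` combines the Con scaling, a smooth
raised-cosine activation twitch ``a(t)`` and a linear, floor-clipped length
dependence ``g(Lc)`` (less tension at shorter lengths).  Fiber strain is
reported relative to the sarcomere length at mitral valve closure (MVC)::

    Ef(t) = Ls(t) / Ls(t_mvc) - 1
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DomainError, NumericalError

__all__ = [
    "ModelConfig",
    "TensionWaveform",
    "StrainTrace",
    "generate_external_tension",
    "simulate_strain",
    "simulate_strain_batch",
    "fiber_strain",
]

#: Recommended activation-time range (ms); outside it the model still runs
#: but the parameter grid no longer brackets the value.
AT_RECOMMENDED = (-100.0, 100.0)


@dataclass(frozen=True)
class ModelConfig:
    """All fixed constants of the sarcomere model and its driving tension.

    Times are in ms, lengths in µm, tensions in units of the peak external
    tension (``G_peak = 1`` by default).  The defaults describe a heart-
    failure-like cycle: MVC at t = 0, MVO at 350 ms, cycle length 800 ms.
    """

    cycle_length: float = 800.0   # ms, one cardiac cycle
    t_mvc: float = 0.0            # ms, mitral valve closure; strain time origin
    t_mvo: float = 350.0          # ms, mitral valve opening; end of systole
    t_onset: float = 20.0         # ms, onset of the external tension rise
    dt_out: float = 2.0           # ms, output sampling step
    dt_int: float = 0.5           # ms, internal Euler sub-step
    Ks: float = 20.0              # series stiffness, tension / µm
    Kp: float = 4.0               # parallel stiffness, tension / µm
    Ls_ref: float = 2.0           # µm, slack/reference sarcomere length
    twitch_duration: float = 450.0  # ms, full duration of the activation twitch
    twitch_rise_frac: float = 0.25  # fraction of the twitch spent rising
    twitch_amp: float = 3.0       # peak isometric tension at Con = 100%
    length_dep_zero: float = 0.5  # fraction of Ls_ref at which active tension hits 0
    G_peak: float = 1.0           # peak external tension (defines the tension unit)
    G_baseline_frac: float = 0.02  # diastolic baseline as a fraction of G_peak
    G_rise_ms: float = 60.0       # smoothstep rise duration of G(t)
    G_decay_ms: float = 80.0      # raised-cosine decay duration of G(t)
    G_decay_end_after_mvo: float = 50.0  # decay finishes this long after MVO
    visc: float = 0.01            # µm / (ms · tension), contractile velocity constant
    warmup_ms: float = 250.0      # pre-MVC integration to settle early activations

    def __post_init__(self) -> None:
        if not (self.t_mvc < self.t_mvo <= self.t_mvc + self.cycle_length):
            raise ConfigurationError(
                f"need t_mvc < t_mvo <= t_mvc + cycle_length, got "
                f"t_mvc={self.t_mvc}, t_mvo={self.t_mvo}, cycle={self.cycle_length}"
            )
        if self.dt_out <= 0 or self.dt_int <= 0:
            raise ConfigurationError("dt_out and dt_int must be positive")
        ratio = self.dt_out / self.dt_int
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                f"dt_int={self.dt_int} must divide dt_out={self.dt_out}"
            )
        for name in ("Ks", "Kp", "visc", "twitch_duration", "Ls_ref", "G_peak"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (self.t_mvc <= self.t_onset < self.t_mvo):
            raise ConfigurationError(
                f"t_onset={self.t_onset} must satisfy t_mvc <= t_onset < t_mvo"
            )
        if not 0.0 <= self.length_dep_zero < 1.0:
            raise ConfigurationError("length_dep_zero must lie in [0, 1)")
        if not 0.0 < self.twitch_rise_frac < 1.0:
            raise ConfigurationError("twitch_rise_frac must lie in (0, 1)")

    @property
    def steps_per_output(self) -> int:
        return int(round(self.dt_out / self.dt_int))

    def digest(self) -> str:
        """Stable hex digest of the configuration, for provenance stamps."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class TensionWaveform:
    """The external tension pulse G(t) over one cycle, with valve markers.

    The waveform never depends on (AT, Con): it is generated once from a
    :class:`ModelConfig` and shared by every simulation.
    """

    t: np.ndarray       # ms, uniform grid with step dt_out
    G: np.ndarray       # tension, same length as t, >= 0
    t_mvc: float
    t_mvo: float
    t_onset: float

    def __post_init__(self) -> None:
        if self.t.shape != self.G.shape:
            raise ConfigurationError("t and G must have equal length")
        if np.any(self.G < 0):
            raise ConfigurationError("external tension must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class StrainTrace:
    """A fiber-strain time series on the 2 ms output grid.

    ``Ef`` is dimensionless strain relative to the sarcomere length at MVC,
    so the sample at ``t = t_mvc`` is exactly zero.  Traces generated by the
    model carry their (at, con) provenance; measured traces leave them None.
    """

    t: np.ndarray
    Ef: np.ndarray
    at: Optional[float] = None
    con: Optional[float] = None
    Ls0: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.t.shape != self.Ef.shape:
            raise ConfigurationError("t and Ef must have equal length")


def _tension_profile(t: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Evaluate the analytic G(t) pulse at arbitrary times.

    Baseline before onset, smoothstep rise over ``G_rise_ms``, plateau at
    ``G_peak``, raised-cosine decay of length ``G_decay_ms`` ending at
    ``t_mvo + G_decay_end_after_mvo``, baseline afterwards.
    """
    t = np.asarray(t, dtype=float)
    base = config.G_baseline_frac * config.G_peak
    u = np.clip((t - config.t_onset) / config.G_rise_ms, 0.0, 1.0)
    rise = u * u * (3.0 - 2.0 * u)
    decay_end = config.t_mvo + config.G_decay_end_after_mvo
    v = np.clip((t - (decay_end - config.G_decay_ms)) / config.G_decay_ms, 0.0, 1.0)
    decay = 0.5 * (1.0 + np.cos(np.pi * v))
    return base + (config.G_peak - base) * rise * decay


def generate_external_tension(config: ModelConfig) -> TensionWaveform:
    """Build the shared external tension waveform for one cardiac cycle.

    Deterministic: two calls with the same config return bitwise-identical
    arrays.
    """
    n = int(round(config.cycle_length / config.dt_out))
    t = config.t_mvc + config.dt_out * np.arange(n + 1)
    G = _tension_profile(t, config)
    return TensionWaveform(
        t=t, G=G, t_mvc=config.t_mvc, t_mvo=config.t_mvo, t_onset=config.t_onset
    )


def fiber_strain(Ls: np.ndarray, Ls0: float) -> np.ndarray:
    """Strain relative to the MVC sarcomere length: ``Ls / Ls0 - 1``."""
    if Ls0 <= 0:
        raise DomainError(f"reference length Ls0 must be positive, got {Ls0}")
    return np.asarray(Ls, dtype=float) / Ls0 - 1.0


def _twitch(tau: np.ndarray, duration: float, rise_frac: float) -> np.ndarray:
    """Smooth activation time course on [0, duration], zero outside.

    Raised-cosine rise over ``rise_frac * duration`` followed by a
    raised-cosine decay over the remainder — cardiac twitches develop
    tension faster than they relax.
    """
    t_rise = rise_frac * duration
    rising = (tau >= 0.0) & (tau < t_rise)
    falling = (tau >= t_rise) & (tau <= duration)
    up = 0.5 * (1.0 - np.cos(np.pi * tau / t_rise))
    down = 0.5 * (1.0 + np.cos(np.pi * (tau - t_rise) / (duration - t_rise)))
    return np.where(rising, up, 0.0) + np.where(falling, down, 0.0)


def simulate_strain_batch(
    at: np.ndarray,
    con: np.ndarray,
    waveform: TensionWaveform,
    config: ModelConfig,
    return_Ls0: bool = False,
) -> np.ndarray:
    """Integrate the sarcomere model for many (AT, Con) pairs at once.

    Returns an ``(n_pairs, n_samples)`` strain matrix on the output grid
    ``t_mvc .. t_mvc + cycle_length`` with step ``dt_out``.  The dynamics are
    elementwise across pairs, so a batch of one is bitwise-identical to the
    corresponding row of any larger batch.

    Integration runs from ``t_mvc - warmup_ms`` so that early activations
    (negative AT) develop tension before the strain origin; the initial
    condition is the passive equilibrium under the diastolic baseline load.
    """
    at = np.atleast_1d(np.asarray(at, dtype=float))
    con = np.atleast_1d(np.asarray(con, dtype=float))
    if at.shape != con.shape:
        raise DomainError("at and con must have matching shapes")
    if np.any(con <= 0):
        bad = con[con <= 0]
        raise DomainError(f"contractility must be positive, got {bad[:5]}")
    lo, hi = AT_RECOMMENDED
    if np.any((at < lo) | (at > hi)):
        warnings.warn(
            f"activation time outside the recommended [{lo:g}, {hi:g}] ms range; "
            "the default parameter grid will not bracket it",
            stacklevel=2,
        )

    dt = config.dt_int
    n_fine = int(round((config.warmup_ms + config.cycle_length) / dt))
    t_fine = (config.t_mvc - config.warmup_ms) + dt * np.arange(n_fine + 1)
    # Clamped linear interpolation of the shared waveform; before the cycle
    # the pulse sits at its diastolic baseline (the waveform's first sample).
    G_fine = np.interp(t_fine, waveform.t, waveform.G)

    Ks, Kp = config.Ks, config.Kp
    Ls_ref = config.Ls_ref
    inv_sum = 1.0 / (Ks + Kp)
    z = config.length_dep_zero
    t_act = config.t_onset + at            # absolute activation instant per pair
    con_scale = (con / 100.0) * config.twitch_amp

    steps_per_out = config.steps_per_output
    n_out = n_fine - int(round(config.warmup_ms / dt))
    first_out = n_fine - n_out             # fine index of t_mvc
    Ls_out = np.empty((at.size, n_out // steps_per_out + 1), dtype=float)

    # Passive equilibrium under the baseline load: T_s = 0, G = Kp (Ls - Ls_ref).
    Lc = np.full(at.size, Ls_ref + G_fine[0] / Kp, dtype=float)

    out_col = 0
    for k in range(n_fine + 1):
        Ls = (G_fine[k] + Ks * Lc + Kp * Ls_ref) * inv_sum
        if k >= first_out and (k - first_out) % steps_per_out == 0:
            Ls_out[:, out_col] = Ls
            out_col += 1
        Ts = Ks * (Ls - Lc)
        a = _twitch(t_fine[k] - t_act, config.twitch_duration, config.twitch_rise_frac)
        g = np.maximum(0.0, (Lc / Ls_ref - z) / (1.0 - z))
        T_iso = con_scale * a * g
        Lc = Lc - dt * config.visc * (T_iso - Ts)

    if not np.all(np.isfinite(Ls_out)):
        bad = np.argwhere(~np.isfinite(Ls_out).all(axis=1)).ravel()
        raise NumericalError(
            f"non-finite sarcomere length for pair indices {bad[:10].tolist()}; "
            "check visc/dt_int stability"
        )
    Ls0 = Ls_out[:, 0].copy()
    Ef = Ls_out / Ls0[:, None] - 1.0
    if return_Ls0:
        return Ef, Ls0
    return Ef


def simulate_strain(
    at: float,
    con: float,
    waveform: TensionWaveform,
    config: ModelConfig,
) -> StrainTrace:
    """Simulate one fiber-strain trace for a single (AT, Con) pair.

    ``at`` is in ms (negative = early activation), ``con`` in percent of
    baseline contractility.  The returned trace is zero at the MVC sample by
    construction.
    """
    Ef, Ls0 = simulate_strain_batch(
        np.array([at], dtype=float),
        np.array([con], dtype=float),
        waveform,
        config,
        return_Ls0=True,
    )
    t = config.t_mvc + config.dt_out * np.arange(Ef.shape[1])
    return StrainTrace(
        t=t, Ef=Ef[0], at=float(at), con=float(con), Ls0=float(Ls0[0])
    )
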