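"""Render protonation dwell events into sampled voltage traces.

The measured signal of one residue window is the sum of

* the telegraph signal of the free terminal carboxyl group,
* (when side chains are free) one telegraph signal per side-chain-bearing
  residue still attached to the anchored peptide, and
* 1/f (pink) noise, normalised to unit RMS.

All voltages are expressed in units of the noise RMS, so the initial
signal-to-noise ratio S is simply the mean on-amplitude at the anchor point.
A protonation event at residue distance ``d`` from the anchor is attenuated by
the electrolyte shielding factor ``exp(-chi * f(d))`` with ``f(d) = sqrt(d)``
by default (worm-like-chain distance scaling).  On top of shielding, the
amplitude of every dwell event carries a normal perturbation (sd ``sigma``,
0.1 by default) modelling slow conformational motion of the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .kinetics import (
    SolutionConditions,
    AminoAcidSpec,
    default_pka_table,
    rates,
    sample_dwell_events,
)

__all__ = [
    "ShieldingModel",
    "NoiseSpec",
    "TelegraphEvents",
    "Trace",
    "event_amplitude",
    "pink_noise",
    "render_trace",
    "simulate_residue_measurement",
]

DEFAULT_SAMPLE_RATE = 1e7  # Hz


def _sqrt_distance(d):
    return np.sqrt(d)


@dataclass(frozen=True)
class ShieldingModel:
    """Exponential signal attenuation with distance from the anchor point.

    ``attenuation(d) = exp(-chi * distance_map(d))`` where ``d`` is the
    1-based residue index counted from the anchor and ``distance_map`` a
    monotone spatial-distance proxy (default: square root of the residue
    count).
    """

    chi: float = 0.2
    distance_map: Callable[[float], float] = _sqrt_distance

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise ValueError("chi must be non-negative")

    def attenuation(self, d) -> float:
        return np.exp(-self.chi * self.distance_map(d))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model of one measurement.

    ``snr`` is the initial signal-to-noise ratio S: the mean on-amplitude at
    the anchor in units of the noise RMS.  ``pink=False`` suppresses the 1/f
    noise entirely (amplitudes keep the same scale).  ``sigma_amp`` is the
    per-dwell-event amplitude perturbation sd.
    """

    snr: float = 10.0
    pink: bool = True
    n_sources: int = 16
    sigma_amp: float = 0.1

    def __post_init__(self) -> None:
        if not (self.snr > 0):
            raise ValueError("snr must be positive")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.sigma_amp < 0:
            raise ValueError("sigma_amp must be non-negative")


@dataclass(frozen=True)
class TelegraphEvents:
    """Dwell events of one protonation site, ready for rasterisation.

    ``durations`` and ``amplitudes`` are parallel arrays over alternating
    dwell events starting from ``first_state_on``; off events have amplitude
    0.  ``site_distance`` is the residue index from the anchor (>= 1).
    """

    durations: np.ndarray
    amplitudes: np.ndarray
    first_state_on: bool
    site_distance: int

    def __post_init__(self) -> None:
        if len(self.durations) != len(self.amplitudes):
            raise ValueError("durations and amplitudes must be parallel")
        if self.site_distance < 1:
            raise ValueError("site_distance must be >= 1")

    @property
    def duration(self) -> float:
        return float(self.durations.sum())


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled voltage trace (units: noise RMS = 1)."""

    sample_rate: float
    values: np.ndarray

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


def event_amplitude(
    d: int,
    shield: ShieldingModel,
    snr: float,
    sigma: float,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw on-state amplitude(s) for a site at residue distance ``d``:
    ``S * Normal(exp(-chi f(d)), sigma**2)``."""
    if d < 1:
        raise ValueError("residue distance d must be >= 1")
    rng = np.random.default_rng(rng)
    mean = shield.attenuation(d)
    if sigma == 0:
        draw = mean if size is None else np.full(size, mean)
    else:
        draw = rng.normal(mean, sigma, size=size)
    return snr * draw


def pink_noise(
    n_samples: int,
    n_sources: int = 16,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Voss-McCartney 1/f noise, rescaled to empirical RMS 1.

    Source ``k`` (k = 0..n_sources-1) is a white Gaussian sequence held
    constant over blocks of ``2**k`` samples; the sum of all sources has an
    approximately 1/f power spectrum over the covered frequency decades.  With
    ``n_sources=1`` the output degenerates to white noise.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng)
    # Pad to the largest hold length so every source is a broadcast add over a
    # (n_blocks, hold) view; float32 halves the memory traffic.
    max_hold = 2 ** (n_sources - 1)
    n_pad = -(-n_samples // max_hold) * max_hold
    total = rng.standard_normal(n_pad, dtype=np.float32)
    for k in range(1, n_sources):
        hold = 2**k
        n_blocks = n_pad // hold
        total.reshape(n_blocks, hold)[...] += rng.standard_normal(
            n_blocks, dtype=np.float32
        )[:, None]
    total = total[:n_samples]
    rms = float(np.sqrt(np.mean(np.square(total, dtype=np.float64))))
    if rms > 0:
        total = total / np.float32(rms)
    return total


def _rasterize(events: TelegraphEvents, n_samples: int, rate: float) -> np.ndarray:
    """Sample-instant lookup: sample i (at time i/rate) takes the amplitude of
    the event covering it; ties at an event boundary take the newer event.
    Events shorter than the sampling interval can be missed entirely."""
    # Event k covers sample indices [ceil(end[k-1]*rate), ceil(end[k]*rate));
    # a sample falling exactly on a boundary belongs to the newer event.
    bounds = np.ceil(np.cumsum(events.durations) * rate).astype(np.int64)
    np.clip(bounds, 0, n_samples, out=bounds)
    counts = np.diff(bounds, prepend=0)
    raster = np.repeat(events.amplitudes.astype(np.float32), counts)
    if len(raster) < n_samples:  # trailing boundary rounding
        raster = np.append(raster, np.full(n_samples - len(raster), raster[-1]))
    return raster


def render_trace(
    event_sets: Sequence[TelegraphEvents],
    duration: float,
    rate: float = DEFAULT_SAMPLE_RATE,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | int | None = None,
) -> Trace:
    """Rasterise and sum telegraph event sets and add unit-RMS pink noise."""
    if not (rate > 0):
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(rng)
    n_samples = int(round(duration * rate))
    values = np.zeros(n_samples, dtype=np.float32)
    for ev in event_sets:
        if ev.duration < duration * (1 - 1e-9):
            raise ValueError("event set does not span the trace duration")
        values += _rasterize(ev, n_samples, rate)
    if noise.pink:
        values += pink_noise(n_samples, noise.n_sources, rng)
    return Trace(sample_rate=rate, values=values)


def _site_events(
    pka: float,
    d: int,
    cond: SolutionConditions,
    shield: ShieldingModel,
    noise: NoiseSpec,
    duration: float,
    rng: np.random.Generator,
) -> TelegraphEvents:
    kin = rates(pka, cond)
    dwells = sample_dwell_events(kin, duration, initial_state="stationary", rng=rng)
    n = len(dwells.durations)
    amplitudes = np.zeros(n)
    on = dwells.states_on
    n_on = int(on.sum())
    if n_on:
        amplitudes[on] = event_amplitude(
            d, shield, noise.snr, noise.sigma_amp, rng, size=n_on
        )
    return TelegraphEvents(
        durations=dwells.durations,
        amplitudes=amplitudes,
        first_state_on=dwells.first_state_on,
        site_distance=d,
    )


def simulate_residue_measurement(
    peptide: str,
    terminal_index: int,
    cond: SolutionConditions,
    shield: ShieldingModel = ShieldingModel(),
    noise: NoiseSpec = NoiseSpec(),
    duration: float = 0.1,
    rate: float = DEFAULT_SAMPLE_RATE,
    side_chains: str = "free",
    rng: np.random.Generator | int | None = None,
    pka_table: dict[str, AminoAcidSpec] | None = None,
) -> Trace:
    """Simulate one measurement window of an anchored peptide.

    The peptide is anchored by its N-terminal residue; the free carboxyl group
    of the current C-terminal residue (at residue distance ``terminal_index``
    from the anchor) produces the primary telegraph signal.  With
    ``side_chains="free"``, every residue of the remaining peptide
    (positions 1..terminal_index) that bears a protonatable side chain
    contributes its own telegraph signal at its own distance; with
    ``"blocked"`` side chains are chemically silenced and only the terminal
    signal is rendered.
    """
    if terminal_index < 1 or terminal_index > len(peptide):
        raise ValueError("terminal_index must be within the peptide")
    if side_chains not in ("free", "blocked"):
        raise ValueError(f"invalid side_chains mode: {side_chains!r}")
    table = pka_table if pka_table is not None else default_pka_table()
    rng = np.random.default_rng(rng)

    terminal_code = peptide[terminal_index - 1]
    try:
        terminal_spec = table[terminal_code]
    except KeyError:
        raise ValueError(f"unknown residue code: {terminal_code!r}") from None

    event_sets = [
        _site_events(
            terminal_spec.carboxyl_pka, terminal_index, cond, shield, noise, duration, rng
        )
    ]
    if side_chains == "free":
        for pos in range(1, terminal_index + 1):
            code = peptide[pos - 1]
            try:
                spec = table[code]
            except KeyError:
                raise ValueError(f"unknown residue code: {code!r}") from None
            if spec.sidechain_pka is not None:
                event_sets.append(
                    _site_events(
                        spec.sidechain_pka, pos, cond, shield, noise, duration, rng
                    )
                )
    return render_trace(event_sets, duration, rate, noise, rng)
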