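"""Two-state protonation kinetics.

A protonatable site (a terminal carboxyl/amine group or an acidic/basic side
chain) alternates between a protonated *on*-state and a deprotonated
*off*-state.  The transition rates follow from the solution pH and the site's
pKa: the off->on (reprotonation) rate is a fixed attempt rate ``k_on`` (1 MHz
by default, i.e. an expected off-time of 1 us) and the on->off (deprotonation)
rate is ``k_off = k_on * 10**(pH - pKa)``, so that at ``pH == pKa`` the site is
protonated half of the time.  Dwell times in either state are exponential with
the rate of the transition leaving that state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "AminoAcidSpec",
    "SolutionConditions",
    "KineticRates",
    "DwellSequence",
    "load_pka_table",
    "default_pka_table",
    "rates",
    "expected_on_fraction",
    "sample_dwell_events",
]

#: Residues whose side chain carries a protonatable group.
SIDECHAIN_RESIDUES = frozenset("CDEHKRY")

#: The 20 canonical one-letter residue codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AminoAcidSpec:
    """pKa values of one amino acid's protonatable groups."""

    code: str
    name: str
    carboxyl_pka: float
    amine_pka: float
    sidechain_pka: float | None = None

    def __post_init__(self) -> None:
        if self.code not in CANONICAL_RESIDUES:
            raise ValueError(f"not a canonical residue code: {self.code!r}")
        for value in (self.carboxyl_pka, self.amine_pka):
            if not (value > 0):
                raise ValueError("pKa values must be strictly positive")
        if self.sidechain_pka is not None and not (self.sidechain_pka > 0):
            raise ValueError("pKa values must be strictly positive")


@dataclass(frozen=True)
class SolutionConditions:
    """Solution pH together with the base reprotonation attempt rate.

    ``base_on_rate`` is the off->on transition rate in Hz; changing it merely
    rescales time, so it is rarely touched.
    """

    ph: float
    base_on_rate: float = 1e6

    def __post_init__(self) -> None:
        if not math.isfinite(self.ph):
            raise ValueError("ph must be finite")
        if not (self.base_on_rate > 0):
            raise ValueError("base_on_rate must be positive")


@dataclass(frozen=True)
class KineticRates:
    """Transition rates (Hz) of a two-state protonation site."""

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if not (self.k_on > 0 and self.k_off > 0):
            raise ValueError("rates must be strictly positive")

    @property
    def stationary_on_fraction(self) -> float:
        return self.k_on / (self.k_on + self.k_off)


@dataclass(frozen=True)
class DwellSequence:
    """Alternating dwell events of one site over a measurement window.

    ``durations[i]`` is the length (s) of the i-th dwell; states alternate
    starting from ``first_state_on``.  The final dwell is truncated at the
    window boundary so the durations sum to the window length.
    """

    first_state_on: bool
    durations: np.ndarray

    @property
    def states_on(self) -> np.ndarray:
        """Boolean on/off state per event."""
        n = len(self.durations)
        states = np.zeros(n, dtype=bool)
        states[0::2] = self.first_state_on
        states[1::2] = not self.first_state_on
        return states

    def total_on_time(self) -> float:
        return float(self.durations[self.states_on].sum())


def load_pka_table(path: str | Path | None = None) -> dict[str, AminoAcidSpec]:
    """Load a pKa table from TSV (columns: code, name, carboxyl_pka,
    amine_pka, sidechain_pka).  Without a path, the packaged default table of
    the 20 standard residues is used."""
    if path is None:
        text = (
            resources.files("protonseq.data").joinpath("pka_table.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    table: dict[str, AminoAcidSpec] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:
        fields = line.split("\t")
        code, name, carboxyl, amine = fields[:4]
        sidechain = None
        if len(fields) > 4 and fields[4].strip():
            sidechain = float(fields[4])
        table[code] = AminoAcidSpec(code, name, float(carboxyl), float(amine), sidechain)
    return table


_DEFAULT_TABLE: dict[str, AminoAcidSpec] | None = None


def default_pka_table() -> dict[str, AminoAcidSpec]:
    """The packaged pKa table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_pka_table()
    return _DEFAULT_TABLE


def rates(pka: float, cond: SolutionConditions) -> KineticRates:
    """Transition rates of a site with the given pKa in the given solution.

    ``k_on = base_on_rate`` and ``k_off = base_on_rate * 10**(pH - pKa)``.
    """
    if not math.isfinite(pka):
        raise ValueError("pka must be finite")
    k_on = cond.base_on_rate
    k_off = cond.base_on_rate * 10.0 ** (cond.ph - pka)
    return KineticRates(k_on=k_on, k_off=k_off)


def expected_on_fraction(pka: float, cond: SolutionConditions) -> float:
    """Stationary protonated fraction ``k_on / (k_on + k_off)``.

    Equals ``1 / (1 + 10**(pH - pKa))`` — the Henderson-Hasselbalch fraction
    of the protonated species.
    """
    if not math.isfinite(pka):
        raise ValueError("pka must be finite")
    return 1.0 / (1.0 + 10.0 ** (cond.ph - pka))


def sample_dwell_events(
    kin: KineticRates,
    duration: float,
    initial_state: str = "stationary",
    rng: np.random.Generator | int | None = None,
) -> DwellSequence:
    """Draw alternating exponential dwell times covering ``duration`` seconds.

    On-times are Exp(k_off) and off-times Exp(k_on).  With
    ``initial_state="stationary"`` the first state is Bernoulli with the
    stationary on-probability; ``"on"``/``"off"`` force it.  The final dwell
    is truncated at the window boundary.
    """
    if not (duration > 0):
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)
    if initial_state == "stationary":
        first_on = bool(rng.random() < kin.stationary_on_fraction)
    elif initial_state in ("on", "off"):
        first_on = initial_state == "on"
    else:
        raise ValueError(f"invalid initial_state: {initial_state!r}")

    # Draw in batches sized from the expected event count until the window is
    # covered; exponential means are 1/k_off (on) and 1/k_on (off).
    mean_cycle = 1.0 / kin.k_on + 1.0 / kin.k_off
    chunks: list[np.ndarray] = []
    covered = 0.0
    start_on = first_on
    while covered < duration:
        remaining = duration - covered
        est = 2 * remaining / mean_cycle + 16
        n = int(min(est, 5e7))
        if n % 2:
            n += 1
        scales = np.empty(n)
        if start_on:
            scales[0::2] = 1.0 / kin.k_off
            scales[1::2] = 1.0 / kin.k_on
        else:
            scales[0::2] = 1.0 / kin.k_on
            scales[1::2] = 1.0 / kin.k_off
        draws = rng.exponential(scales)
        chunks.append(draws)
        covered += float(draws.sum())
        start_on = first_on if (sum(len(c) for c in chunks) % 2 == 0) else not first_on

    durations = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    ends = np.cumsum(durations)
    last = int(np.searchsorted(ends, duration, side="left"))
    durations = durations[: last + 1].copy()
    prev_end = ends[last - 1] if last > 0 else 0.0
    durations[last] = duration - prev_end
    return DwellSequence(first_state_on=first_on, durations=durations)
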