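"""Equivalent-circuit model of a finger-pair impedance spectrum.

A finger pair placed across two fingertip electrodes is modelled as four
"Z blocks" in a fixed topology.  Each block is the classic three-element
tissue motif: a series resistance ``Rs`` (extracellular fluid, plus skin
resistance for the electrode-interface blocks) in series with a parallel
``Rp``-``Cp`` branch (intracellular fluid resistance shunted by the
membrane capacitance)::

    Z(f) = Rs + Rp / (1 + j * 2*pi*f * Rp * Cp)

The pair circuit wires Z1 (electrode/epidermis, source side) and Z4
(electrode/epidermis, drain side) in series with an interior section in
which Z2 (dermis) and Z3 (sweat glands and ducts) are in parallel:

    Z_total(f) = Z1(f) + (Z2(f) || Z3(f)) + Z4(f)

The observable is the magnitude ``|Z_total|`` on a fixed frequency grid,
matching hardware that records RMS voltage (no phase).

A uniform physiological state change (temperature, hydration, blood flow)
is modelled as every resistance scaling by ``s`` and every capacitance by
``1/s``: all time constants ``Rp*Cp`` are preserved, so the whole spectrum
scales by exactly ``s`` and ratios between two pairs' spectra are exactly
invariant.  That invariance is the premise of the ratiometric features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZBlockParams",
    "PairCircuit",
    "FrequencyGrid",
    "StateScale",
    "ImpedanceSpectrum",
    "default_grid",
    "z_block_impedance",
    "pair_impedance",
    "scale_state",
]


@dataclass(frozen=True)
class ZBlockParams:
    """One tissue compartment: Rs in series with Rp || Cp.

    Parameters are in SI units: ``rs`` and ``rp`` in ohms, ``cp`` in farads.
    All three must be strictly positive.
    """

    rs: float
    rp: float
    cp: float

    def __post_init__(self) -> None:
        for name in ("rs", "rp", "cp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"ZBlockParams.{name} must be finite and > 0, got {v!r}"
                )


@dataclass(frozen=True)
class PairCircuit:
    """The four Z blocks of one finger pair.

    ``z1``/``z4`` are the electrode/epidermis interfaces on the current
    source and drain side; ``z2`` is the dermis path and ``z3`` the sweat
    glands and ducts that shunt it.
    """

    z1: ZBlockParams
    z2: ZBlockParams
    z3: ZBlockParams
    z4: ZBlockParams

    @property
    def blocks(self) -> tuple[ZBlockParams, ...]:
        return (self.z1, self.z2, self.z3, self.z4)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing measurement frequencies in hertz."""

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size == 0:
            raise ValueError("FrequencyGrid must contain at least one frequency")
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", tuple(float(x) for x in f))

    def __len__(self) -> int:
        return len(self.frequencies)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


def default_grid() -> FrequencyGrid:
    """The 25-point measurement grid: 20 kHz to 500 kHz in 20 kHz steps."""
    return FrequencyGrid(tuple(float(f) for f in range(20_000, 500_001, 20_000)))


@dataclass(frozen=True)
class StateScale:
    """Dimensionless multiplicative physiological-state factor, > 0."""

    s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.s) or self.s <= 0:
            raise ValueError(f"StateScale.s must be finite and > 0, got {self.s!r}")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """|Z| magnitudes (ohms) for one finger pair on a frequency grid."""

    grid: FrequencyGrid
    magnitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        if m.size != len(self.grid):
            raise ValueError(
                f"expected {len(self.grid)} magnitudes, got {m.size}"
            )
        if not np.all(np.isfinite(m)) or np.any(m <= 0):
            raise ValueError("magnitudes must be finite and > 0")
        object.__setattr__(self, "magnitudes", tuple(float(x) for x in m))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.magnitudes, dtype=float)


def z_block_impedance(params: ZBlockParams, f) -> complex | np.ndarray:
    """Complex impedance of one Z block at frequency ``f`` (Hz).

    Accepts a scalar or an array of frequencies; f must be >= 0.  At DC the
    capacitor is open (Z = Rs + Rp); as f -> inf it shorts (Z -> Rs).
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("frequency must be >= 0")
    z = params.rs + params.rp / (1.0 + 1j * 2.0 * np.pi * f_arr * params.rp * params.cp)
    if np.isscalar(f) or f_arr.ndim == 0:
        return complex(z)
    return z


def _complex_pair_impedance(circuit: PairCircuit, f: np.ndarray) -> np.ndarray:
    z1 = z_block_impedance(circuit.z1, f)
    z2 = z_block_impedance(circuit.z2, f)
    z3 = z_block_impedance(circuit.z3, f)
    z4 = z_block_impedance(circuit.z4, f)
    return z1 + (z2 * z3) / (z2 + z3) + z4


def pair_impedance(circuit: PairCircuit, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Magnitude spectrum |Z1 + (Z2 || Z3) + Z4| on ``grid``."""
    f = grid.as_array()
    z = _complex_pair_impedance(circuit, f)
    return ImpedanceSpectrum(grid=grid, magnitudes=tuple(np.abs(z)))


def scale_state(circuit: PairCircuit, scale: StateScale) -> PairCircuit:
    """Apply a uniform physiological-state change to every block.

    Each Rs and Rp is multiplied by ``scale.s`` and each Cp divided by it,
    so every ``Rp*Cp`` time constant is preserved and the complex spectrum
    of the scaled circuit is exactly ``s`` times the original at every
    frequency.
    """
    s = scale.s

    def _scale(b: ZBlockParams) -> ZBlockParams:
        return ZBlockParams(rs=b.rs * s, rp=b.rp * s, cp=b.cp / s)

    return PairCircuit(
        z1=_scale(circuit.z1),
        z2=_scale(circuit.z2),
        z3=_scale(circuit.z3),
        z4=_scale(circuit.z4),
    )
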