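"""Synthetic multi-subject, multi-session finger-impedance cohorts.

Real finger-impedance datasets of this geometry are not publicly
deposited, so this module generates labelled cohorts with the statistical
structure the ratiometric method assumes and exploits:

* stable per-subject anatomy — each subject owns a fixed set of circuit
  parameters for the five fingers, drawn log-normally around configurable
  medians;
* session-level common-mode drift — each (subject, session) draws one
  multiplicative state scale, shared by all ten finger pairs, combining a
  log-normal day-to-day factor with a linear inverse temperature term
  (warmer hand -> lower impedance);
* small per-measurement multiplicative noise — independent log-normal
  noise per finger pair per placement, standing in for re-placement and
  contact variation.

Finger pairs share fingers: pair (1,2) and pair (1,3) reuse finger 1's
half-circuit exactly, which induces realistic correlation among the ten
pair spectra of one hand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import (
    FrequencyGrid,
    ImpedanceSpectrum,
    PairCircuit,
    StateScale,
    ZBlockParams,
    default_grid,
    pair_impedance,
    scale_state,
)

__all__ = [
    "FingerPair",
    "ALL_PAIRS",
    "FingerHalf",
    "SubjectTemplate",
    "SessionContext",
    "MeasurementRecord",
    "SpectraDataset",
    "CohortConfig",
    "sample_subject",
    "pair_circuit_from_template",
    "session_scale",
    "generate_dataset",
]


@dataclass(frozen=True, order=True)
class FingerPair:
    """An unordered pair of fingers, indexed 1 (thumb) to 5 (little finger)."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if not (1 <= self.a < self.b <= 5):
            raise ValueError(f"require 1 <= a < b <= 5, got ({self.a}, {self.b})")

    def __str__(self) -> str:
        return f"({self.a},{self.b})"


#: The 10 finger pairs in canonical (lexicographic) order.
ALL_PAIRS: tuple[FingerPair, ...] = tuple(
    FingerPair(a, b) for a, b in itertools.combinations(range(1, 6), 2)
)


@dataclass(frozen=True)
class FingerHalf:
    """One finger's contribution to any pair circuit it participates in."""

    epidermis: ZBlockParams
    dermis: ZBlockParams
    sweat: ZBlockParams


@dataclass(frozen=True)
class SubjectTemplate:
    """A subject's stable anatomy: five finger half-circuits + body resistance."""

    subject_id: str
    fingers: tuple[FingerHalf, ...]
    body_resistance: float

    def __post_init__(self) -> None:
        if len(self.fingers) != 5:
            raise ValueError("a SubjectTemplate needs exactly 5 fingers")
        if self.body_resistance <= 0:
            raise ValueError("body_resistance must be > 0")


@dataclass(frozen=True)
class SessionContext:
    """One measurement session: its drift factor and hand temperature."""

    session_id: str
    temperature: float  # degrees Celsius
    drift: StateScale
    gamma: float = 0.02  # fractional impedance change per degC below T_ref
    t_ref: float = 33.0  # reference hand temperature, degC

    def __post_init__(self) -> None:
        if not (25.0 <= self.temperature <= 40.0):
            raise ValueError(
                f"hand temperature {self.temperature} outside plausible range [25, 40]"
            )
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class MeasurementRecord:
    """One placement of a hand: ten pair spectra plus metadata."""

    subject_id: str
    session_id: str
    repeat_index: int
    temperature: float
    spectra: dict[FingerPair, ImpedanceSpectrum]

    def __post_init__(self) -> None:
        if set(self.spectra) != set(ALL_PAIRS):
            raise ValueError("a record must contain exactly the 10 finger pairs")
        grids = {s.grid for s in self.spectra.values()}
        if len(grids) != 1:
            raise ValueError("all spectra in a record must share one grid")

    @property
    def grid(self) -> FrequencyGrid:
        return next(iter(self.spectra.values())).grid

    def scaled(self, s: float) -> "MeasurementRecord":
        """The same record with every magnitude multiplied by ``s``."""
        if s <= 0:
            raise ValueError("scale must be > 0")
        spectra = {
            p: ImpedanceSpectrum(sp.grid, tuple(m * s for m in sp.magnitudes))
            for p, sp in self.spectra.items()
        }
        return replace(self, spectra=spectra)


@dataclass(frozen=True)
class SpectraDataset:
    """A labelled collection of measurement records on one frequency grid."""

    records: tuple[MeasurementRecord, ...]
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        keys = [(r.subject_id, r.session_id, r.repeat_index) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (subject, session, repeat) keys")
        for r in self.records:
            if r.grid != self.grid:
                raise ValueError("all records must share the dataset grid")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(sorted({r.subject_id for r in self.records}))

    def subset(self, predicate) -> "SpectraDataset":
        return SpectraDataset(
            records=tuple(r for r in self.records if predicate(r)), grid=self.grid
        )


def _positive(name: str, value: float) -> float:
    if value <= 0:
        raise ValueError(f"{name} must be > 0, got {value}")
    return value


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters: component medians, dispersions, drift and noise.

    Medians are order-of-magnitude plausible for fingertip tissue at
    20-500 kHz: a high-impedance epidermis/electrode interface, a lower
    dermis path, and a sweat-duct shunt.  ``subject_sigma`` is the
    log-normal sigma of inter-subject component variation (0.2 ~ 20% CV);
    ``drift_sigma`` the log-normal sigma of the per-session common-mode
    factor; ``noise_sigma`` the per-pair per-placement multiplicative
    measurement noise.  ``gamma`` is the linear inverse temperature
    coefficient (fraction per degC) around ``t_ref``.
    ``drift_heterogeneity`` optionally breaks the common-mode assumption
    by giving each pair an extra independent log-normal drift of that
    sigma; 0 keeps drift purely common-mode.
    """

    epidermis_median: ZBlockParams = ZBlockParams(rs=300.0, rp=5000.0, cp=30e-9)
    dermis_median: ZBlockParams = ZBlockParams(rs=150.0, rp=1000.0, cp=10e-9)
    sweat_median: ZBlockParams = ZBlockParams(rs=500.0, rp=2000.0, cp=5e-9)
    body_resistance_median: float = 100.0
    subject_sigma: float = 0.2
    drift_sigma: float = 0.2
    noise_sigma: float = 0.02
    gamma: float = 0.02
    t_ref: float = 33.0
    temperature_range: tuple[float, float] = (29.0, 37.0)
    drift_heterogeneity: float = 0.0
    grid: FrequencyGrid = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        for name in ("subject_sigma", "drift_sigma", "noise_sigma",
                     "gamma", "drift_heterogeneity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        _positive("body_resistance_median", self.body_resistance_median)
        lo, hi = self.temperature_range
        if not (25.0 <= lo <= hi <= 40.0):
            raise ValueError("temperature_range must lie within [25, 40]")


def _sample_block(
    rng: np.random.Generator, median: ZBlockParams, sigma: float
) -> ZBlockParams:
    def draw(m: float) -> float:
        return float(m * np.exp(rng.normal(0.0, sigma))) if sigma > 0 else float(m)

    return ZBlockParams(rs=draw(median.rs), rp=draw(median.rp), cp=draw(median.cp))


def sample_subject(
    seed_or_rng: int | np.random.Generator,
    config: CohortConfig | None = None,
    subject_id: str = "S1",
) -> SubjectTemplate:
    """Draw one subject's anatomy log-normally around the configured medians.

    Deterministic given an integer seed; with ``subject_sigma == 0`` every
    subject equals the medians exactly.
    """
    config = config or CohortConfig()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    sigma = config.subject_sigma
    fingers = tuple(
        FingerHalf(
            epidermis=_sample_block(rng, config.epidermis_median, sigma),
            dermis=_sample_block(rng, config.dermis_median, sigma),
            sweat=_sample_block(rng, config.sweat_median, sigma),
        )
        for _ in range(5)
    )
    body = (
        float(config.body_resistance_median * np.exp(rng.normal(0.0, sigma)))
        if sigma > 0
        else config.body_resistance_median
    )
    return SubjectTemplate(subject_id=subject_id, fingers=fingers, body_resistance=body)


def _series_blocks(a: ZBlockParams, b: ZBlockParams, extra_rs: float = 0.0) -> ZBlockParams:
    # Two blocks in series collapsed to one: series resistances add, the
    # parallel branches combine with Rp summed and Cp in series.
    return ZBlockParams(
        rs=a.rs + b.rs + extra_rs,
        rp=a.rp + b.rp,
        cp=(a.cp * b.cp) / (a.cp + b.cp),
    )


def pair_circuit_from_template(tmpl: SubjectTemplate, pair: FingerPair) -> PairCircuit:
    """Assemble the four-block circuit for one finger pair.

    Z1 and Z4 are the two fingers' epidermis/electrode blocks.  The
    interior dermis path Z2 is the series combination of both fingers'
    dermis blocks with the body resistance absorbed into its series
    resistance; the sweat path Z3 is the series combination of both sweat
    blocks.  Pairs sharing a finger share that finger's parameters exactly.
    """
    fa = tmpl.fingers[pair.a - 1]
    fb = tmpl.fingers[pair.b - 1]
    return PairCircuit(
        z1=fa.epidermis,
        z2=_series_blocks(fa.dermis, fb.dermis, extra_rs=tmpl.body_resistance),
        z3=_series_blocks(fa.sweat, fb.sweat),
        z4=fb.epidermis,
    )


def session_scale(ctx: SessionContext) -> StateScale:
    """Combined common-mode factor of one session.

    ``s = drift * (1 + gamma * (t_ref - temperature))`` — monotonically
    decreasing in temperature, matching the observed inverse dependence of
    mean finger impedance on hand temperature.
    """
    s = ctx.drift.s * (1.0 + ctx.gamma * (ctx.t_ref - ctx.temperature))
    if s <= 0:
        raise ValueError(
            f"session scale {s} <= 0 (gamma too large for temperature "
            f"{ctx.temperature})"
        )
    return StateScale(s)


def generate_dataset(
    n_subjects: int,
    n_sessions: int,
    n_repeats: int,
    noise_sigma: float | None = None,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> SpectraDataset:
    """Generate a labelled cohort of ``n_subjects x n_sessions x n_repeats`` records.

    Per subject: one anatomy template.  Per (subject, session): one
    SessionContext with a log-normal drift factor and a uniform hand
    temperature; the resulting common-mode scale multiplies all ten pair
    circuits.  Per (record, pair): independent multiplicative noise
    ``exp(eps)``, ``eps ~ N(0, noise_sigma^2)``.  Fully reproducible from
    ``seed``.
    """
    if n_subjects < 2 or n_sessions < 2 or n_repeats < 1:
        raise ValueError(
            "need n_subjects >= 2, n_sessions >= 2, n_repeats >= 1"
        )
    config = config or CohortConfig()
    if noise_sigma is None:
        noise_sigma = config.noise_sigma
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    rng = np.random.default_rng(seed)
    grid = config.grid
    records: list[MeasurementRecord] = []

    for i in range(n_subjects):
        tmpl = sample_subject(rng, config, subject_id=f"S{i + 1}")
        base_circuits = {p: pair_circuit_from_template(tmpl, p) for p in ALL_PAIRS}
        for j in range(n_sessions):
            drift = (
                StateScale(float(np.exp(rng.normal(0.0, config.drift_sigma))))
                if config.drift_sigma > 0
                else StateScale(1.0)
            )
            temperature = float(rng.uniform(*config.temperature_range))
            ctx = SessionContext(
                session_id=f"D{j + 1}",
                temperature=temperature,
                drift=drift,
                gamma=config.gamma,
                t_ref=config.t_ref,
            )
            scale = session_scale(ctx)
            session_spectra = {}
            for p in ALL_PAIRS:
                circ = scale_state(base_circuits[p], scale)
                if config.drift_heterogeneity > 0:
                    extra = StateScale(
                        float(np.exp(rng.normal(0.0, config.drift_heterogeneity)))
                    )
                    circ = scale_state(circ, extra)
                session_spectra[p] = pair_impedance(circ, grid).as_array()
            for k in range(n_repeats):
                spectra = {}
                for p in ALL_PAIRS:
                    mags = session_spectra[p]
                    if noise_sigma > 0:
                        mags = mags * np.exp(rng.normal(0.0, noise_sigma))
                    spectra[p] = ImpedanceSpectrum(grid, tuple(mags))
                records.append(
                    MeasurementRecord(
                        subject_id=tmpl.subject_id,
                        session_id=ctx.session_id,
                        repeat_index=k,
                        temperature=temperature,
                        spectra=spectra,
                    )
                )
    return SpectraDataset(records=tuple(records), grid=grid)
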