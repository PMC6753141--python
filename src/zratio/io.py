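"""Reading and writing datasets, combination sets, and result artifacts.

The canonical interchange format for spectra is a long-format CSV with one
row per (record, finger pair, frequency):

    subject_id, session_id, repeat, temperature_C,
    finger_a, finger_b, frequency_hz, impedance_ohm

Frequencies are stored in hertz as integers so that float formatting can
never split a grid point into two keys.  A wide JSON variant stores the
grid once and one magnitude list per pair per record.  Both round-trip
impedance values to full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import FrequencyGrid, ImpedanceSpectrum
from .cohort import ALL_PAIRS, FingerPair, MeasurementRecord, SpectraDataset
from .features import RatioCombinationSet

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_dataset_json",
    "read_dataset_json",
    "write_combinations",
    "read_combinations",
]

_COLUMNS = [
    "subject_id",
    "session_id",
    "repeat",
    "temperature_C",
    "finger_a",
    "finger_b",
    "frequency_hz",
    "impedance_ohm",
]


def write_dataset(ds: SpectraDataset, path: str | Path) -> None:
    """Write a dataset as long-format CSV (one row per pair per frequency)."""
    rows = []
    freqs = [int(round(f)) for f in ds.grid.frequencies]
    for r in ds.records:
        for p in ALL_PAIRS:
            for f_hz, mag in zip(freqs, r.spectra[p].magnitudes):
                rows.append(
                    (
                        r.subject_id,
                        r.session_id,
                        r.repeat_index,
                        r.temperature,
                        p.a,
                        p.b,
                        f_hz,
                        mag,
                    )
                )
    # %.17g round-trips doubles exactly
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_dataset(path: str | Path) -> SpectraDataset:
    """Read a long-format CSV dataset, validating schema and values.

    Errors name the offending column or 1-based data row so bad files can
    be fixed by hand.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {', '.join(missing)}")

    bad = df.index[~(df["impedance_ohm"] > 0)]
    if len(bad):
        raise ValueError(
            f"{path}: non-positive impedance at data row {int(bad[0]) + 1}"
        )
    key_cols = ["subject_id", "session_id", "repeat", "finger_a", "finger_b",
                "frequency_hz"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (subject, session, repeat, pair, frequency) "
            f"key at data row {int(df.index[dup][0]) + 1}"
        )

    grid = FrequencyGrid(
        tuple(float(f) for f in sorted(df["frequency_hz"].unique()))
    )
    records = []
    grouped = df.groupby(["subject_id", "session_id", "repeat"], sort=True)
    for (subject, session, repeat), g in grouped:
        spectra = {}
        for (a, b), gp in g.groupby(["finger_a", "finger_b"]):
            gp = gp.sort_values("frequency_hz")
            if len(gp) != len(grid):
                raise ValueError(
                    f"{path}: record ({subject}, {session}, {repeat}) pair "
                    f"({a},{b}) has {len(gp)} frequencies, expected {len(grid)}"
                )
            spectra[FingerPair(int(a), int(b))] = ImpedanceSpectrum(
                grid, tuple(gp["impedance_ohm"].to_numpy())
            )
        records.append(
            MeasurementRecord(
                subject_id=str(subject),
                session_id=str(session),
                repeat_index=int(repeat),
                temperature=float(g["temperature_C"].iloc[0]),
                spectra=spectra,
            )
        )
    return SpectraDataset(records=tuple(records), grid=grid)


def _pair_key(p: FingerPair) -> str:
    return f"{p.a}-{p.b}"


def write_dataset_json(ds: SpectraDataset, path: str | Path) -> None:
    """Write the wide JSON variant: grid once, one magnitude list per pair."""
    payload = {
        "grid_hz": [int(round(f)) for f in ds.grid.frequencies],
        "records": [
            {
                "subject_id": r.subject_id,
                "session_id": r.session_id,
                "repeat": r.repeat_index,
                "temperature_C": r.temperature,
                "spectra": {
                    _pair_key(p): list(r.spectra[p].magnitudes) for p in ALL_PAIRS
                },
            }
            for r in ds.records
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_dataset_json(path: str | Path) -> SpectraDataset:
    payload = json.loads(Path(path).read_text())
    grid = FrequencyGrid(tuple(float(f) for f in payload["grid_hz"]))
    records = []
    for i, rec in enumerate(payload["records"]):
        spectra = {}
        for key, mags in rec["spectra"].items():
            a, b = (int(x) for x in key.split("-"))
            if np.any(np.asarray(mags) <= 0):
                raise ValueError(
                    f"{path}: non-positive impedance in record {i}, pair {key}"
                )
            spectra[FingerPair(a, b)] = ImpedanceSpectrum(grid, tuple(mags))
        records.append(
            MeasurementRecord(
                subject_id=str(rec["subject_id"]),
                session_id=str(rec["session_id"]),
                repeat_index=int(rec["repeat"]),
                temperature=float(rec["temperature_C"]),
                spectra=spectra,
            )
        )
    return SpectraDataset(records=tuple(records), grid=grid)


def write_combinations(combos: RatioCombinationSet, path: str | Path) -> None:
    """Write a combination set as a JSON list of {num: [a,b], den: [a,b]}."""
    payload = [
        {"num": [n.a, n.b], "den": [d.a, d.b]} for n, d in combos.assignments
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_combinations(path: str | Path) -> RatioCombinationSet:
    payload = json.loads(Path(path).read_text())
    return RatioCombinationSet(
        tuple(
            (FingerPair(*entry["num"]), FingerPair(*entry["den"]))
            for entry in payload
        )
    )
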