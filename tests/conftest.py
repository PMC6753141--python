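import numpy as np
import pytest

from zratio import (
    ALL_PAIRS,
    CohortConfig,
    FrequencyGrid,
    ImpedanceSpectrum,
    MeasurementRecord,
    PairCircuit,
    SpectraDataset,
    ZBlockParams,
    generate_dataset,
)


def random_block(rng: np.random.Generator) -> ZBlockParams:
    """Order-of-magnitude plausible fingertip component values."""
    return ZBlockParams(
        rs=float(rng.uniform(1e2, 1e3)),
        rp=float(rng.uniform(1e2, 1e4)),
        cp=float(rng.uniform(1e-9, 1e-7)),
    )


def random_circuit(rng: np.random.Generator) -> PairCircuit:
    return PairCircuit(*(random_block(rng) for _ in range(4)))


def constant_record(values_by_pair, n_freq=25, temperature=33.0):
    """A record whose pairs have flat spectra at given magnitudes."""
    grid = FrequencyGrid(tuple(20e3 * (i + 1) for i in range(n_freq)))
    spectra = {
        p: ImpedanceSpectrum(grid, (float(values_by_pair[p]),) * n_freq)
        for p in ALL_PAIRS
    }
    return MeasurementRecord(
        subject_id="S1",
        session_id="D1",
        repeat_index=0,
        temperature=temperature,
        spectra=spectra,
    )


@pytest.fixture(scope="session")
def small_dataset() -> SpectraDataset:
    """4 subjects x 2 sessions x 3 repeats with default drift and noise."""
    return generate_dataset(4, 2, 3, seed=7)


@pytest.fixture(scope="session")
def clean_dataset() -> SpectraDataset:
    """Drift-free, noise-free cohort: repeats within a subject are identical."""
    config = CohortConfig(drift_sigma=0.0, noise_sigma=0.0, gamma=0.0)
    return generate_dataset(4, 2, 2, seed=11, config=config)
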