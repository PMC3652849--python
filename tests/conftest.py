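import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pepdisc import DiscrimTables, SearchConfig
from pepdisc.io import ProteinRecord, RawSpectrum
from pepdisc.preprocess import ProcessedSpectrum

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tables() -> DiscrimTables:
    return DiscrimTables.default()


@pytest.fixture()
def config() -> SearchConfig:
    return SearchConfig()  # LTQ-style: 3.0 Da precursor, 0.5 Da fragment


@pytest.fixture()
def toy_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("P1", "MAAKPAAKRAAGGGK"),
        ProteinRecord("P2", "ELVISLIVESKGGGR"),
    ]


def spectrum_from_peaks(mz, intensity, spectrum_id="s1", precursor_mz=500.0, charge=2):
    return RawSpectrum(spectrum_id, precursor_mz, charge, np.asarray(mz, float), np.asarray(intensity, float))


def processed_from_peaks(mz, intensity, spectrum_id="s1", precursor_mz=500.0, charge=2):
    """Build a ProcessedSpectrum directly (bypassing selection) for unit tests."""
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    return ProcessedSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        mz=mz,
        intensity_raw=intensity,
        intensity_norm=intensity / intensity.max(),
        bin_edges=np.linspace(mz.min(), max(mz.max(), mz.min() + 1), 11),
    )
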