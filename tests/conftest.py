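import numpy as np
import pytest

from radbio.dvh import DoseVolumeHistogram, FractionationScheme


@pytest.fixture
def scheme():
    return FractionationScheme(prescription_dose=50.4, n_fractions=28, alpha_beta=4.0)


@pytest.fixture
def simple_cumulative():
    """(0,100),(10,80),(20,40),(30,0): a small hand-checkable curve."""
    return DoseVolumeHistogram(
        structure_label="toy",
        total_volume=50.0,
        dose=[0.0, 10.0, 20.0, 30.0],
        values=[100.0, 80.0, 40.0, 0.0],
        mode="cumulative",
        volume_unit="percent",
    )


def uniform_dose_dvh(dose: float, total_volume: float = 100.0, width: float = 0.001):
    """Whole structure at a single dose (one narrow differential bin)."""
    if dose == 0.0:
        edges = [0.0, width]
        values = [100.0]
    else:
        edges = [0.0, dose - width / 2, dose + width / 2]
        values = [0.0, 100.0]
    return DoseVolumeHistogram(
        structure_label="uniform",
        total_volume=total_volume,
        dose=edges,
        values=values,
        mode="differential",
        volume_unit="percent",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
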