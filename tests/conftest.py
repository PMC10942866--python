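import numpy as np
import pandas as pd
import pytest

from evascites.containers import IntensityMatrix, MarkerPanel, make_sample_table
from evascites.deconvolution import crop_panel
from evascites.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def study_dataset():
    """Default study-scale synthetic dataset (fixed seed)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def study_detection(study_dataset):
    return study_dataset.intensities.binarize()


@pytest.fixture(scope="session")
def study_panel(study_dataset):
    return crop_panel(study_dataset.panel_raw, k=study_dataset.config.k_markers)


def random_matrix(rng, n_genes=20, n_patients=3, n_controls=1, density=0.5):
    """Small random IntensityMatrix with U/S/B fractions and controls."""
    records = []
    for i in range(n_patients):
        for frac in ("U", "S", "B"):
            records.append((f"{frac}{i + 1}", f"P{i + 1}", frac, "HGSC"))
    for j in range(n_controls):
        records.append((f"C{j + 1}", f"K{j + 1}", "U", "CONTROL"))
    samples = make_sample_table(records)
    genes = [f"G{k:03d}" for k in range(n_genes)]
    present = rng.random((n_genes, len(samples))) < density
    vals = np.exp(rng.normal(10, 2, size=present.shape)) * present
    values = pd.DataFrame(vals, index=genes, columns=list(samples.index))
    return IntensityMatrix(values=values, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng)


@pytest.fixture
def toy_panel():
    return MarkerPanel(
        markers={
            "alpha": ["A1", "A2", "A3", "A4"],
            "beta": ["B1", "B2", "B3", "B4"],
        }
    )
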