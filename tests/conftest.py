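import numpy as np
import pandas as pd
import pytest

from glycoprog.glycomics import PEAKS, PeakAnnotation, build_trait_definitions
from glycoprog.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def annotation():
    return PeakAnnotation.default()


@pytest.fixture(scope="session")
def trait_defs(annotation):
    return build_trait_definitions(annotation)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n_patients=250, seed=11))


def make_peak_row(values: dict, sample_id="S1", plate_id="P1", is_standard=0):
    """A peak-table row with the named peaks set and all others zero."""
    row = {"sample_id": sample_id, "plate_id": plate_id,
           "is_standard": is_standard, **{p: 0.0 for p in PEAKS}}
    row.update(values)
    return row


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "plate_id", "is_standard",
                                       *PEAKS])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
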