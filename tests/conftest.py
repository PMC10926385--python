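import numpy as np
import pytest

from gsikit import GenotypeMatrix


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    """3 samples x 2 markers with one missing call."""
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3"],
        marker_ids=["m1", "m2"],
        dosage=np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 0.0]]),
        labels=["A", "A", "B"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
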