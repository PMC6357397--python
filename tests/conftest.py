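import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tadlink import (FeatureMatrix, GenomicInterval, TADSet,
                     generate_cohort, run_full_analysis)
from tadlink.simulate import SyntheticSpec


@pytest.fixture(scope="session")
def default_cohort():
    """A 24-sample synthetic cohort with planted rho=0.9 links."""
    return generate_cohort(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def default_records(default_cohort):
    enh, expr, tads, groups, truth = default_cohort
    return run_full_analysis(enh, expr, tads)


@pytest.fixture
def toy_matrix():
    """3 features x 4 samples with simple coordinates."""
    features = [
        GenomicInterval("chr1", 100, 200, "f1"),
        GenomicInterval("chr1", 300, 400, "f2"),
        GenomicInterval("chr2", 50, 150, "f3"),
    ]
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.5, 0.0, 1.5, 3.0], [0.0, 0.0, 5.0, 1.0]],
        index=["f1", "f2", "f3"], columns=["s1", "s2", "s3", "s4"])
    return FeatureMatrix(values, features)


@pytest.fixture
def two_tads():
    return TADSet([GenomicInterval("chr1", 100, 200, "A"),
                   GenomicInterval("chr1", 400, 500, "B")])
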