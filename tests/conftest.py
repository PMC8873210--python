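import numpy as np
import pytest

from pvcomb import geriatric_rehab_studies, run_meta_pipeline, study_pvalues

#: published per-study p-values of the 12-trial geriatric-rehabilitation
#: meta-analysis, rounded to 4 dp (left, right, two-sided).
TABLE2_PRINTED = np.array([
    (0.6044, 0.3956, 0.7911),
    (0.3928, 0.6072, 0.7857),
    (0.7119, 0.2881, 0.5762),
    (0.5638, 0.4362, 0.8724),
    (0.3778, 0.6222, 0.7555),
    (0.7948, 0.2052, 0.4103),
    (0.7317, 0.2683, 0.5366),
    (0.9949, 0.0051, 0.0102),
    (0.5866, 0.4134, 0.8269),
    (0.9995, 0.0005, 0.0011),
    (0.9924, 0.0076, 0.0152),
    (0.9844, 0.0156, 0.0313),
])


@pytest.fixture(scope="session")
def rehab_records():
    return geriatric_rehab_studies()


@pytest.fixture(scope="session")
def rehab_studies_filled(rehab_records):
    return [study_pvalues(r) for r in rehab_records]


@pytest.fixture(scope="session")
def rehab_meta(rehab_records):
    return run_meta_pipeline(rehab_records)


@pytest.fixture
def rng():
    return np.random.default_rng(20220224)
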