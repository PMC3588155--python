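import numpy as np
import pytest

import crcmolclass as cm
from crcmolclass.cohort import from_records


def molecular_cohort(frame, extra_cols=None):
    """Wrap a 0/1 molecular frame (columns = markers) into a Cohort."""
    recs = frame.to_dict("records")
    for i, r in enumerate(recs):
        r["tumour_id"] = f"T{i + 1:05d}"
        if extra_cols:
            r.update({k: v[i] for k, v in extra_cols.items()})
    return from_records(recs)


@pytest.fixture(scope="session")
def calibrated_model():
    """Joint model calibrated to the published marginals and edge signs."""
    return cm.build_joint(cm.DEFAULT_MARGINALS, cm.DEFAULT_EDGES)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 906-tumour synthetic cohort with default settings."""
    return cm.simulate_cohort(cm.GeneratorConfig(n=906, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
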