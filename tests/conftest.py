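import numpy as np
import pytest

from ssmpca.core import ScanImage, build_common_mask, compute_srp
from ssmpca.synthetic import CohortParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort (12^3 grid) shared across read-only tests."""
    params = CohortParams(n_controls=8, n_patients=9, grid_dims=(12, 12, 12), seed=7)
    scans, truth, table = simulate_cohort(params)
    return params, scans, truth, table


@pytest.fixture(scope="session")
def small_srp(small_cohort):
    _, scans, _, table = small_cohort
    labels = table["label"].to_numpy()
    mask = build_common_mask(scans, 0.35)
    return compute_srp(scans, mask, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_scan(values, subject_id="s"):
    """Wrap a (possibly tiny) array into a 3D ScanImage by padding dims."""
    arr = np.asarray(values, dtype=float)
    while arr.ndim < 3:
        arr = arr[..., None]
    return ScanImage(subject_id=subject_id, voxels=arr)
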