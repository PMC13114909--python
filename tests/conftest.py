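import numpy as np
import pytest

from enoseda.datamodel import ENoseMeasurement, LabeledDataset
from enoseda.nn import autograd


@pytest.fixture
def float64_grads():
    """Run autograd in float64 for finite-difference comparisons."""
    previous = autograd.get_default_dtype()
    autograd.set_default_dtype(np.float64)
    yield
    autograd.set_default_dtype(previous)


def make_dataset(n_classes=3, per_class_per_day=4, n_days=2, seed=0,
                 domain="target") -> LabeledDataset:
    """Small structured dataset with distinguishable class means."""
    rng = np.random.default_rng(seed)
    measurements = []
    for day in range(1, n_days + 1):
        for k in range(n_classes):
            for rep in range(per_class_per_day):
                values = k + 0.1 * rng.standard_normal((10, 120))
                sid = f"{domain}_d{day}_c{k}_r{rep}"
                measurements.append(ENoseMeasurement(values, sid, k, domain, day))
    return LabeledDataset(measurements, [f"c{k}" for k in range(n_classes)])


@pytest.fixture
def small_dataset():
    return make_dataset()
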