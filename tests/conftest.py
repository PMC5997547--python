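import logging

import numpy as np
import pytest

from bctseg import metrics, phantom, pipeline
from bctseg.io_model import TISSUE_LABELS

logging.getLogger("bctseg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Default 10-slice 256^2 phantom volume with ground truth."""
    return phantom.make_volume(default_spec)


@pytest.fixture(scope="session")
def classified(default_phantom):
    """End-to-end classification of the default phantom (shared: costly)."""
    vol, truth = default_phantom
    labels = pipeline.classify_volume(vol, pipeline.PipelineConfig(master_seed=0))
    return labels, truth


@pytest.fixture(scope="session")
def per_class_dsc(classified):
    labels, truth = classified
    return {
        c: metrics.dsc(labels.class_mask(c), truth.class_mask(c)) for c in TISSUE_LABELS
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
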