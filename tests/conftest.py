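import numpy as np
import pytest

from stripeflow import segment, synth


@pytest.fixture(scope="session")
def wt_params():
    return synth.stripe_model_params("WT")


@pytest.fixture(scope="session")
def rendered_embryo():
    """One noiseless rendered WT frame at t=36 with its ground truth."""
    params = synth.stripe_model_params("WT", sigma_n=0.0)
    scene = synth.SceneSpec(seed=3)
    series, truth = synth.generate_embryo_series(params, scene,
                                                 times=np.array([36.0]))
    return series, truth


@pytest.fixture(scope="session")
def segmented_embryo(rendered_embryo):
    series, truth = rendered_embryo
    nf = series.nuclear[0].astype(float)
    mask = segment.cortical_mask(nf)
    labels = segment.fuse_oversegmented(segment.segment_nuclei(nf, mask))
    return series, truth, mask, labels
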