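import numpy as np
import pytest

import lesionquant as lq


@pytest.fixture(scope="session")
def training_slide():
    """One 512-px slide with a generous lesion burden, used for training."""
    spec = lq.SyntheticSlideSpec(
        width_px=512, height_px=512, target_lesion_fraction=0.3, seed=11
    )
    image, gt = lq.generate_slide(spec)
    return image, gt


@pytest.fixture(scope="session")
def patch_set(training_slide):
    image, gt = training_slide
    return lq.sample_patches(image, gt, n_per_class=200, purity=0.9, seed=5)


@pytest.fixture(scope="session")
def classifier(patch_set):
    return lq.fit_classifier(patch_set)


@pytest.fixture(scope="session")
def quantified_slide(classifier):
    """A default-parameter slide at planted fraction 0.2, fully quantified."""
    from lesionquant.pipeline import quantify_slide

    spec = lq.SyntheticSlideSpec(
        width_px=512, height_px=512, target_lesion_fraction=0.2, seed=42
    )
    image, gt = lq.generate_slide(spec)
    out = quantify_slide(image, classifier)
    return image, gt, out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
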