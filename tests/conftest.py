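import numpy as np
import pytest

from lipoquant import ImagingScenario, generate_imaging_condition
from lipoquant.imaging_io import ConditionSet, TwoChannelImage


def make_image(lipid, dna, image_id="img0", condition_id="cond", bit_depth=16):
    return TwoChannelImage(
        lipid=np.asarray(lipid),
        dna=np.asarray(dna),
        bit_depth=bit_depth,
        image_id=image_id,
        condition_id=condition_id,
    )


def make_condition(images, condition_id="cond", variable="var", value=0.0):
    return ConditionSet(condition_id, variable, value, list(images))


@pytest.fixture(scope="session")
def small_condition():
    """A small seeded two-image condition with ground truth."""
    scenario = ImagingScenario(
        image_shape=(96, 96),
        n_images=2,
        n_liposomes_per_image=6,
        liposome_radius=(5.0, 0.5),
        enrichment_rho=2.0,
        seed=11,
        condition_id="small",
    )
    return generate_imaging_condition(scenario)


@pytest.fixture(scope="session")
def default_condition():
    """A default-geometry condition (4 images) with ground truth."""
    scenario = ImagingScenario(n_images=4, enrichment_rho=2.0, seed=5, condition_id="default")
    return generate_imaging_condition(scenario)
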