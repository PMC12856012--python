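import numpy as np
import pytest

from crayfish_sexing.autoencoder import LeakageAudit, TrainConfig, build_scae_features
from crayfish_sexing.synthetic import ImageSimSpec, TabularSimSpec, generate_images, generate_tabular


@pytest.fixture(scope="session")
def study_scale_table():
    """62 F / 50 M table at strong separation with some missing cells."""
    return generate_tabular(
        TabularSimSpec(effect_size=3.0, missing_rate=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def small_imageset():
    """Small sex-dimorphic image set with a held-out test partition."""
    return generate_images(
        ImageSimSpec(n_female=20, n_male=16, noise_sd=0.1, seed=21),
        test_counts={"F": 6, "M": 4},
    )


@pytest.fixture(scope="session")
def smoke_scae(small_imageset):
    """Two-epoch CAE + SCAE feature build with its leakage audit."""
    audit = LeakageAudit()
    cae, scae = build_scae_features(
        small_imageset, TrainConfig(max_epochs=2, seed=3), audit=audit
    )
    return cae, scae, audit, small_imageset
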