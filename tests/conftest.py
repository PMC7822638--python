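import numpy as np
import pytest

from cinempca.evaluate import outer_cv
from cinempca.phantom import PhantomConfig, generate_phantom
from cinempca.study import build_study


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort for I/O and CLI plumbing tests."""
    cfg = PhantomConfig(
        n_per_class=6, image_size=32, n_frames=6, seed=5, max_translation=2.0
    )
    return cfg, generate_phantom(cfg)


@pytest.fixture(scope="session")
def quick_study():
    """Mid-sized preprocessed study for cross-validation mechanics tests."""
    cfg = PhantomConfig(
        n_per_class=15, image_size=64, n_frames=10, seed=7, max_translation=3.0
    )
    return build_study(cfg, mask_variant="small", scale=32)


# --- full-scale study shared by the end-to-end acceptance tests ------------

_FULL_SEED = 11


def _full_config(effect: float) -> PhantomConfig:
    return PhantomConfig(n_per_class=50, image_size=128, seed=_FULL_SEED, effect_size=effect)


@pytest.fixture(scope="session")
def full_cohort_effect1():
    return generate_phantom(_full_config(1.0))


@pytest.fixture(scope="session")
def full_study_effect1(full_cohort_effect1):
    return build_study(
        _full_config(1.0), mask_variant="small", scale=64, subjects=full_cohort_effect1
    )


@pytest.fixture(scope="session")
def full_cv_effect1(full_study_effect1):
    sd = full_study_effect1
    return outer_cv(sd.tensors, sd.labels, classifier_kind="svm", seed=_FULL_SEED)


@pytest.fixture(scope="session")
def auc_by_effect(full_cv_effect1):
    """Mean outer-CV AUC over the effect-size grid at a fixed seed bank."""
    out = {1.0: full_cv_effect1.mean_auc}
    for effect in (0.0, 0.25, 0.5):
        sd = build_study(_full_config(effect), mask_variant="small", scale=64)
        out[effect] = outer_cv(
            sd.tensors, sd.labels, classifier_kind="svm", seed=_FULL_SEED
        ).mean_auc
    return out
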