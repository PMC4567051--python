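import numpy as np
import pytest

from cropfuse import (PhenologyProfile, SceneConfig, generate_scene,
                      default_pool)


def noisefree_profiles():
    """Three well-separated crops with zero field/pixel noise."""
    return (
        PhenologyProfile("early", 0.10, 70, 130, 180, 0.70, 0.70),
        PhenologyProfile("mid", 0.10, 140, 200, 260, 0.80, 0.80),
        PhenologyProfile("late", 0.10, 180, 240, 320, 0.60, 0.60),
    )


@pytest.fixture(scope="session")
def separable_scene():
    """Noise-free, perfectly separable scene: 1024 pixels, 16 fields."""
    config = SceneConfig(
        class_profiles=noisefree_profiles(),
        class_proportions=(0.4, 0.35, 0.25),
        grid_height=32, grid_width=32, field_height=8, field_width=8, seed=7)
    cube, labels, objects = generate_scene(config)
    return config, cube, labels, objects


@pytest.fixture(scope="session")
def noisy_scene():
    """Small noisy 3-class scene with a 50/50 train/validation pool."""
    profiles = (
        PhenologyProfile("a", 0.10, 70, 130, 180, 0.60, 0.80,
                         field_sd=0.05, pixel_sd=0.04),
        PhenologyProfile("b", 0.10, 140, 200, 260, 0.70, 0.90,
                         field_sd=0.05, pixel_sd=0.04),
        PhenologyProfile("c", 0.10, 150, 210, 300, 0.45, 0.70,
                         field_sd=0.08, pixel_sd=0.04),
    )
    config = SceneConfig(
        class_profiles=profiles, class_proportions=(0.4, 0.35, 0.25),
        grid_height=40, grid_width=40, field_height=8, field_width=8, seed=11)
    cube, labels, objects = generate_scene(config)
    pool = default_pool(labels, seed=11)
    return cube, labels, objects, pool


def random_classifier_outputs(rng, n_pixels, n_classes, n_classifiers=3):
    """Random valid ClassifierOutput triple for fusion tests."""
    from cropfuse import ClassifierOutput
    outs = []
    for _ in range(n_classifiers):
        raw = rng.random((n_pixels, n_classes)) ** 2
        proba = raw / raw.sum(axis=1, keepdims=True)
        outs.append(ClassifierOutput(labels=np.argmax(proba, axis=1) + 1,
                                     proba=proba))
    return outs
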