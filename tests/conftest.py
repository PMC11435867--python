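import numpy as np
import pytest

from cottonhsi import (
    MJHResNet,
    ModelConfig,
    PreprocessConfig,
    SceneSpec,
    TrainConfig,
    extract_patches,
    preprocess_chain,
    simulate_scene,
    split_dataset,
    train_model,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 48x48x16 nine-class scene with default noise levels."""
    spec = SceneSpec(rows=48, cols=48, bands=16, blob_count=12, blob_size_range=(4, 10), seed=7)
    raw, dark, white, truth = simulate_scene(spec)
    return raw, dark, white, truth, spec


@pytest.fixture(scope="session")
def clean_scene():
    """Same geometry with all noise terms zero (exact-inversion fixture)."""
    spec = SceneSpec(
        rows=48, cols=48, bands=16, blob_count=12, blob_size_range=(4, 10),
        scatter_mult_sd=0.0, scatter_add_sd=0.0, noise_sd=0.0, seed=7,
    )
    raw, dark, white, truth = simulate_scene(spec)
    return raw, dark, white, truth, spec


@pytest.fixture
def tiny_config():
    """A small architecture for fast forward/backward tests."""
    return ModelConfig(
        in_bands=3, patch_size=5, channels=4, kernel=3,
        blocks_per_branch=2, se_reduction=2, n_classes=3, seed=1,
    )


@pytest.fixture(scope="session")
def trained_tiny(small_scene):
    """A small model trained on the small scene, shared across tests.

    Returns (model, dataset, preprocess result, truth map).
    """
    raw, dark, white, truth, spec = small_scene
    res = preprocess_chain(raw, dark, white, PreprocessConfig(pca_components=8), labels=truth)
    ds = extract_patches(res.cube, res.labels, 5)
    split_dataset(ds, 0.15, seed=0)
    cfg = ModelConfig(in_bands=8, patch_size=5, channels=16, kernel=3,
                      blocks_per_branch=2, se_reduction=8, n_classes=9, seed=0)
    model = MJHResNet(cfg)
    tcfg = TrainConfig(epochs_a=10, epochs_b=5, batch_size=256, seed=0, eval_max=512)
    model, history = train_model(model, ds, tcfg)
    return model, ds, res, truth


def rand_cube(rng, rows, cols, bands):
    from cottonhsi import HsiCube

    return HsiCube(rng.normal(size=(rows, cols, bands)), np.linspace(400, 1000, bands))
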