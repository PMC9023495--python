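import numpy as np
import pytest

from compressnet.imaging import AugmentationConfig
from compressnet.network import LayerSpec, NetworkSpec, build_network, desk_student
from compressnet.synthetic import SynthConfig, generate_dataset


def split_per_class(dataset, n_train: int, n_total: int):
    """Index-split one generated dataset into disjoint train/held-out parts."""
    tr = [i for i in range(len(dataset)) if i % n_total < n_train]
    te = [i for i in range(len(dataset)) if i % n_total >= n_train]
    return dataset.subset(tr), dataset.subset(te)


@pytest.fixture(scope="session")
def small_aug():
    """32-px pipeline used by the desk-scale experiments."""
    return AugmentationConfig(train_out=32, test_resize=36, test_crop=32)


@pytest.fixture(scope="session")
def micro_aug():
    """16-px pipeline for the fastest smoke tests."""
    return AugmentationConfig(train_out=16, test_resize=18, test_crop=16)


@pytest.fixture(scope="session")
def micro_dataset():
    cfg = SynthConfig(n_classes=4, n_per_class=10, image_size=16, noise_sd=0.05, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def micro_student_spec():
    return desk_student(n_classes=4, hidden_dim=16, input_size=16,
                        block_cfg=((6, 5, 2), (8, 6, 1)),
                        stem_filters=4, final_filters=8)


@pytest.fixture()
def micro_student(micro_student_spec):
    return build_network(micro_student_spec, seed=0)


def plain_conv_spec(widths=(5, 6, 4), n_classes=3, hidden_dim=8, input_size=8,
                    kernel=3, has_norm=True, prunable_mask=None):
    """Sequential conv net (no depthwise, no residual) for oracle tests."""
    layers = []
    for i, w in enumerate(widths):
        prunable = (prunable_mask[i] if prunable_mask is not None
                    else i < len(widths) - 1)
        layers.append(LayerSpec(f"conv{i}", "conv", w, kernel=kernel,
                                has_norm=has_norm, prunable=prunable))
    layers.append(LayerSpec("hidden", "fully_connected", hidden_dim,
                            has_norm=False, bias=True))
    layers.append(LayerSpec("head", "fully_connected", n_classes,
                            has_norm=False, bias=True, activation="linear"))
    return NetworkSpec(tuple(layers), hidden_dim=hidden_dim, n_classes=n_classes,
                       input_size=input_size)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
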