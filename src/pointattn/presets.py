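"""Desk-scale presets: the toy study conditions used by the test suite and
the reproduction script.

The toy classification task is four shape families (sphere, cube, torus,
cylinder), 400 training and 100 test clouds of 256 points, k=20, trained
with the standard recipe (SGD, lr 0.03 cosine-annealed to 0). The trunk is
a width-reduced variant of the full-size architecture — (16,16,32,64)
channels with a 128-d global feature — sized for single-CPU NumPy
throughput; every structural element (CW-EdgeConv++ with channel gates,
dynamic graph, global soft attention, max+avg pooled head) is the same.
"""

from __future__ import annotations

import numpy as np

from .networks import (ClassifierConfig, SegmenterConfig,
                       build_classifier)
from .synthetic import make_dataset, make_part_dataset
from .training import TrainConfig, train

__all__ = [
    "TOY_N_POINTS", "TOY_K", "toy_classifier_config", "toy_train_config",
    "toy_dataset", "train_toy_classifier",
    "toy_segmenter_config", "toy_part_dataset",
]

TOY_N_POINTS = 256
TOY_K = 20
TOY_CLASSES = 4
TOY_PER_CLASS = 125          # 400 train / 100 test at the 0.8 split
TOY_EPOCHS = 8


def toy_classifier_config() -> ClassifierConfig:
    return ClassifierConfig(layer_channels=(16, 16, 32, 64), k=TOY_K,
                            global_dim=128, head_width=128,
                            n_classes=TOY_CLASSES, attn_hidden=32)


def toy_train_config(seed: int = 0, epochs: int = TOY_EPOCHS) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=16, seed=seed)


def toy_dataset(seed: int = 0):
    return make_dataset(TOY_CLASSES, TOY_PER_CLASS, split=0.8, seed=seed,
                        mode="shapes", n_points=TOY_N_POINTS)


def train_toy_classifier(seed: int = 0, epochs: int = TOY_EPOCHS,
                         data_seed: int = 0):
    """Train the desk-scale classifier; returns (model, train, test)."""
    train_set, test_set = toy_dataset(seed=data_seed)
    model = build_classifier(toy_classifier_config(), seed=seed,
                             dtype=np.float32)
    train(train_set, model, toy_train_config(seed=seed, epochs=epochs))
    return model, train_set, test_set


def toy_segmenter_config() -> SegmenterConfig:
    return SegmenterConfig(layer_channels=(16, 16, 32, 64), k=TOY_K,
                           global_dim=128, attn_hidden=32,
                           n_categories=2, n_parts=5)


def toy_part_dataset(seed: int = 0, per_class: int = 50):
    return make_part_dataset(per_class, split=0.8, seed=seed,
                             n_points=TOY_N_POINTS)
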