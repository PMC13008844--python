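import numpy as np
import pytest

from stemseg import synthgen as sg
from stemseg.losses import LossConfig
from stemseg.model import ModelConfig
from stemseg.trainer import TrainConfig, fit


def render_dataset(plant_range, canvas=(96, 96), seed0=500, views=range(4)):
    """(3xHxW float image, HxW mask) pairs for a range of synthetic plants."""
    data = []
    for i in plant_range:
        cls = ("simple", "double", "complex")[i % 3]
        spec = sg.make_plant_spec(cls, seed0 + i, canvas)
        for v in views:
            s = sg.render_sample(spec, v, canvas)
            data.append((np.moveaxis(s.image.astype(np.float32) / 255.0, -1, 0), s.mask))
    return data


TINY_TRAIN_CONFIG = TrainConfig(
    total_epochs=20,
    freeze_epochs=0,  # no pretrained weights at this scale, nothing to protect
    batch_size=4,
    lr0=7e-3,
    lr_min=3.5e-4,
    eval_every=10,
    input_size=96,
    seed=0,
    loss=LossConfig(),
    model=ModelConfig(width_mult=0.125),
)


@pytest.fixture(scope="session")
def tiny_datasets():
    """48 train images (12 plants x 4 views) and 24 held-out images at 96 px."""
    return render_dataset(range(12)), render_dataset(range(12, 18))


@pytest.fixture(scope="session")
def tiny_training_run(tiny_datasets):
    """One width-reduced 20-epoch training run shared by the trainer and
    acceptance tests (the dominant cost of the suite)."""
    train_set, val_set = tiny_datasets
    model, history = fit(TINY_TRAIN_CONFIG, train_set, val_set)
    return model, history, val_set


@pytest.fixture(scope="session")
def plant_samples():
    """20 rendered plants at 256 px with exact centerline lengths."""
    samples = []
    for i in range(20):
        cls = ("simple", "double", "complex")[i % 3]
        spec = sg.make_plant_spec(cls, 200 + i, (256, 256))
        samples.append(sg.render_sample(spec, i % 4, (256, 256)))
    return samples
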