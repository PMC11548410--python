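import numpy as np
import pytest

from kinegan.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced simulated dataset: 2 trials per class, 60 total."""
    return simulate_dataset(2, seed=7)


def make_toy_sinusoids(seed: int = 0, n_per_class: int = 64, length: int = 64):
    """Two-class single-channel toy set: sinusoids at rfft bins 3 and 8."""
    rng = np.random.default_rng(seed)
    x, y = [], []
    for cls, k in {0: 3, 1: 8}.items():
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.normal(1.0, 0.05)
            x.append(amp * np.sin(2 * np.pi * k * np.arange(length) / length + phase)[:, None])
            y.append(cls)
    return np.array(x), np.array(y)


#: Small-geometry GAN hyperparameters for the toy sinusoid problem.
TOY_GAN_PARAMS = dict(
    noise_dim=16,
    embed_dim=4,
    reshape_length=16,
    reshape_channels=16,
    block_filters=(32, 16),
    kernel_size=9,
    out_channels=1,
    out_length=64,
    disc_filters=(16, 32),
    disc_label_channels=2,
    minibatch_kernels=4,
    minibatch_dim=3,
    batch_size=32,
)

#: Reduced-size GAN for full 300x9 trials (desk-scale runs).
SMALL_TRIAL_GAN_PARAMS = dict(
    noise_dim=32,
    embed_dim=8,
    reshape_length=75,
    reshape_channels=8,
    block_filters=(16, 8),
    kernel_size=9,
    disc_filters=(8, 16),
    disc_label_channels=4,
    minibatch_kernels=4,
    minibatch_dim=3,
    batch_size=64,
)

#: Reduced-size FCN for desk-scale runs.
SMALL_FCN_PARAMS = dict(
    conv1_filters=8,
    conv2_filters=16,
    dense_units=32,
    epochs=10,
    batch_size=64,
)
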