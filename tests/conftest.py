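import numpy as np
import pytest

from refineseg import (NetConfig, PhantomConfig, TrainConfig,
                       generate_phantom, samples_from_volumes, train)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_phantom():
    """Default-condition phantom volume, 20 slices of 64x64."""
    return generate_phantom(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_setup():
    """Very small phantoms + configs for fast training-path tests."""
    cfg = PhantomConfig(n_slices=4, height=32, width=32, seed=7)
    volumes = [generate_phantom(PhantomConfig(n_slices=4, height=32,
                                              width=32, seed=7 + i))
               for i in range(3)]
    net = NetConfig(n_classes=3, base_channels=2, depth=3, seed=0)
    tcfg = TrainConfig(epochs=2, seed=0)
    return {"phantom_cfg": cfg, "volumes": volumes, "net": net,
            "train": tcfg, "work_size": (32, 32)}


@pytest.fixture(scope="session")
def tiny_checkpoint(tiny_setup):
    """A 2-epoch checkpoint shared by the training-path tests."""
    samples = samples_from_volumes(tiny_setup["volumes"][:2],
                                   work_size=tiny_setup["work_size"])
    ckpt, history = train(samples, tiny_setup["net"], tiny_setup["train"],
                          work_size=tiny_setup["work_size"])
    return ckpt, history
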