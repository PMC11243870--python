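import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from elanet import nn
from elanet.nn.tensor import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def identity_bns(module: nn.Module):
    """Put every batch-norm layer of a module tree into exact identity mode."""
    for _, m in module.named_modules():
        if isinstance(m, nn.BatchNorm2d):
            m.identity_mode()
    return module


def zero_convs(module: nn.Module):
    """Zero all convolution / linear weights and biases in a module tree."""
    for _, m in module.named_modules():
        if isinstance(m, (nn.Conv2d, nn.Linear)):
            m.weight.data[...] = 0.0
            if m.bias is not None:
                m.bias.data[...] = 0.0
    return module


def seed_params(module: nn.Module, seed: int):
    module.initialize(np.random.default_rng(seed))
    return module


def t(arr, batch=True):
    """Wrap a (C,H,W) array as a 1-sample float32 Tensor."""
    arr = np.asarray(arr, dtype=np.float32)
    return Tensor(arr[None] if batch else arr)


def single(out):
    """Strip the batch axis from a 1-sample Tensor output."""
    return out.data[0]
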