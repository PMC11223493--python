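"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_two_class_tensors():
    """Tensor-level two-class problem that is separable by construction:

    classes differ strongly in both event length and the duration feature.
    """
    rng = np.random.default_rng(7)
    n = 300
    xs, ys = [], []
    for label, (length, depth) in enumerate({0: (15, -3.0), 1: (120, -3.0)}.values()):
        for _ in range(n):
            t = np.zeros(251)
            seg_len = 2 * 47 + length
            t[:seg_len] = rng.normal(0.0, 0.3, seg_len)
            t[47 : 47 + length] += depth
            t[-1] = rng.normal(-1.0 if label == 0 else 1.0, 0.2)
            xs.append(t)
            ys.append(label)
    x = np.vstack(xs)
    y = np.array(ys)
    order = rng.permutation(y.size)
    return x[order], y[order]
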