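"""Shared fixtures: small synthetic cohorts and representation extraction."""

from __future__ import annotations

import numpy as np
import pytest

from causalsepsis.nn import Tensor, no_grad
from causalsepsis.records import stack_observations


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def extract_reps(checkpoint, episodes):
    """Eval-mode A, C, X representations for a list of episodes."""
    model = checkpoint.model
    model.eval()
    O = stack_observations(episodes)
    A, C, X = [], [], []
    with no_grad():
        for lo in range(0, len(O), 256):
            a = model.enc.phi_A(Tensor(O[lo:lo + 256]))
            c = model.enc.phi_C(Tensor(O[lo:lo + 256]))
            x = model.enc.fuse(a, c)
            A.append(a.data)
            C.append(c.data)
            X.append(x.data)
    return (np.concatenate(A).astype(np.float64),
            np.concatenate(C).astype(np.float64),
            np.concatenate(X).astype(np.float64))
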