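"""Feature extraction from ICU time-series windows.

The observation window ``O`` (t time steps × o clinical features) is encoded
twice by the same two-branch convolutional architecture with independent
weights: once as the candidate instrument representation ``A = phi_A(O)``
and once as the confounder representation ``C = phi_C(O)``.  Each branch
mixes the temporal and feature axes in opposite orders:

* branch 1 — 1-D conv with input channels ``t`` (kernel 3, padding 1) to 64
  channels over the feature axis, transpose, 1-D conv with input channels
  ``o`` to 32 channels, batch-norm, max-pool → a (32, 32) feature map;
* branch 2 — the transposed order: conv with input channels ``o`` to 64 over
  the time axis, transpose, conv with input channels ``t`` to 32,
  batch-norm, max-pool → a second (32, 32) map.

Each map passes through a small LeNet-style convolutional head (two 5×5
conv + pool blocks, then a linear layer) to a 64-vector; the two are
concatenated to the final 128-dim representation.  The causal feature ``X``
is produced by an MLP over the concatenation ``[A; C]``.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    MLP,
    BatchNorm1d,
    Conv1d,
    Conv2d,
    Linear,
    Module,
    Tensor,
    concat,
    max_pool1d,
    max_pool2d,
)

__all__ = ["LeNetHead", "TemporalSpatialEncoder", "CausalFuse", "EncoderPair"]

ENCODING_DIM = 128  # each of A and C


class LeNetHead(Module):
    """Classic small convolutional head: (1, 32, 32) map → 64-vector."""

    def __init__(self, rng: np.random.Generator, out_dim: int = 64):
        super().__init__()
        self.conv1 = Conv2d(1, 6, 5, rng)
        self.conv2 = Conv2d(6, 16, 5, rng)
        self.fc = Linear(16 * 5 * 5, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = max_pool2d(self.conv1(x).relu())   # (N, 6, 14, 14)
        x = max_pool2d(self.conv2(x).relu())   # (N, 16, 5, 5)
        n = x.shape[0]
        return self.fc(x.reshape(n, 16 * 5 * 5))


class TemporalSpatialEncoder(Module):
    """Two-branch convolutional encoder mapping (N, t, o) → (N, 128)."""

    def __init__(self, t: int, o: int, rng: np.random.Generator):
        super().__init__()
        if t < 4 or o < 4:
            raise ValueError(f"window dims must be at least 4, got (t={t}, o={o})")
        self.t, self.o = t, o
        # branch 1: time-as-channels first
        self.b1_conv1 = Conv1d(t, 64, 3, rng, padding=1)
        self.b1_conv2 = Conv1d(o, 32, 3, rng, padding=1)
        self.b1_bn = BatchNorm1d(32)
        # branch 2: features-as-channels first
        self.b2_conv1 = Conv1d(o, 64, 3, rng, padding=1)
        self.b2_conv2 = Conv1d(t, 32, 3, rng, padding=1)
        self.b2_bn = BatchNorm1d(32)
        self.head1 = LeNetHead(rng)
        self.head2 = LeNetHead(rng)

    def branch_maps(self, O: Tensor) -> tuple[Tensor, Tensor]:
        """The two (N, 32, 32) feature maps, before the LeNet heads."""
        self._check_shape(O)
        m1 = self.b1_conv1(O)                 # (N, 64, o)
        m1 = m1.swapaxes(1, 2)                # (N, o, 64)
        m1 = self.b1_conv2(m1)                # (N, 32, 64)
        m1 = max_pool1d(self.b1_bn(m1))       # (N, 32, 32)
        m2 = self.b2_conv1(O.swapaxes(1, 2))  # (N, 64, t)
        m2 = m2.swapaxes(1, 2)                # (N, t, 64)
        m2 = self.b2_conv2(m2)                # (N, 32, 64)
        m2 = max_pool1d(self.b2_bn(m2))       # (N, 32, 32)
        return m1, m2

    def __call__(self, O: Tensor) -> Tensor:
        m1, m2 = self.branch_maps(O)
        n = m1.shape[0]
        h1 = self.head1(m1.reshape(n, 1, 32, 32))
        h2 = self.head2(m2.reshape(n, 1, 32, 32))
        return concat([h1, h2], axis=1)       # (N, 128)

    def _check_shape(self, O: Tensor) -> None:
        if O.ndim != 3 or O.shape[1:] != (self.t, self.o):
            raise ValueError(
                f"expected O of shape (N, {self.t}, {self.o}), got {tuple(O.shape)}"
            )


class CausalFuse(Module):
    """MLP producing the causal feature X from the concatenation [A; C].

    ``hidden=None`` collapses the MLP to a single linear layer, useful for
    constructing analytically checkable fusions.
    """

    def __init__(self, rng: np.random.Generator, out_dim: int = ENCODING_DIM,
                 hidden: int | None = 256):
        super().__init__()
        self.out_dim = out_dim
        dims = [2 * ENCODING_DIM, out_dim] if hidden is None else \
            [2 * ENCODING_DIM, hidden, out_dim]
        self.mlp = MLP(dims, rng)

    def __call__(self, A: Tensor, C: Tensor) -> Tensor:
        return self.mlp(concat([A, C], axis=1))


class EncoderPair(Module):
    """phi_A and phi_C (same architecture, disjoint weights) plus the fuse MLP."""

    def __init__(self, t: int, o: int, rng: np.random.Generator,
                 x_dim: int = ENCODING_DIM):
        super().__init__()
        self.phi_A = TemporalSpatialEncoder(t, o, rng)
        self.phi_C = TemporalSpatialEncoder(t, o, rng)
        self.fuse = CausalFuse(rng, out_dim=x_dim)

    def __call__(self, O: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        A = self.phi_A(O)
        C = self.phi_C(O)
        X = self.fuse(A, C)
        return A, C, X
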