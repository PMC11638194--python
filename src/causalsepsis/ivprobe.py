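"""Linear probing of learned instrument representations.

On the linear-Gaussian instrument/exposure/outcome benchmark the causal
effect is identified by two-stage least squares (2SLS).  This module trains
the package's encoder and mutual-information machinery on observation
windows carrying the benchmark variables (continuous outcome, so the
classification head is replaced by a linear regression readout) and then
uses the learned instrument representation ``A = phi_A(O)`` — reduced to a
few principal components — as the first-stage instrument set.  If the
mutual-information constraints steer ``A`` towards exogenous content, the
resulting effect estimate moves from the confounded ordinary-least-squares
value towards the true coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncoderPair
from .mi import MIHeads, contrastive_loss, delta_init, fit_heads_loss, freeze_params
from .nn import Adam, Linear, Tensor, default_dtype, no_grad
from .synthetic import linear_iv_observations

__all__ = ["two_stage_least_squares", "ols_slope", "iv_representation_estimate"]


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope of y on x with intercept, by least squares."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[1])


def two_stage_least_squares(instruments: np.ndarray, exposure: np.ndarray,
                            outcome: np.ndarray) -> float:
    """2SLS effect estimate of exposure on outcome given instrument columns."""
    Z = np.column_stack([np.ones(len(exposure)), np.atleast_2d(instruments.T).T])
    first, *_ = np.linalg.lstsq(Z, exposure, rcond=None)
    xhat = Z @ first
    return ols_slope(xhat, outcome)


def _top_components(feats: np.ndarray, k: int) -> np.ndarray:
    centered = feats - feats.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:k].T


@dataclass
class IVProbeResult:
    beta_true: float
    naive: float
    iv_representation: float
    oracle_2sls: float


def iv_representation_estimate(n: int = 3000, beta: float = 1.5,
                               conf: float = 0.8, seed: int = 0,
                               epochs: int = 2, batch_size: int = 128,
                               lambda_causal: float = 1.0,
                               n_components: int = 4) -> IVProbeResult:
    """Train on the embedded benchmark, then probe ``A`` as an instrument."""
    data = linear_iv_observations(n, beta, conf, seed)
    with default_dtype("float32"):
        est = _fit_and_probe(data, seed, epochs, batch_size, lambda_causal,
                             n_components)
    naive = ols_slope(data["x"], data["y"])
    oracle = two_stage_least_squares(data["a"], data["x"], data["y"])
    return IVProbeResult(beta_true=beta, naive=naive,
                         iv_representation=est, oracle_2sls=oracle)


def _fit_and_probe(data: dict, seed: int, epochs: int, batch_size: int,
                   lambda_causal: float, n_components: int) -> float:
    O, y = data["O"], data["y"]
    n, t, o = O.shape
    rng = np.random.default_rng([seed, 21])
    enc = EncoderPair(t, o, rng)
    heads = MIHeads(rng)
    readout = Linear(enc.fuse.out_dim, 1, rng)
    d1 = Tensor(np.array(delta_init()), requires_grad=True)
    d2 = Tensor(np.array(delta_init()), requires_grad=True)
    head_params = list(heads.parameters())
    main_params = (
        list(enc.parameters()) + list(readout.parameters()) + [d1, d2]
    )
    opt_heads = Adam(head_params, lr=1e-3)
    opt_main = Adam(main_params, lr=1e-3)
    y_std = (y - y.mean()) / y.std()
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n - 1, batch_size):
            idx = order[lo:lo + batch_size]
            if len(idx) < 2:
                continue
            Ob = Tensor(O[idx])
            yb = y_std[idx]
            with no_grad():
                A_d, C_d, X_d = enc(Ob)
            for _ in range(5):
                bundle = fit_heads_loss(heads, A_d, C_d, X_d, yb)
                opt_heads.zero_grad()
                bundle.total.backward()
                opt_heads.step()
            A, C, X = enc(Ob)
            pred = readout(X)
            mse = ((pred - Tensor(yb.reshape(-1, 1))) ** 2).mean()
            l1 = contrastive_loss(heads, A, C, X, yb, d1, d2)  # same y as heads
            total = mse + lambda_causal * l1.total
            opt_main.zero_grad()
            with freeze_params(heads):
                total.backward()
            opt_main.step()
    enc.eval()
    with no_grad():
        feats = []
        for lo in range(0, n, 512):
            feats.append(enc.phi_A(Tensor(O[lo:lo + 512])).data)
    A_feats = np.concatenate(feats).astype(np.float64)
    instruments = _top_components(A_feats, n_components)
    return two_stage_least_squares(instruments, data["x"], data["y"])
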