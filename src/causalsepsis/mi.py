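"""Variational mutual-information machinery for instrument learning.

To make ``A = phi_A(O)`` a valid instrument it must be (1) related to the
causal feature ``X``, (2) conditionally unrelated to the outcome ``Y``, and
(3) decorrelated from the confounder representation ``C``; conversely ``C``
must stay related to both ``X`` and ``Y``.  These requirements are enforced
by five diagonal-Gaussian variational heads

    q(X | A), q(Y | A), q(X | C), q(Y | C), q(C | A)

trained in two alternating stages:

* **head fitting** — each head minimises the negative log-likelihood of the
  matched pairs in a batch (the sum of the five is ``L_LLL``); gradients
  reach head parameters only, never the encoders;
* **representation shaping** — with heads held fixed, each contrastive
  component averages ``log q(matched) − log q(mismatched)`` over all d²
  ordered pairs of a batch; components whose mutual information should grow
  (A–X, C–X, C–Y) enter negated, components that should shrink (A–Y, A–C)
  enter positively, combined as

      L_1 = L_AX + L_AY + δ1·(L_CX + L_CY) + δ2·L_AC

  with trainable positive weights δ1, δ2 (softplus-parameterised, init 1).

The binary label is treated as a real-valued target of its Gaussian heads by
default; a Bernoulli head is available behind ``bernoulli_y``.

``mi_probe`` is a standalone MI estimator built from the same head
machinery, used to audit trained representations: it fits a fresh head and
returns an InfoNCE-style matched-versus-mismatched log-ratio, which is
calibrated against analytic Gaussian mutual information in the tests.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

from .nn import Linear, Module, Tensor

__all__ = [
    "gaussian_loglik",
    "bernoulli_loglik",
    "VariationalHead",
    "MIHeads",
    "LossBundle",
    "fit_heads_loss",
    "contrastive_loss",
    "freeze_params",
    "mi_probe",
]

_SIGMA_BOUND = 8.0  # soft bound on the log-variance output; also caps the
                    # reward for collapsing a head's variance, keeping the
                    # unbounded-below contrastive objective from running away


def gaussian_loglik(x: Tensor | np.ndarray, mu: Tensor | np.ndarray,
                    log_var: Tensor | np.ndarray) -> Tensor:
    """Per-sample unnormalised Gaussian log-likelihood.

    Returns the sum over feature dimensions of ``-(x - mu)^2 * exp(-s) - s``
    with ``s`` the log-variance, i.e. the heteroscedastic Gaussian
    log-density up to additive constants.  Inputs of shape ``(d, m)`` (or
    broadcastable) give a ``(d,)`` result; scalars give a scalar.
    """
    x, mu, log_var = Tensor.as_tensor(x), Tensor.as_tensor(mu), Tensor.as_tensor(log_var)
    for name, t in (("x", x), ("mu", mu), ("log_var", log_var)):
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"non-finite values in {name}")
    ll = -((x - mu) ** 2) * (-log_var).exp() - log_var
    if ll.ndim == 0:
        return ll
    return ll.sum(axis=-1)


def bernoulli_loglik(y: Tensor | np.ndarray, logit: Tensor) -> Tensor:
    """Per-sample Bernoulli log-likelihood from a single logit column."""
    y = Tensor.as_tensor(y)
    # log sigma(l) * y + log(1 - sigma(l)) * (1 - y), stable via softplus
    ll = -(1.0 - y) * logit - (-logit).softplus()
    return ll.sum(axis=-1) if ll.ndim > 1 else ll


class VariationalHead(Module):
    """Network mapping a conditioning vector to (mean, log-variance)."""

    def __init__(self, in_dim: int, target_dim: int, rng: np.random.Generator,
                 hidden: int = 128, bernoulli: bool = False,
                 sigma_bound: float = _SIGMA_BOUND):
        super().__init__()
        self.target_dim = target_dim
        self.bernoulli = bernoulli
        self.sigma_bound = sigma_bound
        self.l1 = Linear(in_dim, hidden, rng)
        out = target_dim if bernoulli else 2 * target_dim
        self.l2 = Linear(hidden, out, rng)

    def __call__(self, cond: Tensor) -> tuple[Tensor, Tensor | None]:
        h = self.l1(cond).tanh()
        out = self.l2(h)
        if self.bernoulli:
            return out, None
        mu = out[:, : self.target_dim]
        raw = out[:, self.target_dim:]
        sigma = (raw * (1.0 / self.sigma_bound)).tanh() * self.sigma_bound
        return mu, sigma

    def loglik_matrix(self, cond: Tensor, targets: Tensor) -> Tensor:
        """M[i, j] = log q(target_j | cond_i) over all ordered pairs."""
        d = cond.shape[0]
        out = self(cond)
        if self.bernoulli:
            logit = out[0].reshape(d, 1, self.target_dim)
            t = targets.reshape(1, d, self.target_dim)
            ll = -(1.0 - t) * logit - (-logit).softplus()
            return ll.sum(axis=-1)
        mu, sigma = out
        mu = mu.reshape(d, 1, self.target_dim)
        sigma = sigma.reshape(d, 1, self.target_dim)
        t = targets.reshape(1, d, self.target_dim)
        ll = -((t - mu) ** 2) * (-sigma).exp() - sigma
        return ll.sum(axis=-1)  # (d, d)

    def matched_nll(self, cond: Tensor, targets: Tensor) -> Tensor:
        """Negative mean log-likelihood of matched pairs (the LLL loss)."""
        out = self(cond)
        if self.bernoulli:
            return -bernoulli_loglik(targets, out[0]).mean()
        mu, sigma = out
        return -gaussian_loglik(targets, mu, sigma).mean()


class MIHeads(Module):
    """The five heads q(X|A), q(Y|A), q(X|C), q(Y|C), q(C|A)."""

    NAMES = ("ax", "ay", "cx", "cy", "ac")

    def __init__(self, rng: np.random.Generator, a_dim: int = 128, c_dim: int = 128,
                 x_dim: int = 128, bernoulli_y: bool = False):
        super().__init__()
        self.ax = VariationalHead(a_dim, x_dim, rng)
        self.ay = VariationalHead(a_dim, 1, rng, bernoulli=bernoulli_y)
        self.cx = VariationalHead(c_dim, x_dim, rng)
        self.cy = VariationalHead(c_dim, 1, rng, bernoulli=bernoulli_y)
        self.ac = VariationalHead(a_dim, c_dim, rng)

    def pairs(self, A: Tensor, C: Tensor, X: Tensor, Y: Tensor):
        """(head, conditioning, target) triples in canonical order."""
        return [
            (self.ax, A, X),
            (self.ay, A, Y),
            (self.cx, C, X),
            (self.cy, C, Y),
            (self.ac, A, C),
        ]


@dataclass
class LossBundle:
    """Scalar loss values plus the Tensor nodes needed for backprop."""

    total: Tensor
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.total.data):
            raise FloatingPointError("non-finite loss")


def _as_column(y) -> Tensor:
    y = Tensor.as_tensor(y)
    if y.ndim == 1:
        y = y.reshape(len(y), 1)
    return y


def fit_heads_loss(heads: MIHeads, A: Tensor, C: Tensor, X: Tensor, Y) -> LossBundle:
    """L_LLL: sum of the five matched-pair negative log-likelihoods.

    Encoder outputs are detached, so gradients reach only head parameters
    (the stop-gradient contract of the two-stage scheme).
    """
    if A.shape[0] < 2:
        raise ValueError("head fitting needs a batch of at least 2 samples")
    A, C, X = A.detach(), C.detach(), X.detach()
    Y = _as_column(Y).detach()
    comps: dict[str, float] = {}
    total: Tensor | None = None
    for name, (head, cond, target) in zip(MIHeads.NAMES, heads.pairs(A, C, X, Y)):
        nll = head.matched_nll(cond, target)
        comps[f"lll_{name}"] = nll.item()
        total = nll if total is None else total + nll
    return LossBundle(total=total, components=comps)


def contrastive_loss(heads: MIHeads, A: Tensor, C: Tensor, X: Tensor, Y,
                     delta1_raw: Tensor, delta2_raw: Tensor,
                     exclude: tuple[str, ...] = (),
                     component_cap: float = 10.0) -> LossBundle:
    """L_1: the five pairwise-contrast components combined with δ1, δ2.

    Each component averages ``log q(matched) − log q(mismatched)`` over the
    full d×d ordered-pair grid; A–X, C–X and C–Y enter with the maximising
    (negative) sign, A–Y and A–C with the minimising (positive) sign.
    Gradients flow into the encoders and the δ parameters; callers freeze
    head parameters around the backward pass (see :func:`freeze_params`).
    Components named in ``exclude`` are dropped from the combination
    (used by ablations, e.g. training without the A–Y exclusion term).
    """
    d = A.shape[0]
    if d < 2:
        raise ValueError("contrastive losses need a batch of at least 2 samples")
    Y = _as_column(Y)
    diag = (np.arange(d), np.arange(d))
    signs = {"ax": -1.0, "ay": +1.0, "cx": -1.0, "cy": -1.0, "ac": +1.0}
    comps: dict[str, float] = {}
    terms: dict[str, Tensor] = {}
    for name, (head, cond, target) in zip(MIHeads.NAMES, heads.pairs(A, C, X, Y)):
        M = head.loglik_matrix(cond, target)
        contrast = M[diag].mean() - M.mean()  # (1/d^2) ΣΣ (M_ii − M_ij)
        term = contrast * signs[name]
        comps[f"l_{name}"] = term.item()
        if component_cap > 0:
            # soft magnitude cap: the identity near 0, saturating at the
            # cap — the combined objective is unbounded below and a single
            # runaway contrast would otherwise starve every other term
            term = (term * (1.0 / component_cap)).tanh() * component_cap
        terms[name] = term if name not in exclude else term * 0.0
    delta1 = delta1_raw.softplus()
    delta2 = delta2_raw.softplus()
    total = (
        terms["ax"] + terms["ay"]
        + delta1 * (terms["cx"] + terms["cy"])
        + delta2 * terms["ac"]
    )
    comps["delta1"] = delta1.item()
    comps["delta2"] = delta2.item()
    return LossBundle(total=total, components=comps)


@contextmanager
def freeze_params(module: Module):
    """Temporarily mark a module's parameters as non-trainable.

    Gradients still flow *through* the module's computations (so encoders
    upstream receive them) but are not accumulated into its parameters.
    """
    params = list(module.parameters())
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p in params:
            p.requires_grad = True


def delta_init() -> float:
    """Raw value whose softplus is exactly 1."""
    return float(np.log(np.e - 1.0))


# ---------------------------------------------------------------------------
# Standalone probe
# ---------------------------------------------------------------------------

def _loglik_matrix_np(mu: np.ndarray, sigma: np.ndarray, t: np.ndarray) -> np.ndarray:
    """M[i, j] = sum_k -(t[j,k]-mu[i,k])^2 e^{-sigma[i,k]} - sigma[i,k].

    Matmul decomposition keeps memory at O(n^2) instead of O(n^2 m).
    """
    E = np.exp(-sigma)
    term1 = E @ (t**2).T            # Σ_k E_ik t_jk²
    term2 = (mu * E) @ t.T          # Σ_k μ_ik E_ik t_jk
    const = (mu**2 * E + sigma).sum(axis=1)
    return -term1 + 2.0 * term2 - const[:, None]


def _pca_reduce(x: np.ndarray, max_dim: int, var_floor: float = 0.01) -> np.ndarray:
    """Keep at most ``max_dim`` leading components carrying real variance.

    Learned representations are often effectively low-rank; standardising
    negligible-variance components would amplify noise, so components below
    ``var_floor`` of the total variance are discarded.
    """
    if x.shape[1] <= max_dim:
        return x
    centered = x - x.mean(0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    share = sv**2 / np.sum(sv**2)
    k = max(1, min(max_dim, int(np.sum(share >= var_floor))))
    return centered @ vt[:k].T


def _ridge_directions(u: np.ndarray, v: np.ndarray, max_dim: int,
                      lam: float = 1e-2) -> np.ndarray:
    """Directions of ``u`` most predictive of ``v`` (reduced-rank ridge).

    A wide conditioning representation often hides its target-relevant
    content in low-variance directions, so the probe projects ``u`` onto the
    left singular vectors of the ridge-regression coefficient matrix rather
    than onto principal components.  Returns a (u_dim, k) projection.
    """
    n, p = u.shape
    G = u.T @ u / n + lam * np.eye(p)
    B = np.linalg.solve(G, u.T @ v / n)  # (p, v_dim)
    w, sv, _ = np.linalg.svd(B, full_matrices=False)
    k = min(max_dim, int(np.sum(sv > 1e-10 * max(sv[0], 1e-30))), v.shape[1])
    return w[:, : max(k, 1)]


def mi_probe(u: np.ndarray, v: np.ndarray, train_steps: int = 0,
             seed: int = 0, max_dim: int = 8, ridge_lambda: float = 0.1,
             var_floor: float = 1e-6) -> float:
    """Estimate the mutual information between paired samples ``u`` and ``v``.

    Fits a fresh linear-Gaussian variational head q(v|u) by maximum
    likelihood on half of the pairs (cross-fitted both ways) and returns,
    on the held-out halves, the InfoNCE contrast

        mean_i [ log q(v_i|u_i) − log-mean-exp_j log q(v_i|u_j) ]

    contrasting the matched conditioning against mismatched ones.  The
    estimate is ≈0 for independent inputs, increases with dependence, and
    matches the analytic mutual information of bivariate Gaussians closely
    when it is far below log n.

    Wide targets are reduced to their variance-carrying principal
    components; wide conditioning inputs are projected onto their most
    target-predictive ridge directions (fit-half statistics only).  Both
    reductions make wide-input estimates lower bounds on the
    full-representation MI, which is the direction the audits need.  The
    linear-Gaussian head admits an exact maximum-likelihood fit, so
    ``train_steps`` is accepted for interface compatibility but no
    iterative optimisation is required.
    """
    u = np.atleast_2d(np.asarray(u, dtype=np.float64))
    v = np.atleast_2d(np.asarray(v, dtype=np.float64))
    if u.shape[0] == 1:
        u = u.T
    if v.shape[0] == 1:
        v = v.T
    if v.shape[1] > max_dim:
        v = _pca_reduce(v, max_dim)
    n = u.shape[0]
    rng = np.random.default_rng(seed)
    split = rng.permutation(n)
    halves = (split[: n // 2], split[n // 2:])
    estimates = []
    for fit_idx, eval_idx in (halves, halves[::-1]):
        uu = _pca_reduce(u, 32, var_floor=1e-4) if u.shape[1] > max_dim else u
        uu = (uu - uu[fit_idx].mean(0)) / (uu[fit_idx].std(0) + 1e-9)
        vv = (v - v[fit_idx].mean(0)) / (v[fit_idx].std(0) + 1e-9)
        if uu.shape[1] > max_dim:
            proj = _ridge_directions(uu[fit_idx], vv[fit_idx], max_dim,
                                     lam=ridge_lambda)
            uu = uu @ proj
            uu = (uu - uu[fit_idx].mean(0)) / (uu[fit_idx].std(0) + 1e-9)
        # exact ML fit of the linear head: v | u ~ N(W[1; u], diag(s2))
        Xf = np.column_stack([np.ones(len(fit_idx)), uu[fit_idx]])
        coef, *_ = np.linalg.lstsq(Xf, vv[fit_idx], rcond=None)
        s2 = (vv[fit_idx] - Xf @ coef).var(axis=0) + var_floor
        Xe = np.column_stack([np.ones(len(eval_idx)), uu[eval_idx]])
        mu = Xe @ coef
        # M[i, j] = log q(v_j | u_i) up to shared constants
        M = -(((vv[eval_idx][None, :, :] - mu[:, None, :]) ** 2)
              / (2.0 * s2)).sum(-1)
        # InfoNCE: for each target v_i, contrast the matched conditioning
        # u_i against mismatched u_j (log-mean-exp down column i); a
        # constant critic gives exactly zero, so independence maps to ≈0
        col_max = M.max(axis=0, keepdims=True)
        lme = col_max[0] + np.log(np.exp(M - col_max).mean(axis=0))
        estimates.append(np.mean(np.diag(M) - lme))
    return float(np.mean(estimates))
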