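"""Back-door adjustment over static indicators and note tokens.

The observed confounders — static indicators ``B`` (age group, sex,
admission category, comorbidity) and the note vocabulary ``Z`` — open
back-door paths from the causal feature ``X`` to the outcome.  Intervening
on ``X`` replaces the conditional ``P(Y|X)`` by the adjusted

    P(Y|do(X)) = Σ_b P(Y|X, b) P(b) + Σ_z P(Y|X, z) P(z)

treating the two confounders as independent.  Because the classifier ends
in a softmax, the expectation over strata is moved inside the network with
the Normalized Weighted Geometric Mean (NWGM) approximation: the
prior-weighted sums are computed on the *feature* level,

    f_y(X) = α1·X + α2·Σ_b P(b)·M(b)
    f_z(X) = β1·X + β2·Σ_w P(w)·s_w·H(w),   s_w = H(w)·X / n

with ``M(b)`` a learned per-level embedding projected to X's dimension,
``H(w)`` a pretrained word vector linearly projected to X's dimension,
``s_w`` the importance of token ``w`` for ``X`` and ``n`` the feature
dimension.  The adjusted representation ``f_y(X) + f_z(X)`` is concatenated
with the confounder representation ``C`` and fed to the final classifier;
for a point-mass prior the NWGM approximation is exact.

Priors are estimated on the training split only: ``P(B)`` from level
frequencies (numeric statics bucketised into quintiles), ``P(Z)`` from
token frequencies in ICU-period notes.  Word vectors are read from GloVe
text format; out-of-vocabulary tokens are dropped with renormalisation and
a logged count.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .nn import Linear, Module, Tensor, concat

__all__ = [
    "load_word_vectors",
    "save_word_vectors",
    "AdjustmentContext",
    "build_context",
    "f_y",
    "f_z",
    "do_predict",
    "softmax",
]

logger = logging.getLogger(__name__)

EMB_DIM = 32  # per-level static embedding width before projection to X's dim


def load_word_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read a GloVe-format text file: token then whitespace-separated floats."""
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            tok, vals = parts[0], np.array(parts[1:], dtype=np.float64)
            if dim is None:
                dim = len(vals)
            elif len(vals) != dim:
                raise ValueError(
                    f"inconsistent vector width for {tok!r}: {len(vals)} != {dim}"
                )
            vectors[tok] = vals
    if not vectors:
        raise ValueError(f"no word vectors found in {path}")
    return vectors


def save_word_vectors(path: str | Path, vectors: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for tok, vec in vectors.items():
            fh.write(tok + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")


def _check_normalized(p: np.ndarray, what: str) -> None:
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"{what} prior is not a normalized distribution")


class AdjustmentContext(Module):
    """Priors and learned effect tables used by the adjustment.

    Holds, per static feature, the level prior ``P(B)`` and a learned
    embedding row per level (projected to X's dimension through a fully
    connected layer), plus the token prior ``P(Z)``, the fixed word-vector
    table ``H(Z)`` with its learned projection, and the trainable mixing
    scalars α1, α2, β1, β2.
    """

    def __init__(self, feature_levels: dict[str, list[str]],
                 feature_priors: dict[str, np.ndarray],
                 vocab: list[str], p_z: np.ndarray, h_raw: np.ndarray,
                 n: int, rng: np.random.Generator,
                 numeric_edges: dict[str, np.ndarray] | None = None,
                 oov_dropped: int = 0):
        super().__init__()
        self.n = n
        self.feature_levels = feature_levels
        self.feature_priors = {k: np.asarray(v, float) for k, v in feature_priors.items()}
        for name, p in self.feature_priors.items():
            _check_normalized(p, f"static feature {name!r}")
        self.vocab = list(vocab)
        self.p_z = np.asarray(p_z, dtype=np.float64)
        _check_normalized(self.p_z, "token")
        self.h_raw = np.asarray(h_raw, dtype=np.float64)  # (V, d_glove), fixed
        self.numeric_edges = numeric_edges or {}
        self.oov_dropped = oov_dropped
        # learned parts
        total_levels = sum(len(v) for v in feature_levels.values())
        self.level_embeddings = Tensor(
            rng.normal(scale=0.1, size=(total_levels, EMB_DIM)), requires_grad=True
        )
        self.m_proj = Linear(EMB_DIM, n, rng)
        self.h_proj = Linear(self.h_raw.shape[1], n, rng)
        # α1 = β1 = 1/2 makes the α2 = β2 = 0 configuration the identity on X
        self.alpha1 = Tensor(np.array(0.5), requires_grad=True)
        self.alpha2 = Tensor(np.array(0.1), requires_grad=True)
        self.beta1 = Tensor(np.array(0.5), requires_grad=True)
        self.beta2 = Tensor(np.array(0.1), requires_grad=True)
        # row offsets of each feature's levels in the embedding table
        self._offsets: dict[str, int] = {}
        off = 0
        for name, levels in feature_levels.items():
            self._offsets[name] = off
            off += len(levels)

    # -- adjustment terms ----------------------------------------------------
    def static_adjustment(self) -> Tensor:
        """Σ_b P(b) M(b), averaged over static features → (n,) vector."""
        m_all = self.m_proj(self.level_embeddings)  # (total_levels, n)
        terms = []
        for name, levels in self.feature_levels.items():
            off = self._offsets[name]
            p = Tensor(self.feature_priors[name].reshape(len(levels), 1))
            terms.append((m_all[off:off + len(levels)] * p).sum(axis=0))
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total * (1.0 / len(terms))

    def projected_word_vectors(self) -> Tensor:
        return self.h_proj(Tensor(self.h_raw))  # (V, n)


def f_y(X: Tensor | np.ndarray, ctx: AdjustmentContext) -> Tensor:
    """Static-indicator adjustment: α1·X + α2·Σ_b P(b)·M(b)."""
    X = Tensor.as_tensor(X)
    return ctx.alpha1 * X + ctx.alpha2 * ctx.static_adjustment()


def f_z(X: Tensor | np.ndarray, ctx: AdjustmentContext,
        softmax_importance: bool = False) -> Tensor:
    """Note-token adjustment: β1·X + β2·Σ_w P(w)·s_w·H(w).

    ``s_w = H(w)·X / n`` scores each token's importance for X; scores are
    used raw by default, with an optional softmax normalisation for
    sensitivity analysis.
    """
    X = Tensor.as_tensor(X)
    H = ctx.projected_word_vectors()                     # (V, n)
    s = (X @ H.transpose()) * (1.0 / ctx.n)              # (N, V)
    if softmax_importance:
        s = s - s.logsumexp(axis=-1, keepdims=True)
        s = s.exp()
    weighted = s * Tensor(ctx.p_z)                       # (N, V)
    term = weighted @ H                                  # (N, n)
    return ctx.beta1 * X + ctx.beta2 * term


def softmax(logits: Tensor) -> Tensor:
    return (logits - logits.logsumexp(axis=-1, keepdims=True)).exp()


def do_predict(X: Tensor | np.ndarray, C: Tensor | np.ndarray,
               ctx: AdjustmentContext, classifier: Module,
               use_b: bool = True, use_z: bool = True) -> Tensor:
    """P(Y|do(X)): softmax of the classifier on [f_y(X)+f_z(X); C].

    The expectations over B and Z strata are the prior-weighted sums inside
    ``f_y``/``f_z`` (the NWGM linearisation); no sampling over strata.
    Disabling a branch (``use_b``/``use_z``) replaces its term by the plain
    half-identity α1·X (resp. β1·X) so the two halves still sum to X-scale.
    """
    X, C = Tensor.as_tensor(X), Tensor.as_tensor(C)
    ya = f_y(X, ctx) if use_b else ctx.alpha1 * X
    za = f_z(X, ctx) if use_z else ctx.beta1 * X
    x_adj = ya + za
    logits = classifier(concat([x_adj, C], axis=1))
    return softmax(logits)


# ---------------------------------------------------------------------------
# Context construction
# ---------------------------------------------------------------------------

def _quintile_levels(values: np.ndarray) -> tuple[list[str], np.ndarray]:
    edges = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    labels = [f"q{i + 1}" for i in range(5)]
    return labels, edges


def bucketize(value: float, edges: np.ndarray) -> str:
    return f"q{int(np.searchsorted(edges, value, side='right')) + 1}"


def build_context(static_records: list[dict], note_bags: list[list[tuple[str, int]]],
                  word_vectors: dict[str, np.ndarray] | str | Path,
                  n: int = 128, seed: int = 0,
                  coverage_threshold: float = 0.9) -> AdjustmentContext:
    """Estimate priors from the training split and assemble the context.

    ``static_records`` are the per-episode B mappings; numeric fields are
    bucketised into quintiles before level counting.  ``note_bags`` are the
    per-episode (token, count) lists; tokens without a word vector are
    dropped from P(Z) with renormalisation.
    """
    if not note_bags or not any(note_bags):
        raise ValueError("empty note corpus: cannot estimate token priors")
    if not isinstance(word_vectors, dict):
        word_vectors = load_word_vectors(word_vectors)
    rng = np.random.default_rng(seed)

    # static priors
    keys = sorted({k for rec in static_records for k in rec})
    feature_levels: dict[str, list[str]] = {}
    feature_priors: dict[str, np.ndarray] = {}
    numeric_edges: dict[str, np.ndarray] = {}
    for key in keys:
        vals = [rec[key] for rec in static_records if key in rec]
        if all(isinstance(v, (int, float, np.integer, np.floating))
               and not isinstance(v, bool) for v in vals):
            labels_, edges = _quintile_levels(np.asarray(vals, float))
            numeric_edges[key] = edges
            lvls = [bucketize(float(v), edges) for v in vals]
        else:
            lvls = [str(v) for v in vals]
            labels_ = sorted(set(lvls))
        counts = np.array([lvls.count(lab) for lab in labels_], dtype=np.float64)
        feature_levels[key] = labels_
        feature_priors[key] = counts / counts.sum()

    # token priors over the covered vocabulary
    counts: dict[str, float] = {}
    total_mass = 0.0
    dropped = 0
    for bag in note_bags:
        for tok, c in bag:
            total_mass += c
            if tok in word_vectors:
                counts[tok] = counts.get(tok, 0.0) + c
            else:
                dropped += c
    if not counts:
        raise ValueError("no note token has a word vector")
    coverage = 1.0 - dropped / total_mass
    if coverage < coverage_threshold:
        warnings.warn(
            f"word-vector coverage {coverage:.3f} below threshold "
            f"{coverage_threshold} ({dropped:.0f} token occurrences dropped)"
        )
    if dropped:
        logger.info("dropped %d out-of-vocabulary token occurrences", dropped)
    vocab = sorted(counts)
    p_z = np.array([counts[t] for t in vocab])
    p_z = p_z / p_z.sum()
    h_raw = np.stack([word_vectors[t] for t in vocab])
    return AdjustmentContext(
        feature_levels, feature_priors, vocab, p_z, h_raw, n, rng,
        numeric_edges=numeric_edges, oov_dropped=int(dropped),
    )
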