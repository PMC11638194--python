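"""The assembled predictor and its two-stage training loop.

One model per prediction horizon: the encoder pair produces the candidate
instrument ``A``, the confounder representation ``C`` and the causal
feature ``X``; the back-door adjustment maps ``X`` to its intervened form;
a small fully connected classifier on ``[X_adj; C]`` outputs the sepsis
probability.  Training alternates

* ``k`` head-fitting steps per batch — the five variational heads minimise
  ``L_LLL`` on detached encoder outputs (only head parameters move);
* one main step — minimise classification cross-entropy plus
  ``lambda_causal * L_1`` through the encoders, fuse, adjustment and
  classifier, with head parameters frozen.

Setting ``lambda_causal = 0`` and disabling the adjustment reduces the
system to a plain supervised model, used as the confounded baseline.
Ablation variants reproduce the component grid of the ablation study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import backdoor as bd
from .encoder import ENCODING_DIM, EncoderPair
from .mi import (
    MIHeads,
    contrastive_loss,
    delta_init,
    fit_heads_loss,
    freeze_params,
)
from .nn import MLP, Adam, Module, Tensor, concat, default_dtype, no_grad
from .records import EpisodeRecord, stack_observations

__all__ = [
    "TrainConfig",
    "SepsisCausalModel",
    "Checkpoint",
    "train",
    "predict",
    "ablate",
    "ABLATION_VARIANTS",
]

logger = logging.getLogger(__name__)


def _clip_gradients(params, max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in params
                        if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale

ABLATION_VARIANTS = ("iv_only", "iv_plus_Z", "iv_plus_B", "backdoor_only",
                     "full", "plain")


@dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 64
    lr_heads: float = 1e-3
    lr_main: float = 1e-3
    k_head_steps: int = 5
    lambda_causal: float = 1.0
    horizon_h: int = 3
    seed: int = 0
    x_dim: int = ENCODING_DIM
    bernoulli_y: bool = False
    use_mi: bool = True
    use_b: bool = True
    use_z: bool = True
    mi_exclude: tuple = ()  # contrastive components dropped from L_1
    warmup_epochs: int = 1  # supervised-only epochs before causal losses
    grad_clip: float = 5.0  # global gradient-norm ceiling per step
    dtype: str = "float32"  # training precision; inference upcasts exactly

    def __post_init__(self):
        self.mi_exclude = tuple(self.mi_exclude)
        for name in ("epochs", "batch_size", "k_head_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_causal < 0:
            raise ValueError("lambda_causal must be non-negative")

    @property
    def use_backdoor(self) -> bool:
        return self.use_b or self.use_z


class SepsisCausalModel(Module):
    """Encoders + variational heads + adjustment + classifier."""

    def __init__(self, t: int, o: int, cfg: TrainConfig,
                 ctx: bd.AdjustmentContext | None):
        super().__init__()
        rng = np.random.default_rng([cfg.seed, 11])
        self.t, self.o = t, o
        self.cfg = cfg
        self.enc = EncoderPair(t, o, rng, x_dim=cfg.x_dim)
        self.heads = MIHeads(rng, x_dim=cfg.x_dim, bernoulli_y=cfg.bernoulli_y)
        self.ctx = ctx
        self.classifier = MLP([cfg.x_dim + ENCODING_DIM, 64, 2], rng,
                              activation="relu")
        self.delta1_raw = Tensor(np.array(delta_init()), requires_grad=True)
        self.delta2_raw = Tensor(np.array(delta_init()), requires_grad=True)

    def logits(self, X: Tensor, C: Tensor) -> Tensor:
        cfg = self.cfg
        if cfg.use_backdoor:
            ya = bd.f_y(X, self.ctx) if cfg.use_b else self.ctx.alpha1 * X
            za = bd.f_z(X, self.ctx) if cfg.use_z else self.ctx.beta1 * X
            x_adj = ya + za
        else:
            x_adj = X
        return self.classifier(concat([x_adj, C], axis=1))

    def main_parameters(self):
        """Everything updated by the main step (never head parameters)."""
        head_ids = {id(p) for p in self.heads.parameters()}
        return [p for p in self.parameters() if id(p) not in head_ids]

    def predict_proba(self, O: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode P(Y=1) per episode; deterministic, batch invariant."""
        was_training = self.training
        self.eval()
        out = []
        with no_grad():
            for lo in range(0, len(O), batch_size):
                A, C, X = self.enc(Tensor(O[lo:lo + batch_size]))
                probs = bd.softmax(self.logits(X, C))
                out.append(probs.data[:, 1])
        self.train(was_training)
        return np.concatenate(out) if out else np.zeros(0)


@dataclass
class Checkpoint:
    model: SepsisCausalModel
    cfg: TrainConfig
    metrics: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        m = self.model
        meta = {
            "t": m.t,
            "o": m.o,
            "cfg": asdict(self.cfg),
            "metrics": self.metrics,
            "ctx": None,
        }
        if m.ctx is not None:
            meta["ctx"] = {
                "feature_levels": m.ctx.feature_levels,
                "feature_priors": {k: v.tolist() for k, v in
                                   m.ctx.feature_priors.items()},
                "vocab": m.ctx.vocab,
                "numeric_edges": {k: v.tolist() for k, v in
                                  m.ctx.numeric_edges.items()},
                "oov_dropped": m.ctx.oov_dropped,
                "glove_dim": int(m.ctx.h_raw.shape[1]) if m.ctx.h_raw.size
                             else 1,
            }
        arrays = m.state_arrays("model.")
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @staticmethod
    def load(path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(bytes(arrays.pop("meta_json")).decode())
        cfg = TrainConfig(**meta["cfg"])
        ctx = None
        if meta["ctx"] is not None:
            c = meta["ctx"]
            ctx = bd.AdjustmentContext(
                feature_levels=c["feature_levels"],
                feature_priors={k: np.array(v) for k, v in
                                c["feature_priors"].items()},
                vocab=c["vocab"],
                p_z=arrays["model.ctx.p_z"],
                h_raw=arrays["model.ctx.h_raw"],
                n=cfg.x_dim,
                rng=np.random.default_rng(0),
                numeric_edges={k: np.array(v) for k, v in
                               c["numeric_edges"].items()},
                oov_dropped=c["oov_dropped"],
            )
        model = SepsisCausalModel(meta["t"], meta["o"], cfg, ctx)
        model.load_state_arrays(arrays, "model.")
        model.eval()
        return Checkpoint(model=model, cfg=cfg, metrics=meta["metrics"])


def _build_context(train_eps: list[EpisodeRecord], cfg: TrainConfig,
                   word_vectors) -> bd.AdjustmentContext | None:
    if not cfg.use_backdoor:
        return None
    statics = [ep.B for ep in train_eps] if cfg.use_b else [{} for _ in train_eps]
    if cfg.use_z:
        if word_vectors is None:
            raise ValueError("use_z requires word vectors")
        if not isinstance(word_vectors, dict):
            word_vectors = bd.load_word_vectors(word_vectors)
        bags = [ep.Z for ep in train_eps]
        return bd.build_context([s for s in statics if s] or [{}],
                                bags, word_vectors, n=cfg.x_dim, seed=cfg.seed)
    # static-only context: trivial one-token note side, never used
    dummy_vecs = {"_": np.zeros(1)}
    return bd.build_context(statics, [[("_", 1)]], dummy_vecs,
                            n=cfg.x_dim, seed=cfg.seed)


def _class_nll(logits: Tensor, y: np.ndarray) -> Tensor:
    logp = logits - logits.logsumexp(axis=-1, keepdims=True)
    picked = logp[np.arange(len(y)), y.astype(int)]
    return -picked.mean()


def train(train_eps: list[EpisodeRecord], cfg: TrainConfig,
          word_vectors=None, metrics_path: str | Path | None = None
          ) -> Checkpoint:
    """Two-stage training; returns the final (or last-good) checkpoint."""
    with default_dtype(cfg.dtype):
        return _train(train_eps, cfg, word_vectors, metrics_path)


def _train(train_eps: list[EpisodeRecord], cfg: TrainConfig,
           word_vectors=None, metrics_path: str | Path | None = None
           ) -> Checkpoint:
    if not train_eps:
        raise ValueError("no training episodes")
    O_all = stack_observations(train_eps)
    y_all = np.array([ep.Y for ep in train_eps], dtype=np.int64)
    t, o = O_all.shape[1], O_all.shape[2]
    ctx = _build_context(train_eps, cfg, word_vectors)
    model = SepsisCausalModel(t, o, cfg, ctx)
    opt_main = Adam(model.main_parameters(), lr=cfg.lr_main)
    opt_heads = Adam(list(model.heads.parameters()), lr=cfg.lr_heads)
    rng = np.random.default_rng([cfg.seed, 12])
    use_causal = cfg.use_mi and cfg.lambda_causal > 0
    log_rows: list[tuple] = []
    last_good = model.state_arrays()
    step = 0
    diverged = False
    for epoch in range(cfg.epochs):
        causal_now = use_causal and epoch >= cfg.warmup_epochs
        order = rng.permutation(len(train_eps))
        try:
            for lo in range(0, len(order) - 1, cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                if len(idx) < 2:
                    continue
                O = Tensor(O_all[idx])
                y = y_all[idx]
                y_t = y.astype(np.float64)
                if use_causal:
                    with no_grad():
                        A_d, C_d, X_d = model.enc(O)
                    for _ in range(cfg.k_head_steps):
                        bundle = fit_heads_loss(model.heads, A_d, C_d, X_d, y_t)
                        opt_heads.zero_grad()
                        bundle.total.backward()
                        _clip_gradients(opt_heads.params, cfg.grad_clip)
                        opt_heads.step()
                    log_rows.append((step, "l_lll", bundle.total.item()))
                A, C, X = model.enc(O)
                cls = _class_nll(model.logits(X, C), y)
                log_rows.append((step, "cls", cls.item()))
                if causal_now:
                    l1 = contrastive_loss(model.heads, A, C, X, y_t,
                                          model.delta1_raw, model.delta2_raw,
                                          exclude=tuple(cfg.mi_exclude))
                    total = cls + cfg.lambda_causal * l1.total
                    for name, val in l1.components.items():
                        log_rows.append((step, name, val))
                else:
                    total = cls
                if not np.isfinite(total.data):
                    raise FloatingPointError("non-finite training loss")
                opt_main.zero_grad()
                with freeze_params(model.heads):
                    total.backward()
                _clip_gradients(opt_main.params, cfg.grad_clip)
                opt_main.step()
                step += 1
        except FloatingPointError:
            logger.warning("training diverged at epoch %d; restoring last-good "
                           "checkpoint", epoch)
            model.load_state_arrays(last_good)
            diverged = True
            break
        last_good = model.state_arrays()
    model.eval()
    metrics = {
        "final_cls_loss": next((v for s, n, v in reversed(log_rows)
                                if n == "cls"), float("nan")),
        "steps": step,
        "diverged": diverged,
    }
    if metrics_path is not None:
        with open(metrics_path, "w") as fh:
            fh.write("step,loss,value,seed\n")
            for s, name, val in log_rows:
                fh.write(f"{s},{name},{val:.6f},{cfg.seed}\n")
    return Checkpoint(model=model, cfg=cfg, metrics=metrics)


def predict(ckpt: Checkpoint | SepsisCausalModel,
            episodes: list[EpisodeRecord], batch_size: int = 256) -> np.ndarray:
    """Per-episode P(sepsis within horizon), in [0, 1]."""
    model = ckpt.model if isinstance(ckpt, Checkpoint) else ckpt
    O = stack_observations(episodes)
    if O.shape[1:] != (model.t, model.o):
        raise ValueError(
            f"episode windows of shape {O.shape[1:]} do not match the "
            f"checkpoint's ({model.t}, {model.o})"
        )
    return model.predict_proba(O, batch_size=batch_size)


def variant_config(variant: str, cfg: TrainConfig) -> TrainConfig:
    """Translate an ablation variant name into training flags."""
    table = {
        "iv_only": dict(use_mi=True, use_b=False, use_z=False),
        "iv_plus_Z": dict(use_mi=True, use_b=False, use_z=True),
        "iv_plus_B": dict(use_mi=True, use_b=True, use_z=False),
        "backdoor_only": dict(use_mi=False, lambda_causal=0.0,
                              use_b=True, use_z=True),
        "full": dict(use_mi=True, use_b=True, use_z=True),
        "plain": dict(use_mi=False, lambda_causal=0.0,
                      use_b=False, use_z=False),
    }
    if variant not in table:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {ABLATION_VARIANTS}"
        )
    return replace(cfg, **table[variant])


def ablate(variant: str, train_eps: list[EpisodeRecord],
           test_eps: list[EpisodeRecord], cfg: TrainConfig,
           word_vectors=None) -> dict:
    """Train one ablation variant and score it on the test episodes."""
    from .evaluate import auc  # local import to avoid a cycle

    vcfg = variant_config(variant, cfg)
    wv = word_vectors if vcfg.use_z else None
    ckpt = train(train_eps, vcfg, word_vectors=wv)
    scores = predict(ckpt, test_eps)
    labels = np.array([ep.Y for ep in test_eps])
    return {"variant": variant, "auc": auc(scores, labels), "checkpoint": ckpt}
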