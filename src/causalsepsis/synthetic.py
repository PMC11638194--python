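"""Synthetic ICU episodes from a structural causal model with known truth.

The generator mirrors the causal graph the predictor is built for: a latent
severity ``s`` drives the outcome through the causal path, an unobserved
confounder ``e`` and two observed confounder traits — a note tilt ``z`` and
a demographic tilt ``b`` — open back-door paths by influencing both the
observations and the outcome:

    logit P(Y=1) = b0 + beta_causal*s + gamma_e*e + gamma_Z*z + gamma_B*b

Observation channels are partitioned (by a seed-fixed permutation, recorded
in the manifest) into severity-signal channels with lagged temporal ramps,
nuisance channels driven by ``e``, ``z`` and ``b``, and pure-noise channels.
The severity signal-to-noise ratio grows as the window approaches onset, so
shorter prediction horizons are genuinely easier.  Note tokens follow a
Zipf prior tilted towards designated severity and confounder token subsets;
static indicators (age, sex, admission category, comorbidity count) are
drawn with priors that up-weight elderly and comorbid patients.

``make_interventional_split`` regenerates the same episodes with the Z→Y
and B→Y edges severed (their tilt terms removed from the outcome equation)
while all marginals of O, B and Z are untouched — the test bed for
confounding-robustness claims.  ``linear_iv_benchmark`` emits the classic
linear-Gaussian instrument/exposure/outcome triple for oracle-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .records import EpisodeRecord

__all__ = [
    "SCMConfig",
    "GroundTruth",
    "simulate_episodes",
    "make_interventional_split",
    "synthetic_word_vectors",
    "linear_iv_benchmark",
    "linear_iv_observations",
]

WORD_VECTOR_DIM = 50
TOKENS_PER_NOTE = 40
N_SEVERITY_TOKENS = 50
N_CONFOUNDER_TOKENS = 50
BASE_LOGIT = -1.1          # outcome base rate at zero tilts
AMP_FLOOR = 0.6            # severity signal amplitude at the longest horizon
AMP_CEIL = 2.0             # severity signal amplitude at onset


@dataclass
class SCMConfig:
    """Parameters of the synthetic structural causal model.

    Effect strengths are on the logit scale; setting all three gammas to 0
    yields an unconfounded generator.  Defaults give a strongly confounded
    cohort whose full training run still fits in minutes on one CPU.
    """

    n_stays: int = 5000
    t: int = 24
    o: int = 20
    beta_causal: float = 2.0
    gamma_e: float = 0.8
    gamma_Z: float = 1.5
    gamma_B: float = 1.0
    vocab_size: int = 500
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("beta_causal", "gamma_e", "gamma_Z", "gamma_B", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config value for {name}")
        if self.n_stays <= 0:
            raise ValueError("n_stays must be positive")
        if self.o < 16:
            raise ValueError("need at least 16 observation channels")
        if self.vocab_size < N_SEVERITY_TOKENS + N_CONFOUNDER_TOKENS + 10:
            raise ValueError("vocab_size too small for the token subsets")


@dataclass
class GroundTruth:
    """Per-episode latents, never exposed to the model."""

    s: np.ndarray
    e: np.ndarray
    z_tilt: np.ndarray
    b_tilt: np.ndarray
    p_obs: np.ndarray       # P(Y=1) under the observational equation
    p_int: np.ndarray       # P(Y=1) with Z→Y and B→Y severed
    channel_roles: dict[str, list[int]] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {"channel_roles": self.channel_roles}


def _channel_roles(o: int, rng: np.random.Generator) -> dict[str, list[int]]:
    """Seed-fixed assignment of channels to causal roles."""
    perm = rng.permutation(o)
    n_sig = max(3, (3 * o) // 10)
    n_e = max(2, o // 5)
    n_z = max(2, (3 * o) // 20)
    n_b = max(2, (3 * o) // 20)
    idx = np.cumsum([n_sig, n_e, n_z, n_b])
    return {
        "signal": sorted(int(c) for c in perm[: idx[0]]),
        "e": sorted(int(c) for c in perm[idx[0]: idx[1]]),
        "z": sorted(int(c) for c in perm[idx[1]: idx[2]]),
        "b": sorted(int(c) for c in perm[idx[2]: idx[3]]),
        "noise": sorted(int(c) for c in perm[idx[3]:]),
    }


def signal_amplitude(horizon_h: int) -> float:
    """Severity SNR multiplier: grows linearly as the window nears onset.

    Windows ending closer to onset carry a stronger physiological signal,
    from ``AMP_FLOOR`` at horizon 6 up to ``AMP_CEIL`` at horizon 0.
    """
    return AMP_FLOOR + (AMP_CEIL - AMP_FLOOR) * (6 - horizon_h) / 6.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _simulate(cfg: SCMConfig, horizon_h: int, interventional: bool
              ) -> tuple[list[EpisodeRecord], GroundTruth]:
    if not 0 <= horizon_h <= 6:
        raise ValueError(f"horizon_h must be in [0, 6], got {horizon_h}")
    # all latent draws are horizon-independent: the same stays observed at
    # different distances to onset differ only in signal strength
    rng = np.random.default_rng([cfg.seed, 100])
    n, t, o = cfg.n_stays, cfg.t, cfg.o
    roles = _channel_roles(o, np.random.default_rng([cfg.seed, 101]))

    # latents
    s = rng.normal(size=n)
    e = rng.normal(size=n)
    z_tilt = rng.normal(size=n)

    # static indicators with demographic priors
    age = np.clip(rng.normal(64, 16, size=n), 18, 99)
    sex = rng.choice(["F", "M"], size=n, p=[0.45, 0.55])
    admission = rng.choice(["medical", "surgical", "emergency"], size=n,
                           p=[0.5, 0.3, 0.2])
    comorbidity = np.minimum(rng.poisson(1.5, size=n), 6)
    b_tilt = (
        0.02 * (age - 64.0)
        + 0.45 * (comorbidity - 1.5)
        + 0.40 * (admission == "emergency")
    ) / 0.75

    # outcome, with the interventional equation sharing the uniform draws
    logit_obs = (
        BASE_LOGIT + cfg.beta_causal * s + cfg.gamma_e * e
        + cfg.gamma_Z * z_tilt + cfg.gamma_B * b_tilt
    )
    logit_int = BASE_LOGIT + cfg.beta_causal * s + cfg.gamma_e * e
    p_obs, p_int = _sigmoid(logit_obs), _sigmoid(logit_int)
    u_y = rng.uniform(size=n)
    y = (u_y < (p_int if interventional else p_obs)).astype(int)

    # observation windows: severity enters through lagged within-window
    # ramps (temporal structure for the encoder) scaled by a horizon-level
    # amplitude that grows as the window nears onset
    tau = np.arange(t) / max(t - 1, 1)
    amp = signal_amplitude(horizon_h)
    O = rng.normal(scale=cfg.noise_sd, size=(n, t, o))
    role_rng = np.random.default_rng([cfg.seed, 102])
    lags = role_rng.uniform(0.0, 0.6, size=len(roles["signal"]))
    for k, ch in enumerate(roles["signal"]):
        ramp = np.clip((tau - lags[k]) / (1.0 - lags[k]), 0.0, None)
        O[:, :, ch] += s[:, None] * (amp * ramp)[None, :] * 1.5
    profiles = role_rng.normal(scale=0.4, size=(3, t))
    for k, ch in enumerate(roles["e"]):
        O[:, :, ch] += e[:, None] * (1.0 + profiles[0][None, :])
    for k, ch in enumerate(roles["z"]):
        O[:, :, ch] += z_tilt[:, None] * (1.0 + profiles[1][None, :])
    for k, ch in enumerate(roles["b"]):
        O[:, :, ch] += b_tilt[:, None] * (1.0 + profiles[2][None, :])

    # note tokens: Zipf prior tilted by severity and the confounder trait
    V = cfg.vocab_size
    zipf = 1.0 / np.arange(1, V + 1) ** 1.1
    tok_rng = np.random.default_rng([cfg.seed, 103])
    tok_perm = tok_rng.permutation(V)
    sev_tokens = tok_perm[:N_SEVERITY_TOKENS]
    conf_tokens = tok_perm[N_SEVERITY_TOKENS:N_SEVERITY_TOKENS + N_CONFOUNDER_TOKENS]
    base_log = np.log(zipf / zipf.sum())
    logits = np.tile(base_log, (n, 1))
    logits[:, sev_tokens] += 0.8 * s[:, None]
    logits[:, conf_tokens] += 0.8 * z_tilt[:, None]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    episodes: list[EpisodeRecord] = []
    for i in range(n):
        counts = rng.multinomial(TOKENS_PER_NOTE, probs[i])
        nz = np.nonzero(counts)[0]
        bag = [(f"w{j:04d}", int(counts[j])) for j in nz]
        episodes.append(
            EpisodeRecord(
                stay_id=i,
                O=O[i],
                B={
                    "age": float(age[i]),
                    "sex": str(sex[i]),
                    "admission_type": str(admission[i]),
                    "comorbidity": int(comorbidity[i]),
                },
                Z=bag,
                Y=int(y[i]),
                horizon_h=horizon_h,
            )
        )
    gt = GroundTruth(s=s, e=e, z_tilt=z_tilt, b_tilt=b_tilt,
                     p_obs=p_obs, p_int=p_int, channel_roles=roles)
    return episodes, gt


def simulate_episodes(cfg: SCMConfig, horizon_h: int = 3
                      ) -> tuple[list[EpisodeRecord], GroundTruth]:
    """Observational episodes plus their ground-truth latents."""
    return _simulate(cfg, horizon_h, interventional=False)


def make_interventional_split(cfg: SCMConfig, horizon_h: int = 3
                              ) -> list[EpisodeRecord]:
    """The same generator with the Z→Y and B→Y edges severed.

    Identical draws to :func:`simulate_episodes` for the same config — only
    the outcome equation drops the observed-confounder tilt terms, so the
    marginals of O, B and Z coincide by construction.  Evaluation only.
    """
    episodes, _ = _simulate(cfg, horizon_h, interventional=True)
    return episodes


def interventional_with_truth(cfg: SCMConfig, horizon_h: int = 3
                              ) -> tuple[list[EpisodeRecord], GroundTruth]:
    return _simulate(cfg, horizon_h, interventional=True)


def synthetic_word_vectors(cfg: SCMConfig, dim: int = WORD_VECTOR_DIM
                           ) -> dict[str, np.ndarray]:
    """Random unit vectors per token, fixed by the config seed.

    Synthetic stand-in for pretrained embeddings in GloVe text format; see
    :func:`causalsepsis.backdoor.save_word_vectors` to serialise them.
    """
    rng = np.random.default_rng([cfg.seed, 104])
    vecs = rng.normal(size=(cfg.vocab_size, dim))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return {f"w{j:04d}": vecs[j] for j in range(cfg.vocab_size)}


# ---------------------------------------------------------------------------
# Linear instrumental-variable benchmark
# ---------------------------------------------------------------------------

def linear_iv_benchmark(n: int, beta: float, conf: float, seed: int = 0) -> dict:
    """Classic linear-Gaussian IV triple with known causal effect.

    ``a`` is a valid instrument for the exposure ``x``; the confounder ``u``
    enters both the exposure and the outcome with strength ``conf``, so
    ordinary least squares of ``y`` on ``x`` is biased while two-stage least
    squares recovers ``beta``.
    """
    if n < 100:
        raise ValueError(f"need n >= 100, got {n}")
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    u = rng.normal(size=n)
    x = a + conf * u + 0.5 * rng.normal(size=n)
    y = beta * x + conf * u + 0.5 * rng.normal(size=n)
    return {"a": a, "x": x, "y": y, "u": u, "beta": beta, "conf": conf}


def linear_iv_observations(n: int, beta: float, conf: float, seed: int = 0,
                           t: int = 8, o: int = 6) -> dict:
    """The linear IV benchmark embedded as observation windows.

    Channel 0 carries the instrument, channel 1 the exposure, channels 2–3
    the confounded error, the rest pure noise; each is repeated over the
    time axis with small independent jitter.  Used to probe whether learned
    instrument representations de-bias a linear effect estimate.
    """
    data = linear_iv_benchmark(n, beta, conf, seed)
    rng = np.random.default_rng([seed, 105])
    O = rng.normal(scale=0.3, size=(n, t, o))
    O[:, :, 0] += data["a"][:, None]
    O[:, :, 1] += data["x"][:, None]
    O[:, :, 2] += data["u"][:, None]
    O[:, :, 3] += data["u"][:, None]
    data["O"] = O
    return data
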