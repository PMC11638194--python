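"""Metrics and reports: AUC per horizon, ablation tables, causal gap.

AUC is the area under the ROC curve computed from the rank statistic with
midrank tie handling.  The observational-versus-interventional
generalisation gap — AUC on a synthetic split with confounder→outcome
edges severed minus AUC on the matched observational split — measures how
much of a model's apparent skill rests on confounded shortcuts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .records import EpisodeRecord

__all__ = [
    "auc",
    "bootstrap_auc_ci",
    "MetricReport",
    "horizon_report",
    "generalization_gap",
]

HORIZONS = tuple(range(7))


def auc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes present."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError(
            f"AUC needs both classes; labels contain only {classes.tolist()}"
        )
    return float(roc_auc_score(labels, scores))


def bootstrap_auc_ci(scores, labels, n_boot: int = 1000, seed: int = 0,
                     level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the AUC over episodes."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    vals = []
    n = len(scores)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        vals.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    """Per-horizon AUCs with a monotonicity diagnostic.

    ``trend`` is the Spearman rank correlation between AUC and time-to-onset
    (negative values mean performance improves as onset nears, the pattern
    expected when the physiological signal intensifies before onset).
    """

    auc_by_horizon: dict[int, float]
    trend: float
    seeds: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "auc_by_horizon": {str(k): v for k, v in
                                   self.auc_by_horizon.items()},
                "trend": self.trend,
                "seeds": self.seeds,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @staticmethod
    def from_json(text_or_path: str | Path) -> "MetricReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        obj = json.loads(text)
        return MetricReport(
            auc_by_horizon={int(k): v for k, v in obj["auc_by_horizon"].items()},
            trend=obj["trend"],
            seeds=list(obj.get("seeds", [])),
        )


def horizon_report(checkpoints: dict[int, object],
                   episodes_by_h: dict[int, list[EpisodeRecord]],
                   seeds: list[int] | None = None) -> MetricReport:
    """One AUC per horizon h = 0..6 on the held-out episodes."""
    from .model import predict  # local import to avoid a cycle
    from scipy.stats import spearmanr

    missing = [h for h in HORIZONS if h not in checkpoints or h not in episodes_by_h]
    if missing:
        raise ValueError(f"missing horizons: {missing}")
    aucs = {}
    for h in HORIZONS:
        eps = episodes_by_h[h]
        scores = predict(checkpoints[h], eps)
        aucs[h] = auc(scores, [ep.Y for ep in eps])
    hs = np.array(sorted(aucs))
    vals = np.array([aucs[h] for h in hs])
    trend = float(spearmanr(hs, vals).statistic) if len(set(vals)) > 1 else 0.0
    return MetricReport(auc_by_horizon=aucs, trend=trend, seeds=seeds or [])


def plot_horizon_aucs(report: MetricReport, path: str | Path,
                      label: str = "causal model") -> None:
    """Bar plot of AUC against hours-to-onset (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hs = sorted(report.auc_by_horizon)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar([str(h) for h in hs], [report.auc_by_horizon[h] for h in hs],
           color="#4878a8", label=label)
    ax.set_xlabel("hours before onset")
    ax.set_ylabel("AUC")
    ax.set_ylim(0.5, 1.0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def generalization_gap(ckpt, observational: list[EpisodeRecord],
                       interventional: list[EpisodeRecord]) -> float:
    """AUC on the interventional split minus AUC on the observational split.

    Near zero for a model whose skill is causal; clearly negative when the
    model leans on confounded shortcuts that the severed split removes.
    """
    from .model import predict

    if not observational or not interventional:
        raise ValueError("both splits must be non-empty")
    shapes = {observational[0].O.shape, interventional[0].O.shape}
    if len(shapes) != 1:
        raise ValueError(f"mismatched window shapes across splits: {shapes}")
    auc_obs = auc(predict(ckpt, observational), [ep.Y for ep in observational])
    auc_int = auc(predict(ckpt, interventional), [ep.Y for ep in interventional])
    return auc_int - auc_obs
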