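"""Shared episode containers and on-disk episode format.

An :class:`EpisodeRecord` is one supervised example derived from an ICU stay:
the windowed observation matrix ``O`` of shape ``(t, o)`` (time steps ×
clinical features), the static-indicator mapping ``B`` (demographics,
admission category, comorbidity), the note token bag ``Z`` as
``(token, count)`` pairs, the binary sepsis-within-horizon label ``Y`` and
the prediction horizon in hours.

Episode sets are written as one directory per experiment: an ``.npz`` with
the stacked numeric arrays per split, a JSON-lines sidecar for the
non-numeric fields, and a JSON manifest with counts, seed and drop reasons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpisodeRecord", "stack_observations", "save_episodes", "load_episodes"]


@dataclass
class EpisodeRecord:
    stay_id: int
    O: np.ndarray  # (t, o) float
    B: dict[str, object]
    Z: list[tuple[str, int]]
    Y: int
    horizon_h: int

    def __post_init__(self):
        self.O = np.asarray(self.O, dtype=np.float64)
        if self.O.ndim != 2:
            raise ValueError(f"O must be 2-D (t, o), got shape {self.O.shape}")
        if self.Y not in (0, 1):
            raise ValueError(f"Y must be binary, got {self.Y}")
        if not 0 <= self.horizon_h <= 6:
            raise ValueError(f"horizon_h must be in [0, 6], got {self.horizon_h}")


def stack_observations(episodes: list[EpisodeRecord]) -> np.ndarray:
    """Stack per-episode O matrices into an (N, t, o) array."""
    return np.stack([ep.O for ep in episodes])


def labels(episodes: list[EpisodeRecord]) -> np.ndarray:
    return np.array([ep.Y for ep in episodes], dtype=np.int64)


def save_episodes(path: str | Path, splits: dict[str, list[EpisodeRecord]],
                  manifest_extra: dict | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"splits": {}}
    for name, eps in splits.items():
        np.savez(
            path / f"{name}.npz",
            O=stack_observations(eps) if eps else np.zeros((0, 0, 0)),
            Y=labels(eps),
            horizon=np.array([ep.horizon_h for ep in eps], dtype=np.int64),
            stay_id=np.array([ep.stay_id for ep in eps], dtype=np.int64),
        )
        with open(path / f"{name}.jsonl", "w") as fh:
            for ep in eps:
                fh.write(json.dumps({"B": ep.B, "Z": ep.Z}) + "\n")
        manifest["splits"][name] = {
            "n": len(eps),
            "n_pos": int(sum(ep.Y for ep in eps)),
        }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_episodes(path: str | Path, split: str) -> list[EpisodeRecord]:
    path = Path(path)
    arrs = np.load(path / f"{split}.npz")
    with open(path / f"{split}.jsonl") as fh:
        extras = [json.loads(line) for line in fh]
    out = []
    for i, extra in enumerate(extras):
        out.append(
            EpisodeRecord(
                stay_id=int(arrs["stay_id"][i]),
                O=arrs["O"][i],
                B=extra["B"],
                Z=[(tok, int(c)) for tok, c in extra["Z"]],
                Y=int(arrs["Y"][i]),
                horizon_h=int(arrs["horizon"][i]),
            )
        )
    return out
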