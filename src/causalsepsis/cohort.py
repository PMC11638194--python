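"""Cohort construction: inclusion rules, horizon windows and splits.

Input is a per-stay table plus three tabular streams (long-format
time series, static indicators, note token counts); sepsis onset labels and
timestamps are assumed to be computed upstream.  This module applies the
inclusion criteria (adults at first hospital admission, one ICU stay per
hospital admission), cuts one observation window per stay for a given
prediction horizon ``h`` — ending exactly ``h`` hours before onset for
positives, uniformly placed among feasible windows for controls — and
builds class-balanced training and ≈4:1 negative:positive evaluation
splits with disjoint stays.

Expected columns
----------------
stays:  ``stay_id, hadm_id, age, onset_time, label``
        (onset_time in hours since ICU admission; NaN for non-sepsis)
series: ``stay_id, time_h, feature, value``
static: ``stay_id`` plus one column per static indicator
notes:  ``stay_id, token, count``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import EpisodeRecord

__all__ = ["SplitSpec", "filter_cohort", "build_horizon_examples", "make_splits"]

logger = logging.getLogger(__name__)

MIN_AGE = 18.0


@dataclass
class SplitSpec:
    """Allocation and class-ratio contract for the three splits.

    Stays are allocated 70/15/15 (train/val/test) per class before ratio
    enforcement; training is balanced 1:1 by down-sampling the majority
    class, and each evaluation split is brought to ``eval_neg_pos_ratio``
    (≈4) negatives per positive.
    """

    train_frac: float = 0.70
    val_frac: float = 0.15
    eval_neg_pos_ratio: float = 4.0
    seed: int = 0


def filter_cohort(stays: pd.DataFrame) -> pd.DataFrame:
    """Apply the inclusion criteria to a stay table.

    Keeps stays of patients at least 18 years old at first hospital
    admission whose hospital admission contributed exactly one ICU stay.
    Records with missing age are rejected with a logged reason code.  Drop
    reasons and counts are stored in ``result.attrs['drop_reasons']``.
    """
    required = {"stay_id", "hadm_id", "age", "onset_time", "label"}
    missing = required - set(stays.columns)
    if missing:
        raise ValueError(f"stay table missing columns: {sorted(missing)}")
    if stays["stay_id"].duplicated().any():
        raise ValueError("stay_id values must be unique")
    reasons: dict[str, int] = {}
    out = stays.copy()

    missing_age = out["age"].isna()
    if missing_age.any():
        reasons["missing_age"] = int(missing_age.sum())
        logger.warning("rejected %d stays with missing age", missing_age.sum())
    out = out[~missing_age]

    underage = out["age"] < MIN_AGE
    reasons["underage"] = int(underage.sum())
    out = out[~underage]

    multi = out["hadm_id"].duplicated(keep=False)
    reasons["multiple_icu_stays_per_hadm"] = int(multi.sum())
    out = out[~multi]

    out = out.reset_index(drop=True)
    out.attrs["drop_reasons"] = reasons
    return out


def _grid_window(series: pd.DataFrame, features: list[str], start: float,
                 window_len_t: int) -> tuple[np.ndarray, np.ndarray]:
    """Hourly-binned window [start, start + T): values and observation mask.

    Within each hourly bin the last observation wins; gaps are filled by
    carry-forward, then by the within-window per-feature median, then 0.
    """
    T = window_len_t
    values = np.full((T, len(features)), np.nan)
    sel = series[(series["time_h"] >= start) & (series["time_h"] < start + T)]
    if len(sel):
        bins = np.floor(sel["time_h"].to_numpy() - start).astype(int)
        order = np.argsort(sel["time_h"].to_numpy(), kind="stable")
        feat_idx = {f: i for i, f in enumerate(features)}
        fcol = sel["feature"].to_numpy()[order]
        vcol = sel["value"].to_numpy()[order]
        bcol = bins[order]
        for b, f, v in zip(bcol, fcol, vcol):
            j = feat_idx.get(f)
            if j is not None:
                values[b, j] = v
    mask = (~np.isnan(values)).astype(np.float64)
    # carry-forward
    for j in range(values.shape[1]):
        col = values[:, j]
        last = np.nan
        for i in range(len(col)):
            if np.isnan(col[i]):
                col[i] = last
            else:
                last = col[i]
        if np.isnan(col).any():
            med = np.nanmedian(col) if not np.isnan(col).all() else 0.0
            col[np.isnan(col)] = med
    return values, mask


def build_horizon_examples(
    stays: pd.DataFrame,
    series: pd.DataFrame,
    static: pd.DataFrame,
    notes: pd.DataFrame,
    horizon_h: int,
    window_len_t: int = 24,
    append_mask: bool = True,
    seed: int = 0,
) -> tuple[list[EpisodeRecord], dict[str, int]]:
    """Cut one horizon-``h`` observation window per eligible stay.

    For positives the window ends exactly ``horizon_h`` hours before onset;
    stays whose onset is too early to fit the full window are dropped and
    counted.  For controls the window start is drawn uniformly among
    integer-hour starts that fit inside the observed span, with the given
    seed.  Returns the examples and a dict of drop reasons.
    """
    if not 0 <= horizon_h <= 6:
        raise ValueError(f"horizon_h must be in [0, 6], got {horizon_h}")
    if window_len_t <= 0:
        raise ValueError(f"window_len_t must be positive, got {window_len_t}")
    rng = np.random.default_rng(seed)
    features = sorted(series["feature"].unique())
    static_by_id = static.set_index("stay_id")
    notes_by_id = dict(tuple(notes.groupby("stay_id"))) if len(notes) else {}
    series_by_id = dict(tuple(series.groupby("stay_id")))
    drops = {"window_infeasible": 0, "no_series": 0}
    examples: list[EpisodeRecord] = []
    for row in stays.itertuples():
        s = series_by_id.get(row.stay_id)
        if s is None or not len(s):
            drops["no_series"] += 1
            continue
        span = float(s["time_h"].max())
        if row.label == 1:
            start = float(row.onset_time) - horizon_h - window_len_t
            if start < 0:
                drops["window_infeasible"] += 1
                continue
        else:
            max_start = int(np.floor(span - window_len_t))
            if max_start < 0:
                drops["window_infeasible"] += 1
                continue
            start = float(rng.integers(0, max_start + 1))
        values, mask = _grid_window(s, features, start, window_len_t)
        O = np.concatenate([values, mask], axis=1) if append_mask else values
        b_rec = (
            static_by_id.loc[row.stay_id].to_dict()
            if row.stay_id in static_by_id.index else {}
        )
        nb = notes_by_id.get(row.stay_id)
        z_bag = (
            [(str(t), int(c)) for t, c in zip(nb["token"], nb["count"])]
            if nb is not None else []
        )
        examples.append(
            EpisodeRecord(
                stay_id=int(row.stay_id), O=O, B=b_rec, Z=z_bag,
                Y=int(row.label), horizon_h=horizon_h,
            )
        )
    return examples, drops


def _ratio_enforce(pos: list, neg: list, ratio: float, rng: np.random.Generator):
    """Down-sample to ``ratio`` negatives per positive (rounding to nearest)."""
    want_neg = int(round(ratio * len(pos)))
    if want_neg <= len(neg):
        keep = rng.permutation(len(neg))[:want_neg]
        neg = [neg[i] for i in sorted(keep)]
    else:
        want_pos = int(np.floor(len(neg) / ratio))
        keep = rng.permutation(len(pos))[:want_pos]
        pos = [pos[i] for i in sorted(keep)]
    return pos, neg


def make_splits(
    examples: list[EpisodeRecord], spec: SplitSpec
) -> tuple[list[EpisodeRecord], list[EpisodeRecord], list[EpisodeRecord]]:
    """Stay-disjoint train/val/test with 1:1 train and ≈4:1 eval ratios."""
    pos = [ep for ep in examples if ep.Y == 1]
    neg = [ep for ep in examples if ep.Y == 0]
    n_pos, n_neg = len(pos), len(neg)
    # every eval split needs at least 1 positive and ratio negatives
    min_pos = int(np.ceil(1 / spec.val_frac))
    min_neg = int(np.ceil(spec.eval_neg_pos_ratio / spec.val_frac))
    if n_pos < min_pos or n_neg < min_neg:
        raise ValueError(
            f"insufficient examples for splitting: have {n_pos} positives and "
            f"{n_neg} negatives, need at least {min_pos} positives and "
            f"{min_neg} negatives so each evaluation split holds >=1 positive "
            f"and >={int(spec.eval_neg_pos_ratio)} negatives"
        )
    rng = np.random.default_rng(spec.seed)

    def allocate(group: list[EpisodeRecord]):
        order = rng.permutation(len(group))
        n = len(group)
        n_train = int(round(spec.train_frac * n))
        n_val = int(round(spec.val_frac * n))
        tr = [group[i] for i in order[:n_train]]
        va = [group[i] for i in order[n_train:n_train + n_val]]
        te = [group[i] for i in order[n_train + n_val:]]
        return tr, va, te

    pos_tr, pos_va, pos_te = allocate(pos)
    neg_tr, neg_va, neg_te = allocate(neg)

    # train: balance 1:1 by down-sampling the majority class
    k = min(len(pos_tr), len(neg_tr))
    pos_tr = [pos_tr[i] for i in sorted(rng.permutation(len(pos_tr))[:k])]
    neg_tr = [neg_tr[i] for i in sorted(rng.permutation(len(neg_tr))[:k])]
    # eval splits: enforce the negative:positive ratio
    pos_va, neg_va = _ratio_enforce(pos_va, neg_va, spec.eval_neg_pos_ratio, rng)
    pos_te, neg_te = _ratio_enforce(pos_te, neg_te, spec.eval_neg_pos_ratio, rng)

    def interleave(p, n):
        out = p + n
        order = rng.permutation(len(out))
        return [out[i] for i in order]

    train, val, test = interleave(pos_tr, neg_tr), interleave(pos_va, neg_va), \
        interleave(pos_te, neg_te)
    ids = [set(ep.stay_id for ep in s) for s in (train, val, test)]
    assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2]), \
        "splits share stay_ids"
    return train, val, test
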