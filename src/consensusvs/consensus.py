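"""Weighted z-score consensus ranking.

Each channel's raw scores are oriented so higher is better, standardized to
zero mean and unit (population) standard deviation over the pooled
actives+decoys screening pool, then combined as a weighted mean with each
channel weighted by its best model's w_new.  Compounds are ranked by
descending weighted average; rank 1 is the top pick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateChannelError, MissingScoreError
from .scoring_channels import ChannelScores


def orient(scores: ChannelScores) -> ChannelScores:
    """Negate lower_better channels so higher = better everywhere downstream."""
    if scores.orientation == "lower_better":
        return ChannelScores(scores.channel, -scores.scores, "higher_better")
    return ChannelScores(scores.channel, scores.scores.copy(), "higher_better")


def zscore(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Standardize to mean 0, population SD 1."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least two values to z-score")
    sd = arr.std(ddof=0)
    if sd == 0.0:
        raise DegenerateChannelError("zero variance; channel cannot be z-scored")
    return (arr - arr.mean()) / sd


@dataclass
class ConsensusResult:
    """Ranked consensus output plus the standardization metadata."""

    table: pd.DataFrame  # rank, id, weighted_average, z_<channel>..., w_<channel>...
    weights: dict[str, float]
    orientation_map: dict[str, str]
    z_stats: dict[str, tuple[float, float]]  # channel -> (mean, population sd)

    @property
    def ranking(self) -> list[str]:
        return list(self.table["id"])


def weighted_consensus(
    channel_scores: Sequence[ChannelScores],
    weights: Mapping[str, float],
) -> ConsensusResult:
    """Combine oriented, z-scored channels into one descending ranking.

    ``weighted_average(c) = sum_k w_k z_k(c) / sum_k w_k`` where ``w_k`` is
    the channel's best-model w_new.  Every compound must appear in every
    channel; ties in the weighted average break by ascending compound id.
    """
    if not channel_scores:
        raise ValueError("no channels supplied")
    for ch in channel_scores:
        if ch.channel not in weights:
            raise KeyError(f"no weight supplied for channel {ch.channel!r}")
        if not 0.0 < float(weights[ch.channel]) < 1.0:
            raise ValueError(
                f"weight for {ch.channel!r} must be in (0, 1), "
                f"got {weights[ch.channel]}")

    ids = set(channel_scores[0].scores.index)
    for ch in channel_scores[1:]:
        missing = ids.symmetric_difference(ch.scores.index)
        if missing:
            raise MissingScoreError(
                f"compounds missing from some channel: {sorted(missing)[:10]}")
    order = sorted(ids)

    z_cols: dict[str, np.ndarray] = {}
    z_stats: dict[str, tuple[float, float]] = {}
    orientation_map: dict[str, str] = {}
    for ch in channel_scores:
        orientation_map[ch.channel] = ch.orientation
        oriented = orient(ch).scores.loc[order].to_numpy(dtype=float)
        z_stats[ch.channel] = (float(oriented.mean()), float(oriented.std(ddof=0)))
        z_cols[ch.channel] = zscore(oriented)

    w = np.array([float(weights[ch.channel]) for ch in channel_scores])
    Z = np.column_stack([z_cols[ch.channel] for ch in channel_scores])
    weighted_average = Z @ w / w.sum()

    df = pd.DataFrame({"id": order, "weighted_average": weighted_average})
    for ch in channel_scores:
        df[f"z_{ch.channel}"] = z_cols[ch.channel]
        df[f"w_{ch.channel}"] = float(weights[ch.channel])
    df = df.sort_values(["weighted_average", "id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return ConsensusResult(
        table=df,
        weights={ch.channel: float(weights[ch.channel]) for ch in channel_scores},
        orientation_map=orientation_map,
        z_stats=z_stats,
    )


class ConsensusRanker:
    """Estimator-style wrapper: ``fit`` ingests channels and weights,
    ``transform`` attaches roles and returns the ranked table."""

    def __init__(self, weights: Mapping[str, float] | None = None):
        self.weights = weights

    def fit(self, channel_scores: Sequence[ChannelScores],
            weights: Mapping[str, float] | None = None) -> "ConsensusRanker":
        w = weights if weights is not None else self.weights
        if w is None:
            raise ValueError("weights must be supplied at init or fit time")
        self.result_ = weighted_consensus(channel_scores, w)
        return self

    def transform(self, roles: Mapping[str, str] | None = None) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise RuntimeError("ConsensusRanker is not fitted")
        df = self.result_.table.copy()
        if roles is not None:
            df.insert(2, "role", [roles.get(c, "unknown") for c in df["id"]])
        return df
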