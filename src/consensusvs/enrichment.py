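"""Retrospective screening metrics over a ranked actives+decoys pool.

* ROC AUC — the normalized Mann-Whitney statistic of the ranking;
* EF_f — enrichment factor at fraction ``f``: the share of all actives
  recovered in the top ``ceil(f N)`` compounds divided by ``f``; capped at
  ``1/f``;
* BEDROC — exponentially early-weighted recognition (Truchon-Bayly),
  min-max normalized to [0, 1] so a perfect ranking scores exactly 1;
* decoy percentage in the top slice.

Rank 1 is the best compound.  Compounds with tied consensus scores should
be pre-ordered by id so metrics are reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DomainError


def _labels01(ranking: Sequence[str], labels: Mapping[str, str]) -> np.ndarray:
    y = np.array([1 if labels[c] == "active" else 0 for c in ranking], dtype=int)
    return y


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("both actives and decoys must be present")


def roc_auc(ranking: Sequence[str], labels: Mapping[str, str]) -> float:
    """Area under the ROC curve of the ranking (ties rank-averaged)."""
    y = _labels01(ranking, labels)
    _check_two_classes(y)
    scores = -np.arange(len(y), dtype=float)  # earlier rank = higher score
    return float(roc_auc_score(y, scores))


def enrichment_factor(ranking: Sequence[str], labels: Mapping[str, str],
                      fraction: float) -> float:
    """EF at ``fraction``; the top slice is ``ceil(fraction * N)`` compounds
    so that small pools never yield an empty slice."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError(f"fraction must be in (0, 1], got {fraction}")
    y = _labels01(ranking, labels)
    n = len(y)
    n_actives = int(y.sum())
    if n == 0 or n_actives == 0:
        return 0.0
    top = math.ceil(fraction * n)
    hits = int(y[:top].sum())
    return (hits / n_actives) / fraction


def bedroc(ranking: Sequence[str], labels: Mapping[str, str],
           alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC.

    Sum of ``exp(-alpha * r_i / N)`` over active ranks ``r_i`` (1-based),
    min-max normalized between the worst ranking (actives at the bottom)
    and the perfect one (actives at ranks 1..n).
    """
    if alpha <= 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    y = _labels01(ranking, labels)
    _check_two_classes(y)
    n_total = len(y)
    ranks = np.flatnonzero(y) + 1  # 1-based ranks of the actives
    n_act = len(ranks)
    s = np.exp(-alpha * ranks / n_total).sum()
    best = np.exp(-alpha * np.arange(1, n_act + 1) / n_total).sum()
    worst = np.exp(-alpha * np.arange(n_total - n_act + 1, n_total + 1) / n_total).sum()
    return float((s - worst) / (best - worst))


def decoy_fraction_top(ranking: Sequence[str], labels: Mapping[str, str],
                       fraction: float) -> float:
    """Percentage of decoys in the top ``ceil(fraction * N)`` slice."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError(f"fraction must be in (0, 1], got {fraction}")
    y = _labels01(ranking, labels)
    top = math.ceil(fraction * len(y))
    return 100.0 * float((1 - y[:top]).sum()) / top


@dataclass
class EnrichmentReport:
    """All enrichment metrics for one ranked pool."""

    auc_roc: float
    ef: dict[float, float]
    bedroc: float
    bedroc_alpha: float
    decoy_pct_top: dict[float, float]
    n_actives: int
    n_total: int

    def to_json(self) -> str:
        return json.dumps(
            {"auc_roc": self.auc_roc,
             "ef": {str(k): v for k, v in self.ef.items()},
             "bedroc": self.bedroc, "bedroc_alpha": self.bedroc_alpha,
             "decoy_pct_top": {str(k): v for k, v in self.decoy_pct_top.items()},
             "n_actives": self.n_actives, "n_total": self.n_total},
            indent=2, sort_keys=True)


def evaluate_ranking(ranking: Sequence[str], labels: Mapping[str, str],
                     ef_fractions: Sequence[float] = (0.01, 0.05),
                     decoy_fractions: Sequence[float] = (0.01,),
                     alpha: float = 20.0) -> EnrichmentReport:
    """The full enrichment report for one ranking."""
    y = _labels01(ranking, labels)
    _check_two_classes(y)
    return EnrichmentReport(
        auc_roc=roc_auc(ranking, labels),
        ef={f: enrichment_factor(ranking, labels, f) for f in ef_fractions},
        bedroc=bedroc(ranking, labels, alpha),
        bedroc_alpha=alpha,
        decoy_pct_top={f: decoy_fraction_top(ranking, labels, f)
                       for f in decoy_fractions},
        n_actives=int(y.sum()),
        n_total=len(y),
    )


def roc_curve_points(ranking: Sequence[str],
                     labels: Mapping[str, str]) -> pd.DataFrame:
    """FPR/TPR points of the ranking's ROC curve, for the curve CSV/plot."""
    y = _labels01(ranking, labels)
    _check_two_classes(y)
    fpr, tpr, _ = roc_curve(y, -np.arange(len(y), dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def plot_roc(ranking: Sequence[str], labels: Mapping[str, str], path) -> None:
    """Write a ROC curve plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = roc_curve_points(ranking, labels)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(pts["fpr"], pts["tpr"], label=f"AUC = {roc_auc(ranking, labels):.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
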