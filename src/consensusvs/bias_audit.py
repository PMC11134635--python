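"""Three-stage actives/decoys dataset bias assessment.

1. Physicochemical significance: per-property Welch two-sample t-tests
   between actives and decoys at p < 0.05, with counts of significant and
   non-significant properties over the 17-property panel.
2. Diversity ranking: MaxMin diversity-picking order over Tanimoto distance
   on fingerprints (rank 1 = most diverse pick), summarized as mean ranks
   for actives vs decoys with a two-sample test.
3. PCA neighbor analysis: project standardized features to two principal
   components, count decoys within a percentile-threshold Euclidean
   distance of each active, and report the median count, ratio-corrected to
   the reference 1:125 active-to-decoy composition:

       corrected_median = median * (n_decoys / n_actives) / 125
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .chem_features import FeatureMatrix, tanimoto
from .errors import DomainError, EmptyInputError

BASELINE_RATIO = 125.0  # reference 1:125 active-to-decoy composition


@dataclass
class PropertyTest:
    name: str
    t_statistic: float
    p_value: float
    significant: bool
    excluded: bool = False  # zero variance in both groups


@dataclass
class BiasReport:
    property_tests: list[PropertyTest] = field(default_factory=list)
    n_significant: int = 0
    n_non_significant: int = 0
    diversity_ranks: pd.Series | None = None  # id -> rank
    actives_mean_rank: float | None = None
    decoys_mean_rank: float | None = None
    rank_t_statistic: float | None = None
    rank_p_value: float | None = None
    median_neighbors: float | None = None
    corrected_median_neighbors: float | None = None
    threshold_distance: float | None = None
    neighbor_counts: pd.Series | None = None  # active id -> decoy neighbors

    def to_json(self) -> str:
        return json.dumps(
            {"property_tests": [vars(t) for t in self.property_tests],
             "n_significant": self.n_significant,
             "n_non_significant": self.n_non_significant,
             "actives_mean_rank": self.actives_mean_rank,
             "decoys_mean_rank": self.decoys_mean_rank,
             "rank_t_statistic": self.rank_t_statistic,
             "rank_p_value": self.rank_p_value,
             "median_neighbors": self.median_neighbors,
             "corrected_median_neighbors": self.corrected_median_neighbors,
             "threshold_distance": self.threshold_distance},
            indent=2, sort_keys=True)


def physchem_significance(actives: FeatureMatrix, decoys: FeatureMatrix,
                          p_threshold: float = 0.05) -> BiasReport:
    """Welch t-test per property between the active and decoy panels."""
    if len(actives.compound_ids) < 2 or len(decoys.compound_ids) < 2:
        raise EmptyInputError("both groups need at least 2 compounds")
    if list(actives.feature_names) != list(decoys.feature_names):
        raise ValueError("panels must share the same property columns")
    report = BiasReport()
    for j, name in enumerate(actives.feature_names):
        a = actives.values[:, j]
        d = decoys.values[:, j]
        if a.std(ddof=0) == 0.0 and d.std(ddof=0) == 0.0:
            report.property_tests.append(
                PropertyTest(name, float("nan"), float("nan"), False, excluded=True))
            continue
        t, p = stats.ttest_ind(a, d, equal_var=False)
        sig = bool(p < p_threshold)
        report.property_tests.append(PropertyTest(name, float(t), float(p), sig))
        if sig:
            report.n_significant += 1
        else:
            report.n_non_significant += 1
    return report


def diversity_ranks(fingerprints: FeatureMatrix) -> pd.Series:
    """MaxMin diversity-picking rank per compound (1 = first pick).

    The pick starts at the medoid (the compound with the largest total
    Tanimoto similarity to the rest, ties by id), making ranks seed-free;
    each subsequent pick maximizes the minimum Tanimoto distance to the
    already-picked set, ties again by id.
    """
    ids = list(fingerprints.compound_ids)
    n = len(ids)
    if n < 2:
        raise EmptyInputError("need at least 2 compounds to rank diversity")
    X = fingerprints.values
    sim = np.empty((n, n))
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(X[i], X[j])
    dist = 1.0 - sim
    totals = sim.sum(axis=1)
    start = min(range(n), key=lambda i: (-totals[i], ids[i]))
    picked = [start]
    remaining = set(range(n)) - {start}
    min_dist = dist[start].copy()
    while remaining:
        nxt = min(remaining, key=lambda i: (-min_dist[i], ids[i]))
        picked.append(nxt)
        remaining.discard(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
    ranks = np.empty(n, dtype=int)
    for rank, i in enumerate(picked, start=1):
        ranks[i] = rank
    return pd.Series(ranks, index=ids)


def diversity_summary(fingerprints: FeatureMatrix,
                      labels: Mapping[str, str]) -> BiasReport:
    """Diversity ranks plus mean-rank comparison between actives and decoys."""
    ranks = diversity_ranks(fingerprints)
    a = ranks[[c for c in ranks.index if labels[c] == "active"]]
    d = ranks[[c for c in ranks.index if labels[c] == "decoy"]]
    report = BiasReport(diversity_ranks=ranks)
    report.actives_mean_rank = float(a.mean()) if len(a) else None
    report.decoys_mean_rank = float(d.mean()) if len(d) else None
    if len(a) >= 2 and len(d) >= 2:
        t, p = stats.ttest_ind(a, d, equal_var=False)
        report.rank_t_statistic = float(t)
        report.rank_p_value = float(p)
    return report


def pca_neighbor_analysis(features: FeatureMatrix, labels: Mapping[str, str],
                          percentile: float = 10.0, standardize: bool = True
                          ) -> tuple[float, pd.Series, float]:
    """Median decoy-neighbor count per active in 2-component PCA space.

    Features are standardized (skip via ``standardize=False`` when they
    already are), projected to two principal components; the neighborhood
    threshold is the stated percentile of the pooled active-to-decoy
    Euclidean distances.

    Returns (median_count, per_active_counts, threshold_distance).
    """
    ids = features.compound_ids
    if len(ids) < 3:
        raise EmptyInputError("need at least 3 compounds for PCA neighbor analysis")
    act_idx = [i for i, c in enumerate(ids) if labels[c] == "active"]
    dec_idx = [i for i, c in enumerate(ids) if labels[c] == "decoy"]
    if not act_idx or not dec_idx:
        raise ValueError("both actives and decoys must be present")
    X = features.values
    if standardize:
        X = StandardScaler().fit_transform(X)
    proj = PCA(n_components=2, random_state=0).fit_transform(X)
    A = proj[act_idx]
    D = proj[dec_idx]
    dists = np.sqrt(((A[:, None, :] - D[None, :, :]) ** 2).sum(axis=2))
    threshold = float(np.percentile(dists.ravel(), percentile))
    counts = (dists <= threshold).sum(axis=1)
    per_active = pd.Series(counts, index=[ids[i] for i in act_idx])
    return float(np.median(counts)), per_active, threshold


def corrected_median(median: float, n_actives: int, n_decoys: int,
                     baseline_ratio: float = BASELINE_RATIO) -> float:
    """Ratio-corrected median neighbor count.

    Normalizes the raw median to the reference decoy-to-active composition
    so pools of different sizes are comparable; at exactly
    ``n_decoys / n_actives == baseline_ratio`` the median is unchanged.
    """
    if n_actives <= 0 or n_decoys <= 0:
        raise DomainError("compound counts must be positive")
    if baseline_ratio <= 0:
        raise DomainError("baseline_ratio must be positive")
    return median * (n_decoys / n_actives) / baseline_ratio


def bias_audit(panel_actives: FeatureMatrix, panel_decoys: FeatureMatrix,
               fingerprints: FeatureMatrix, features: FeatureMatrix,
               labels: Mapping[str, str], percentile: float = 10.0) -> BiasReport:
    """Run all three stages and merge into one report."""
    report = physchem_significance(panel_actives, panel_decoys)
    div = diversity_summary(fingerprints, labels)
    report.diversity_ranks = div.diversity_ranks
    report.actives_mean_rank = div.actives_mean_rank
    report.decoys_mean_rank = div.decoys_mean_rank
    report.rank_t_statistic = div.rank_t_statistic
    report.rank_p_value = div.rank_p_value
    median, per_active, threshold = pca_neighbor_analysis(features, labels, percentile)
    n_act = len(panel_actives.compound_ids)
    n_dec = len(panel_decoys.compound_ids)
    report.median_neighbors = median
    report.corrected_median_neighbors = corrected_median(median, n_act, n_dec)
    report.threshold_distance = threshold
    report.neighbor_counts = per_active
    return report
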