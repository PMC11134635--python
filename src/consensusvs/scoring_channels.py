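"""The four raw per-compound score channels.

* ``qsar`` — measured pIC50 of the actives (higher is better);
* ``similarity`` — max Tanimoto (ECFP4) to cluster-representative compounds
  chosen by longest canonical SMILES (higher is better);
* ``pharmacophore`` — RMSE between a compound's 2D feature-family count
  vector (donor, acceptor, aromatic, hydrophobe, positive/negative
  ionizable) and its cluster's consensus vector (lower is better).  This is
  a 2D surrogate for 3D pharmacophore feature-match scoring;
* ``docking`` — binding-affinity scores in kcal/mol ingested from a table or
  from Vina-format log files (lower, i.e. more negative, is better).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import ChemicalFeatures
from sklearn.cluster import KMeans

from .chem_features import FeatureMatrix, compute_fingerprints, tanimoto
from .data_io import CompoundRecord
from .errors import (
    ConfigError,
    DuplicateIdError,
    EmptyInputError,
    FormatError,
)

log = logging.getLogger(__name__)

CHANNELS = ("qsar", "similarity", "pharmacophore", "docking")
ORIENTATIONS = {"qsar": "higher_better", "similarity": "higher_better",
                "pharmacophore": "lower_better", "docking": "lower_better"}

FEATURE_FAMILIES = ("Donor", "Acceptor", "Aromatic", "Hydrophobe",
                    "PosIonizable", "NegIonizable")


@dataclass
class ChannelScores:
    """Raw scores for one channel, with its orientation metadata."""

    channel: str
    scores: pd.Series  # index = compound ids, values = raw scores
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_better", "lower_better"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.scores.index.has_duplicates:
            raise DuplicateIdError(f"duplicate compound ids in {self.channel} scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.scores.index, "channel": self.channel,
             "raw_score": self.scores.values, "orientation": self.orientation}
        )


def write_channel_csv(tables: Sequence[ChannelScores], path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(path, index=False)


def read_channel_csv(path) -> list[ChannelScores]:
    df = pd.read_csv(path, dtype={"id": str})
    out = []
    for channel, grp in df.groupby("channel", sort=True):
        orientation = grp["orientation"].iloc[0]
        out.append(ChannelScores(channel, pd.Series(grp["raw_score"].values,
                                                    index=grp["id"].values), orientation))
    return out


@dataclass
class ClusterModel:
    """K-means cluster assignment over ECFP4 bit vectors."""

    assignments: pd.Series  # id -> cluster label
    k: int
    seed: int
    representatives: dict[int, str] = field(default_factory=dict)
    consensus: dict[int, np.ndarray] = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return list(self.assignments.index[self.assignments == label])


def kmeans_clusters(fingerprints: FeatureMatrix, k: int, seed: int = 0,
                    max_retries: int = 10) -> ClusterModel:
    """K-means on binary fingerprint rows (Euclidean on the bit vectors).

    ``k`` is constrained to the 3–5 range used for chemotype grouping.
    Empty clusters trigger a bounded re-seed.
    """
    if not 3 <= k <= 5:
        raise ConfigError(f"k must be in [3, 5], got {k}")
    n = len(fingerprints.compound_ids)
    if n < k:
        raise EmptyInputError(f"need at least k={k} compounds, got {n}")
    X = fingerprints.values
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, random_state=seed + attempt, n_init=10)
        labels = km.fit_predict(X)
        if len(set(labels)) == k:
            if attempt:
                log.info("kmeans re-seeded %d time(s) to avoid empty clusters", attempt)
            return ClusterModel(
                assignments=pd.Series(labels, index=fingerprints.compound_ids),
                k=k, seed=seed + attempt,
            )
    raise RuntimeError(f"kmeans produced an empty cluster in {max_retries} attempts")


def representatives_by_longest_smiles(
    clusters: ClusterModel, records: Sequence[CompoundRecord]
) -> list[str]:
    """Per cluster, the compound with the longest canonical SMILES.

    Length proxies structural complexity; ties break to the
    lexicographically smallest SMILES for determinism.
    """
    by_id = {r.id: r for r in records}
    reps: list[str] = []
    for label in sorted(set(clusters.assignments)):
        members = clusters.members(label)
        if not members:
            continue
        best = min(members, key=lambda c: (-len(by_id[c].smiles), by_id[c].smiles))
        clusters.representatives[label] = best
        reps.append(best)
    return reps


def similarity_scores(
    records: Sequence[CompoundRecord], representatives: Sequence[str]
) -> ChannelScores:
    """Max ECFP4 Tanimoto of each compound to the representative set."""
    if not representatives:
        raise EmptyInputError("representative list is empty")
    fm = compute_fingerprints(records, families=("ecfp4",))
    rep_rows = fm.select(list(representatives)).values
    scores = {}
    for i, rec in enumerate(records):
        row = fm.values[i]
        scores[rec.id] = max(tanimoto(row, rep) for rep in rep_rows)
    return ChannelScores("similarity",
                         pd.Series(scores, index=[r.id for r in records]),
                         ORIENTATIONS["similarity"])


_FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(
    str(Path(RDConfig.RDDataDir) / "BaseFeatures.fdef")
)


def feature_family_counts(record: CompoundRecord) -> np.ndarray:
    """Count of 2D pharmacophore feature points per family (6-vector)."""
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {record.id!r}")
    counts = dict.fromkeys(FEATURE_FAMILIES, 0)
    for feat in _FEATURE_FACTORY.GetFeaturesForMol(mol):
        fam = feat.GetFamily()
        if fam in counts:
            counts[fam] += 1
    return np.array([counts[f] for f in FEATURE_FAMILIES], dtype=float)


def pharmacophore_scores(
    records: Sequence[CompoundRecord],
    clusters: ClusterModel,
    min_features: int = 4,
) -> ChannelScores:
    """RMSE of each compound's feature-family counts vs its cluster consensus.

    A cluster's consensus vector is the per-family mean count over members;
    the model is retained only when at least ``min_features`` families have
    nonzero consensus, otherwise members fall back to the global consensus.
    """
    if not 3 <= min_features <= 5:
        raise ConfigError(f"min_features must be in [3, 5], got {min_features}")
    by_id = {r.id: r for r in records}
    counts = {r.id: feature_family_counts(r) for r in records}
    global_consensus = np.mean([counts[c] for c in clusters.assignments.index], axis=0)
    consensus: dict[int, np.ndarray] = {}
    for label in sorted(set(clusters.assignments)):
        members = clusters.members(label)
        vec = np.mean([counts[c] for c in members], axis=0)
        if int(np.count_nonzero(vec)) < min_features:
            log.warning(
                "cluster %d consensus has < %d nonzero feature families; "
                "members scored against the global consensus", label, min_features)
            vec = global_consensus
        consensus[label] = vec
    clusters.consensus = consensus
    scores = {}
    for cid, label in clusters.assignments.items():
        diff = counts[cid] - consensus[label]
        scores[cid] = float(np.sqrt(np.mean(diff ** 2)))
    ordered = [r.id for r in records if r.id in scores]
    return ChannelScores("pharmacophore",
                         pd.Series([scores[c] for c in ordered], index=ordered),
                         ORIENTATIONS["pharmacophore"])


_VINA_MODE_RE = re.compile(r"^\s*1\s+(-?\d+(?:\.\d+)?)\s+")


def parse_vina_log(path: str | Path) -> float:
    """Best-mode affinity (kcal/mol) from a Vina-format log file."""
    text = Path(path).read_text()
    in_table = False
    for line in text.splitlines():
        if line.strip().startswith("-----+"):
            in_table = True
            continue
        if in_table:
            m = _VINA_MODE_RE.match(line)
            if m:
                return float(m.group(1))
    # fall back: first mode line anywhere
    for line in text.splitlines():
        m = _VINA_MODE_RE.match(line)
        if m:
            return float(m.group(1))
    raise FormatError(f"{path}: no docking mode table found")


def ingest_docking_scores(
    path: str | Path,
    known_ids: Sequence[str] | None = None,
) -> tuple[ChannelScores, list[str]]:
    """Docking scores from a CSV (``id,score``) or a directory of Vina logs.

    Returns the channel table plus the list of orphan ids (present in the
    score source but not in ``known_ids``).  Conflicting duplicate scores
    are an error; missing ids are the caller's to handle and are logged.
    """
    path = Path(path)
    if path.is_dir():
        rows = []
        for logfile in sorted(path.glob("*.log")) + sorted(path.glob("*.txt")):
            rows.append({"id": logfile.stem, "score": parse_vina_log(logfile)})
        if not rows:
            raise EmptyInputError(f"no Vina log files in {path}")
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype={"id": str})
        if "id" not in df.columns or "score" not in df.columns:
            raise FormatError(f"{path}: docking table needs columns id, score")
        if df.empty:
            raise EmptyInputError(f"{path} has no rows")
    dup = df[df.duplicated("id", keep=False)]
    if not dup.empty:
        conflicting = dup.groupby("id")["score"].nunique()
        bad = sorted(conflicting[conflicting > 1].index)
        if bad:
            raise DuplicateIdError(f"conflicting docking scores for ids {bad}")
        df = df.drop_duplicates("id")
    orphans: list[str] = []
    if known_ids is not None:
        known = set(known_ids)
        orphans = sorted(set(df["id"]) - known)
        missing = sorted(known - set(df["id"]))
        if missing:
            log.warning("docking scores missing for %d ids (e.g. %s)",
                        len(missing), missing[:5])
    table = ChannelScores("docking",
                          pd.Series(df["score"].values, index=df["id"].values),
                          ORIENTATIONS["docking"])
    return table, orphans


def qsar_targets(records: Sequence[CompoundRecord]) -> ChannelScores:
    """pIC50 of each active as the QSAR channel's raw target."""
    actives = [r for r in records if r.role == "active"]
    missing = [r.id for r in actives if r.pic50 is None]
    if missing:
        raise ValueError(f"actives without activity values: {missing}")
    return ChannelScores(
        "qsar",
        pd.Series([r.pic50 for r in actives], index=[r.id for r in actives]),
        ORIENTATIONS["qsar"],
    )


def stub_docking_scores(
    records: Sequence[CompoundRecord],
    representatives: Sequence[str],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> ChannelScores:
    """A stand-in docking scorer for end-to-end tests: negated similarity
    plus Gaussian noise, scaled into a kcal/mol-like range."""
    sim = similarity_scores(records, representatives)
    rng = np.random.default_rng(seed)
    scores = -5.0 - 5.0 * sim.scores + rng.normal(0.0, noise_sd, size=len(sim.scores))
    return ChannelScores("docking", scores, ORIENTATIONS["docking"])
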