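"""Stage functions chaining the full screening workflow over a working
directory, plus the deterministic run manifest.

Every stage reads and writes documented files under one ``workdir`` so the
CLI subcommands stay thin.  All randomness flows from config seeds; the
manifest records inputs, seeds, package version and output hashes, and is
byte-identical across reruns of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias_audit import bias_audit
from .chem_features import (
    FeatureMatrix,
    compute_descriptors,
    compute_fingerprints,
    compute_physchem_panel,
    write_feature_matrix,
)
from .config import RunConfig
from .consensus import ConsensusResult, weighted_consensus
from .data_io import (
    CompoundRecord,
    curate,
    read_compound_table,
    split_dataset,
    write_curated_csv,
    write_rejects_csv,
)
from .enrichment import evaluate_ranking, roc_curve_points
from .errors import ConfigError
from .model_selection import (
    fit_channel_selector,
    leaderboard,
    predict_channel_scores,
)
from .scoring_channels import (
    CHANNELS,
    ChannelScores,
    ingest_docking_scores,
    kmeans_clusters,
    pharmacophore_scores,
    qsar_targets,
    read_channel_csv,
    representatives_by_longest_smiles,
    similarity_scores,
    write_channel_csv,
)
from .synthetic import (
    SyntheticSpec,
    bundle_to_tables,
    generate_channel_scores,
    generate_compounds,
)

log = logging.getLogger(__name__)


def _timed(stage):
    def wrapper(cfg: RunConfig, workdir: Path, **kwargs):
        t0 = time.perf_counter()
        result = stage(cfg, workdir, **kwargs)
        log.info("stage %s finished in %.2f s", stage.__name__, time.perf_counter() - t0)
        return result
    wrapper.__name__ = stage.__name__
    return wrapper


@_timed
def stage_simulate(cfg: RunConfig, workdir: Path):
    spec = SyntheticSpec(
        n_actives=cfg.simulate.n_actives, n_decoys=cfg.simulate.n_decoys,
        channel_noise={c: cfg.simulate.channel_noise for c in CHANNELS},
        activity_noise_sd=cfg.simulate.activity_noise_sd, seed=cfg.seed)
    bundle = generate_compounds(spec)
    channels = generate_channel_scores(bundle, spec)
    actives, decoys = bundle_to_tables(bundle)
    actives.to_csv(workdir / "actives.csv", index=False)
    decoys.to_csv(workdir / "decoys.csv", index=False)
    # the synthetic docking table stands in for external docking runs
    docking = channels["docking"].scores
    pd.DataFrame({"id": docking.index, "score": docking.values}).to_csv(
        workdir / "docking_scores.csv", index=False)
    write_channel_csv(list(channels.values()), workdir / "synthetic_channels.csv")
    return bundle


@_timed
def stage_curate(cfg: RunConfig, workdir: Path):
    actives_csv = cfg.actives_csv or workdir / "actives.csv"
    decoys_csv = cfg.decoys_csv or workdir / "decoys.csv"
    actives, rej_a = read_compound_table(actives_csv, role="active")
    decoys, rej_d = read_compound_table(decoys_csv, role="decoy")
    curated_a, rej_ca = curate(actives)
    curated_d, rej_cd = curate(decoys)
    curated_a = split_dataset(curated_a, train_frac=cfg.split.train_frac,
                              external_n=cfg.split.external_n, seed=cfg.split.seed)
    write_curated_csv(curated_a + curated_d, workdir / "curated.csv")
    write_rejects_csv(rej_a + rej_d + rej_ca + rej_cd, workdir / "rejects.csv")
    return curated_a + curated_d


def _load_curated(workdir: Path) -> list[CompoundRecord]:
    df = pd.read_csv(workdir / "curated.csv", dtype={"id": str})
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        if row.role == "active" and row.pic50 == row.pic50:
            kwargs["pic50"] = float(row.pic50)
        records.append(CompoundRecord(id=row.id, smiles=row.smiles, role=row.role,
                                      split=row.split, **kwargs))
    return records


@_timed
def stage_featurize(cfg: RunConfig, workdir: Path):
    records = _load_curated(workdir)
    fps = compute_fingerprints(records, families=("ecfp4",))
    desc = compute_descriptors(records)
    features = FeatureMatrix.hstack([fps, desc])
    write_feature_matrix(features, workdir / "features.csv")
    panel = compute_physchem_panel(records)
    write_feature_matrix(panel, workdir / "physchem.csv")
    return features, panel


def _load_features(workdir: Path, name: str) -> FeatureMatrix:
    df = pd.read_csv(workdir / f"{name}.csv", index_col="id")
    df.index = df.index.astype(str)
    sidecar = json.loads((workdir / f"{name}.blocks.json").read_text())
    return FeatureMatrix(
        compound_ids=list(df.index), feature_names=list(df.columns),
        values=df.to_numpy(dtype=float),
        blocks={k: tuple(v) for k, v in sidecar["blocks"].items()})


@_timed
def stage_score(cfg: RunConfig, workdir: Path):
    records = _load_curated(workdir)
    actives = [r for r in records if r.role == "active"]
    fps = compute_fingerprints(actives, families=("ecfp4",))
    sim_clusters = kmeans_clusters(fps, k=cfg.channels.similarity_k,
                                   seed=cfg.channels.cluster_seed)
    reps = representatives_by_longest_smiles(sim_clusters, actives)
    sim = similarity_scores(actives, reps)
    pharm_clusters = kmeans_clusters(fps, k=cfg.channels.pharmacophore_k,
                                     seed=cfg.channels.cluster_seed + 1)
    pharm = pharmacophore_scores(actives, pharm_clusters,
                                 min_features=cfg.channels.min_features)
    qsar = qsar_targets(actives)
    docking_src = cfg.channels.docking_scores or workdir / "docking_scores.csv"
    docking, orphans = ingest_docking_scores(docking_src,
                                             known_ids=[r.id for r in records])
    if orphans:
        log.info("docking table has %d orphan ids", len(orphans))
    tables = [qsar, sim, pharm, docking]
    write_channel_csv(tables, workdir / "channels_raw.csv")
    return tables


@_timed
def stage_select_model(cfg: RunConfig, workdir: Path):
    records = _load_curated(workdir)
    features = _load_features(workdir, "features")
    blocks = cfg.models.feature_blocks
    if blocks:
        parts = [features.block(b) for b in blocks]
        features = parts[0] if len(parts) == 1 else FeatureMatrix.hstack(parts)
    channels = {t.channel: t for t in read_channel_csv(workdir / "channels_raw.csv")}
    modeling_ids = [r.id for r in records
                    if r.role == "active" and r.split in ("train", "validation")]
    external_ids = [r.id for r in records
                    if r.role == "active" and r.split == "external"]
    reports = {}
    boards = []
    weights = {}
    predicted: list[ChannelScores] = []
    for channel in CHANNELS:
        table = channels[channel]
        targets = table.scores[table.scores.index.isin(modeling_ids)]
        selector = fit_channel_selector(
            features.select([c for c in features.compound_ids
                             if c in targets.index]),
            targets, channel=channel, models=cfg.models.models,
            selector=cfg.models.selector,
            selector_sizes=tuple(cfg.models.selector_sizes),
            train_frac=cfg.split.train_frac, mode=cfg.models.mode,
            cv_folds=cfg.models.cv_folds, split_seed=cfg.models.split_seed,
            grid_seed=cfg.models.grid_seed)
        report = selector.best_report_
        ext = table.scores[table.scores.index.isin(external_ids)]
        if len(ext):
            from .model_selection import external_r2
            external_r2(report, features.select(
                [c for c in features.compound_ids if c in ext.index]), ext)
        reports[channel] = report
        weights[channel] = report.breakdown.w_new
        boards.append(leaderboard(selector.reports_))
        predicted.append(predict_channel_scores(report, features))
    pd.concat(boards, ignore_index=True).to_csv(workdir / "leaderboard.csv",
                                                index=False)
    (workdir / "model_reports.json").write_text(
        json.dumps({c: json.loads(r.to_json()) for c, r in reports.items()},
                   indent=2, sort_keys=True))
    if cfg.models.decoy_score_mode == "predictions":
        write_channel_csv(predicted, workdir / "channels_scored.csv")
    elif cfg.models.decoy_score_mode == "raw":
        raw = list(read_channel_csv(workdir / "synthetic_channels.csv"))
        write_channel_csv(raw, workdir / "channels_scored.csv")
    else:
        raise ConfigError(
            f"unknown decoy_score_mode {cfg.models.decoy_score_mode!r}")
    (workdir / "weights.json").write_text(json.dumps(weights, indent=2,
                                                     sort_keys=True))
    return reports, weights


@_timed
def stage_consensus(cfg: RunConfig, workdir: Path) -> ConsensusResult:
    channels = read_channel_csv(workdir / "channels_scored.csv")
    weights = json.loads((workdir / "weights.json").read_text())
    result = weighted_consensus(channels, weights)
    records = _load_curated(workdir)
    roles = {r.id: r.role for r in records}
    out = result.table.copy()
    out.insert(2, "role", [roles.get(c, "unknown") for c in out["id"]])
    out.to_csv(workdir / "ranked.csv", index=False, float_format="%.10g")
    return result


@_timed
def stage_enrich(cfg: RunConfig, workdir: Path):
    ranked = pd.read_csv(workdir / "ranked.csv", dtype={"id": str})
    ranking = list(ranked["id"])
    labels = dict(zip(ranked["id"], ranked["role"]))
    report = evaluate_ranking(ranking, labels,
                              ef_fractions=tuple(cfg.enrich.ef_fractions),
                              decoy_fractions=tuple(cfg.enrich.decoy_fractions),
                              alpha=cfg.enrich.bedroc_alpha)
    (workdir / "enrichment.json").write_text(report.to_json())
    roc_curve_points(ranking, labels).to_csv(workdir / "roc_curve.csv",
                                             index=False, float_format="%.10g")
    return report


@_timed
def stage_bias_audit(cfg: RunConfig, workdir: Path):
    records = _load_curated(workdir)
    labels = {r.id: r.role for r in records}
    panel = _load_features(workdir, "physchem")
    features = _load_features(workdir, "features")
    act_ids = [r.id for r in records if r.role == "active"]
    dec_ids = [r.id for r in records if r.role == "decoy"]
    report = bias_audit(panel.select(act_ids), panel.select(dec_ids),
                        features.block("ecfp4"), features, labels,
                        percentile=cfg.bias.percentile)
    (workdir / "bias_report.json").write_text(report.to_json())
    per_prop = pd.DataFrame([vars(t) for t in report.property_tests])
    per_prop.to_csv(workdir / "bias_properties.csv", index=False)
    percomp = pd.DataFrame({"id": report.diversity_ranks.index,
                            "diversity_rank": report.diversity_ranks.values})
    percomp["decoy_neighbors"] = [
        report.neighbor_counts.get(c, np.nan) for c in percomp["id"]]
    percomp.to_csv(workdir / "bias_compounds.csv", index=False)
    return report


STAGES = {
    "simulate": stage_simulate,
    "curate": stage_curate,
    "featurize": stage_featurize,
    "score": stage_score,
    "select-model": stage_select_model,
    "consensus": stage_consensus,
    "enrich": stage_enrich,
    "bias-audit": stage_bias_audit,
}

RUN_ALL_ORDER = ["simulate", "curate", "featurize", "score", "select-model",
                 "consensus", "enrich", "bias-audit"]

MANIFEST_FILES = [
    "actives.csv", "decoys.csv", "docking_scores.csv", "synthetic_channels.csv",
    "curated.csv", "rejects.csv", "features.csv", "physchem.csv",
    "channels_raw.csv", "channels_scored.csv", "leaderboard.csv",
    "model_reports.json", "weights.json", "ranked.csv", "enrichment.json",
    "roc_curve.csv", "bias_report.json", "bias_properties.csv",
    "bias_compounds.csv",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(cfg: RunConfig, workdir: Path, stages: list[str]) -> Path:
    """Machine-readable run manifest: config, seeds, versions, output hashes.

    Deterministic by construction so identical runs produce identical
    manifests."""
    manifest = {
        "package": "consensusvs",
        "version": __version__,
        "stages": stages,
        "config": json.loads(json.dumps(
            yaml_safe(cfg), sort_keys=True)),
        "seeds": {"run": cfg.seed, "split": cfg.split.seed,
                  "cluster": cfg.channels.cluster_seed,
                  "model_split": cfg.models.split_seed,
                  "grid": cfg.models.grid_seed},
        "outputs": {name: _sha256(workdir / name)
                    for name in MANIFEST_FILES if (workdir / name).exists()},
    }
    path = workdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def yaml_safe(cfg: RunConfig) -> dict:
    import yaml as _yaml
    return _yaml.safe_load(cfg.to_yaml())


def run_stage(name: str, cfg: RunConfig, workdir: str | Path):
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if name == "run-all":
        for stage in RUN_ALL_ORDER:
            STAGES[stage](cfg, workdir)
        write_manifest(cfg, workdir, RUN_ALL_ORDER)
        return
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; valid: {sorted(STAGES)}")
    result = STAGES[name](cfg, workdir)
    write_manifest(cfg, workdir, [name])
    return result
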