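"""Deterministic synthetic actives/decoys datasets and channel scores.

Molecules are enumerated from a combinatorial scaffold+substituent grammar
(four drug-like six-membered cores, three substitution slots, ~25
substituents: > 10^4 distinct products), so every pipeline stage is
testable without downloads.  Actives receive a pIC50 that is a linear
function of computed physicochemical descriptors plus Gaussian noise,
rescaled into the [4, 10] potency window; decoys carry no activity.

Channel scores are monotone transforms of a shared latent activity plus
independent per-channel Gaussian noise, in each channel's documented
orientation, emulating four imperfect measurements of one underlying
signal.  Decoy latent activity is drawn from a normal distribution centred
two pIC50 units below the active mean: separable but overlapping, so
enrichment metrics are non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_features import PHYSCHEM_PANEL
from .data_io import CompoundRecord, DatasetBundle
from .errors import ConfigError
from .scoring_channels import CHANNELS, ORIENTATIONS, ChannelScores

_CORES = (
    "c1c({A})cc({B})cc1{C}",      # benzene, 1,3,5-substituted
    "c1nc({A})cc({B})c1{C}",      # pyridine
    "c1nc({A})nc({B})c1{C}",      # pyrimidine
    "C1CC({A})N({B})CC1{C}",      # piperidine
)

_SUBSTITUENTS = (
    "[H]", "C", "CC", "CCC", "C(C)C", "CCCC", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "I", "C#N", "C(=O)O", "C(=O)N", "C(=O)C",
    "C(F)(F)F", "CO", "CCO", "S", "SC",
)

GRAMMAR_CAPACITY = len(_CORES) * len(_SUBSTITUENTS) ** 3  # 62 500 combos

DEFAULT_ACTIVITY_MODEL: dict[str, float] = {
    "clogp": 0.8,
    "tpsa": -0.02,
    "mol_weight": 0.01,
}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic screening dataset."""

    n_actives: int = 40
    n_decoys: int = 500
    activity_model: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_MODEL))
    activity_noise_sd: float = 0.1
    channel_noise: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CHANNELS})
    property_shift: dict[str, float] | None = None
    decoy_latent_offset: float = -2.0
    decoy_latent_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 10:
            raise ConfigError("n_actives must be >= 10 for modeling tests")
        if self.n_decoys < 1:
            raise ConfigError("n_decoys must be >= 1")
        if self.activity_noise_sd < 0 or any(v < 0 for v in self.channel_noise.values()):
            raise ConfigError("noise SDs must be >= 0")
        for prop in (self.property_shift or {}):
            if prop not in PHYSCHEM_PANEL:
                raise ConfigError(f"unknown property {prop!r} in property_shift")
        for ch in self.channel_noise:
            if ch not in CHANNELS:
                raise ConfigError(f"unknown channel {ch!r} in channel_noise")


def _enumerate_unique(rng: np.random.Generator, n: int,
                      cores: tuple[str, ...] = _CORES,
                      exclude: set[str] | None = None) -> list[str]:
    """Sample ``n`` distinct canonical SMILES from the grammar."""
    seen: set[str] = set(exclude or ())
    out: list[str] = []
    attempts = 0
    max_attempts = 200 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not draw {n} unique molecules from the grammar "
                f"(capacity ~{GRAMMAR_CAPACITY} combinations)")
        core = cores[rng.integers(len(cores))]
        a, b, c = (_SUBSTITUENTS[i] for i in rng.integers(len(_SUBSTITUENTS), size=3))
        smiles = core.format(A=a, B=b, C=c)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(canonical)
    return out


def _panel_values(smiles: list[str], props: list[str]) -> np.ndarray:
    funcs = [PHYSCHEM_PANEL[p] for p in props]
    vals = np.empty((len(smiles), len(props)))
    for i, s in enumerate(smiles):
        mol = Chem.MolFromSmiles(s)
        vals[i] = [float(f(mol)) for f in funcs]
    return vals


def generate_compounds(spec: SyntheticSpec) -> DatasetBundle:
    """Emit a reproducible actives+decoys bundle per the spec.

    With ``property_shift`` set, actives are drawn from the low tail and
    decoys from the high tail of the shifted properties' pooled
    distribution, producing a deliberately biased dataset for audit tests;
    otherwise both groups are random disjoint samples of the grammar.
    """
    n_total = spec.n_actives + spec.n_decoys
    if n_total > 10_000:
        raise ConfigError(
            f"{n_total} compounds exceeds the grammar's enumerable capacity "
            "guarantee (10^4 distinct molecules)")
    rng = np.random.default_rng(spec.seed)

    if spec.property_shift:
        pool_n = min(max(4 * n_total, 2000), 10_000)
        pool = _enumerate_unique(rng, pool_n)
        props = sorted(spec.property_shift)
        vals = _panel_values(pool, props)
        z = (vals - vals.mean(axis=0)) / np.where(vals.std(axis=0) == 0, 1,
                                                  vals.std(axis=0))
        score = z @ np.array([spec.property_shift[p] for p in props])
        jitter = rng.normal(0, 1e-6, size=pool_n)  # deterministic tie-break
        order = np.argsort(score + jitter, kind="stable")
        active_idx = order[: spec.n_actives]
        decoy_idx = order[-spec.n_decoys:]
        active_smiles = [pool[i] for i in active_idx]
        decoy_smiles = [pool[i] for i in decoy_idx]
    else:
        # Actives form a congeneric series on one scaffold core (as real
        # SAR-derived active sets do); decoys are diverse across all cores.
        active_core = _CORES[rng.integers(len(_CORES))]
        active_smiles = _enumerate_unique(rng, spec.n_actives,
                                          cores=(active_core,))
        decoy_smiles = _enumerate_unique(rng, spec.n_decoys,
                                         exclude=set(active_smiles))

    # Latent activity of the actives: linear model on descriptors + noise,
    # affinely rescaled into the [4, 10] pIC50 window.
    props = sorted(spec.activity_model)
    coefs = np.array([spec.activity_model[p] for p in props])
    desc = _panel_values(active_smiles, props)
    signal = desc @ coefs
    # activity_noise_sd is relative to the signal's own spread; a dedicated
    # stream keeps the draw independent of how many molecules were sampled
    rng_act = np.random.default_rng([spec.seed, 4241])
    noise_scale = spec.activity_noise_sd * max(float(signal.std(ddof=0)), 1e-12)
    raw = signal + rng_act.normal(0.0, noise_scale, size=spec.n_actives)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        pic50 = np.full(spec.n_actives, 7.0)
    else:
        pic50 = 4.0 + 6.0 * (raw - lo) / (hi - lo)

    actives = [
        CompoundRecord(id=f"ACT{i:04d}", smiles=s, role="active",
                       pic50=float(round(p, 6)))
        for i, (s, p) in enumerate(zip(active_smiles, pic50))
    ]
    decoys = [
        CompoundRecord(id=f"DEC{i:04d}", smiles=s, role="decoy")
        for i, s in enumerate(decoy_smiles)
    ]
    return DatasetBundle(actives=actives, decoys=decoys,
                         provenance=f"synthetic grammar, seed={spec.seed}",
                         seed=spec.seed)


def latent_activity(bundle: DatasetBundle, spec: SyntheticSpec) -> pd.Series:
    """Shared latent activity per compound, on the pIC50 scale.

    Actives use their pIC50; decoys draw from
    ``N(mean_active + decoy_latent_offset, decoy_latent_sd)``, seeded from
    the spec, so repeated calls agree exactly.
    """
    rng = np.random.default_rng([spec.seed, 7919])
    mu = float(np.mean([r.pic50 for r in bundle.actives]))
    decoy_latent = rng.normal(mu + spec.decoy_latent_offset,
                              spec.decoy_latent_sd, size=len(bundle.decoys))
    return pd.Series(
        {r.id: float(r.pic50) for r in bundle.actives}
        | {r.id: float(v) for r, v in zip(bundle.decoys, decoy_latent)}
    )


def generate_channel_scores(bundle: DatasetBundle,
                            spec: SyntheticSpec) -> dict[str, ChannelScores]:
    """Four channels as monotone transforms of the latent activity + noise.

    The latent is standardized over the pool; each channel adds independent
    Gaussian noise of its configured SD on that standardized scale (so
    ``channel_noise == 1`` means noise SD equal to signal SD), then maps
    through a channel-specific monotone link:

    * qsar — identity back onto the pIC50 scale (higher better);
    * similarity — logistic squash into (0, 1) (higher better);
    * docking — negative affine, kcal/mol-like (lower better);
    * pharmacophore — softplus decreasing in activity, >= 0 (lower better).
    """
    latent = latent_activity(bundle, spec)
    ids = list(latent.index)
    mu, sd = float(latent.mean()), float(latent.std(ddof=0))
    z = (latent.to_numpy() - mu) / (sd if sd > 0 else 1.0)
    out: dict[str, ChannelScores] = {}
    for k, channel in enumerate(CHANNELS):
        rng = np.random.default_rng([spec.seed, 104729, k])
        e = z + rng.normal(0.0, spec.channel_noise.get(channel, 1.0), size=len(z))
        if channel == "qsar":
            raw = mu + sd * e
        elif channel == "similarity":
            raw = 1.0 / (1.0 + np.exp(-1.2 * e))
        elif channel == "docking":
            raw = -7.0 - 1.5 * e
        else:  # pharmacophore: RMSE-like, decreasing in activity
            raw = np.log1p(np.exp(1.0 - 1.2 * e))
        out[channel] = ChannelScores(channel, pd.Series(raw, index=ids),
                                     ORIENTATIONS[channel])
    return out


def bundle_to_tables(bundle: DatasetBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Actives and decoys tables in the CSV schema ``data_io`` consumes."""
    actives = pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles, "pic50": r.pic50} for r in bundle.actives])
    decoys = pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles} for r in bundle.decoys])
    return actives, decoys
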