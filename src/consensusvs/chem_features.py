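"""Fingerprint families, the RDKit descriptor block, and the 17-property
physicochemical panel.

Six 2D fingerprint families are supported (atom pairs, Avalon, ECFP4, ECFP6,
MACCS keys, topological torsions) plus a scalar-descriptor block: the full
RDKit descriptor list augmented with summary statistics (min/max/mean) of
Gasteiger partial charges.  Everything is a pure function of the canonical
SMILES and the declared parameters, so feature matrices are reproducible
bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import (
    AllChem,
    Crippen,
    Descriptors,
    Lipinski,
    MACCSkeys,
    QED,
    rdFingerprintGenerator,
    rdMolDescriptors,
)
from rdkit.Avalon import pyAvalonTools

from .data_io import CompoundRecord
from .errors import ConfigError

log = logging.getLogger(__name__)

FINGERPRINT_FAMILIES = ("atompair", "avalon", "ecfp4", "ecfp6", "maccs", "torsion")

# Community-default widths: 2048 bits for hashed families, Avalon 512,
# MACCS fixed at 167.
_N_BITS = 2048
_AVALON_BITS = 512


@dataclass
class FeatureMatrix:
    """Named numeric features per compound, organised in column blocks."""

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n_compounds, n_features), float64, finite
    blocks: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> [start, stop)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.compound_ids)} ids x {len(self.feature_names)} features"
            )
        covered: set[int] = set()
        for name, (lo, hi) in self.blocks.items():
            cols = range(lo, hi)
            if covered & set(cols):
                raise ValueError(f"block {name!r} overlaps another block")
            covered |= set(cols)
        if self.blocks and covered != set(range(self.values.shape[1])):
            raise ValueError("blocks must cover all columns exactly")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.feature_names)

    def block(self, name: str) -> "FeatureMatrix":
        """Sub-matrix for one named block."""
        lo, hi = self.blocks[name]
        return FeatureMatrix(
            compound_ids=list(self.compound_ids),
            feature_names=self.feature_names[lo:hi],
            values=self.values[:, lo:hi],
            blocks={name: (0, hi - lo)},
        )

    def select(self, ids: Sequence[str]) -> "FeatureMatrix":
        """Row subset in the given id order."""
        index = {c: i for i, c in enumerate(self.compound_ids)}
        rows = [index[c] for c in ids]
        return FeatureMatrix(
            compound_ids=list(ids),
            feature_names=list(self.feature_names),
            values=self.values[rows],
            blocks=dict(self.blocks),
        )

    @staticmethod
    def hstack(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        ids = parts[0].compound_ids
        for p in parts[1:]:
            if p.compound_ids != ids:
                raise ValueError("cannot hstack matrices over different compounds")
        names: list[str] = []
        blocks: dict[str, tuple[int, int]] = {}
        offset = 0
        for p in parts:
            for bname, (lo, hi) in p.blocks.items():
                blocks[bname] = (offset + lo, offset + hi)
            names.extend(p.feature_names)
            offset += len(p.feature_names)
        return FeatureMatrix(
            compound_ids=list(ids),
            feature_names=names,
            values=np.hstack([p.values for p in parts]),
            blocks=blocks,
        )


def _mols(records: Sequence[CompoundRecord]) -> list[Chem.Mol]:
    mols = []
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {r.id!r}: {r.smiles!r}")
        mols.append(mol)
    return mols


def _fingerprint_block(mols: list[Chem.Mol], family: str) -> np.ndarray:
    if family == "ecfp4":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_N_BITS)
        fps = [gen.GetFingerprint(m) for m in mols]
    elif family == "ecfp6":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=_N_BITS)
        fps = [gen.GetFingerprint(m) for m in mols]
    elif family == "atompair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=_N_BITS)
        fps = [gen.GetFingerprint(m) for m in mols]
    elif family == "torsion":
        gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=_N_BITS)
        fps = [gen.GetFingerprint(m) for m in mols]
    elif family == "avalon":
        fps = [pyAvalonTools.GetAvalonFP(m, nBits=_AVALON_BITS) for m in mols]
    elif family == "maccs":
        fps = [MACCSkeys.GenMACCSKeys(m) for m in mols]
    else:
        raise ConfigError(
            f"unknown fingerprint family {family!r}; valid: {FINGERPRINT_FAMILIES}"
        )
    arr = np.zeros((len(fps), fps[0].GetNumBits()), dtype=float)
    for i, fp in enumerate(fps):
        arr[i, list(fp.GetOnBits())] = 1.0
    return arr


def compute_fingerprints(
    records: Sequence[CompoundRecord],
    families: Sequence[str] = ("ecfp4",),
) -> FeatureMatrix:
    """Concatenated bit-vector blocks for the requested fingerprint families."""
    for fam in families:
        if fam not in FINGERPRINT_FAMILIES:
            raise ConfigError(
                f"unknown fingerprint family {fam!r}; valid: {FINGERPRINT_FAMILIES}"
            )
    mols = _mols(records)
    parts = []
    for fam in families:
        block = _fingerprint_block(mols, fam)
        parts.append(
            FeatureMatrix(
                compound_ids=[r.id for r in records],
                feature_names=[f"{fam}_{j}" for j in range(block.shape[1])],
                values=block,
                blocks={fam: (0, block.shape[1])},
            )
        )
    return FeatureMatrix.hstack(parts)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A&B| / |A|B| over binary bit vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _gasteiger_stats(mol: Chem.Mol) -> tuple[float, float, float]:
    mol = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(mol)
    charges = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()], dtype=float
    )
    charges = charges[np.isfinite(charges)]
    if charges.size == 0:
        return (np.nan, np.nan, np.nan)
    return (float(charges.min()), float(charges.max()), float(charges.mean()))


def compute_descriptors(records: Sequence[CompoundRecord]) -> FeatureMatrix:
    """The full RDKit scalar-descriptor block plus Gasteiger-charge summaries.

    Non-finite entries (rare descriptor failures) are imputed to the column
    median and logged; the returned matrix is always finite.
    """
    mols = _mols(records)
    names = [n for n, _ in Descriptors.descList]
    rows = []
    for mol in mols:
        vals = Descriptors.CalcMolDescriptors(mol)
        row = [vals.get(n, np.nan) for n in names]
        row.extend(_gasteiger_stats(mol))
        rows.append(row)
    all_names = names + ["GasteigerMin", "GasteigerMax", "GasteigerMean"]
    values = np.asarray(rows, dtype=float)
    values = _impute_median(values, all_names)
    return FeatureMatrix(
        compound_ids=[r.id for r in records],
        feature_names=all_names,
        values=values,
        blocks={"descriptors": (0, len(all_names))},
    )


def _impute_median(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    values = values.copy()
    bad = ~np.isfinite(values)
    if bad.any():
        for j in np.unique(np.where(bad)[1]):
            col = values[:, j]
            finite = col[np.isfinite(col)]
            fill = float(np.median(finite)) if finite.size else 0.0
            col[~np.isfinite(col)] = fill
            values[:, j] = col
            log.warning(
                "imputed %d non-finite values in column %s with median %.4g",
                int(bad[:, j].sum()), names[j], fill,
            )
    return values


def _esol_logs(mol: Chem.Mol) -> float:
    """Delaney ESOL aqueous-solubility estimate (log mol/L) from 2D features."""
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    rb = Lipinski.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def _largest_ring_size(mol: Chem.Mol) -> int:
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


# The 17-property physicochemical panel used by the bias audit.  Order is the
# panel definition; the count is enforced.
PHYSCHEM_PANEL: dict[str, callable] = {
    "mol_weight": Descriptors.MolWt,
    "clogp": Crippen.MolLogP,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "ring_count": rdMolDescriptors.CalcNumRings,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
    "fraction_csp3": rdMolDescriptors.CalcFractionCSP3,
    "formal_charge": Chem.GetFormalCharge,
    "molar_refractivity": Crippen.MolMR,
    "stereocenters": lambda m: rdMolDescriptors.CalcNumAtomStereoCenters(m)
    + rdMolDescriptors.CalcNumUnspecifiedAtomStereoCenters(m),
    "heteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
    "qed": QED.qed,
    "logs_esol": _esol_logs,
    "largest_ring": _largest_ring_size,
}


def compute_physchem_panel(
    records: Sequence[CompoundRecord],
    panel: Mapping[str, callable] | None = None,
) -> FeatureMatrix:
    """The 17 configured physicochemical properties per compound.

    The panel is configurable but its width is enforced at exactly 17
    properties, matching the balanced-representation audit it feeds.
    """
    panel = dict(panel if panel is not None else PHYSCHEM_PANEL)
    if len(panel) != 17:
        raise ConfigError(f"physicochemical panel must have 17 properties, got {len(panel)}")
    mols = _mols(records)
    names = list(panel)
    values = np.array(
        [[float(panel[n](m)) for n in names] for m in mols], dtype=float
    )
    values = _impute_median(values, names)
    return FeatureMatrix(
        compound_ids=[r.id for r in records],
        feature_names=names,
        values=values,
        blocks={"physchem": (0, len(names))},
    )


def write_feature_matrix(fm: FeatureMatrix, csv_path, sidecar_path=None) -> None:
    """Write a matrix as CSV with a JSON sidecar recording block ranges."""
    import json
    from pathlib import Path

    fm.frame.to_csv(csv_path, index_label="id")
    if sidecar_path is None:
        sidecar_path = Path(str(csv_path)).with_suffix(".blocks.json")
    with open(sidecar_path, "w") as fh:
        json.dump(
            {"blocks": {k: list(v) for k, v in fm.blocks.items()},
             "n_compounds": len(fm.compound_ids),
             "n_features": len(fm.feature_names)},
            fh, indent=2, sort_keys=True,
        )
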