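"""Reading, curating and splitting compound datasets.

Compounds arrive as delimited tables (``id,smiles[,ic50_uM|pic50]``) or SD
files.  Curation mirrors standard ligand-preparation practice for 2D
screening: keep the largest organic fragment (salt/counter-ion stripping),
neutralize charges where a simple proton-transfer rule applies, canonicalize,
and merge duplicates.  Activities are handled on the pIC50 scale,
``pIC50 = 6 - log10(IC50 in uM)``, so that micromolar potency maps to 6 and
nanomolar to 9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import DomainError, DuplicateIdError, EmptyInputError, FormatError

ROLES = ("active", "decoy")
SPLITS = ("train", "validation", "external", "unassigned")


@dataclass(frozen=True)
class CompoundRecord:
    """One curated molecule with identity, role and activity fields."""

    id: str
    smiles: str
    role: str  # "active" | "decoy"
    ic50_uM: float | None = None
    pic50: float | None = None
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        if self.role == "decoy" and (self.ic50_uM is not None or self.pic50 is not None):
            raise ValueError(f"decoy {self.id!r} must not carry activity values")
        if self.ic50_uM is not None:
            if self.ic50_uM <= 0:
                raise DomainError(f"ic50_uM must be positive, got {self.ic50_uM}")
            expected = pic50_from_ic50(self.ic50_uM)
            if self.pic50 is not None and abs(self.pic50 - expected) > 1e-9:
                raise ValueError(
                    f"{self.id!r}: pic50 {self.pic50} inconsistent with "
                    f"ic50_uM {self.ic50_uM} (expected {expected})"
                )
            if self.pic50 is None:
                object.__setattr__(self, "pic50", expected)


@dataclass
class RejectedRecord:
    id: str
    smiles: str
    reason: str


@dataclass
class DatasetBundle:
    """Actives plus decoys forming one retrospective screening pool."""

    actives: list[CompoundRecord]
    decoys: list[CompoundRecord]
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.actives] + [r.id for r in self.decoys]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise DuplicateIdError(f"id collision across actives/decoys: {dup!r}")

    @property
    def records(self) -> list[CompoundRecord]:
        return list(self.actives) + list(self.decoys)


def pic50_from_ic50(ic50_uM: float) -> float:
    """pIC50 = 6 - log10(IC50/uM).  IC50 of 1 uM maps to 6."""
    if not ic50_uM > 0:
        raise DomainError(f"IC50 must be positive, got {ic50_uM}")
    return 6.0 - math.log10(ic50_uM)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50`; returns IC50 in uM."""
    return 10.0 ** (6.0 - pic50)


def read_compound_table(path: str | Path, role: str) -> tuple[list[CompoundRecord], list[RejectedRecord]]:
    """Read a compound CSV, returning parseable records plus listed rejects.

    The file must have ``id`` and ``smiles`` columns; actives may carry
    ``ic50_uM`` or ``pic50``.  Unparseable SMILES are collected and reported,
    never silently dropped.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no rows")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise DuplicateIdError(f"{path}: duplicate ids {dups}")

    records: list[CompoundRecord] = []
    rejects: list[RejectedRecord] = []
    for row in df.itertuples(index=False):
        smiles = str(row.smiles)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            rejects.append(RejectedRecord(str(row.id), smiles, "unparseable SMILES"))
            continue
        kwargs: dict = {}
        if role == "active":
            ic50 = getattr(row, "ic50_uM", None)
            pic = getattr(row, "pic50", None)
            if ic50 is not None and np.isfinite(ic50):
                kwargs["ic50_uM"] = float(ic50)
            elif pic is not None and pic == pic:
                kwargs["pic50"] = float(pic)
        records.append(
            CompoundRecord(id=str(row.id), smiles=Chem.MolToSmiles(mol), role=role, **kwargs)
        )
    return records, rejects


def read_sdf(path: str | Path, role: str) -> tuple[list[CompoundRecord], list[RejectedRecord]]:
    """Read an SD file; the molecule title line supplies the id."""
    path = Path(path)
    records: list[CompoundRecord] = []
    rejects: list[RejectedRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    seen: set[str] = set()
    for i, mol in enumerate(supplier):
        if mol is None:
            rejects.append(RejectedRecord(f"sdf_entry_{i}", "", "unparseable SDF record"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        cid = name.strip() or f"sdf_entry_{i}"
        if cid in seen:
            raise DuplicateIdError(f"{path}: duplicate id {cid!r}")
        seen.add(cid)
        records.append(CompoundRecord(id=cid, smiles=Chem.MolToSmiles(mol), role=role))
    return records, rejects


_UNCHARGER = rdMolStandardize.Uncharger()


def _curate_one(record: CompoundRecord) -> CompoundRecord | RejectedRecord:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return RejectedRecord(record.id, record.smiles, "unparseable SMILES")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        return RejectedRecord(record.id, record.smiles, "empty molecule")
    # Largest-fragment keep: most heavy atoms, ties by canonical SMILES order.
    best = max(
        frags,
        key=lambda m: (m.GetNumHeavyAtoms(), _neg_lex(Chem.MolToSmiles(m))),
    )
    neutral = _UNCHARGER.uncharge(best)
    smiles = Chem.MolToSmiles(neutral)
    if not smiles:
        return RejectedRecord(record.id, record.smiles, "reduced to empty molecule")
    return replace(record, smiles=smiles)


class _neg_lex(str):
    """Inverts lexicographic comparison so max() prefers the smallest string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def curate(records: Sequence[CompoundRecord]) -> tuple[list[CompoundRecord], list[RejectedRecord]]:
    """Strip salts, neutralize, canonicalize, and merge duplicates.

    Duplicates (identical canonical SMILES after curation, within the same
    role) are merged keeping the first-seen id.  Output order is input order,
    so the operation is deterministic and idempotent.
    """
    curated: list[CompoundRecord] = []
    rejects: list[RejectedRecord] = []
    seen: dict[tuple[str, str], str] = {}
    for rec in records:
        out = _curate_one(rec)
        if isinstance(out, RejectedRecord):
            rejects.append(out)
            continue
        key = (out.role, out.smiles)
        if key in seen:
            continue
        seen[key] = out.id
        curated.append(out)
    return curated, rejects


def split_dataset(
    actives: Sequence[CompoundRecord],
    train_frac: float = 0.7,
    external_n: int = 10,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Assign actives to train/validation/external partitions.

    The external hold-out is sampled first (it is never seen during model
    selection); the remainder is split train:validation at ``train_frac``.
    Assignment is a pure function of the seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0,1), got {train_frac}")
    if external_n < 0:
        raise ValueError("external_n must be >= 0")
    n = len(actives)
    if external_n >= n:
        raise EmptyInputError(
            f"external_n={external_n} leaves no compounds to model (n={n})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    external = set(order[:external_n])
    remainder = [i for i in range(n) if i not in external]
    n_train = int(round(train_frac * len(remainder)))
    if n_train == 0 or n_train == len(remainder):
        raise EmptyInputError(
            f"train_frac={train_frac} leaves an empty partition for n={len(remainder)}"
        )
    rng2 = np.random.default_rng(seed + 1)
    shuffled = list(rng2.permutation(remainder))
    train = set(shuffled[:n_train])
    out = []
    for i, rec in enumerate(actives):
        if i in external:
            split = "external"
        elif i in train:
            split = "train"
        else:
            split = "validation"
        out.append(replace(rec, split=split))
    return out


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabular view of records, suitable for writing the curated CSV."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "smiles": r.smiles,
                "role": r.role,
                "ic50_uM": r.ic50_uM,
                "pic50": r.pic50,
                "split": r.split,
            }
            for r in records
        ]
    )


def write_curated_csv(records: Iterable[CompoundRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_rejects_csv(rejects: Iterable[RejectedRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in rejects], columns=["id", "smiles", "reason"]).to_csv(
        path, index=False
    )
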