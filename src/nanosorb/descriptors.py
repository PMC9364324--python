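"""Molecular descriptor tables for QSAR modelling.

The primary path is ingestion of externally computed descriptor tables
(CSV with one row per compound and one named real-valued column per
descriptor).  A native RDKit-based calculator covers a small, unambiguously
defined subset; the full vendor descriptor set (topological
autocorrelations, Wiener path counts, E-state fragment counts, ...) is
deliberately not reimplemented, because exact parity with any particular
toolkit version cannot be established -- those columns are treated as
opaque ingested data.

Native subset definitions (hydrogens made explicit before counting,
aromaticity perceived by RDKit):

nAtom
    total number of atoms, including explicit hydrogens.
nHBDon
    number of hydrogen-bond donors (Lipinski NH/OH count).
nRotB
    number of rotatable bonds (strict definition; terminal and ring bonds
    are not rotatable).
nAcid
    number of acidic groups (carboxylic, sulfonic, phosphonic acid
    patterns).
nBase
    number of basic nitrogen atoms (amines not amide-like).
nSmallRings
    number of rings of size 3--6 in the smallest set of smallest rings.
Fsp3
    fraction of carbon atoms that are sp3 hybridised, in [0, 1]; 0.0 for
    molecules without carbon.
C1SP3
    number of sp3 carbons bound to exactly one other carbon.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

__all__ = [
    "DESCRIPTOR_VOCABULARY",
    "BASIC_DESCRIPTORS",
    "ingest_descriptor_table",
    "require_columns",
    "compute_basic_descriptors",
]

#: Descriptor names the pipeline's frozen models draw on.  Unknown names in
#: ingested tables are allowed (with a warning) so vendor tables can be
#: passed through untouched.
DESCRIPTOR_VOCABULARY = frozenset(
    {
        "ALogP", "XLogP", "AMR", "Fsp3", "nHBDon", "nAtom", "nAcid", "nBase",
        "nRotB", "nSmallRings", "nAtomP", "C1SP3", "TopoPSA",
        "khs.sOH", "khs.ssNH", "khs.aasC", "khs.aaaC", "khs.aasN",
        "khs.ssssC", "khs.sssSiH", "khs.ssssSi", "khs.sBr",
        "ATSm1", "ATSm4", "ATSp1", "ATSp5",
        "WTPT.4", "WPATH", "Kier1", "Kier2",
        "fragC", "ECCEN", "MDEO.11", "SCH.7",
    }
)

#: Subset computed natively from SMILES.
BASIC_DESCRIPTORS = (
    "nAtom", "nHBDon", "nRotB", "nAcid", "nBase", "nSmallRings", "Fsp3", "C1SP3",
)

_COUNT_DESCRIPTORS = frozenset(
    n for n in DESCRIPTOR_VOCABULARY
    if n.startswith(("n", "khs.")) or n in {"C1SP3", "WPATH"}
)

_ACID_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in ("[CX3](=O)[OX2H1]", "[SX4](=O)(=O)[OX2H1]", "[PX4](=O)([OX2H1])")
]
_BASE_SMARTS = Chem.MolFromSmarts(
    "[NX3;H2,H1,H0;!$(NC=O);!$(NS(=O)=O);!$(N=*);!$([N+]);!$(Nc)]"
)


def ingest_descriptor_table(
    path: str | Path | pd.DataFrame, *, id_col: str = "id"
) -> pd.DataFrame:
    """Read and validate a descriptor table.

    The table must carry an ``id`` column of unique compound identifiers;
    every other column is a numeric descriptor.  Descriptor names outside
    the registered vocabulary are accepted with a warning.  A non-numeric
    cell or a duplicate id raises ``ValueError``.
    """
    df = path.copy() if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    if id_col not in df.columns:
        raise ValueError(f"descriptor table missing id column {id_col!r}")
    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate compound ids: {dupes}")
    df = df.set_index(id_col)
    unknown = [c for c in df.columns if c not in DESCRIPTOR_VOCABULARY]
    if unknown:
        warnings.warn(
            f"descriptor columns outside registered vocabulary: {unknown}",
            stacklevel=2,
        )
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as err:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric value in column {col!r} at row {row!r}"
            ) from err
    return df


def require_columns(table: pd.DataFrame, names: Iterable[str]) -> None:
    """Raise ``KeyError`` naming every descriptor a model needs but the
    table lacks."""
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise KeyError(f"descriptor table missing required columns: {missing}")


def _describe_mol(mol: Chem.Mol) -> dict[str, float]:
    molh = Chem.AddHs(mol)
    n_acid = sum(len(molh.GetSubstructMatches(p)) for p in _ACID_SMARTS)
    c1sp3 = 0
    for atom in molh.GetAtoms():
        if atom.GetSymbol() == "C" and atom.GetHybridization() == Chem.HybridizationType.SP3:
            c_neighbors = sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "C")
            if c_neighbors == 1:
                c1sp3 += 1
    ring_info = molh.GetRingInfo()
    n_small = sum(1 for ring in ring_info.AtomRings() if 3 <= len(ring) <= 6)
    return {
        "nAtom": float(molh.GetNumAtoms()),
        "nHBDon": float(Lipinski.NumHDonors(mol)),
        "nRotB": float(rdMolDescriptors.CalcNumRotatableBonds(mol, strict=True)),
        "nAcid": float(n_acid),
        "nBase": float(len(molh.GetSubstructMatches(_BASE_SMARTS))),
        "nSmallRings": float(n_small),
        "Fsp3": float(Descriptors.FractionCSP3(mol)),
        "C1SP3": float(c1sp3),
    }


def compute_basic_descriptors(
    smiles: Sequence[str], ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Compute the native descriptor subset for a batch of SMILES.

    Returns ``(table, errors)`` where ``table`` has one row per parseable
    SMILES and columns :data:`BASIC_DESCRIPTORS`, and ``errors`` lists
    ``(id, message)`` for rows whose SMILES could not be parsed; the batch
    continues past bad rows.
    """
    if ids is None:
        ids = list(smiles)
    if len(ids) != len(smiles):
        raise ValueError("ids and smiles must have equal length")
    rows, errors = {}, []
    for cid, smi in zip(ids, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors.append((str(cid), f"unparseable SMILES: {smi!r}"))
            continue
        rows[str(cid)] = _describe_mol(mol)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(BASIC_DESCRIPTORS))
    table.index.name = "id"
    return table, errors
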