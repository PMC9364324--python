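"""Biological surface adsorption index (BSAI) models.

The BSAI relationship is a linear free-energy model for the adsorption
affinity of a small molecule to a nanomaterial surface:

    log k = c + E*r_e + S*p_s + A*a + B*b + V*v

where [E, S, A, B, V] are the Abraham solute descriptors of the molecule
(excess molar refraction, dipolarity/polarizability, hydrogen-bond acidity,
hydrogen-bond basicity, McGowan characteristic volume) and [c, r_e, p_s, a,
b, v] are per-nanomaterial "nanodescriptors" weighting, respectively, the
baseline adsorption constant and the contributions of lone-pair electron,
polarity/polarizability, H-bond acidity, H-bond basicity and hydrophobicity
interactions.  log k is the base-10 logarithm of the adsorption affinity
constant.

Nanodescriptor values are experimental quantities supplied by the user as a
registry (YAML or JSON mapping of nanomaterial id to the six coefficients);
this module never hardcodes them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AbrahamDescriptors",
    "NanoDescriptorSet",
    "ABRAHAM_COLUMNS",
    "predict_bsai",
    "batch_predict",
    "load_nano_registry",
    "clean_compound_dataset",
]

#: Column order of the Abraham solute descriptors throughout the package.
ABRAHAM_COLUMNS = ("E", "S", "A", "B", "V")


@dataclass(frozen=True)
class AbrahamDescriptors:
    """Abraham solute descriptors [E, S, A, B, V] of one compound."""

    E: float  #: excess molar refraction
    S: float  #: dipolarity / polarizability
    A: float  #: hydrogen-bond acidity
    B: float  #: hydrogen-bond basicity
    V: float  #: McGowan characteristic volume (always > 0 for real molecules)

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.S, self.A, self.B, self.V], dtype=float)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("Abraham descriptors must all be finite")


@dataclass(frozen=True)
class NanoDescriptorSet:
    """Nanodescriptors [c, r_e, p_s, a, b, v] of one nanomaterial.

    ``r_e`` and ``p_s`` are the lone-pair and polarity/polarizability weights
    (named after the Abraham descriptors E and S they multiply, to avoid
    clashing with the correlation coefficient r and the p-value p).
    """

    enm_id: str
    c: float
    r_e: float
    p_s: float
    a: float
    b: float
    v: float

    def weights(self) -> np.ndarray:
        """Weights in ABRAHAM_COLUMNS order (excluding the intercept c)."""
        return np.array([self.r_e, self.p_s, self.a, self.b, self.v], dtype=float)

    def __post_init__(self) -> None:
        vals = [self.c, self.r_e, self.p_s, self.a, self.b, self.v]
        if not all(math.isfinite(x) for x in vals):
            raise ValueError(f"nanodescriptors for {self.enm_id!r} must be finite")


def predict_bsai(compound: AbrahamDescriptors, nano: NanoDescriptorSet) -> float:
    """Predicted log k (base 10) of ``compound`` on ``nano``.

    Returns ``c + E*r_e + S*p_s + A*a + B*b + V*v`` exactly.
    """
    return float(nano.c + compound.as_array() @ nano.weights())


def batch_predict(
    compounds: pd.DataFrame, registry: Iterable[NanoDescriptorSet]
) -> pd.DataFrame:
    """Predicted log k for every compound x nanomaterial pair.

    Parameters
    ----------
    compounds
        DataFrame with columns E, S, A, B, V; the index identifies compounds.
    registry
        Nanodescriptor sets; ``enm_id`` must be unique.

    Returns
    -------
    DataFrame of shape (n_compounds, n_enms): the log k matrix, rows indexed
    like ``compounds``, columns by ``enm_id``.
    """
    registry = list(registry)
    if not registry:
        raise ValueError("nanodescriptor registry is empty")
    ids = [n.enm_id for n in registry]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate enm_id in registry: {dupes}")
    missing = [c for c in ABRAHAM_COLUMNS if c not in compounds.columns]
    if missing:
        raise ValueError(f"compound table missing Abraham columns: {missing}")
    X = compounds.loc[:, list(ABRAHAM_COLUMNS)].to_numpy(dtype=float)
    if X.size and not np.all(np.isfinite(X)):
        raise ValueError("compound table contains non-finite descriptor values")
    W = np.array([n.weights() for n in registry]).T  # (5, n_enms)
    c = np.array([n.c for n in registry])
    values = X @ W + c  # broadcasting the intercepts over rows
    return pd.DataFrame(values, index=compounds.index, columns=ids)


def load_nano_registry(path: str | Path) -> list[NanoDescriptorSet]:
    """Load a nanodescriptor registry from YAML or JSON.

    Accepted layout: a mapping of enm_id to a mapping with keys
    ``c, r_e, p_s, a, b, v``, or a list of such mappings each carrying an
    ``enm_id`` key.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    entries: list[NanoDescriptorSet] = []
    if isinstance(data, Mapping):
        items = [{"enm_id": k, **v} for k, v in data.items()]
    else:
        items = list(data)
    for item in items:
        try:
            entries.append(
                NanoDescriptorSet(
                    enm_id=str(item["enm_id"]),
                    c=float(item["c"]),
                    r_e=float(item["r_e"]),
                    p_s=float(item["p_s"]),
                    a=float(item["a"]),
                    b=float(item["b"]),
                    v=float(item["v"]),
                )
            )
        except KeyError as err:
            raise ValueError(f"registry entry {item!r} missing key {err}") from err
    return entries


def clean_compound_dataset(
    raw: pd.DataFrame,
    corrections: Mapping[str, str] | None = None,
    exclusions: Iterable[str] | None = None,
    *,
    key_col: str = "key",
    smiles_col: str = "smiles",
    compound_col: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clean a raw Abraham-descriptor compound table in three steps.

    1. apply SMILES ``corrections`` (key -> corrected SMILES); a correction
       whose key is absent is ignored with a warning;
    2. drop rows whose key is in ``exclusions`` (poor data quality, metals,
       salts);
    3. collapse replicate entries of the same compound (identified by
       ``compound_col`` when given, else by SMILES) to one randomly chosen
       representative under ``seed``, then collapse groups of isomers --
       rows identical in all five Abraham descriptors -- to one.

    The operation is idempotent: cleaning a cleaned table is the identity.
    """
    import warnings

    df = raw.copy()
    if df[key_col].duplicated().any():
        raise ValueError("compound keys must be unique")
    corrections = dict(corrections or {})
    exclusions = set(exclusions or ())

    keys = df[key_col].astype(str)
    for key, smi in corrections.items():
        mask = keys == str(key)
        if not mask.any():
            warnings.warn(f"correction key {key!r} not found; skipped", stacklevel=2)
            continue
        df.loc[mask, smiles_col] = smi

    df = df[~keys.isin({str(k) for k in exclusions})]

    rng = np.random.default_rng(seed)
    ident = df[compound_col] if compound_col else df[smiles_col]
    # one random representative per replicated compound
    pick = lambda idx: idx[rng.integers(len(idx))]  # noqa: E731
    keep = {pick(grp.to_numpy()) for _, grp in df.groupby(ident, sort=False).groups.items()}
    df = df.loc[df.index.isin(keep)]

    # isomers share all five Abraham descriptors; keep the first of each group
    df = df.drop_duplicates(subset=list(ABRAHAM_COLUMNS), keep="first")
    return df
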