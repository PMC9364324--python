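"""Synthetic input generators with known ground truth.

Every pipeline stage can be exercised at desk scale without any external
download: Abraham-descriptor compound tables shaped like the open
experimental collections the BSAI models are applied to, molecular
descriptor tables whose response is generated exactly (or noisily) from a
specified linear model, and PMF profiles with closed-form adsorption
constants.  All generators are pure functions of their configuration; the
same seed always reproduces the same output.

The default descriptor ranges bracket typical small-organic values; they
are plumbing defaults for testing, not estimates of any particular
empirical data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pmf import PMFProfile
from .qsar import LinearModel

__all__ = [
    "GeneratorConfig",
    "ABRAHAM_RANGES",
    "DESCRIPTOR_RANGES",
    "gen_abraham_compounds",
    "gen_table_from_model",
    "gen_pmf",
]

#: Default per-descriptor uniform ranges for Abraham descriptors.
ABRAHAM_RANGES: dict[str, tuple[float, float]] = {
    "E": (-0.5, 3.0),
    "S": (0.0, 3.0),
    "A": (0.0, 2.0),
    "B": (0.0, 3.0),
    "V": (0.3, 3.0),
}

#: Realistic sampling ranges for named molecular descriptors.  Integer
#: ranges generate integer-valued count descriptors.
DESCRIPTOR_RANGES: dict[str, tuple[float, float] | tuple[int, int, str]] = {
    "ALogP": (-2.0, 6.0),
    "XLogP": (-2.0, 6.0),
    "AMR": (10.0, 150.0),
    "Fsp3": (0.0, 1.0),
    "TopoPSA": (0.0, 200.0),
    "ATSm1": (50.0, 500.0),
    "ATSm4": (0.0, 300.0),
    "ATSp1": (100.0, 2000.0),
    "ATSp5": (0.0, 2000.0),
    "WTPT.4": (0.0, 20.0),
    "WPATH": (50.0, 5000.0),
    "Kier1": (1.0, 20.0),
    "Kier2": (1.0, 15.0),
    "fragC": (0.0, 4000.0),
    "ECCEN": (20.0, 500.0),
    "MDEO.11": (0.0, 3.0),
    "SCH.7": (0.0, 2.0),
    "nAtom": (5, 80, "int"),
    "nHBDon": (0, 6, "int"),
    "nAcid": (0, 3, "int"),
    "nBase": (0, 3, "int"),
    "nRotB": (0, 12, "int"),
    "nSmallRings": (0, 4, "int"),
    "nAtomP": (0, 30, "int"),
    "C1SP3": (0, 6, "int"),
    "khs.sOH": (0, 4, "int"),
    "khs.ssNH": (0, 3, "int"),
    "khs.aasC": (0, 6, "int"),
    "khs.aaaC": (0, 4, "int"),
    "khs.aasN": (0, 2, "int"),
    "khs.ssssC": (0, 3, "int"),
    "khs.sssSiH": (0, 1, "int"),
    "khs.ssssSi": (0, 1, "int"),
    "khs.sBr": (0, 2, "int"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration shared by the generators."""

    n: int = 100
    seed: int = 0
    noise_sd: float = 0.0
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    correlation: float | None = None  # pairwise latent Gaussian correlation

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")


def _uniform_via_copula(
    rng: np.random.Generator, n: int, k: int, correlation: float | None
) -> np.ndarray:
    """n x k uniforms, optionally with a shared Gaussian-copula pairwise
    correlation."""
    if not correlation:
        return rng.random((n, k))
    from scipy.stats import norm

    C = np.full((k, k), float(correlation))
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C)
    zmat = rng.standard_normal((n, k)) @ L.T
    return norm.cdf(zmat)


def gen_abraham_compounds(config: GeneratorConfig) -> pd.DataFrame:
    """Synthetic compound table with Abraham descriptors [E, S, A, B, V].

    Values are uniform within per-descriptor ranges (defaults
    :data:`ABRAHAM_RANGES`), optionally correlated through a Gaussian
    copula.  Row index ``c0001, c0002, ...`` gives unique compound keys.
    """
    ranges = {**ABRAHAM_RANGES, **dict(config.ranges)}
    cols = list(ABRAHAM_RANGES)
    rng = np.random.default_rng(config.seed)
    U = _uniform_via_copula(rng, config.n, len(cols), config.correlation)
    data = {
        c: ranges[c][0] + U[:, i] * (ranges[c][1] - ranges[c][0])
        for i, c in enumerate(cols)
    }
    idx = pd.Index([f"c{i + 1:04d}" for i in range(config.n)], name="key")
    return pd.DataFrame(data, index=idx)


def _sample_descriptor(
    rng: np.random.Generator, name: str, n: int,
    ranges: Mapping[str, tuple[float, float]],
) -> np.ndarray:
    if name in ranges:
        lo, hi = ranges[name]
        return rng.uniform(lo, hi, size=n)
    spec = DESCRIPTOR_RANGES.get(name)
    if spec is None:
        return rng.uniform(0.0, 1.0, size=n)
    if len(spec) == 3:
        lo, hi, _ = spec
        return rng.integers(lo, hi + 1, size=n).astype(float)
    lo, hi = spec
    return rng.uniform(lo, hi, size=n)


def gen_table_from_model(
    model: LinearModel,
    config: GeneratorConfig,
    n_decoys: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Descriptor table plus response generated from a linear model.

    Columns are sampled independently: one per model term (realistic
    per-descriptor ranges) and ``n_decoys`` uniform decoy columns named
    ``decoy_01, ...`` that carry no signal.  The response is the model
    evaluated on its own columns plus Gaussian noise of sd
    ``config.noise_sd``; at ``noise_sd=0`` ordinary least squares on the
    true columns recovers the generating coefficients exactly.
    """
    rng = np.random.default_rng(config.seed)
    data = {}
    for name, _coef in model.terms:
        data[name] = _sample_descriptor(rng, name, config.n, config.ranges)
    for d in range(n_decoys):
        data[f"decoy_{d + 1:02d}"] = rng.uniform(0.0, 1.0, size=config.n)
    idx = pd.Index([f"c{i + 1:04d}" for i in range(config.n)], name="key")
    table = pd.DataFrame(data, index=idx)
    response = np.full(config.n, model.intercept)
    for name, coef in model.terms:
        response = response + coef * table[name].to_numpy()
    if config.noise_sd > 0:
        response = response + rng.normal(0.0, config.noise_sd, size=config.n)
    return table, pd.Series(response, index=idx, name="log_k")


def gen_pmf(
    kind: str,
    config: GeneratorConfig,
    *,
    depth: float = 10.0,
    well_width: float = 1.0,
    length: float = 2.0,
    n_points: int = 201,
    temperature: float = 310.0,
) -> tuple[PMFProfile, dict[str, float]]:
    """Synthetic PMF profile with known ground truth.

    kind
        ``flat``: w = 0 everywhere; truth k = length.
        ``square_well``: w = -depth for z <= well_width, 0 beyond; truth
        k = well_width * exp(beta*depth) + (length - well_width).
        ``smooth_well``: a smooth attractive well of the given depth and
        width reaching a flat plateau; truth records the constructed
        plateau onset, and k by dense quadrature.

    Gaussian noise of sd ``config.noise_sd`` (kJ/mol) is added to w.
    Returns ``(profile, truth)`` with truth keys ``k``, ``log10_k`` and
    ``cutoff``.
    """
    rng = np.random.default_rng(config.seed)
    z = np.linspace(0.0, length, n_points)
    beta = 1.0 / (8.31446261815324e-3 * temperature)
    if kind == "flat":
        w = np.zeros_like(z)
        k_true, c_true = length, length
    elif kind == "square_well":
        w = np.where(z <= well_width, -depth, 0.0)
        k_true = well_width * np.exp(beta * depth) + (length - well_width)
        c_true = length
    elif kind == "smooth_well":
        # parabolic attractive well climbing to the bulk plateau at
        # well_width; the junction keeps a finite slope so the plateau
        # onset is well defined
        def shape(zz):
            return np.where(zz < well_width, -depth * (1.0 - (zz / well_width) ** 2), 0.0)

        w = shape(z)
        zf = np.linspace(0.0, length, 200_001)
        k_true = float(np.trapezoid(np.exp(-beta * shape(zf)), zf))
        c_true = well_width
    else:
        raise ValueError(f"unknown PMF kind {kind!r}")
    if config.noise_sd > 0:
        w = w + rng.normal(0.0, config.noise_sd, size=len(z))
    profile = PMFProfile(z, w, temperature)
    truth = {"k": float(k_true), "log10_k": float(np.log10(k_true)), "cutoff": float(c_true)}
    return profile, truth
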