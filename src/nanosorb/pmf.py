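"""Adsorption affinity from a potential of mean force (PMF).

A constrained-MD simulation yields the free-energy profile w(z) of a
molecule as a function of its distance z from a nanomaterial surface.  The
adsorption constant follows by integrating the Boltzmann factor of the
profile over the adsorbed region,

    k = integral_0^c exp(-beta * w(z)) dz,      beta = 1/(k_B T),

where the cutoff c is the onset of the bulk plateau of the profile.  The
usual material-dependent prefactor is omitted (it would have to be measured
and cancels in within-material rankings), so k carries units of length
(nm).  w is in kJ/mol, hence k_B is the molar gas constant in kJ/(mol K);
the default temperature is 310 K (physiological).  Before integration the
profile is shifted so the plateau mean is zero -- with the prefactor
omitted, an absolute offset of w is a pure multiplicative constant on k,
and anchoring the bulk at zero standardizes comparisons between profiles.

log k is reported base-10, matching the QSAR models' convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GAS_CONSTANT_KJ",
    "PMFProfile",
    "AffinityResult",
    "read_pmf",
    "logk_from_pmf",
    "detect_plateau",
    "compare_md_qsar",
]

#: Molar gas constant in kJ/(mol K).
GAS_CONSTANT_KJ = 8.31446261815324e-3


@dataclass(frozen=True)
class PMFProfile:
    """A free-energy profile w(z): distances z (nm, strictly increasing),
    free energies w (kJ/mol), and the simulation temperature (K)."""

    z: np.ndarray
    w: np.ndarray
    temperature: float = 310.0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "w", w)
        if z.shape != w.shape or z.ndim != 1:
            raise ValueError("z and w must be equal-length 1-D arrays")
        if len(z) < 4:
            raise ValueError("a PMF profile needs at least 4 points")
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(w))):
            raise ValueError("PMF values must be finite")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        """1/(k_B T) in mol/kJ."""
        return 1.0 / (GAS_CONSTANT_KJ * self.temperature)


@dataclass(frozen=True)
class AffinityResult:
    """Adsorption affinity from one PMF: k (nm, prefactor omitted), its
    base-10 logarithm, and the cutoff used."""

    k: float
    log10_k: float
    cutoff: float


def read_pmf(
    path: str | Path | io.TextIOBase, temperature: float = 310.0
) -> PMFProfile:
    """Read a two-column (z [nm], w [kJ/mol]) text profile.

    Whitespace- or comma-separated; lines starting with '#' and a single
    optional non-numeric header line are skipped.
    """
    text = path.read() if hasattr(path, "read") else Path(path).read_text()
    z_vals, w_vals = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            zi, wi = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if lineno == 1 or not z_vals:  # tolerate one header line
                continue
            raise ValueError(f"cannot parse PMF line {lineno}: {line!r}")
        z_vals.append(zi)
        w_vals.append(wi)
    return PMFProfile(np.array(z_vals), np.array(w_vals), temperature)


def logk_from_pmf(
    profile: PMFProfile, cutoff: float, *, shift_to_plateau: bool = True
) -> AffinityResult:
    """Integrate the Boltzmann factor of the PMF up to ``cutoff``.

    Composite trapezoid on exp(-beta w(z)) over [min(z), cutoff], evaluated
    in log-sum-exp form so deep attractive wells (w << 0) cannot overflow.
    With ``shift_to_plateau`` the profile is first shifted so the mean of
    w at z >= cutoff (or of the last few points when the cutoff is the grid
    end) is zero.
    """
    z, w = profile.z, profile.w.copy()
    if not (z[0] < cutoff <= z[-1] + 1e-12):
        raise ValueError(
            f"cutoff {cutoff} outside profile range ({z[0]}, {z[-1]}]"
        )
    if shift_to_plateau:
        tail = w[z >= cutoff - 1e-12]
        if len(tail) == 0:
            tail = w[-4:]
        w = w - tail.mean()

    mask = z <= cutoff + 1e-12
    zi, wi = z[mask], w[mask]
    if abs(zi[-1] - cutoff) > 1e-12:  # land exactly on the cutoff
        w_c = float(np.interp(cutoff, z, w))
        zi = np.append(zi, cutoff)
        wi = np.append(wi, w_c)

    # trapezoid in log space: k = sum_j (dz_j/2) (e^{-b w_j} + e^{-b w_{j+1}})
    b = profile.beta
    log_terms = np.concatenate([-b * wi[:-1], -b * wi[1:]])
    log_weights = np.log(np.concatenate([np.diff(zi) / 2.0] * 2))
    log_k = float(logsumexp(log_terms + log_weights))
    log10_k = log_k / np.log(10.0)
    # k itself may exceed float range for very deep wells; log10_k is the
    # quantity of record
    k = float(np.exp(log_k)) if log_k < 700.0 else float("inf")
    return AffinityResult(k=k, log10_k=log10_k, cutoff=float(cutoff))


def detect_plateau(
    profile: PMFProfile,
    window: int = 10,
    slope_tol: float = 0.5,
    value_tol: float = 1.0,
) -> float:
    """Onset of the bulk plateau of a PMF, used as the integration cutoff.

    The bulk level is the mean of the last ``window`` points.  Scanning
    outward from the global minimum of w, the plateau onset is the smallest
    z whose forward window fits a line with |slope| <= ``slope_tol``
    (kJ/mol per nm) and whose value is within ``value_tol`` (kJ/mol) of the
    bulk level.  Raises when no such point exists (profile too short or
    still rising at its end).
    """
    z, w = profile.z, profile.w
    if len(z) < window + 1:
        raise ValueError("profile too short for the requested window")
    w_bulk = float(w[-window:].mean())
    start = int(np.argmin(w))
    for i in range(start, len(z) - window + 1):
        zw, ww = z[i : i + window], w[i : i + window]
        slope = float(np.polyfit(zw, ww, 1)[0])
        if abs(slope) <= slope_tol and abs(w[i] - w_bulk) <= value_tol:
            return float(z[i])
    raise ValueError(
        "no plateau found beyond the PMF minimum; extend the profile to bulk "
        "separation or relax the tolerances"
    )


def compare_md_qsar(
    logk_md: dict[str, float],
    logk_qsar: dict[str, float],
    exclude: set[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation between MD-derived and QSAR-predicted log k.

    Only molecules present in both mappings are used; ``exclude`` removes
    ids before correlating (e.g. a charged outlier).  Needs >= 3 shared
    molecules after exclusion.
    """
    from scipy import stats

    exclude = exclude or set()
    shared = sorted((set(logk_md) & set(logk_qsar)) - exclude)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared molecules after exclusion")
    x = np.array([logk_md[m] for m in shared], dtype=float)
    y = np.array([logk_qsar[m] for m in shared], dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
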