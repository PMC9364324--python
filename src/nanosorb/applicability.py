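"""Applicability-domain (AD) constructions for the log-k models.

Three complementary constructions are provided.

Insubria graphs
    For compounds without measured responses: prediction vs leverage.  A
    compound is inside the AD when its leverage is *smaller than* the
    critical hat value h* = 3(N+1)/n and (optionally) its prediction lies
    within mean +/- 3 sd of the predictions for a reference set of probe
    compounds.  Three modes: ``both_thresholds``, ``hat_only``, ``none``.

Williams plots
    For training/validation compounds: standardized cross-validated
    residual vs leverage.  A compound is outside the AD when |residual| > 3
    or when its leverage *exceeds* h*.  Note the deliberate boundary
    asymmetry with the Insubria rule (h = h* is out for Insubria, in for
    Williams); both follow the respective conventions literally.

Ordination centroid
    A distance-based AD: pairwise Mahalanobis distances between compounds
    (pooled covariance of the full set), embedded in two dimensions by
    non-metric multidimensional scaling; a compound is inside when its
    distance to the centroid of the probe compounds is at most the largest
    probe-centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

__all__ = [
    "ADReport",
    "leverages",
    "critical_hat",
    "insubria_filter",
    "williams_flags",
    "ordination_centroid_ad",
]

InsubriaMode = Literal["both_thresholds", "hat_only", "none"]


@dataclass(frozen=True)
class ADReport:
    """Per-compound applicability-domain assessment."""

    leverage: np.ndarray
    h_star: float
    mode: InsubriaMode
    in_domain: np.ndarray  # boolean, aligned with leverage
    pred_low: float | None = None
    pred_high: float | None = None

    @property
    def n_in(self) -> int:
        return int(self.in_domain.sum())

    def to_frame(self, predictions: Sequence[float] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"h": self.leverage, "in_domain": self.in_domain})
        if predictions is not None:
            df.insert(1, "pred", np.asarray(predictions, float))
        return df


def leverages(design: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Diagonal of the hat (projection) matrix X (X'X)^-1 X'.

    ``design`` must already include its intercept column if the model has
    one.  Requires n > p is not enforced (n == p gives all ones), but rank
    deficiency raises.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    # h_ii via the thin QR: rows of Q have squared norms equal to leverage
    Q, _ = np.linalg.qr(X)
    return np.sum(Q * Q, axis=1)


def critical_hat(n_descriptors: int, n_reference: int) -> float:
    """Critical hat threshold h* = 3 (N + 1) / n.

    ``n_descriptors`` is the number of descriptors N in the model and
    ``n_reference`` the size n of the reference (probe or training) set.
    """
    if n_reference <= 0:
        raise ValueError("reference-set size must be positive")
    return 3.0 * (n_descriptors + 1) / n_reference


def insubria_filter(
    hats: Sequence[float],
    predictions: Sequence[float],
    h_star: float,
    probe_predictions: Sequence[float] | None = None,
    mode: InsubriaMode = "both_thresholds",
) -> ADReport:
    """Insubria-graph AD flags for compounds without measured responses.

    In ``both_thresholds`` mode a compound is in-domain iff its leverage is
    strictly below ``h_star`` and its prediction lies within mean +/- 3 sd
    (sample sd, n-1) of ``probe_predictions``; ``hat_only`` drops the
    prediction band; ``none`` applies no thresholds at all.
    """
    h = np.asarray(hats, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    if h.shape != pred.shape:
        raise ValueError("hats and predictions must align")
    if mode not in ("both_thresholds", "hat_only", "none"):
        raise ValueError(f"unknown Insubria mode {mode!r}")
    low = high = None
    flags = np.ones(h.shape, dtype=bool)
    if mode != "none":
        flags &= h < h_star  # h == h* is outside: "smaller than the critical hat"
    if mode == "both_thresholds":
        if probe_predictions is None or len(probe_predictions) == 0:
            raise ValueError("both_thresholds mode needs probe predictions")
        probes = np.asarray(probe_predictions, dtype=float)
        sd = float(probes.std(ddof=1)) if len(probes) > 1 else 0.0
        low = float(probes.mean() - 3.0 * sd)
        high = float(probes.mean() + 3.0 * sd)
        flags &= (pred >= low) & (pred <= high)
    return ADReport(
        leverage=h, h_star=h_star, mode=mode, in_domain=flags,
        pred_low=low, pred_high=high,
    )


def williams_flags(
    standardized_cv_residuals: Sequence[float],
    hats: Sequence[float],
    h_star: float,
    residual_limit: float = 3.0,
) -> np.ndarray:
    """Williams-plot AD flags: in-domain iff |residual| <= 3 and h <= h*."""
    res = np.asarray(standardized_cv_residuals, dtype=float)
    h = np.asarray(hats, dtype=float)
    if res.shape != h.shape:
        raise ValueError("residuals and hats must align")
    return (np.abs(res) <= residual_limit) & (h <= h_star)


def loo_standardized_residuals(
    design: np.ndarray | pd.DataFrame, response: Sequence[float]
) -> np.ndarray:
    """Leave-one-out (externally studentized-style) standardized residuals.

    Computed from a single fit via the hat identity: the deleted residual
    is e_i / (1 - h_ii), standardized by the residual standard error and
    sqrt(1 - h_ii), i.e. r_i = e_i / (s * sqrt(1 - h_ii)).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ coef
    h = leverages(X)
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ValueError("need more rows than design columns")
    s = np.sqrt(np.sum(e**2) / dof)
    return e / (s * np.sqrt(np.clip(1.0 - h, 1e-12, None)))


def mahalanobis_distances(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Mahalanobis distances with the pooled covariance of the
    full compound set (condensed form upgraded to a square matrix)."""
    X = np.asarray(matrix, dtype=float)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    # ridge for singular covariance (duplicated columns, tiny n)
    try:
        VI = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        VI = np.linalg.pinv(cov)
    return squareform(pdist(X, metric="mahalanobis", VI=VI))


def ordination_centroid_ad(
    descriptor_matrix: np.ndarray | pd.DataFrame,
    probe_idx: Sequence[int],
    *,
    seed: int = 0,
    n_restarts: int = 20,
    max_stress: float = 0.30,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Distance-based AD via a 2-D non-metric MDS embedding.

    Pairwise Mahalanobis distances of all compounds are embedded in two
    dimensions by seeded NMDS (``n_restarts`` random initializations, the
    lowest-stress solution kept).  A compound is in-domain when its
    distance to the centroid of the probe compounds is at most the largest
    probe-centroid distance.

    Returns ``(flags, embedding, stress)``.  Raises if the best embedding's
    normalized stress exceeds ``max_stress`` (non-convergence).
    """
    X = np.asarray(descriptor_matrix, dtype=float)
    probe_idx = np.asarray(probe_idx, dtype=int)
    if len(probe_idx) < 3:
        raise ValueError("need at least 3 probe compounds")
    D = mahalanobis_distances(X)
    if not np.any(D > 1e-12):
        # all compounds coincide: degenerate but well defined, everything in
        return np.ones(len(X), dtype=bool), np.zeros((len(X), 2)), 0.0
    mds = MDS(
        n_components=2,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=300,
    )
    emb = mds.fit_transform(D)
    stress = float(mds.stress_)
    if not np.isfinite(stress) or stress > max_stress:
        raise RuntimeError(
            f"non-metric MDS did not converge (normalized stress {stress:.3f})"
        )
    centroid = emb[probe_idx].mean(axis=0)
    dist = np.linalg.norm(emb - centroid, axis=1)
    radius = float(dist[probe_idx].max())
    return dist <= radius, emb, stress
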