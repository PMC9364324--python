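"""Statistical comparison of nanomaterials on predicted log k matrices.

Workflow: predicted log k values (nanomaterials as items, compounds as
features) are shifted by the global minimum to make them non-negative,
turned into a Bray-Curtis dissimilarity matrix, and related to the
nanodescriptors by distance-based redundancy analysis (dbRDA) with
permutation tests of each predictor's marginal effect.  Per-category group
comparisons use the Kruskal-Wallis rank-sum test with Dunn's post-hoc test
and Holm-adjusted p-values; monotone associations use Spearman's rank
correlation.

dbRDA follows the McArdle-Anderson construction: the squared
dissimilarities are Gower-centered (G = -1/2 J D^2 J), sums of squares are
traces of projections of G onto the predictor space, and negative
eigenvalues of G are retained in the total sum of squares.  The marginal
(type-III-like) F for a predictor compares the sum of squares it explains
given all the others to the residual mean square of the full model;
p-values come from freely permuting the rows/columns of G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarginalTestResult",
    "min_shift",
    "bray_curtis",
    "dbrda_marginal",
    "kruskal_dunn",
    "spearman",
]


@dataclass(frozen=True)
class MarginalTestResult:
    predictor: str
    F: float
    df_num: int
    df_den: int
    p_value: float
    n_permutations: int


def min_shift(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Shift all values by the global minimum so the smallest becomes 0.

    Leaves an already non-negative matrix with minimum 0 untouched, so the
    operation is idempotent.
    """
    values = np.asarray(matrix, dtype=float)
    if values.size == 0:
        return matrix
    if not np.all(np.isfinite(values)):
        raise ValueError("log k matrix contains non-finite values")
    shifted = matrix - values.min()
    return shifted


def bray_curtis(rows: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between the rows of a non-negative matrix.

    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i).  A pair of all-zero rows has
    no defined dissimilarity and raises.
    """
    X = np.asarray(rows, dtype=float)
    if np.any(X < 0):
        raise ValueError("Bray-Curtis needs non-negative values; min_shift first")
    zero_rows = np.where(~X.any(axis=1))[0]
    if len(zero_rows) > 1:
        raise ValueError(
            f"Bray-Curtis undefined for all-zero row pairs (rows {zero_rows.tolist()})"
        )
    D = squareform(pdist(X, metric="braycurtis"))
    ids = rows.index if isinstance(rows, pd.DataFrame) else pd.RangeIndex(len(X))
    return pd.DataFrame(D, index=ids, columns=ids)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def dbrda_marginal(
    dissim: pd.DataFrame | np.ndarray,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> list[MarginalTestResult]:
    """Marginal permutation F-tests of each predictor in dbRDA.

    For predictor j with full-model hat matrix H and reduced hat matrix
    H_(-j):  F_j = [tr(H G) - tr(H_(-j) G)] / [tr((I - H) G) / (n - p - 1)]
    with G the Gower-centered matrix.  The permutation p-value relabels the
    items (jointly permuting rows and columns of G) ``n_perm`` times and
    counts permuted F >= observed, so p >= 1/(n_perm + 1).
    """
    D = np.asarray(dissim, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if len(predictors) != n:
        raise ValueError("predictor rows must match dissimilarity items")
    names = list(predictors.columns)
    p = len(names)
    if n <= p + 1:
        raise ValueError("need more items than predictors + 1")
    Xp = predictors.to_numpy(dtype=float)
    Xp = Xp - Xp.mean(axis=0)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xp])) < p + 1:
        corr = np.corrcoef(Xp, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"collinear predictors: {pairs or names}")

    G = _gower_center(D)
    ones = np.ones((n, 1))
    H_full = _hat(np.column_stack([ones, Xp]))
    resid_proj = np.eye(n) - H_full
    df_den = n - p - 1

    # tr(H G) for symmetric idempotent H equals the elementwise sum H * G
    ss_full = float(np.sum(H_full * G))
    ss_res = float(np.sum(resid_proj * G))
    H_reduced = {
        j: _hat(np.column_stack([ones, np.delete(Xp, j, axis=1)]))
        for j in range(p)
    }
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]

    results = []
    for j, name in enumerate(names):
        Hr = H_reduced[j]
        ss_j = ss_full - float(np.sum(Hr * G))
        F_obs = (ss_j / 1.0) / (ss_res / df_den)
        exceed = 0
        for perm in perms:
            Gp = G[np.ix_(perm, perm)]
            ss_full_p = float(np.sum(H_full * Gp))
            ss_j_p = ss_full_p - float(np.sum(Hr * Gp))
            ss_res_p = float(np.sum(resid_proj * Gp))
            F_p = (ss_j_p / 1.0) / (ss_res_p / df_den)
            if F_p >= F_obs - 1e-12:
                exceed += 1
        p_val = (exceed + 1) / (n_perm + 1)
        results.append(
            MarginalTestResult(name, float(F_obs), 1, df_den, float(p_val), n_perm)
        )
    return results


def kruskal_dunn(
    values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Kruskal-Wallis test plus Dunn's pairwise post-hoc with Holm p-values.

    Returns ``((H, p_kw), pairs)`` where ``pairs`` has one row per group
    pair with Dunn z, the raw two-sided p and the Holm-adjusted p.  Dunn's
    z uses rank sums with the tie correction
    sigma^2 = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [v[g == lab] for lab in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one value")
    H, p_kw = stats.kruskal(*samples)

    N = len(v)
    ranks = stats.rankdata(v)  # average ranks on ties
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    mean_ranks = {lab: ranks[g == lab].mean() for lab in labels}
    sizes = {lab: int((g == lab).sum()) for lab in labels}

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            sigma = np.sqrt(
                (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = 0.0 if sigma == 0 else (mean_ranks[a] - mean_ranks[b]) / sigma
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p_raw, 1.0)})
    pairs = pd.DataFrame(rows)
    pairs["p_holm"] = multipletests(pairs["p_raw"], method="holm")[1]
    return (float(H), float(p_kw)), pairs


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if stats.rankdata(x).std() == 0 or stats.rankdata(y).std() == 0:
        raise ValueError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
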