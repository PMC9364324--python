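"""Secondary descriptor-based QSAR models for log k.

The BSAI relationship needs experimentally determined Abraham solute
descriptors, which are unavailable for most metabolites of interest.  The
workaround is a second tier of models: ordinary multiple linear regressions
of BSAI-predicted log k on cheaply computable molecular descriptors, built
by forward selection with a variance-inflation-factor guard.  Once trained
(or loaded from the packaged frozen registry of 19 nanomaterial models,
each with exactly five descriptor terms), these models predict log k from
molecular structure alone.

Training protocol
-----------------
* the compounds with the global minimum and maximum response are forced
  into the training set; the rest are binned into response quantiles and
  each bin is split randomly at the chosen train fraction (default 0.8);
* forward selection adds, at each of at most five steps, the candidate
  descriptor with the largest gain in R^2 among candidates whose inclusion
  keeps every variance-inflation factor of the working design <= 2;
* the final model is refit by ordinary least squares on the selected
  columns, and adjusted R^2 is reported for training and validation sets.

Ties in R^2 gain are broken lexicographically by descriptor name, and all
randomness is seed-controlled, so training is fully reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import require_columns

__all__ = [
    "LinearModel",
    "SplitSpec",
    "SelectionStep",
    "TrainResult",
    "partition_dataset",
    "vif",
    "forward_select",
    "adjusted_r2",
    "evaluate_model",
    "load_frozen_models",
]


@dataclass(frozen=True)
class LinearModel:
    """One linear log-k model: intercept plus named descriptor terms."""

    enm_id: str
    intercept: float
    terms: tuple[tuple[str, float], ...]
    n_train: int | None = None
    split_ratio: float | None = None
    seed: int | None = None

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def __post_init__(self) -> None:
        names = self.descriptor_names
        if len(set(names)) != len(names):
            raise ValueError(f"model {self.enm_id!r} repeats a descriptor")
        vals = [self.intercept, *(c for _, c in self.terms)]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"model {self.enm_id!r} has non-finite coefficients")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split specification."""

    ratio: float = 0.8
    seed: int = 0
    n_quantiles: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("train fraction must be in (0, 1)")
        if self.n_quantiles < 1:
            raise ValueError("n_quantiles must be >= 1")


@dataclass(frozen=True)
class SelectionStep:
    descriptor: str
    r2: float
    max_vif: float


@dataclass(frozen=True)
class TrainResult:
    model: LinearModel
    r2_train_adj: float
    r2_validate_adj: float | None
    trace: tuple[SelectionStep, ...] = field(default_factory=tuple)


def partition_dataset(
    response: pd.Series, spec: SplitSpec
) -> tuple[list, list]:
    """Split compound ids into (train, validate) on the response.

    The global extremes are always trained on, so predictions never require
    extrapolating beyond the response range; the remaining compounds are
    binned into ``spec.n_quantiles`` response quantiles and each bin is
    split randomly at ``spec.ratio``.
    """
    if response.isna().any() or not np.all(np.isfinite(response.to_numpy(float))):
        raise ValueError("responses must be finite")
    ids = list(response.index)
    if len(ids) != len(set(ids)):
        raise ValueError("compound ids must be unique")
    forced = {response.idxmin(), response.idxmax()}
    rest = response.drop(index=list(forced))
    if rest.empty:
        if len(ids) < 10:
            warnings.warn("too few compounds: validation set is empty", stacklevel=2)
        return list(forced), []

    n_bins = min(spec.n_quantiles, max(1, len(rest) // 2))
    if n_bins < spec.n_quantiles:
        warnings.warn(
            f"too few compounds for {spec.n_quantiles} quantile bins; using {n_bins}",
            stacklevel=2,
        )
    bins = pd.qcut(rest.rank(method="first"), q=n_bins, labels=False)
    rng = np.random.default_rng(spec.seed)
    train, validate = list(forced), []
    for b in range(n_bins):
        members = list(rest.index[bins == b])
        rng.shuffle(members)
        n_train = int(round(spec.ratio * len(members)))
        train.extend(members[:n_train])
        validate.extend(members[n_train:])
    if not validate:
        warnings.warn("validation set is empty", stacklevel=2)
    return train, validate


def vif(design: pd.DataFrame, column: str) -> float:
    """Variance-inflation factor of ``column`` within ``design``.

    1/(1 - R^2) of the column regressed (with intercept) on all the other
    columns.  Perfect collinearity returns ``inf`` rather than raising.
    """
    others = [c for c in design.columns if c != column]
    if not others:
        return 1.0
    y = design[column].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(design)), design[others].to_numpy(float)]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return np.inf
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coef incl. intercept, R^2)."""
    Xi = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return coef, r2


def forward_select(
    table: pd.DataFrame,
    response: Sequence[float] | pd.Series,
    *,
    enm_id: str = "model",
    max_terms: int = 5,
    vif_max: float = 2.0,
    validate_table: pd.DataFrame | None = None,
    validate_response: Sequence[float] | pd.Series | None = None,
) -> TrainResult:
    """Build a linear model by forward selection under a VIF constraint.

    At each step the candidate column with the largest R^2 of the working
    OLS fit is added, restricted to candidates whose inclusion keeps every
    VIF of the included set <= ``vif_max``; selection stops at
    ``max_terms`` terms or when no admissible candidate improves the fit.
    Ties are broken lexicographically by descriptor name.
    """
    y = np.asarray(response, dtype=float)
    if len(table) != len(y):
        raise ValueError("table rows and response length differ")
    if len(y) < max_terms + 2:
        raise ValueError("too few rows to select that many descriptors")
    selected: list[str] = []
    trace: list[SelectionStep] = []
    r2_current = 0.0
    y_const = float(np.sum((y - y.mean()) ** 2)) == 0.0
    candidates = sorted(table.columns)

    while len(selected) < max_terms and not y_const:
        best: tuple[float, str, float] | None = None  # (r2, name, max_vif)
        for name in candidates:
            if name in selected:
                continue
            cols = selected + [name]
            design = table[cols]
            max_v = max(vif(design, c) for c in cols) if len(cols) > 1 else 1.0
            if max_v > vif_max:
                continue
            _, r2 = _ols_r2(design.to_numpy(float), y)
            # strict > keeps the lexicographically first name on exact ties
            if best is None or r2 > best[0] + 1e-12:
                best = (r2, name, max_v)
        if best is None or best[0] <= r2_current + 1e-12:
            break
        r2_current, chosen, max_v = best
        selected.append(chosen)
        trace.append(SelectionStep(chosen, r2_current, max_v))

    if not selected and not y_const:
        # a constant response legitimately yields an intercept-only model;
        # anything else failing at step one signals an unusable design
        raise ValueError("no admissible descriptor improves the fit")

    coef, r2 = _ols_r2(table[selected].to_numpy(float), y) if selected else (
        np.array([y.mean()]), 1.0 if y_const else 0.0,
    )
    model = LinearModel(
        enm_id=enm_id,
        intercept=float(coef[0]),
        terms=tuple(zip(selected, (float(c) for c in coef[1:]))),
        n_train=len(y),
    )
    p = len(selected)
    r2_tr_adj = adjusted_r2_from_r2(r2, n=len(y), p=p) if len(y) > p + 1 else r2
    r2_val_adj = None
    if validate_table is not None and validate_response is not None and len(validate_table):
        pred = evaluate_model(model, validate_table)
        r2_val_adj = adjusted_r2(pred, np.asarray(validate_response, float), p=p)
    return TrainResult(model, r2_tr_adj, r2_val_adj, tuple(trace))


def adjusted_r2_from_r2(r2: float, *, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError("need n > p + 1 for adjusted R^2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def adjusted_r2(predicted: Sequence[float], observed: Sequence[float], p: int) -> float:
    """Adjusted coefficient of determination of predictions against
    observations, penalised for ``p`` predictors."""
    yhat = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance")
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return adjusted_r2_from_r2(r2, n=len(y), p=p)


def evaluate_model(model: LinearModel, table: pd.DataFrame) -> pd.Series:
    """Per-compound log k: intercept + sum of coefficient * descriptor."""
    require_columns(table, model.descriptor_names)
    values = np.full(len(table), model.intercept, dtype=float)
    for name, coef in model.terms:
        values = values + coef * table[name].to_numpy(float)
    return pd.Series(values, index=table.index, name=model.enm_id)


def load_frozen_models(path: str | Path | None = None) -> dict[str, LinearModel]:
    """Load the packaged registry of 19 frozen five-term models.

    Returns a mapping of nanomaterial id to :class:`LinearModel`.  A custom
    registry ``path`` with the same JSON layout may be supplied.
    """
    if path is None:
        raw = (
            resources.files("nanosorb").joinpath("data/frozen_models.json").read_text()
        )
    else:
        raw = Path(path).read_text()
    data = json.loads(raw)
    models = {}
    for entry in data["models"]:
        model = LinearModel(
            enm_id=entry["enm_id"],
            intercept=float(entry["intercept"]),
            terms=tuple((str(n), float(c)) for n, c in entry["terms"]),
        )
        if len(model.terms) != 5:
            raise ValueError(f"frozen model {model.enm_id!r} must have 5 terms")
        models[model.enm_id] = model
    if len(models) != int(data.get("n_models", len(models))):
        raise ValueError("frozen registry size does not match its manifest")
    return models
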