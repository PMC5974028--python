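"""Cross-validated accuracy of the niche growth model.

Ten-fold cross-validation, stratified by species so every species appears
in each training split, with the niche model refit from scratch on each
training set. Accuracy is summarized overall and per species by

    bias = mean(observed - predicted)      (positive = underestimation)
    RMSE = sqrt(mean((observed - predicted)^2))

computed from out-of-fold predictions only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth_model import (
    ConvergenceError,
    ThetaSpec,
    fit_niche_model,
    predict_heights_frame,
)

__all__ = ["ValidationReport", "bias", "rmse", "tenfold_cv"]


def bias(observed, predicted) -> float:
    """Mean of (observed - predicted), m. Positive means the model
    underestimates."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted lengths differ")
    if observed.size == 0:
        raise ValueError("empty input")
    return float(np.mean(observed - predicted))


def rmse(observed, predicted) -> float:
    """Root of the mean squared (observed - predicted), m."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted lengths differ")
    if observed.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


@dataclass
class ValidationReport:
    per_species: pd.DataFrame  # species, adaptive_class, n, bias, rmse
    overall_bias: float
    overall_rmse: float
    fold_assignment: np.ndarray  # fold id per input record
    residuals: np.ndarray  # observed - predicted, input order
    seed: int
    k: int
    failed_folds: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall_bias": self.overall_bias,
                "overall_rmse": self.overall_rmse,
                "k": self.k,
                "seed": self.seed,
                "failed_folds": self.failed_folds,
                "per_species": self.per_species.to_dict(orient="records"),
            },
            indent=2,
        )


def _stratified_folds(
    species: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold ids 0..k-1, balanced within each species; a rotating offset
    keeps overall fold sizes near-equal."""
    folds = np.empty(len(species), dtype=int)
    offset = 0
    for sp in pd.unique(species):
        idx = np.flatnonzero(species == sp)
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return folds


def tenfold_cv(
    data: pd.DataFrame, spec: ThetaSpec, k: int = 10, seed: int = 0
) -> ValidationReport:
    """k-fold cross-validation with per-fold refits.

    Records are shuffled (seeded) into k near-equal folds stratified by
    species; each fold is predicted by a niche model fit on the remaining
    folds. A fold whose fit fails to converge is flagged in
    ``failed_folds`` (its records get NaN predictions), never silently
    dropped.
    """
    n = len(data)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    rng = np.random.default_rng(seed)
    species = data["species"].to_numpy()
    folds = _stratified_folds(species, k, rng)

    predicted = np.full(n, np.nan)
    failed: list[int] = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        try:
            model = fit_niche_model(data.loc[train], spec)
        except ConvergenceError:
            failed.append(fold)
            continue
        predicted[test] = predict_heights_frame(model, data.loc[test])

    observed = data["height"].to_numpy(dtype=float)
    ok = ~np.isnan(predicted)
    residuals = observed - predicted

    rows = []
    frame = pd.DataFrame(
        {
            "species": species,
            "adaptive_class": (
                data["adaptive_class"].to_numpy()
                if "adaptive_class" in data.columns
                else np.repeat("unknown", n)
            ),
            "obs": observed,
            "pred": predicted,
        }
    )[ok]
    for sp, grp in frame.groupby("species", sort=True):
        rows.append(
            {
                "species": sp,
                "adaptive_class": grp["adaptive_class"].iloc[0],
                "n": len(grp),
                "bias": bias(grp["obs"], grp["pred"]),
                "rmse": rmse(grp["obs"], grp["pred"]),
            }
        )
    per_species = pd.DataFrame(rows)

    return ValidationReport(
        per_species=per_species,
        overall_bias=bias(observed[ok], predicted[ok]),
        overall_rmse=rmse(observed[ok], predicted[ok]),
        fold_assignment=folds,
        residuals=residuals,
        seed=seed,
        k=k,
        failed_folds=failed,
    )
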