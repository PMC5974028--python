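"""PLSR screening of a large climate-variable pool.

A single-response partial least squares regression (NIPALS, via
scikit-learn) reduces a pool of candidate climate variables — in the full
analysis, the ~218 annual/seasonal/monthly variables a climate downscaler
emits — to the handful that drive height growth potential. The number of
components is chosen by leave-one-out cross-validation: the smallest count
beyond which the root-mean-square error of prediction (RMSEP) stops
improving by more than a relative threshold (default 2%). Variables are
then selected by the magnitude of their loadings — correlations between
component scores and the original variables — on the retained components,
with an absolute-value cutoff of 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PLSRResult",
    "fit_plsr",
    "loo_rmsep",
    "select_variables",
    "gen_climate_pool",
]


@dataclass
class PLSRResult:
    n_components: int
    scores: np.ndarray  # n_obs x n_components
    loadings: pd.DataFrame  # variables x components, correlation scale
    rmsep_by_components: dict[int, float] = field(default_factory=dict)
    selected_variables: list[str] = field(default_factory=list)
    variable_names: list[str] = field(default_factory=list)


def _check_matrix(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    constant = X.columns[X.std(axis=0) == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    return X, y


def fit_plsr(X: pd.DataFrame, y, max_components: int = 5) -> PLSRResult:
    """Fit single-response PLSR with internally standardized variables.

    Loadings are reported as Pearson correlations between each original
    variable and each component's scores, which is the scale the 0.4
    selection cutoff applies to. Deterministic.
    """
    X, y = _check_matrix(X, y)
    max_components = min(max_components, X.shape[1], len(X) - 1)
    pls = PLSRegression(n_components=max_components, scale=True)
    pls.fit(X.to_numpy(dtype=float), y)
    scores = pls.x_scores_
    xs = (X - X.mean()) / X.std(ddof=1)
    load = np.empty((X.shape[1], max_components))
    for k in range(max_components):
        t = scores[:, k]
        tc = (t - t.mean())
        denom = np.sqrt(np.sum(tc**2))
        for j in range(X.shape[1]):
            xj = xs.iloc[:, j].to_numpy()
            load[j, k] = float(
                np.sum(tc * (xj - xj.mean()))
                / (denom * np.sqrt(np.sum((xj - xj.mean()) ** 2)))
            )
    loadings = pd.DataFrame(
        load,
        index=list(X.columns),
        columns=[f"comp{k + 1}" for k in range(max_components)],
    )
    return PLSRResult(
        n_components=max_components,
        scores=scores,
        loadings=loadings,
        variable_names=list(X.columns),
    )


def loo_rmsep(
    X: pd.DataFrame,
    y,
    max_components: int = 5,
    improvement_threshold: float = 0.02,
) -> tuple[dict[int, float], int]:
    """Leave-one-out RMSEP per component count, plus the selected count.

    Component count 0 is the mean-only predictor. The selected count is
    the smallest k such that adding component k+1 fails to reduce RMSEP
    by more than ``improvement_threshold`` of the mean-only RMSEP — the
    null scale, so the rule stays meaningful when RMSEP is near zero.
    """
    X, y = _check_matrix(X, y)
    n = len(y)
    if n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    if max_components >= n - 1:
        raise ValueError("max_components must be < n - 1")
    max_components = min(max_components, X.shape[1])

    Xa = X.to_numpy(dtype=float)
    press = np.zeros(max_components + 1)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = Xa[mask], y[mask]
        press[0] += (y[i] - ytr.mean()) ** 2
        for k in range(1, max_components + 1):
            pls = PLSRegression(n_components=k, scale=True)
            pls.fit(Xtr, ytr)
            pred = float(pls.predict(Xa[i : i + 1]).ravel()[0])
            press[k] += (y[i] - pred) ** 2
    rmsep = {k: float(np.sqrt(press[k] / n)) for k in range(max_components + 1)}

    scale = rmsep[0] if rmsep[0] > 0 else 1.0
    selected = max_components
    for k in range(max_components):
        if (rmsep[k] - rmsep[k + 1]) / scale <= improvement_threshold:
            selected = k
            break
    selected = max(selected, 1)  # keep at least one component
    return rmsep, selected


def select_variables(
    result: PLSRResult, cutoff: float = 0.4, components: int | str = "main"
) -> list[str]:
    """Variables whose absolute loading on any retained component is >=
    cutoff. ``components="main"`` retains the LOO-selected count stored in
    the result (falling back to all fitted components)."""
    if components == "main":
        ncomp = result.n_components
    else:
        ncomp = int(components)
    sub = result.loadings.iloc[:, :ncomp]
    mask = (sub.abs() >= cutoff).any(axis=1)
    selected = [v for v in result.loadings.index[mask]]
    result.selected_variables = selected
    return selected


def gen_climate_pool(
    n_obs: int = 200,
    n_vars: int = 218,
    n_informative: int = 3,
    driver_loading: float = 0.9,
    signal_sd: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Synthetic screening pool: ``n_vars`` standardized covariates of
    which the first ``n_informative`` drive the response through a shared
    latent factor (climate pools are collinear — e.g. the degree-day
    family all track temperature), with loading ``driver_loading`` on
    that factor. The remaining variables are independent noise.

    Returns (X, y, informative_names).
    """
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_obs)
    X = rng.standard_normal((n_obs, n_vars))
    lam = float(driver_loading)
    X[:, :n_informative] = (
        lam * latent[:, None]
        + np.sqrt(1 - lam**2) * X[:, :n_informative]
    )
    names = [f"cv{j + 1:03d}" for j in range(n_vars)]
    drivers = names[:n_informative]
    y = signal_sd * latent + rng.normal(0, noise_sd, n_obs)
    return pd.DataFrame(X, columns=names), y, drivers
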