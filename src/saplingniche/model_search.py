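"""Log-linearized all-subsets screening of climate variables.

The exponential trajectory h = theta1*(e^{theta2*age} - 1) is vertically
shifted by one theta1 unit and log-transformed, giving the linear form

    ln(h + theta1) = ln(theta1) + theta2 * age.

With a single pooled theta1 estimate as the shift, each candidate climate
subset is screened by ordinary least squares on the linearized design:
the subset's (scaled) variables enter both the intercept block (acting on
ln theta1) and an age-interaction block (acting on theta2), alongside age
itself. All 2^12 = 4,096 subsets of the 12 modelling variables are ranked
by AIC; ties break toward smaller subsets, then lexicographically. The
search is a screening device: the winning specifications are refit with
the full nonlinear :func:`saplingniche.growth_model.fit_niche_model`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import scale_climate
from .growth_model import pooled_exponential_start

__all__ = [
    "SubsetModelResult",
    "pooled_exponential_fit",
    "loglinearize",
    "enumerate_subsets",
    "aic",
    "run_all_subsets",
    "variable_frequency",
    "delta_aic_improves",
    "results_to_frame",
]


@dataclass
class SubsetModelResult:
    """OLS screening fit for one climate-variable subset."""

    subset: tuple[str, ...]
    coefficients: np.ndarray
    aic: float
    rmse: float  # log-scale units
    r2: float
    rank: int = 0
    rank_deficient: bool = False


def pooled_exponential_fit(data: pd.DataFrame):
    """Climate-free exponential fit h = t1*(e^{t2*age} - 1).

    Returns (theta1_hat, theta2_hat, r2). Needs >= 3 distinct ages.
    """
    ages = np.asarray(data["age"], dtype=float)
    y = np.asarray(data["height"], dtype=float)
    t1, t2 = pooled_exponential_start(ages, y)
    fitted = t1 * np.expm1(t2 * ages)
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return t1, t2, r2


def loglinearize(data: pd.DataFrame, theta1_hat: float) -> pd.DataFrame:
    """Shift heights up by theta1_hat and log-transform.

    Returns a table with ``log_shifted_height``, ``age`` and the scaled
    climate columns; design matrices for individual subsets are assembled
    by :func:`run_all_subsets`. Rejects non-positive shifted responses,
    reporting the offending record ids.
    """
    if theta1_hat <= 0:
        raise ValueError(f"theta1_hat must be > 0, got {theta1_hat}")
    shifted = np.asarray(data["height"], dtype=float) + theta1_hat
    if (shifted <= 0).any():
        bad = data.loc[shifted <= 0]
        ids = (
            bad["pop_id"].tolist()
            if "pop_id" in bad.columns
            else bad.index.tolist()
        )
        raise ValueError(
            f"non-positive shifted response for record(s) {ids[:10]}"
        )
    scaled = scale_climate(data)
    out = pd.DataFrame({"log_shifted_height": np.log(shifted)})
    out["age"] = np.asarray(scaled["age"], dtype=float)
    for col in scaled.columns:
        if col in ("age", "height", "log_shifted_height"):
            continue
        if pd.api.types.is_numeric_dtype(scaled[col]):
            out[col] = np.asarray(scaled[col], dtype=float)
    if "pop_id" in data.columns:
        out.insert(0, "pop_id", data["pop_id"].to_numpy())
    return out


def enumerate_subsets(variables) -> list[tuple[str, ...]]:
    """All subsets of the variable list (including the empty set), ordered
    by size then lexicographically within size. 12 variables -> 4,096."""
    variables = tuple(variables)
    if len(set(variables)) != len(variables):
        raise ValueError("duplicate variable names")
    ordered = sorted(variables)
    subsets: list[tuple[str, ...]] = []
    for k in range(len(ordered) + 1):
        subsets.extend(itertools.combinations(ordered, k))
    return subsets


def aic(sse: float, n: int, p: int) -> float:
    """Gaussian AIC: n*[ln(2*pi) + ln(sse/n) + 1] + 2p.

    A zero SSE (perfect fit) yields -inf as the 'perfect fit' sentinel.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if sse == 0:
        return float("-inf")
    return n * (math.log(2 * math.pi) + math.log(sse / n) + 1.0) + 2 * p


def run_all_subsets(
    data: pd.DataFrame, variables, theta1_hat: float
) -> list[SubsetModelResult]:
    """One OLS fit per climate-variable subset on the log-linearized design.

    Each subset's design is [1, age, vars..., vars x age...]; the
    parameter count for AIC is p = 2 + 2k for a k-variable subset. Results
    are returned ranked by ascending AIC (ties: smaller subset first, then
    lexicographic). Rank-deficient subsets are flagged, not dropped.
    """
    table = loglinearize(data, theta1_hat)
    y = np.asarray(table["log_shifted_height"], dtype=float)
    age = np.asarray(table["age"], dtype=float)
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    cols = {v: np.asarray(table[v], dtype=float) for v in variables}

    results = []
    for subset in enumerate_subsets(variables):
        k = len(subset)
        x = np.column_stack(
            [np.ones(n), age]
            + [cols[v] for v in subset]
            + [cols[v] * age for v in subset]
        )
        beta, sse_arr, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        deficient = rank < x.shape[1]
        resid = y - x @ beta
        sse = float(resid @ resid)
        p = 2 + 2 * k
        results.append(
            SubsetModelResult(
                subset=subset,
                coefficients=beta,
                aic=aic(sse, n, p),
                rmse=float(np.sqrt(sse / max(n - p, 1))),
                r2=1.0 - sse / sst if sst > 0 else float("nan"),
                rank_deficient=deficient,
            )
        )

    results.sort(key=lambda r: (r.aic, len(r.subset), r.subset))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def variable_frequency(
    results: list[SubsetModelResult], top_k: int
) -> dict[str, float]:
    """Fraction of the top_k AIC-ranked subsets containing each variable."""
    if not 1 <= top_k <= len(results):
        raise ValueError(f"top_k must be in [1, {len(results)}], got {top_k}")
    ranked = sorted(results, key=lambda r: r.rank)[:top_k]
    variables = sorted({v for r in results for v in r.subset})
    return {
        v: sum(1 for r in ranked if v in r.subset) / top_k for v in variables
    }


def delta_aic_improves(aic_base: float, aic_candidate: float) -> bool:
    """True iff the candidate improves on the base by more than 2 AIC
    units (strict), the conventional 'substantial support' threshold."""
    if not (math.isfinite(aic_base) and math.isfinite(aic_candidate)):
        raise ValueError("AIC values must be finite")
    return aic_base - aic_candidate > 2.0


def results_to_frame(results: list[SubsetModelResult]) -> pd.DataFrame:
    """Flatten ranked subset results to a table (one row per subset, with
    per-variable membership flags)."""
    variables = sorted({v for r in results for v in r.subset})
    rows = []
    for r in sorted(results, key=lambda x: x.rank):
        row = {"rank": r.rank, "aic": r.aic, "rmse": r.rmse, "r2": r.r2,
               "n_vars": len(r.subset), "rank_deficient": r.rank_deficient,
               "subset": "+".join(r.subset)}
        for v in variables:
            row[f"has_{v}"] = int(v in r.subset)
        rows.append(row)
    return pd.DataFrame(rows)
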