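"""Climate-niche height-growth model for conifer saplings.

The core model is an exponential height–age trajectory

    h(age) = theta1 * (exp(theta2 * age) - 1)

— the sapling-stage limb of a Chapman-Richards curve — in which the two
curve parameters are themselves linear functions of climate:

    theta1 = a10 + sum_j a1j * c_j        (asymptotic scale, m)
    theta2 = a20 + sum_j a2j * c_j        (relative growth rate, 1/year)

with c_j the scaled climate variables (see :mod:`saplingniche.climate`).
Heights are population means (m); ages are years since planting. Errors
are assumed i.i.d. Gaussian with constant variance, so full-information
maximum likelihood reduces to nonlinear least squares: there is a single
equation and the assumed error structure has equal variances and zero
covariances, making the Gaussian ML and least-squares estimates identical.

Fitting uses multi-start trust-region least squares; starting values come
from a pooled (climate-free) exponential fit with all climate coefficients
at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .climate import (
    ApplicabilityError,
    ClimateVector,
    check_applicability_frame,
    scale_climate,
    validate_climate_names,
)

__all__ = [
    "ThetaSpec",
    "FittedGrowthModel",
    "ProvenancePop",
    "RankDeficiencyError",
    "ConvergenceError",
    "theta",
    "predict_height",
    "fit_niche_model",
    "growth_acceleration",
    "cumulative_growth",
    "scenario_compare",
    "reference_annual_model",
]


class RankDeficiencyError(ValueError):
    """Raised when the design does not identify the model parameters."""


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails to converge; carries diagnostics."""


@dataclass(frozen=True)
class ThetaSpec:
    """Which climate variables enter each curve-parameter function."""

    theta1_vars: tuple[str, ...] = ()
    theta2_vars: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "theta1_vars", validate_climate_names(self.theta1_vars)
        )
        object.__setattr__(
            self, "theta2_vars", validate_climate_names(self.theta2_vars)
        )

    @property
    def n_params(self) -> int:
        """Total estimated coefficients: two intercepts plus one per variable."""
        return 2 + len(self.theta1_vars) + len(self.theta2_vars)


@dataclass(frozen=True)
class ProvenancePop:
    """One population-level height observation from a provenance trial."""

    pop_id: str
    species: str
    adaptive_class: str  # "generalist" | "specialist"
    age: float  # years, in [1, 25]
    height: float  # m, >= 0
    climate: ClimateVector

    def __post_init__(self):
        if not (1 <= self.age <= 25):
            raise ValueError(f"age {self.age} outside sapling range [1, 25]")
        if self.height < 0:
            raise ValueError(f"negative height {self.height}")


@dataclass
class FittedGrowthModel:
    """A fitted (or ground-truth) niche growth model.

    ``theta1_coeffs``/``theta2_coeffs`` hold the intercept followed by one
    coefficient per variable in the corresponding spec list. Fit statistics
    follow the usual nonlinear-regression conventions: pseudo R^2 =
    1 - SSE/SST_corrected, RMSE = sqrt(SSE / (n - p)), and
    AIC = n*[ln(2*pi) + ln(SSE/n) + 1] + 2p.
    """

    spec: ThetaSpec
    theta1_coeffs: np.ndarray
    theta2_coeffs: np.ndarray
    n: int = 0
    p: int = 0
    sse: float = float("nan")
    pseudo_r2: float = float("nan")
    rmse: float = float("nan")
    aic: float = float("nan")
    coeff_se: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    perfect_fit: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.theta1_coeffs = np.atleast_1d(
            np.asarray(self.theta1_coeffs, dtype=float)
        )
        self.theta2_coeffs = np.atleast_1d(
            np.asarray(self.theta2_coeffs, dtype=float)
        )
        if len(self.theta1_coeffs) != 1 + len(self.spec.theta1_vars):
            raise ValueError("theta1_coeffs length does not match spec")
        if len(self.theta2_coeffs) != 1 + len(self.spec.theta2_vars):
            raise ValueError("theta2_coeffs length does not match spec")

    # -- climate-function evaluation over tabular data ------------------
    def theta1(self, climate: ClimateVector) -> float:
        return theta(self.theta1_coeffs, self.spec.theta1_vars, climate)

    def theta2(self, climate: ClimateVector) -> float:
        return theta(self.theta2_coeffs, self.spec.theta2_vars, climate)

    def theta_arrays(
        self, scaled: pd.DataFrame
    ) -> tuple[np.ndarray, np.ndarray]:
        """theta1 and theta2 for every row of a scaled climate table."""
        x1 = _design(scaled, self.spec.theta1_vars)
        x2 = _design(scaled, self.spec.theta2_vars)
        return x1 @ self.theta1_coeffs, x2 @ self.theta2_coeffs

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "spec": {
                "theta1_vars": list(self.spec.theta1_vars),
                "theta2_vars": list(self.spec.theta2_vars),
            },
            "theta1_coeffs": self.theta1_coeffs.tolist(),
            "theta2_coeffs": self.theta2_coeffs.tolist(),
            "n": self.n,
            "p": self.p,
            "sse": self.sse,
            "pseudo_r2": self.pseudo_r2,
            "rmse": self.rmse,
            "aic": self.aic,
            "coeff_se": self.coeff_se,
            "converged": self.converged,
            "perfect_fit": self.perfect_fit,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedGrowthModel":
        d = json.loads(text)
        return cls(
            spec=ThetaSpec(
                tuple(d["spec"]["theta1_vars"]),
                tuple(d["spec"]["theta2_vars"]),
            ),
            theta1_coeffs=np.asarray(d["theta1_coeffs"]),
            theta2_coeffs=np.asarray(d["theta2_coeffs"]),
            n=d["n"],
            p=d["p"],
            sse=d["sse"],
            pseudo_r2=d["pseudo_r2"],
            rmse=d["rmse"],
            aic=d["aic"],
            coeff_se=d.get("coeff_se", {}),
            converged=d.get("converged", True),
            perfect_fit=d.get("perfect_fit", False),
            warnings=d.get("warnings", []),
        )


def reference_annual_model() -> FittedGrowthModel:
    """The published annual-variable niche model for Pacific Northwest
    conifers: theta1 driven by DD5, DD_18 and Eref, theta2 by DD5.

    Used as the default ground truth of the synthetic-data generator and
    as the standard coefficient set for scenario analyses.
    """
    spec = ThetaSpec(theta1_vars=("dd5", "dd_18", "eref"), theta2_vars=("dd5",))
    return FittedGrowthModel(
        spec=spec,
        theta1_coeffs=np.array([2.801085, 0.061629, -0.02025, -0.15363]),
        theta2_coeffs=np.array([0.099673, -0.00037]),
        n=616,
        p=spec.n_params,
        pseudo_r2=0.9703,
        rmse=0.6558,
        aic=1234.25,
        coeff_se={"theta1_intercept": 0.2903, "theta2_intercept": 0.00357},
    )


def theta(coeffs, var_names, climate: ClimateVector) -> float:
    """Evaluate a climate function: intercept + sum(coeff * scaled value)."""
    coeffs = np.asarray(coeffs, dtype=float)
    var_names = tuple(var_names)
    if len(coeffs) != 1 + len(var_names):
        raise ValueError(
            f"need {1 + len(var_names)} coefficients for {var_names}, "
            f"got {len(coeffs)}"
        )
    value = coeffs[0]
    for c, name in zip(coeffs[1:], var_names):
        value += c * climate[name]
    return float(value)


def predict_height(
    model: FittedGrowthModel, age: float, climate: ClimateVector
) -> float:
    """Predicted mean height (m) at a given age and site climate.

    Exactly 0 at age 0. Raises ApplicabilityError outside the model's
    climatic domain (DD5 <= 100 in original units).
    """
    climate.check_applicability()
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    t1 = model.theta1(climate)
    t2 = model.theta2(climate)
    return float(t1 * np.expm1(t2 * age))


def growth_acceleration(
    model: FittedGrowthModel, climate: ClimateVector, age: float
) -> float:
    """Second derivative of the trajectory in age: theta1 * theta2^2 *
    exp(theta2 * age), in m/year^2."""
    climate.check_applicability()
    t1 = model.theta1(climate)
    t2 = model.theta2(climate)
    return float(t1 * t2**2 * np.exp(t2 * age))


def cumulative_growth(
    model: FittedGrowthModel,
    climate: ClimateVector,
    age_from: float,
    age_to: float,
) -> float:
    """Closed-form integral of the trajectory over [age_from, age_to]:
    theta1/theta2 * (e^{theta2*b} - e^{theta2*a}) - theta1*(b - a), in
    m*years. Near theta2 = 0 the quadratic series limit is used."""
    if age_from > age_to:
        raise ValueError("age_from must be <= age_to")
    climate.check_applicability()
    t1 = model.theta1(climate)
    t2 = model.theta2(climate)
    a, b = age_from, age_to
    if abs(t2) < 1e-8:
        return float(t1 * t2 * (b**2 - a**2) / 2.0)
    return float(t1 / t2 * (np.exp(t2 * b) - np.exp(t2 * a)) - t1 * (b - a))


def scenario_compare(
    model: FittedGrowthModel,
    scenario_climates: dict[str, ClimateVector],
    age_grid,
) -> pd.DataFrame:
    """Trajectories, accelerations and cumulative growth (from age 0)
    under labelled climate scenarios, e.g. current vs. future normals.

    Returns a long table keyed by (scenario, age).
    """
    rows = []
    for label, climate in scenario_climates.items():
        try:
            climate.check_applicability()
        except ApplicabilityError as err:
            raise ApplicabilityError(f"scenario {label!r}: {err}") from err
        for age in age_grid:
            rows.append(
                {
                    "scenario": label,
                    "age": float(age),
                    "height": predict_height(model, age, climate),
                    "acceleration": growth_acceleration(model, climate, age),
                    "cumulative": cumulative_growth(model, climate, 0.0, age),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitting


def _design(scaled: pd.DataFrame, var_names: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(scaled))]
    cols += [np.asarray(scaled[v], dtype=float) for v in var_names]
    return np.column_stack(cols)


def pooled_exponential_start(
    ages: np.ndarray, heights: np.ndarray
) -> tuple[float, float]:
    """Least-squares fit of the climate-free curve h = t1*(e^{t2*age}-1),
    used for starting values. Requires >= 3 distinct ages for a stable
    two-parameter fit."""
    ages = np.asarray(ages, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if len(np.unique(ages)) < 3:
        raise RankDeficiencyError(
            "pooled exponential fit needs >= 3 distinct ages"
        )

    def resid(params):
        t1, t2 = params
        return t1 * np.expm1(t2 * ages) - heights

    best = None
    for t2_0 in (0.05, 0.1, 0.2):
        denom = np.expm1(t2_0 * np.median(ages))
        t1_0 = max(np.median(heights) / denom, 1e-3) if denom > 0 else 1.0
        sol = least_squares(resid, [t1_0, t2_0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    return float(best.x[0]), float(best.x[1])


def fit_niche_model(
    data: pd.DataFrame,
    spec: ThetaSpec,
    n_starts: int = 4,
    seed: int = 0,
) -> FittedGrowthModel:
    """Fit the niche growth model by Gaussian maximum likelihood.

    ``data`` must carry columns ``age``, ``height`` and the climate
    variables named in ``spec`` in original units. With i.i.d. normal
    errors the ML fit is the nonlinear least-squares minimizer of the sum
    of squared residuals of h = theta1(c)*(e^{theta2(c)*age} - 1).

    Multi-start trust-region least squares with starts from the pooled
    exponential fit (climate coefficients 0) plus perturbed copies; cost
    tolerance 1e-10. Raises RankDeficiencyError on unidentifiable designs
    and ConvergenceError if no start converges.
    """
    p = spec.n_params
    if len(data) < p + 2:
        raise ValueError(f"need at least {p + 2} observations, got {len(data)}")
    check_applicability_frame(data)

    scaled = scale_climate(data)
    y = np.asarray(scaled["height"], dtype=float)
    ages = np.asarray(scaled["age"], dtype=float)
    x1 = _design(scaled, spec.theta1_vars)
    x2 = _design(scaled, spec.theta2_vars)
    k1 = x1.shape[1]

    if np.linalg.matrix_rank(x1) < x1.shape[1]:
        raise RankDeficiencyError("theta1 climate design is rank-deficient")
    if np.linalg.matrix_rank(x2) < x2.shape[1]:
        raise RankDeficiencyError("theta2 climate design is rank-deficient")

    t1_0, t2_0 = pooled_exponential_start(ages, y)

    def split(params):
        return params[:k1], params[k1:]

    def resid(params):
        c1, c2 = split(params)
        return (x1 @ c1) * np.expm1((x2 @ c2) * ages) - y

    base = np.zeros(p)
    base[0], base[k1] = t1_0, t2_0
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(max(n_starts - 1, 0)):
        jitter = base.copy()
        jitter[0] *= rng.uniform(0.5, 1.5)
        jitter[k1] *= rng.uniform(0.5, 1.5)
        starts.append(jitter)

    best = None
    for start in starts:
        sol = least_squares(
            resid, start, method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise ConvergenceError(
            "niche model fit failed to converge from any start "
            f"(spec={spec}, n={len(data)})"
        )

    c1, c2 = split(best.x)
    res = best.fun
    n = len(y)
    sse = float(res @ res)
    sst = float(np.sum((y - y.mean()) ** 2))
    pseudo_r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(sse / (n - p)))
    perfect = sse <= 1e-12 * max(sst, 1.0)
    aic = float("-inf") if perfect else _aic(sse, n, p)

    warnings = []
    # standard errors from the Gauss-Newton covariance J'J^-1 * s^2
    coeff_se: dict[str, float] = {}
    if not perfect:
        jac = best.jac
        jtj = jac.T @ jac
        s2 = sse / (n - p)
        try:
            cov = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * s2
            warnings.append("singular information matrix; SEs from pseudoinverse")
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        names = ["theta1_intercept"] + [f"theta1_{v}" for v in spec.theta1_vars]
        names += ["theta2_intercept"] + [f"theta2_{v}" for v in spec.theta2_vars]
        coeff_se = dict(zip(names, se.tolist()))

    t1_all = x1 @ c1
    t2_all = x2 @ c2
    if (t1_all < 0).any():
        warnings.append("theta1 negative for some observations")
    if (t2_all < 0).any():
        warnings.append("theta2 negative for some observations")

    return FittedGrowthModel(
        spec=spec,
        theta1_coeffs=c1,
        theta2_coeffs=c2,
        n=n,
        p=p,
        sse=sse,
        pseudo_r2=pseudo_r2,
        rmse=rmse,
        aic=aic,
        coeff_se=coeff_se,
        converged=True,
        perfect_fit=perfect,
        warnings=warnings,
    )


def _aic(sse: float, n: int, p: int) -> float:
    return n * (np.log(2 * np.pi) + np.log(sse / n) + 1.0) + 2 * p


def predict_heights_frame(
    model: FittedGrowthModel, data: pd.DataFrame, age=None
) -> np.ndarray:
    """Vectorized prediction over a table in original units. ``age``
    overrides the table's age column when given (scalar or array)."""
    check_applicability_frame(data)
    scaled = scale_climate(data)
    t1, t2 = model.theta_arrays(scaled)
    ages = np.asarray(scaled["age"], dtype=float) if age is None else np.asarray(age, dtype=float)
    return t1 * np.expm1(t2 * ages)
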