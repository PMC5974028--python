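"""Height-growth vs ecosystem-function analysis of inventory plots.

Pipeline (order fixed): keep plots at least 70% conifer by tree species,
average repeated samplings of the same plot, attach the niche-model
predicted height at the standard age of 8 years, then correlate height
and diversity against productivity, biomass and each other — on the full
data and on the central 95% (both coordinates within mean +/- 2 sd).

Inventory productivity classes are an inverted ordinal (1 = most
productive, 225+ cubic feet/acre/year; 7 = least, 0-19). For correlations
to carry the intuitive sign, classes are recoded to the midpoint of their
growth range before correlating; the recoding is flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth_model import FittedGrowthModel, predict_heights_frame
from .synthetic_data import PRODUCTIVITY_CLASS_MIDPOINTS

__all__ = [
    "CorrelationResult",
    "filter_conifer_plots",
    "average_repeated",
    "attach_predicted_height",
    "correlate",
    "trim_95",
    "fig_battery",
    "battery_to_frame",
]


@dataclass
class CorrelationResult:
    """Pearson correlation plus the simple-regression summary (slope F
    test with df (1, n-2), equivalent to the correlation t-test)."""

    x_name: str
    y_name: str
    r: float
    n: int
    f_stat: float
    df: tuple[int, int]
    p: float
    slope: float
    intercept: float
    trimmed: bool = False
    retained_n: int = 0
    significant: bool = False  # p < 0.05; regression line suppressed if not


def filter_conifer_plots(
    plots: pd.DataFrame, threshold: float = 0.70
) -> pd.DataFrame:
    """Retain plots whose conifer fraction is >= threshold (inclusive)."""
    return plots.loc[plots["conifer_fraction"] >= threshold].reset_index(
        drop=True
    )


def average_repeated(plots: pd.DataFrame) -> pd.DataFrame:
    """Average numeric attributes of repeated samplings per plot_id.

    Non-numeric attributes must agree across samplings; conflicts raise.
    ``n_samplings`` records how many rows were merged.
    """
    numeric = [
        c
        for c in plots.columns
        if c not in ("plot_id", "n_samplings")
        and pd.api.types.is_numeric_dtype(plots[c])
    ]
    other = [
        c for c in plots.columns if c not in numeric + ["plot_id", "n_samplings"]
    ]
    for col in other:
        conflicting = plots.groupby("plot_id")[col].nunique()
        bad = conflicting[conflicting > 1]
        if len(bad):
            raise ValueError(
                f"conflicting values of {col!r} for plot(s) "
                f"{bad.index.tolist()[:10]}"
            )
    agg = {c: "mean" for c in numeric}
    agg.update({c: "first" for c in other})
    out = plots.groupby("plot_id", sort=False, as_index=False).agg(agg)
    counts = plots.groupby("plot_id", sort=False).size().to_numpy()
    out["n_samplings"] = counts
    return out


def attach_predicted_height(
    plots: pd.DataFrame, model: FittedGrowthModel, age: float = 8.0
) -> pd.DataFrame:
    """Add/overwrite ``predicted_height`` with the model prediction at the
    given age for each plot's climate."""
    out = plots.copy()
    out["predicted_height"] = predict_heights_frame(model, out, age=age)
    return out


def recode_productivity(classes) -> np.ndarray:
    """Map inverted 1-7 productivity classes to growth-range midpoints
    (cubic feet/acre/year) so larger = more productive."""
    classes = np.asarray(classes)
    return np.array(
        [PRODUCTIVITY_CLASS_MIDPOINTS[int(c)] for c in classes], dtype=float
    )


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson r with regression slope/intercept and the slope F test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    lr = stats.linregress(x, y)
    r = float(lr.rvalue)
    # F = t^2 of the slope; r^2 -> 1 (exact fit) gives an infinite F
    with np.errstate(over="ignore", divide="ignore"):
        f = float(r**2 * (n - 2) / max(1.0 - r**2, np.finfo(float).tiny))
    p = float(lr.pvalue)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        r=r,
        n=n,
        f_stat=f,
        df=(1, n - 2),
        p=p,
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        retained_n=n,
        significant=p < 0.05,
    )


def trim_95(x, y) -> np.ndarray:
    """Indices of points with BOTH coordinates within their variable's
    mean +/- 2 sd (about 95% of a normal marginal). A zero-sd coordinate
    retains exactly the points equal to the mean."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched inputs with n >= 3")
    keep = np.ones(len(x), dtype=bool)
    for v in (x, y):
        mu, sd = v.mean(), v.std()
        keep &= np.abs(v - mu) <= 2 * sd
    return np.flatnonzero(keep)


#: The six relations examined: (x, y) column pairs after recoding.
BATTERY_PAIRS = [
    ("productivity", "predicted_height"),
    ("biomass", "predicted_height"),
    ("productivity", "tree_diversity"),
    ("biomass", "tree_diversity"),
    ("tree_diversity", "predicted_height"),
    ("species_diversity", "predicted_height"),
]


def fig_battery(
    plots: pd.DataFrame, model: FittedGrowthModel | None = None
) -> list[CorrelationResult]:
    """Full and 95%-trimmed correlation summaries for the six
    height/diversity vs ecosystem-function pairings.

    ``plots`` must be pipeline-prepared (filtered, averaged); if
    ``predicted_height`` is absent and a model is given, it is attached at
    age 8. Productivity classes are midpoint-recoded before correlating.
    """
    if "predicted_height" not in plots.columns:
        if model is None:
            raise ValueError("need predicted_height column or a model")
        plots = attach_predicted_height(plots, model)
    table = plots.copy()
    table["productivity"] = recode_productivity(table["productivity_class"])

    results = []
    for x_name, y_name in BATTERY_PAIRS:
        x = table[x_name].to_numpy(dtype=float)
        y = table[y_name].to_numpy(dtype=float)
        results.append(correlate(x, y, x_name, y_name))
        idx = trim_95(x, y)
        trimmed = correlate(x[idx], y[idx], x_name, y_name)
        trimmed.trimmed = True
        trimmed.retained_n = len(idx)
        results.append(trimmed)
    return results


def battery_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular summary; slope/intercept are withheld (NaN) for
    non-significant fits, mirroring suppressed regression lines."""
    rows = []
    for res in results:
        rows.append(
            {
                "x": res.x_name,
                "y": res.y_name,
                "trimmed": res.trimmed,
                "r": res.r,
                "n": res.n,
                "f_stat": res.f_stat,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
                "slope": res.slope if res.significant else np.nan,
                "intercept": res.intercept if res.significant else np.nan,
                "significant": res.significant,
                "retained_n": res.retained_n,
            }
        )
    return pd.DataFrame(rows)
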