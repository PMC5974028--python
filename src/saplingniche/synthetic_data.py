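"""Synthetic provenance-trial and forest-inventory datasets.

Two generators reproduce the statistical structure the analysis assumes,
so every downstream stage is testable without the (unpublished) compiled
trial data or an inventory-database extract.

``gen_provenance_dataset`` draws population-level height observations:
climates uniform over configurable Pacific-Northwest ranges (independent
by default, optionally Gaussian-copula correlated), integer ages on
[1, 25], and heights equal to the niche-model curve under a ground-truth
coefficient set plus i.i.d. Gaussian noise. Species labelled adaptive
specialists receive extra population-level noise, emulating the larger
prediction residuals observed for specialist conifers; heights are floored
at zero. The default noise sd of 0.65 m matches the overall cross-validated
error scale of the fitted model (about 0.65 m).

``gen_fia_plots`` draws inventory-style plots: a climate vector, the
model-predicted height at the standard age of 8 years, and ecosystem
attributes (productivity class 1-7, aboveground dry biomass, alpha tree
and species diversity) coupled to predicted height through a Gaussian
copula with configurable target correlations. A minority of plots falls
below the 70% conifer-fraction threshold so that filtering is exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import CLIMATE_VARS, DD5_APPLICABILITY_MIN, PNW_CLIMATE_RANGES
from .growth_model import (
    FittedGrowthModel,
    predict_heights_frame,
    reference_annual_model,
)

__all__ = [
    "GeneratorConfig",
    "PlotGeneratorConfig",
    "gen_provenance_dataset",
    "gen_fia_plots",
    "write_dataset",
    "derive_seeds",
]


def derive_seeds(root: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one root seed."""
    state = np.random.SeedSequence(int(root)).generate_state(n, np.uint64)
    return [int(s % (2**31)) for s in state]

#: Midpoints (cubic feet/acre/year) of the 7 inventory productivity classes;
#: class 1 (225+) is open-ended and represented by 250.
PRODUCTIVITY_CLASS_MIDPOINTS = {
    1: 250.0,
    2: 194.5,
    3: 142.0,
    4: 102.0,
    5: 67.0,
    6: 34.5,
    7: 9.5,
}

#: Marginal distribution of alpha tree diversity (counts 1-8). Half the
#: mass lies at or below 2, putting the sample median near 2.5.
_TREE_DIVERSITY_PMF = np.array(
    [0.28, 0.22, 0.16, 0.11, 0.08, 0.06, 0.05, 0.04]
)


@dataclass
class GeneratorConfig:
    """Study conditions for the provenance-trial generator.

    Defaults mirror the compiled trial structure: 616 populations of 15
    conifer species, ages 1-25, climates spanning maritime to interior
    montane Pacific Northwest, height noise sd 0.65 m, and extra noise
    (0.35 m, added in quadrature) for adaptive-specialist species.
    """

    n_populations: int = 616
    n_species: int = 15
    specialist_fraction: float = 0.4
    age_range: tuple[int, int] = (1, 25)
    climate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PNW_CLIMATE_RANGES)
    )
    climate_correlation: np.ndarray | None = None  # None = independent
    noise_sd: float = 0.65
    specialist_extra_sd: float = 0.35
    true_model: FittedGrowthModel | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.n_species < 1 or self.n_species > self.n_populations:
            raise ValueError("n_species must be in [1, n_populations]")
        if self.noise_sd < 0 or self.specialist_extra_sd < 0:
            raise ValueError("noise sds must be >= 0")
        lo, hi = self.age_range
        if not (1 <= lo <= hi <= 25):
            raise ValueError("age_range must lie within [1, 25]")
        missing = [v for v in CLIMATE_VARS if v not in self.climate_ranges]
        if missing:
            raise ValueError(f"climate_ranges missing {missing}")
        dd5_lo, _ = self.climate_ranges["dd5"]
        if dd5_lo <= DD5_APPLICABILITY_MIN:
            raise ValueError(
                "climate_ranges must keep DD5 above "
                f"{DD5_APPLICABILITY_MIN:g} (got lower bound {dd5_lo:g})"
            )

    def resolved_model(self) -> FittedGrowthModel:
        return self.true_model or reference_annual_model()


def _draw_climates(
    rng: np.random.Generator,
    n: int,
    ranges: dict[str, tuple[float, float]],
    correlation: np.ndarray | None,
) -> pd.DataFrame:
    """Uniform marginals over the configured ranges; if a correlation
    matrix is given, a Gaussian copula imposes it across variables."""
    k = len(CLIMATE_VARS)
    if correlation is None:
        u = rng.uniform(size=(n, k))
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        z = rng.multivariate_normal(np.zeros(k), corr, size=n)
        from scipy.stats import norm

        u = norm.cdf(z)
    data = {}
    for j, var in enumerate(CLIMATE_VARS):
        lo, hi = ranges[var]
        data[var] = lo + (hi - lo) * u[:, j]
    return pd.DataFrame(data)


def gen_provenance_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate population-level height records.

    Returns a table with columns pop_id, species, adaptive_class, age,
    height and the 12 climate variables (original units). Deterministic
    given config.seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = config.resolved_model()
    n = config.n_populations

    n_specialist = int(round(config.specialist_fraction * config.n_species))
    species_names = [f"sp{j + 1:02d}" for j in range(config.n_species)]
    species_class = {
        name: ("specialist" if j < n_specialist else "generalist")
        for j, name in enumerate(species_names)
    }
    # every species appears at least once, remainder assigned at random
    species_idx = np.concatenate(
        [
            np.arange(config.n_species),
            rng.integers(0, config.n_species, n - config.n_species),
        ]
    )
    rng.shuffle(species_idx)
    species = np.array(species_names)[species_idx]
    adaptive_class = np.array([species_class[s] for s in species])

    climates = _draw_climates(
        rng, n, config.climate_ranges, config.climate_correlation
    )
    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, n)

    df = climates.copy()
    df.insert(0, "pop_id", [f"pop{i + 1:04d}" for i in range(n)])
    df.insert(1, "species", species)
    df.insert(2, "adaptive_class", adaptive_class)
    df.insert(3, "age", ages)
    df["height"] = 0.0  # placeholder so prediction helper sees full schema

    mean_height = predict_heights_frame(model, df)
    sd = np.where(
        adaptive_class == "specialist",
        np.hypot(config.noise_sd, config.specialist_extra_sd),
        config.noise_sd,
    )
    noise = rng.normal(0.0, 1.0, n) * sd
    df["height"] = np.maximum(mean_height + noise, 0.0)
    return df


@dataclass
class PlotGeneratorConfig:
    """Study conditions for the inventory-plot generator.

    Default coupling strengths are the observed height-ecosystem-function
    correlations for conifer-dominated western-US plots (productivity
    +0.282, biomass +0.162, tree diversity -0.022, species diversity
    +0.080, plus tree-diversity couplings to productivity +0.255 and
    biomass +0.158).
    """

    n_plots: int = 44000
    conifer_fraction_beta: tuple[float, float] = (8.0, 1.0)
    tree_diversity_range: tuple[int, int] = (1, 8)
    productivity_noise: float = 1.0
    biomass_noise: float = 1.0
    coupling_strengths: dict[str, float] = field(
        default_factory=lambda: {
            "productivity": 0.282,
            "biomass": 0.162,
            "tree_diversity": -0.022,
            "species_diversity": 0.080,
            "tree_diversity_productivity": 0.255,
            "tree_diversity_biomass": 0.158,
        }
    )
    climate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PNW_CLIMATE_RANGES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        lo, hi = self.tree_diversity_range
        if not (1 <= lo <= hi <= 8):
            raise ValueError("tree_diversity_range must lie within [1, 8]")
        for key, rho in self.coupling_strengths.items():
            if not -1 < rho < 1:
                raise ValueError(f"coupling {key}={rho} outside (-1, 1)")


def _latent_matrix(
    rng: np.random.Generator, z_height: np.ndarray, c: dict[str, float]
) -> np.ndarray:
    """Latent standard-normal variables (productivity, biomass, tree
    diversity, species diversity) with target correlations to the
    standardized predicted height and among themselves (Gaussian copula).
    """
    n = len(z_height)
    # order: height, productivity, biomass, tree_div, species_div
    target = np.eye(5)
    target[0, 1] = target[1, 0] = c.get("productivity", 0.0)
    target[0, 2] = target[2, 0] = c.get("biomass", 0.0)
    target[0, 3] = target[3, 0] = c.get("tree_diversity", 0.0)
    target[0, 4] = target[4, 0] = c.get("species_diversity", 0.0)
    target[1, 3] = target[3, 1] = c.get("tree_diversity_productivity", 0.0)
    target[2, 3] = target[3, 2] = c.get("tree_diversity_biomass", 0.0)
    target[1, 2] = target[2, 1] = c.get("productivity_biomass", 0.5)
    # nudge to the nearest PD matrix if the user-specified entries clash
    w, v = np.linalg.eigh(target)
    if w.min() < 1e-8:
        target = v @ np.diag(np.clip(w, 1e-8, None)) @ v.T
        d = np.sqrt(np.diag(target))
        target = target / np.outer(d, d)
    chol = np.linalg.cholesky(target)
    eps = rng.standard_normal((n, 4))
    # condition on the realized height scores: the first latent IS
    # z_height, the rest combine it with fresh noise via the Cholesky rows
    out = np.empty((n, 4))
    for j in range(1, 5):
        out[:, j - 1] = chol[j, 0] * z_height + eps @ chol[j, 1:]
    return out


def _quantile_map_discrete(
    latent: np.ndarray, pmf: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Map latent normals to a discrete marginal via the probability
    integral transform."""
    from scipy.stats import norm

    u = norm.cdf(latent)
    edges = np.cumsum(pmf) / pmf.sum()
    idx = np.searchsorted(edges, u, side="right")
    return values[np.clip(idx, 0, len(values) - 1)]


def gen_fia_plots(
    config: PlotGeneratorConfig, model: FittedGrowthModel | None = None
) -> pd.DataFrame:
    """Generate inventory-style plot records.

    Columns: plot_id, conifer_fraction, productivity_class (1 = most
    productive), biomass (dry, arbitrary mass units), tree_diversity,
    species_diversity, n_samplings, predicted_height (m, age 8) and the
    12 climate variables (original units). Deterministic given seed.
    """
    config.validate()
    model = model or reference_annual_model()
    rng = np.random.default_rng(config.seed)
    n = config.n_plots

    climates = _draw_climates(rng, n, config.climate_ranges, None)
    df = climates.copy()
    df.insert(0, "plot_id", [f"plot{i + 1:06d}" for i in range(n)])
    df["age"] = 8.0
    height = predict_heights_frame(model, df, age=8.0)
    df = df.drop(columns=["age"])
    df["predicted_height"] = height

    sd_h = height.std()
    z_h = (height - height.mean()) / (sd_h if sd_h > 0 else 1.0)
    latent = _latent_matrix(rng, z_h, config.coupling_strengths)

    # productivity: 7 ordinal classes, class 1 = highest potential growth
    prod_latent = latent[:, 0]
    class_pmf = np.array([0.05, 0.08, 0.13, 0.19, 0.23, 0.19, 0.13])
    # map high latent -> low class number (most productive)
    prod_class = _quantile_map_discrete(
        -prod_latent, class_pmf, np.arange(1, 8)
    )

    # biomass: lognormal, positive, noisier with biomass_noise
    biom_latent = latent[:, 1]
    biomass = np.exp(
        np.log(60.0) + 0.9 * config.biomass_noise * biom_latent
    )

    lo, hi = config.tree_diversity_range
    pmf = _TREE_DIVERSITY_PMF[lo - 1 : hi]
    tree_div = _quantile_map_discrete(
        latent[:, 2], pmf, np.arange(lo, hi + 1)
    )

    # species diversity: shifted-geometric-like counts >= 1
    sp_pmf = 0.45 * 0.55 ** np.arange(12)
    species_div = _quantile_map_discrete(
        latent[:, 3], sp_pmf, np.arange(1, 13)
    )

    a, b = config.conifer_fraction_beta
    df["conifer_fraction"] = rng.beta(a, b, n)
    df["productivity_class"] = prod_class
    df["biomass"] = biomass
    df["tree_diversity"] = tree_div
    df["species_diversity"] = species_div
    df["n_samplings"] = 1
    return df


def write_dataset(df: pd.DataFrame, path, config=None) -> None:
    """Write a generated table to CSV with a JSON sidecar recording the
    generating config (including the seed)."""
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        payload = {}
        for f in dataclasses.fields(config):
            value = getattr(config, f.name)
            if isinstance(value, np.ndarray):
                value = value.tolist()
            elif isinstance(value, FittedGrowthModel):
                value = json.loads(value.to_json())
            elif isinstance(value, tuple):
                value = list(value)
            payload[f.name] = value
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(payload, indent=2, default=str))
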