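"""Household-clustered bivariate blood-pressure data generator.

Emulates the structure of a women's biomarker survey: households are drawn
first (with mostly one, sometimes two or three, sampled women each), each
household receives a region, household-level covariates and a bivariate
household random effect; each woman then receives woman-level covariates, a
bivariate residual, and her SBP/DBP follow the linear model of
:mod:`bpjoint.bivml`. The default configuration reproduces the study
conditions: 3727 households (~4744 women), the published covariate marginals,
fixed-effect sizes, and household/woman covariance components.

Also provides a deterministic toy region geometry (grid of unit squares) so
the mapping stage runs without any shapefile download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .bivml import VarianceComponents
from .cohort import CovariateScheme, Factor, build_design, default_scheme

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate_population",
    "generate_region_geometry",
    "config_to_yaml",
    "config_from_yaml",
    "GHANA_REGIONS_2014",
]

#: The ten administrative regions in existence at the 2014 survey.
GHANA_REGIONS_2014 = (
    "Western", "Central", "Greater Accra", "Volta", "Eastern",
    "Ashanti", "Brong Ahafo", "Northern", "Upper East", "Upper West",
)


def _check_prob_table(name: str, probs) -> None:
    values = np.asarray(list(probs.values()) if isinstance(probs, dict) else probs, float)
    if (values < 0).any():
        raise ValueError(f"{name}: negative probability")
    if abs(values.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name}: probabilities sum to {values.sum()!r}, not 1")


@dataclass
class GeneratorConfig:
    """All true parameters and marginal distributions the simulator uses.

    ``beta1``/``beta2`` map indicator labels (``"<factor> <level>"``, matching
    the design columns of the scheme implied by ``covariate_marginals``) to
    effect sizes in mmHg for SBP and DBP respectively.
    """

    n_households: int
    household_women_count_distribution: dict[int, float]
    covariate_marginals: dict[str, dict[str, float]]
    intercepts: tuple[float, float]
    beta1: dict[str, float]
    beta2: dict[str, float]
    varcomp: VarianceComponents
    region_names: tuple[str, ...] = GHANA_REGIONS_2014
    region_assignment_probs: dict[str, float] | None = None
    ever_told_prob: float = 0.069
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_households <= 0:
            raise ValueError("n_households must be positive")
        _check_prob_table("household size distribution",
                          self.household_women_count_distribution)
        for factor, marg in self.covariate_marginals.items():
            _check_prob_table(f"marginals for {factor}", marg)
        if self.region_assignment_probs is None:
            p = 1.0 / len(self.region_names)
            self.region_assignment_probs = {r: p for r in self.region_names}
        if set(self.region_assignment_probs) != set(self.region_names):
            raise ValueError("region_assignment_probs keys must match region_names")
        _check_prob_table("region assignment", self.region_assignment_probs)
        if set(self.beta1) != set(self.beta2):
            raise ValueError("beta1 and beta2 must index identical covariate levels")
        if not 0.0 <= self.ever_told_prob <= 1.0:
            raise ValueError("ever_told_prob must lie in [0, 1]")

    def scheme(self) -> CovariateScheme:
        """Covariate scheme implied by the marginals: first level is the reference."""
        base = default_scheme()
        factors = []
        for name, marg in self.covariate_marginals.items():
            levels = tuple(marg)
            if name in base.names:
                factors.append(dataclasses.replace(
                    base[name], levels=levels, reference=levels[0]))
            else:
                factors.append(Factor(name, levels, levels[0]))
        return CovariateScheme(factors=tuple(factors))

    def beta_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(intercept, effects) stacked in design-column order, per outcome."""
        labels = self.scheme().indicator_labels()
        missing = [lb for lb in labels if lb not in self.beta1]
        if missing:
            raise ValueError(f"beta1/beta2 missing effect(s) for {missing}")
        b1 = np.array([self.intercepts[0], *(self.beta1[lb] for lb in labels)])
        b2 = np.array([self.intercepts[1], *(self.beta2[lb] for lb in labels)])
        return b1, b2


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

# Published point estimates of the joint model, keyed by design-column label.
_BETA_SBP = {
    "age 25–34": 2.45, "age 35–44": 8.72, "age 45–49": 15.85,
    "obesity Obese": 5.10,
    "cooking_fuel Transition": -0.02, "cooking_fuel Primitive": -0.75,
    "education No education": -2.05, "education Primary": 0.61,
    "wealth Poorer/poorest": -0.73, "wealth Middle": -0.11,
    "water_source Unimproved": -0.68,
    "toilet_type Unimproved": 1.75,
    "household_size 1–3 members": 0.78,
    "wall_type Non-durable materials": -0.003,
    "vegetable Didn't eat vegetable": 0.31,
}
_BETA_DBP = {
    "age 25–34": 3.29, "age 35–44": 6.78, "age 45–49": 10.05,
    "obesity Obese": 4.20,
    "cooking_fuel Transition": -0.46, "cooking_fuel Primitive": -2.06,
    "education No education": -1.23, "education Primary": 0.43,
    "wealth Poorer/poorest": -0.14, "wealth Middle": -0.14,
    "water_source Unimproved": -0.39,
    "toilet_type Unimproved": 0.61,
    "household_size 1–3 members": 0.65,
    "wall_type Non-durable materials": 0.47,
    "vegetable Didn't eat vegetable": 0.34,
}

# Published sample marginals (proportions of 4744 women).
_MARGINALS = {
    "age": {"15–24": 0.356, "25–34": 0.306, "35–44": 0.249, "45–49": 0.089},
    "obesity": {"Not obese": 0.872, "Obese": 0.128},
    "cooking_fuel": {"Advanced": 0.188, "Transition": 0.303, "Primitive": 0.509},
    "education": {"Secondary/higher": 0.567, "No education": 0.244, "Primary": 0.189},
    "wealth": {"Richer/richest": 0.356, "Poorer/poorest": 0.437, "Middle": 0.207},
    "water_source": {"Improved": 0.141, "Unimproved": 0.859},
    "toilet_type": {"Improved": 0.360, "Unimproved": 0.640},
    "household_size": {">3 members": 0.709, "1–3 members": 0.291},
    "wall_type": {"Durable materials": 0.302, "Non-durable materials": 0.698},
    "vegetable": {"Ate vegetable at least once": 0.863, "Didn't eat vegetable": 0.137},
}


def default_config() -> GeneratorConfig:
    """Study-condition defaults: 3727 households, published marginals and effects.

    Variance components place 38.91/16.37 mmHg^2 at the household level and
    224.49/101.75 mmHg^2 at the woman level for SBP/DBP, with level
    correlations 0.81 (household) and 0.73 (woman). Intercepts (112, 72) mmHg
    are clinically plausible reference-group means (not published; configurable).
    The women-per-household distribution P(1)=0.76, P(2)=0.21, P(3)=0.03 makes
    3727 households yield ~4744 women on average.
    """
    return GeneratorConfig(
        n_households=3727,
        household_women_count_distribution={1: 0.76, 2: 0.21, 3: 0.03},
        covariate_marginals={k: dict(v) for k, v in _MARGINALS.items()},
        intercepts=(112.0, 72.0),
        beta1=dict(_BETA_SBP),
        beta2=dict(_BETA_DBP),
        varcomp=VarianceComponents.from_correlations(
            var_h=(38.91, 16.37), rho_h=0.81,
            var_e=(224.49, 101.75), rho_e=0.73,
        ),
        region_names=GHANA_REGIONS_2014,
        ever_told_prob=0.069,
    )


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _sample_mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Zero-mean MVN draws; eigen-based factor so semi-definite covariances work."""
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((size, cov.shape[0])) @ factor.T


def _draw_categorical(rng: np.random.Generator, table: dict[str, float], size: int
                      ) -> np.ndarray:
    levels = np.array(list(table), dtype=object)
    probs = np.array(list(table.values()), dtype=float)
    return rng.choice(levels, size=size, p=probs / probs.sum())


def generate_population(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate one woman-level table under the configured truth.

    Household-level draws (region, household covariates, bivariate household
    effect) are shared by all women of a household; woman-level covariates and
    residuals are independent across women. Identical ``(config, seed)`` pairs
    reproduce identical tables. ``seed`` overrides ``config.seed`` when given.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (argument or config.seed)")
    rng = np.random.default_rng(int(seed))
    scheme = config.scheme()
    n_hh = config.n_households

    size_table = dict(config.household_women_count_distribution)
    sizes = rng.choice(np.array(list(size_table), dtype=int), size=n_hh,
                       p=np.array(list(size_table.values()), dtype=float))
    n_women = int(sizes.sum())
    hh_index = np.repeat(np.arange(n_hh), sizes)

    regions = _draw_categorical(rng, config.region_assignment_probs, n_hh)

    columns: dict[str, np.ndarray] = {}
    for f in scheme:
        marg = config.covariate_marginals[f.name]
        if f.household_level:
            columns[f.name] = _draw_categorical(rng, marg, n_hh)[hh_index]
        else:
            columns[f.name] = _draw_categorical(rng, marg, n_women)

    h_eff = _sample_mvn(rng, config.varcomp.sigma_h, n_hh)
    resid = _sample_mvn(rng, config.varcomp.sigma_e, n_women)

    frame = pd.DataFrame(columns)
    x, _ = build_design(frame, scheme)
    b1, b2 = config.beta_vectors()
    sbp = x @ b1 + h_eff[hh_index, 0] + resid[:, 0]
    dbp = x @ b2 + h_eff[hh_index, 1] + resid[:, 1]
    ever_told = (rng.random(n_women) < config.ever_told_prob).astype(int)

    out = pd.DataFrame({
        "woman_id": [f"W{i + 1:05d}" for i in range(n_women)],
        "household_id": [f"H{j + 1:05d}" for j in hh_index],
        "region": regions[hh_index],
        "sbp": np.round(sbp, 6),
        "dbp": np.round(dbp, 6),
        "ever_told": ever_told,
    })
    for f in scheme:
        out[f.name] = columns[f.name]
    return out


# ---------------------------------------------------------------------------
# Toy region geometry
# ---------------------------------------------------------------------------

def generate_region_geometry(region_names) -> dict:
    """Deterministic GeoJSON FeatureCollection: one unit square per region.

    Squares are laid out on a grid (row-major, ``ceil(sqrt(k))`` columns) in
    lon/lat degrees, so any standards-compliant reader accepts the output.
    A stand-in for real administrative boundaries; the property ``name``
    carries the region name used for joining.
    """
    names = list(region_names)
    if len(names) == 0:
        raise ValueError("need at least one region name")
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    cols = int(np.ceil(np.sqrt(len(names))))
    features = []
    for i, name in enumerate(names):
        x0, y0 = float(i % cols), float(i // cols)
        ring = [[x0, y0], [x0 + 1.0, y0], [x0 + 1.0, y0 + 1.0], [x0, y0 + 1.0], [x0, y0]]
        features.append({
            "type": "Feature",
            "properties": {"name": name},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return {"type": "FeatureCollection", "features": features}


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

def _config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "n_households": config.n_households,
        "household_women_count_distribution": {
            int(k): float(v) for k, v in config.household_women_count_distribution.items()},
        "covariate_marginals": {k: dict(v) for k, v in config.covariate_marginals.items()},
        "intercepts": [float(x) for x in config.intercepts],
        "beta1": dict(config.beta1),
        "beta2": dict(config.beta2),
        "sigma_h": config.varcomp.sigma_h.tolist(),
        "sigma_e": config.varcomp.sigma_e.tolist(),
        "region_names": list(config.region_names),
        "region_assignment_probs": dict(config.region_assignment_probs),
        "ever_told_prob": config.ever_told_prob,
        "seed": config.seed,
    }


def config_to_yaml(config: GeneratorConfig, path=None) -> str:
    """Serialize a config to YAML (round-trips through :func:`config_from_yaml`)."""
    text = yaml.safe_dump(_config_to_dict(config), sort_keys=False, allow_unicode=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> GeneratorConfig:
    """Load a config from a YAML string or file path."""
    try:
        import os
        is_path = os.path.exists(str(source)) and "\n" not in str(source)
    except (TypeError, ValueError):
        is_path = False
    if is_path:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    return GeneratorConfig(
        n_households=int(raw["n_households"]),
        household_women_count_distribution={
            int(k): float(v)
            for k, v in raw["household_women_count_distribution"].items()},
        covariate_marginals=raw["covariate_marginals"],
        intercepts=tuple(raw["intercepts"]),
        beta1=raw["beta1"],
        beta2=raw["beta2"],
        varcomp=VarianceComponents(
            sigma_h=np.asarray(raw["sigma_h"], dtype=float),
            sigma_e=np.asarray(raw["sigma_e"], dtype=float)),
        region_names=tuple(raw["region_names"]),
        region_assignment_probs=raw.get("region_assignment_probs"),
        ever_told_prob=float(raw.get("ever_told_prob", 0.069)),
        seed=raw.get("seed"),
    )
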