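"""Self-contained synthetic worlds for exercising the attribution pipeline.

Real inputs — adjoint sensitivity fields from a chemical transport model,
SSP/RCP gridded emission inventories, GBD baseline health tables — are
cluster-scale data products. The generator builds a small planet with the
same statistical structure:

* a rectilinear lat-lon grid (default 9 x 12, coarse stand-in for the
  2 deg x 2.5 deg transport-model grid);
* contiguous countries with fractional coastal cells, grouped into
  longitude-banded regions and tagged with synthetic HDI values and GDP
  ranks;
* per-receptor sensitivity kernels that decay with great-circle distance
  from the country's population centroid and, for ``wind_skew > 1``, are
  displaced so that source cells *west* of a receptor contribute more —
  the prevailing-westerlies transport asymmetry;
* scenario emission fields that are cellwise scaled-down copies of a
  baseline inventory, with per-country, per-species reduction fractions;
* monotone concave GBD-like relative-risk breakpoint curves and baseline
  rate/population tables with ordered lower/central/upper bounds.

Everything is reproducible: each ``generate_*`` call derives its own RNG
from ``config.seed`` plus a fixed per-stage salt, so identical configs give
byte-identical outputs and stages can be regenerated independently.

Alongside the data, :class:`SyntheticTruth` records totals planted by
construction (per-receptor domestic/external sensitivity mass and the
pairwise exchange weights under a unit uniform emission change) so that
downstream recovery tests have an oracle that never runs the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import SensitivityField
from .emissions import SPECIES, EmissionScenario
from .errors import ConfigurationError, GenerationError, ValidationError
from .grid import Grid
from .health import BOUNDS, OUTCOMES, RiskModel, RRCurve
from .masks import CountryMaskSet

# Stage salts for deriving independent, reproducible RNG streams.
_SALTS = {"countries": 1, "sensitivities": 2, "scenarios": 3, "health": 4}

#: Kernel amplitude per species, ug m^-3 exposure per Tg yr^-1 emitted at
#: the kernel center. Primary carbonaceous aerosol is more potent per unit
#: mass than secondary-inorganic precursors.
SPECIES_AMPLITUDE = {"BC": 0.050, "OC": 0.040, "NH3": 0.015, "NOx": 0.012, "SO2": 0.020}

#: Baseline global totals per species, Tg yr^-1 (order-of-magnitude
#: anthropogenic totals: NOx/SO2 ~ 1e2, NH3/OC tens, BC a few).
SPECIES_TOTAL_TG = {"BC": 8.0, "OC": 35.0, "NH3": 60.0, "NOx": 110.0, "SO2": 100.0}

AGE_GROUPS = ("25_49", "50_69", "70plus")
_AGE_POP_SHARE = {"25_49": 0.45, "50_69": 0.35, "70plus": 0.20}
_AGE_RATE_MULT = {"25_49": 0.3, "50_69": 1.0, "70plus": 4.0}
_OUTCOME_BASE_RATE = {
    "ihd": 2.0e-3, "stroke": 1.5e-3, "copd": 8.0e-4,
    "lri": 4.0e-4, "lung_cancer": 5.0e-4, "t2d": 3.0e-4,
}


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic planet.

    ``wind_skew`` (>= 1, dimensionless) displaces each receptor's
    sensitivity kernel westward by ``wind_skew - 1`` cells, so 1 means no
    prevailing wind. ``kernel_scale`` is the e-folding decay length of the
    kernels in grid cells.
    """

    n_lat: int = 9
    n_lon: int = 12
    lat_bounds: tuple[float, float] = (-90.0, 90.0)
    lon_bounds: tuple[float, float] = (-180.0, 180.0)
    n_countries: int = 10
    n_regions: int = 3
    seed: int = 0
    wind_skew: float = 2.0
    kernel_scale: float = 2.0
    land_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_lat < 2 or self.n_lon < 2:
            raise ConfigurationError("n_lat and n_lon must be >= 2")
        if self.n_countries < 2:
            raise ConfigurationError("need at least 2 countries")
        if not (1 <= self.n_regions <= self.n_countries):
            raise ConfigurationError("need 1 <= n_regions <= n_countries")
        if self.wind_skew < 1:
            raise ConfigurationError("wind_skew must be >= 1")
        if self.kernel_scale <= 0:
            raise ConfigurationError("kernel_scale must be positive")
        if not (0 < self.land_fraction <= 1):
            raise ConfigurationError("land_fraction must be in (0, 1]")
        if self.lat_bounds[0] >= self.lat_bounds[1] or (
            self.lon_bounds[0] >= self.lon_bounds[1]
        ):
            raise ConfigurationError("degenerate lat/lon bounds")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SALTS[stage]])


@dataclass
class ScenarioSpec:
    """One scenario: a label plus per-country (x species) reduction fractions.

    ``reductions`` may be a scalar (applied to every country and species),
    a mapping country_id -> scalar, or country_id -> {species: fraction};
    ``None`` marks the baseline. Fractions must lie in [0, 1].
    """

    scenario_id: str
    reductions: float | Mapping[str, float | Mapping[str, float]] | None = None

    def reduction(self, country_id: str, species: str) -> float:
        if self.reductions is None:
            return 0.0
        if np.isscalar(self.reductions):
            r = float(self.reductions)
        else:
            entry = self.reductions.get(country_id, 0.0)
            r = float(entry.get(species, 0.0)) if isinstance(entry, Mapping) else float(entry)
        if not 0.0 <= r <= 1.0:
            raise ValidationError(
                f"reduction {r} for ({country_id}, {species}) outside [0, 1]"
            )
        return r


@dataclass
class SyntheticTruth:
    """Totals planted by construction, for recovery tests.

    ``kernel_integrals[(receptor, species)]`` is the sum of the sensitivity
    field over all cells. ``pair_weights`` is a source-country x receptor
    matrix of sensitivity mass (summed over species) falling inside each
    source country; ``domestic``/``external`` split each receptor's total
    mass by its own territory. All are exposures per unit uniform emission
    change, so ratios (e.g. the planted TF = external / total) are what a
    linearized pipeline under a spatially uniform reduction must recover.
    """

    kernel_integrals: dict[tuple[str, str], float]
    pair_weights: pd.DataFrame
    domestic: pd.Series
    external: pd.Series

    def planted_tf(self, receptor: str) -> float:
        tot = self.domestic[receptor] + self.external[receptor]
        return float(self.external[receptor] / tot)


@dataclass
class SyntheticWorld:
    """A complete generated world plus its planted truth."""

    config: WorldConfig
    grid: Grid
    masks: CountryMaskSet
    sensitivities: SensitivityField
    truth: SyntheticTruth
    risk_model: RiskModel
    baseline_exposure: pd.Series  # per-country ug m^-3


def generate_grid(config: WorldConfig) -> Grid:
    """Build the world's rectilinear grid from the config bounds."""
    return Grid.regular(config.n_lat, config.n_lon, config.lat_bounds, config.lon_bounds)


def _neighbors(i: int, j: int, n_lat: int, n_lon: int, wrap: bool):
    if i > 0:
        yield i - 1, j
    if i < n_lat - 1:
        yield i + 1, j
    yield i, (j - 1) % n_lon if wrap else j - 1
    yield i, (j + 1) % n_lon if wrap else j + 1


def generate_countries(grid: Grid, config: WorldConfig) -> CountryMaskSet:
    """Grow contiguous countries on the grid and tag them with attributes.

    Countries are grown by seeded multi-source region growing (4-connected,
    wrapping in longitude when the grid spans the full circle), which makes
    contiguity hold by construction. Interior cells get fraction 1; cells
    bordering unclaimed territory get a fraction in [0.5, 1), standing in
    for fractional coastline masks. Regions are longitude-ordered bands of
    countries; HDI and GDP rank are synthetic draws.
    """
    if config.n_countries > grid.n_cells:
        raise GenerationError("more countries than grid cells")
    rng = config.rng("countries")
    n_lat, n_lon = grid.shape
    wrap = abs((config.lon_bounds[1] - config.lon_bounds[0]) - 360.0) < 1e-9

    target = max(config.n_countries, int(round(config.land_fraction * grid.n_cells)))
    owner = -np.ones(grid.shape, dtype=int)
    flat_seeds = rng.choice(grid.n_cells, size=config.n_countries, replace=False)
    for c, s in enumerate(flat_seeds):
        owner[s // n_lon, s % n_lon] = c
    assigned = config.n_countries
    stall = 0
    while assigned < target and stall < 10 * grid.n_cells:
        c = int(rng.integers(config.n_countries))
        cells = np.argwhere(owner == c)
        frontier = []
        for i, j in cells:
            for ni, nj in _neighbors(int(i), int(j), n_lat, n_lon, wrap):
                if 0 <= nj < n_lon and owner[ni, nj] < 0:
                    frontier.append((ni, nj))
        if not frontier:
            stall += 1
            continue
        ni, nj = frontier[int(rng.integers(len(frontier)))]
        owner[ni, nj] = c
        assigned += 1
        stall = 0
    if assigned < config.n_countries:
        raise GenerationError("could not place all countries")

    fractions = np.zeros((config.n_countries,) + grid.shape)
    for c in range(config.n_countries):
        cells = np.argwhere(owner == c)
        for i, j in cells:
            coastal = any(
                not (0 <= nj < n_lon) or owner[ni, nj] < 0
                for ni, nj in _neighbors(int(i), int(j), n_lat, n_lon, wrap)
            )
            fractions[c, i, j] = rng.uniform(0.5, 1.0) if coastal else 1.0

    ids = [f"C{c:02d}" for c in range(config.n_countries)]
    areas = grid.cell_areas()
    cent_lon = []
    for c in range(config.n_countries):
        w = fractions[c] * areas
        lon_c = np.deg2rad(grid.lon_centers)[None, :]
        x = float((w * np.cos(lon_c)).sum())
        y = float((w * np.sin(lon_c)).sum())
        cent_lon.append(np.rad2deg(np.arctan2(y, x)))
    order = np.argsort(np.asarray(cent_lon), kind="stable")
    region_of = np.empty(config.n_countries, dtype=int)
    splits = np.array_split(order, config.n_regions)
    for r, chunk in enumerate(splits):
        region_of[chunk] = r
    table = pd.DataFrame(
        {
            "country_id": ids,
            "name": [f"Country {c:02d}" for c in range(config.n_countries)],
            "region": [f"R{r:01d}" for r in region_of],
            "hdi": rng.uniform(0.30, 0.95, config.n_countries).round(4),
            "gdp_rank": rng.permutation(config.n_countries) + 1,
        }
    )
    return CountryMaskSet(grid=grid, fractions=fractions, table=table)


def population_centroid(grid: Grid, fraction: np.ndarray) -> tuple[float, float]:
    """Area-and-fraction weighted centroid of a country (deg lat, deg lon).

    Longitude uses the circular mean so countries straddling the antimeridian
    get a sensible center.
    """
    w = fraction * grid.cell_areas()
    if w.sum() <= 0:
        raise ValidationError("country has zero mask weight")
    lat = float((w * grid.lat_centers[:, None]).sum() / w.sum())
    lon_c = np.deg2rad(grid.lon_centers)[None, :]
    lon = float(np.rad2deg(np.arctan2(
        (w * np.sin(lon_c)).sum(), (w * np.cos(lon_c)).sum()
    )))
    return lat, lon


def generate_sensitivities(
    grid: Grid, masks: CountryMaskSet, config: WorldConfig
) -> tuple[SensitivityField, SyntheticTruth]:
    """Gaussian transport kernels per receptor country and species.

    For receptor m, lambda_m(I) = A_k * g_m * exp(-d(I, c*)^2 / (2 sigma^2))
    with d the great-circle distance to the kernel center c*: the
    population centroid displaced ``wind_skew - 1`` cells westward, so
    upwind (western) source cells contribute more when wind_skew > 1 and
    the kernel is symmetric east-west when wind_skew == 1. sigma is
    ``kernel_scale`` cells; A_k is the species amplitude and g_m a mild
    per-receptor lognormal factor.
    """
    rng = config.rng("sensitivities")
    n_lat, n_lon = grid.shape
    dlon_deg = (config.lon_bounds[1] - config.lon_bounds[0]) / n_lon
    dlat_deg = (config.lat_bounds[1] - config.lat_bounds[0]) / n_lat
    sigma_km = config.kernel_scale * 111.0 * 0.5 * (dlat_deg + dlon_deg)

    receptors = masks.country_ids
    lam = np.zeros((len(receptors), len(SPECIES), n_lat, n_lon))
    for m, cid in enumerate(receptors):
        lat0, lon0 = population_centroid(grid, masks.fraction(cid))
        shift = (config.wind_skew - 1.0) * dlon_deg
        lon_center = lon0 - shift
        lon_center = ((lon_center + 180.0) % 360.0) - 180.0
        d = grid.great_circle_km(lat0, lon_center)
        kernel = np.exp(-(d**2) / (2.0 * sigma_km**2))
        g = rng.lognormal(mean=0.0, sigma=0.2)
        for k, sp in enumerate(SPECIES):
            lam[m, k] = SPECIES_AMPLITUDE[sp] * g * kernel

    sens = SensitivityField(
        receptors=list(receptors), species=tuple(SPECIES), values=lam, grid=grid
    )

    integrals = {
        (cid, sp): float(lam[m, k].sum())
        for m, cid in enumerate(receptors)
        for k, sp in enumerate(SPECIES)
    }
    lam_total = lam.sum(axis=1)  # over species
    pair = np.einsum("nij,mij->nm", masks.fractions, lam_total)
    pair_df = pd.DataFrame(pair, index=receptors, columns=receptors)
    totals = lam_total.reshape(len(receptors), -1).sum(axis=1)
    domestic = pd.Series(np.diag(pair), index=receptors)
    external = pd.Series(totals, index=receptors) - domestic
    truth = SyntheticTruth(
        kernel_integrals=integrals,
        pair_weights=pair_df,
        domestic=domestic,
        external=external,
    )
    return sens, truth


def generate_scenarios(
    grid: Grid,
    masks: CountryMaskSet,
    config: WorldConfig,
    scenario_specs: Sequence[ScenarioSpec],
    year: int = 2040,
) -> list[EmissionScenario]:
    """Baseline inventory plus mitigation scenarios as scaled copies.

    The baseline allocates each species' global total across cells in
    proportion to country coverage times lognormal noise, so it is positive
    wherever any country fraction is. A mitigation scenario scales each
    cell by ``1 - rho`` where rho is the mask-weighted mean of the member
    countries' reduction fractions in that cell; unclaimed cell fractions
    are left unreduced.
    """
    base_specs = [s for s in scenario_specs if s.reductions is None]
    if len(base_specs) != 1 or len(scenario_specs) < 2:
        raise ValidationError(
            "scenario_specs must contain exactly one baseline (reductions=None) "
            "and at least one mitigation scenario"
        )
    rng = config.rng("scenarios")
    coverage = masks.coverage()
    noise = rng.lognormal(mean=0.0, sigma=0.5, size=grid.shape)
    weight = coverage * noise
    wsum = weight.sum()
    if wsum <= 0:
        raise GenerationError("no claimed cells to emit from")
    base_values = np.stack(
        [SPECIES_TOTAL_TG[sp] * weight / wsum for sp in SPECIES]
    )

    out = []
    for spec in scenario_specs:
        if spec.reductions is None:
            values = base_values
        else:
            values = np.empty_like(base_values)
            for k, sp in enumerate(SPECIES):
                weighted = np.zeros(grid.shape)
                for cid in masks.country_ids:
                    weighted += masks.fraction(cid) * spec.reduction(cid, sp)
                with np.errstate(invalid="ignore", divide="ignore"):
                    rho = np.where(coverage > 0, weighted / np.maximum(coverage, 1e-300), 0.0)
                values[k] = base_values[k] * (1.0 - rho)
        out.append(
            EmissionScenario(
                scenario_id=spec.scenario_id,
                species=tuple(SPECIES),
                values=values.copy(),
                grid=grid,
                year=year,
            )
        )
    return out


def generate_health_tables(
    masks: CountryMaskSet,
    config: WorldConfig,
    outcomes: Sequence[str] = OUTCOMES,
    age_groups: Sequence[str] = AGE_GROUPS,
    tmrel: float = 4.15,
    year: int = 2040,
) -> tuple[RiskModel, pd.Series]:
    """GBD-like risk model inputs plus baseline exposures per country.

    RR curves are saturating exponentials 1 + a (1 - exp(-(z - tmrel)/b))
    sampled at fixed breakpoints: monotone non-decreasing, concave, RR = 1
    at the TMREL; the lower/central/upper curves scale ``a`` by 0.75/1/1.3
    so the bounds are ordered pointwise. Baseline death rates get 0.8x /
    1.25x bounds; population is shared across countries by lognormal draws.
    Baseline population-weighted exposure is uniform in [15, 60] ug m^-3,
    well above the TMREL.
    """
    rng = config.rng("health")
    breakpoints = np.concatenate([[tmrel], tmrel + np.array([2, 5, 10, 20, 40, 70, 110, 160.0])])
    bound_scale = {"lower": 0.75, "central": 1.0, "upper": 1.3}

    curves: dict[tuple[str, str, str], RRCurve] = {}
    for outcome in outcomes:
        for age in age_groups:
            a = rng.uniform(0.3, 1.5)
            b = rng.uniform(30.0, 80.0)
            shape = 1.0 - np.exp(-(breakpoints - tmrel) / b)
            for bound in BOUNDS:
                curves[(outcome, age, bound)] = RRCurve(
                    exposures=breakpoints, rr=1.0 + bound_scale[bound] * a * shape
                )

    rows = []
    pops = []
    exposures = {}
    for cid in masks.country_ids:
        total_pop = float(rng.lognormal(mean=np.log(4e7), sigma=0.8))
        for age in age_groups:
            pops.append(
                {"country_id": cid, "age_group": age,
                 "pop": total_pop * _AGE_POP_SHARE[age]}
            )
        for outcome in outcomes:
            country_factor = float(rng.lognormal(mean=0.0, sigma=0.3))
            for age in age_groups:
                central = _OUTCOME_BASE_RATE[outcome] * _AGE_RATE_MULT[age] * country_factor
                for bound, mult in (("lower", 0.8), ("central", 1.0), ("upper", 1.25)):
                    rows.append(
                        {"country_id": cid, "outcome": outcome, "age_group": age,
                         "bound": bound, "y0": central * mult}
                    )
        exposures[cid] = float(rng.uniform(15.0, 60.0))

    model = RiskModel(
        curves=curves,
        rates=pd.DataFrame(rows),
        population=pd.DataFrame(pops),
        tmrel=tmrel,
        year=year,
    )
    return model, pd.Series(exposures, name="baseline_exposure")


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate every component of a synthetic world from one config."""
    grid = generate_grid(config)
    masks = generate_countries(grid, config)
    sens, truth = generate_sensitivities(grid, masks, config)
    model, exposure = generate_health_tables(masks, config)
    return SyntheticWorld(
        config=config, grid=grid, masks=masks, sensitivities=sens,
        truth=truth, risk_model=model, baseline_exposure=exposure,
    )
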