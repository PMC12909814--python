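"""GBD-style health impact model for PM2.5 exposure changes.

Premature deaths for a country, outcome and age group follow the
attributable-fraction form

    Mortality = y0 * (1 - 1/RR(z)) * Pop

with RR(z) read from a breakpoint exposure-response table (linear
interpolation between breakpoints, constant beyond the last one, RR = 1 at
and below the theoretical-minimum-risk exposure level TMREL). The
deaths-avoided attribution evaluates this twice per source cell — once at
the receptor's baseline exposure and once with that cell's exposure
contribution removed — and differences the two, per outcome x age group,
then aggregates. Central, lower and upper bounds run the same calculation
with bound-consistent RR curves and baseline rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import ExposureContribution
from .errors import ValidationError
from .grid import Grid

log = logging.getLogger(__name__)

BOUNDS = ("lower", "central", "upper")

#: Mortality outcomes linked to long-term PM2.5 exposure.
OUTCOMES = ("ihd", "stroke", "copd", "lri", "lung_cancer", "t2d")


@dataclass(frozen=True)
class RRCurve:
    """Breakpoint exposure -> relative-risk table for one outcome/age/bound.

    The first breakpoint is the TMREL: RR there must be 1 and exposures
    below it carry no excess risk.
    """

    exposures: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        exposures = np.asarray(self.exposures, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        if exposures.ndim != 1 or exposures.shape != rr.shape or exposures.size < 1:
            raise ValidationError("curve needs matching 1-D exposure/rr arrays")
        if np.any(np.diff(exposures) <= 0):
            raise ValidationError("curve exposures must be strictly ascending")
        if not np.all(np.isfinite(rr)) or rr[0] < 1 - 1e-12 or np.any(rr < 1 - 1e-12):
            raise ValidationError("relative risks must be finite and >= 1")
        if np.any(np.diff(rr) < -1e-12):
            raise ValidationError("relative risks must be non-decreasing")
        object.__setattr__(self, "exposures", exposures)
        object.__setattr__(self, "rr", rr)

    @property
    def tmrel(self) -> float:
        return float(self.exposures[0])


def relative_risk(exposure, curve: RRCurve):
    """Evaluate RR at one or many exposures.

    Linear interpolation between breakpoints; RR = RR(first breakpoint)
    (i.e. 1 when the table starts at TMREL) below the table and constant
    beyond the last breakpoint. Exposures must be non-negative.
    """
    x = np.asarray(exposure, dtype=float)
    if np.any(x < 0):
        raise ValidationError("exposure must be non-negative")
    out = np.interp(x, curve.exposures, curve.rr)
    return float(out) if np.isscalar(exposure) else out


@dataclass
class RiskModel:
    """RR curves plus per-country baseline rates and population.

    Parameters
    ----------
    curves : dict
        (outcome, age_group, bound) -> RRCurve.
    rates : DataFrame
        Columns ``country_id, outcome, age_group, bound, y0`` with y0 the
        baseline death rate (deaths per person-year), projected to ``year``.
    population : DataFrame
        Columns ``country_id, age_group, pop`` (persons), projected to
        ``year``.
    tmrel : float
        Exposure (ug m^-3) below which RR = 1.
    year : int
        Analysis year the rates/population are projected to.
    """

    curves: dict[tuple[str, str, str], RRCurve]
    rates: pd.DataFrame
    population: pd.DataFrame
    tmrel: float = 4.15
    year: int = 2040

    def __post_init__(self) -> None:
        need = {"country_id", "outcome", "age_group", "bound", "y0"}
        if not need.issubset(self.rates.columns):
            raise ValidationError(f"rates table needs columns {sorted(need)}")
        if not {"country_id", "age_group", "pop"}.issubset(self.population.columns):
            raise ValidationError("population table needs country_id, age_group, pop")
        if (self.rates["y0"] < 0).any() or (self.population["pop"] < 0).any():
            raise ValidationError("y0 and pop must be non-negative")
        self._terms_cache: dict[tuple[str, str], list] = {}

    @property
    def countries(self) -> list[str]:
        return sorted(self.population["country_id"].unique())

    @property
    def bounds_present(self) -> tuple[str, ...]:
        return tuple(b for b in BOUNDS if (self.rates["bound"] == b).any())

    def _hazard_terms(self, country: str, bound: str):
        """[(y0 * pop, curve)] over outcome x age for one country/bound."""
        key = (country, bound)
        if key in self._terms_cache:
            return self._terms_cache[key]
        pop = self.population[self.population["country_id"] == country]
        if pop.empty:
            raise ValidationError(f"country {country!r} missing from population")
        pop_by_age = dict(zip(pop["age_group"], pop["pop"]))
        rows = self.rates[
            (self.rates["country_id"] == country) & (self.rates["bound"] == bound)
        ]
        if rows.empty:
            raise ValidationError(
                f"no baseline rates for country {country!r}, bound {bound!r}"
            )
        terms = []
        for _, r in rows.iterrows():
            age = r["age_group"]
            if age not in pop_by_age:
                raise ValidationError(
                    f"age group {age!r} missing from population of {country!r}"
                )
            curve = self.curves.get((r["outcome"], age, bound))
            if curve is None:
                raise ValidationError(
                    f"missing RR curve for {(r['outcome'], age, bound)}"
                )
            terms.append((float(r["y0"]) * float(pop_by_age[age]), curve))
        self._terms_cache[key] = terms
        return terms


def mortality(exposure, model: RiskModel, country: str, bound: str = "central"):
    """PM2.5-attributable deaths per year at a given exposure.

    Sums y0 * (1 - 1/RR(z)) * pop over every outcome x age-group
    combination for the country; vectorized over ``exposure``.
    """
    x = np.asarray(exposure, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for scale, curve in model._hazard_terms(country, bound):
        rr = np.interp(x, curve.exposures, curve.rr)
        out += scale * (1.0 - 1.0 / rr)
    return float(out) if np.isscalar(exposure) else out


@dataclass
class MortalityContribution:
    """Deaths avoided per receptor country and source cell (deaths yr^-1).

    ``values[m, i, j]`` is the marginal co-benefit of cell (i, j)'s
    exposure contribution for receptor m: mortality at the receptor's
    baseline exposure minus mortality with that one cell's contribution
    applied. Positive for emission reductions.
    """

    receptors: list[str]
    values: np.ndarray
    grid: Grid
    scenario_id: str
    baseline_id: str
    bound: str = "central"
    baseline_exposure: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.receptors),) + self.grid.shape
        if self.values.shape != expected:
            raise ValidationError(f"D shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("deaths avoided must be finite")

    def receptor_total(self, receptor: str) -> float:
        return float(self.values[self.receptors.index(receptor)].sum())

    def total(self) -> float:
        return float(self.values.sum())


def deaths_avoided(
    dj: ExposureContribution,
    baseline_exposure: dict[str, float] | pd.Series,
    model: RiskModel,
    bound: str = "central",
) -> MortalityContribution:
    """Per-cell marginal deaths avoided for every receptor country.

    For receptor m with baseline exposure J_m and per-cell contribution
    dJ[m, I] (negative for reductions),

        D[m, I] = mortality(J_m) - mortality(J_m + dJ[m, I])

    so emission reductions yield positive co-benefits. Perturbed exposures
    below zero are clamped at zero with a logged warning. Cells with
    dJ = 0 yield exactly 0.
    """
    base = dict(baseline_exposure)
    n = len(dj.receptors)
    out = np.zeros_like(dj.values)
    for m, receptor in enumerate(dj.receptors):
        if receptor not in base:
            raise ValidationError(f"no baseline exposure for receptor {receptor!r}")
        jm = float(base[receptor])
        perturbed = jm + dj.values[m]
        if np.any(perturbed < 0):
            log.warning(
                "receptor %s: %d perturbed exposures below 0 clamped",
                receptor, int((perturbed < 0).sum()),
            )
            perturbed = np.clip(perturbed, 0.0, None)
        m0 = mortality(jm, model, receptor, bound)
        d = m0 - mortality(perturbed, model, receptor, bound)
        d[dj.values[m] == 0.0] = 0.0
        out[m] = d
    return MortalityContribution(
        receptors=list(dj.receptors),
        values=out,
        grid=dj.grid,
        scenario_id=dj.scenario_id,
        baseline_id=dj.baseline_id,
        bound=bound,
        baseline_exposure={r: float(base[r]) for r in dj.receptors},
    )


def joint_deaths_avoided(
    dj: ExposureContribution,
    baseline_exposure: dict[str, float] | pd.Series,
    model: RiskModel,
    bound: str = "central",
) -> pd.Series:
    """Deaths avoided per receptor when all cells are removed jointly.

    Evaluates mortality at J_m and at J_m + sum_I dJ[m, I]. Differs from
    the cellwise-summed marginal co-benefits by the curvature of the RR
    curve (the non-additivity residual); identical when RR is locally
    linear over the perturbation.
    """
    base = dict(baseline_exposure)
    vals = {}
    for m, receptor in enumerate(dj.receptors):
        jm = float(base[receptor])
        total = max(jm + float(dj.values[m].sum()), 0.0)
        vals[receptor] = mortality(jm, model, receptor, bound) - mortality(
            total, model, receptor, bound
        )
    return pd.Series(vals, name="joint_deaths_avoided")


def nonadditivity(
    dj: ExposureContribution,
    baseline_exposure: dict[str, float] | pd.Series,
    model: RiskModel,
    bound: str = "central",
) -> pd.DataFrame:
    """Marginal-sum vs joint-removal deaths avoided per receptor."""
    marginal = deaths_avoided(dj, baseline_exposure, model, bound)
    joint = joint_deaths_avoided(dj, baseline_exposure, model, bound)
    rows = []
    for receptor in dj.receptors:
        ms = marginal.receptor_total(receptor)
        js = float(joint[receptor])
        rows.append(
            {
                "receptor": receptor,
                "marginal_sum": ms,
                "joint": js,
                "residual": ms - js,
            }
        )
    return pd.DataFrame(rows).set_index("receptor")


def uncertainty_passes(
    dj: ExposureContribution,
    baseline_exposure: dict[str, float] | pd.Series,
    model: RiskModel,
    bounds: tuple[str, ...] = BOUNDS,
) -> dict[str, MortalityContribution]:
    """Full deaths-avoided evaluation at each uncertainty bound.

    Each bound uses its own RR curves and baseline rates. A bound absent
    from the model falls back to the central inputs with a warning.
    """
    present = set(model.bounds_present)
    out = {}
    for bound in bounds:
        use = bound
        if bound not in present:
            warnings.warn(
                f"bound {bound!r} missing from risk model; using central",
                stacklevel=2,
            )
            use = "central"
        result = deaths_avoided(dj, baseline_exposure, model, use)
        result.bound = bound
        out[bound] = result
    return out
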