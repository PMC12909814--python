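"""Scenario emission fields: sector aggregation, conservative regridding,
and scenario-minus-baseline deltas.

Emission values are stored as annual mass per cell (Tg yr^-1 per cell),
never as flux density, so conservation checks are plain sums. Readers of
flux-density datasets must multiply by cell area before constructing an
:class:`EmissionScenario`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .grid import Grid

#: Precursor species of PM2.5 tracked throughout the pipeline.
SPECIES = ("BC", "OC", "NH3", "NOx", "SO2")

#: Sectors aggregated by default: all anthropogenic non-biomass-burning.
DEFAULT_SECTORS = (
    "agriculture",
    "aviation",
    "residential_commercial",
    "power_plants",
    "industry",
    "international_shipping",
    "solvents",
    "surface_transportation",
    "waste",
)

#: Biomass-burning sectors, excluded by default but accepted if explicitly
#: passed in an include list.
BIOMASS_SECTORS = (
    "agricultural_waste_burning",
    "deforestation",
    "savanna_burning",
)

KNOWN_SECTORS = DEFAULT_SECTORS + BIOMASS_SECTORS


def _check_species(species: Sequence[str]) -> tuple[str, ...]:
    unknown = set(species) - set(SPECIES)
    if unknown:
        raise ValidationError(f"unknown species {sorted(unknown)}; expected {SPECIES}")
    return tuple(species)


@dataclass
class EmissionScenario:
    """Gridded annual emissions for one scenario and year.

    ``values`` has shape (n_species, n_lat, n_lon) in Tg yr^-1 per cell,
    with the leading axis ordered like ``species``.
    """

    scenario_id: str
    species: tuple[str, ...]
    values: np.ndarray
    grid: Grid
    year: int = 2040

    def __post_init__(self) -> None:
        self.species = _check_species(self.species)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.species),) + self.grid.shape
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("emission values must be finite")
        if self.values.min() < 0:
            raise ValidationError("emission values must be non-negative")

    def total(self, species: str | None = None) -> float:
        """Global total in Tg yr^-1, optionally for one species."""
        if species is None:
            return float(self.values.sum())
        return float(self.values[self.species.index(species)].sum())

    def field(self, species: str) -> np.ndarray:
        if species not in self.species:
            raise ValidationError(f"species {species!r} not in scenario")
        return self.values[self.species.index(species)]


@dataclass
class EmissionDelta:
    """Cellwise signed difference of a scenario against the baseline."""

    scenario_id: str
    baseline_id: str
    species: tuple[str, ...]
    values: np.ndarray  # (n_species, n_lat, n_lon), Tg yr^-1, signed
    grid: Grid
    year: int = 2040

    def __post_init__(self) -> None:
        self.species = _check_species(self.species)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.species),) + self.grid.shape
        if self.values.shape != expected:
            raise ValidationError(f"delta shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("emission delta must be finite")

    def field(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]


def aggregate_sectors(
    raw_fields: Mapping[str, np.ndarray],
    include: Iterable[str] = DEFAULT_SECTORS,
    *,
    scenario_id: str = "aggregate",
    species: Sequence[str] = SPECIES,
    grid: Grid | None = None,
    year: int = 2040,
) -> EmissionScenario:
    """Sum per-sector fields into one scenario field.

    ``raw_fields`` maps sector name -> array of shape
    (n_species, n_lat, n_lon). Sectors in ``include`` but absent from
    ``raw_fields`` are treated as zero only if they are known sector names;
    unknown names raise. The default include list covers the nine
    anthropogenic non-biomass-burning sectors; biomass-burning sectors are
    excluded by default but summed like any other if explicitly included.
    """
    include = list(include)
    unknown = [s for s in include if s not in KNOWN_SECTORS]
    if unknown:
        raise ValidationError(f"unknown sector(s) {unknown}; known: {KNOWN_SECTORS}")
    unknown_raw = [s for s in raw_fields if s not in KNOWN_SECTORS]
    if unknown_raw:
        raise ValidationError(f"unknown sector(s) in input {unknown_raw}")
    if grid is None:
        raise ValidationError("aggregate_sectors requires the target grid")
    shape = (len(species),) + grid.shape
    total = np.zeros(shape)
    for sector in include:
        if sector not in raw_fields:
            continue
        arr = np.asarray(raw_fields[sector], dtype=float)
        if arr.shape != shape:
            raise ValidationError(
                f"sector {sector!r} field shape {arr.shape} != {shape}"
            )
        total += arr
    return EmissionScenario(
        scenario_id=scenario_id, species=tuple(species), values=total,
        grid=grid, year=year,
    )


def _interval_overlap(edges_src: np.ndarray, edges_dst: np.ndarray) -> np.ndarray:
    """Pairwise overlap lengths between 1-D source and target cell intervals.

    Returns an (n_dst, n_src) matrix of intersection lengths, using the
    half-open west/south-inclusive convention (zero-length touches count 0).
    """
    lo = np.maximum(edges_dst[:-1, None], edges_src[None, :-1])
    hi = np.minimum(edges_dst[1:, None], edges_src[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid_conservative(
    values: np.ndarray,
    source: Grid,
    target: Grid,
    country_mask: np.ndarray | None = None,
) -> np.ndarray:
    """First-order conservative regridding of a per-cell mass field.

    Each source cell's mass is split among target cells in proportion to the
    fractional *area* overlap (latitude overlap measured in sin(lat) so the
    split is areally exact on the sphere). When ``country_mask`` is given
    (fractions on the source grid), the field is multiplied by the mask
    before regridding, mirroring a per-country regrid of the inventory.

    Total mass is conserved exactly (up to float rounding) whenever the
    target grid covers the source grid.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-2:] != source.shape:
        raise ValidationError(
            f"field shape {values.shape} does not match source grid {source.shape}"
        )
    if country_mask is not None:
        country_mask = np.asarray(country_mask, dtype=float)
        if country_mask.shape != source.shape:
            raise ValidationError("country mask must live on the source grid")
        values = values * country_mask

    # Latitude overlap in sin(lat) so that shares are proportional to area.
    w_lat = _interval_overlap(
        np.sin(np.deg2rad(source.lat_edges)), np.sin(np.deg2rad(target.lat_edges))
    )
    w_lon = _interval_overlap(source.lon_edges, target.lon_edges)
    if w_lat.sum() == 0 or w_lon.sum() == 0:
        raise ValidationError("source and target grids do not overlap")

    # Normalize per *source* cell so each source cell distributes its mass.
    src_lat = np.diff(np.sin(np.deg2rad(source.lat_edges)))
    src_lon = np.diff(source.lon_edges)
    w_lat = w_lat / src_lat[None, :]
    w_lon = w_lon / src_lon[None, :]

    if values.ndim == 2:
        return w_lat @ values @ w_lon.T
    out = np.einsum("ai,...ij,bj->...ab", w_lat, values, w_lon)
    return out


def scenario_delta(
    scenario: EmissionScenario, baseline: EmissionScenario
) -> EmissionDelta:
    """Cellwise ``scenario - baseline`` emission difference."""
    if not scenario.grid.matches(baseline.grid):
        raise ValidationError("scenario and baseline grids differ")
    if scenario.species != baseline.species:
        raise ValidationError("scenario and baseline species differ")
    if scenario.year != baseline.year:
        raise ValidationError("scenario and baseline years differ")
    return EmissionDelta(
        scenario_id=scenario.scenario_id,
        baseline_id=baseline.scenario_id,
        species=scenario.species,
        values=scenario.values - baseline.values,
        grid=scenario.grid,
        year=scenario.year,
    )
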