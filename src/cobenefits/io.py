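"""File formats: CF-style NetCDF for gridded fields, CSV for tables.

NetCDF files carry cell-center ``lat``/``lon`` coordinates plus explicit
``lat_edges``/``lon_edges`` variables so grids round-trip exactly. All
files are NETCDF3 (scipy backend), which keeps them plain and portable.
Health tables use the flat CSV schemas that GBD exports map onto:
``rates.csv`` (country_id, outcome, age_group, bound, y0, pop),
``rr_curves.csv`` (outcome, age_group, bound, exposure, rr) and
``baseline_exposure.csv`` (country_id, exposure).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .attribution import ContributionMatrix, ExposureContribution, SensitivityField
from .emissions import EmissionDelta, EmissionScenario
from .errors import ValidationError
from .grid import Grid
from .health import MortalityContribution, RiskModel, RRCurve
from .masks import CountryMaskSet

_ENGINE = "scipy"


def _grid_coords(grid: Grid) -> dict:
    return {
        "lat": ("lat", grid.lat_centers),
        "lon": ("lon", grid.lon_centers),
        "lat_edges": ("lat_edge", grid.lat_edges),
        "lon_edges": ("lon_edge", grid.lon_edges),
    }


def _grid_from(ds: xr.Dataset) -> Grid:
    if "lat_edges" not in ds or "lon_edges" not in ds:
        raise ValidationError("file lacks lat_edges/lon_edges grid variables")
    return Grid(lat_edges=ds["lat_edges"].values, lon_edges=ds["lon_edges"].values)


def write_scenario(path: str | Path, scenario: EmissionScenario) -> None:
    ds = xr.Dataset(
        {"emissions": (("species", "lat", "lon"), scenario.values)},
        coords={"species": list(scenario.species), **_grid_coords(scenario.grid)},
        attrs={
            "units": "Tg yr-1 per cell",
            "scenario_id": scenario.scenario_id,
            "year": scenario.year,
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_scenario(path: str | Path) -> EmissionScenario:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return EmissionScenario(
        scenario_id=str(ds.attrs["scenario_id"]),
        species=tuple(str(s) for s in ds["species"].values),
        values=ds["emissions"].values,
        grid=_grid_from(ds),
        year=int(ds.attrs["year"]),
    )


def write_delta(path: str | Path, delta: EmissionDelta) -> None:
    ds = xr.Dataset(
        {"delta": (("species", "lat", "lon"), delta.values)},
        coords={"species": list(delta.species), **_grid_coords(delta.grid)},
        attrs={
            "units": "Tg yr-1 per cell",
            "scenario_id": delta.scenario_id,
            "baseline_id": delta.baseline_id,
            "year": delta.year,
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_delta(path: str | Path) -> EmissionDelta:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return EmissionDelta(
        scenario_id=str(ds.attrs["scenario_id"]),
        baseline_id=str(ds.attrs["baseline_id"]),
        species=tuple(str(s) for s in ds["species"].values),
        values=ds["delta"].values,
        grid=_grid_from(ds),
        year=int(ds.attrs["year"]),
    )


def write_sensitivities(path: str | Path, sens: SensitivityField) -> None:
    ds = xr.Dataset(
        {"lambda_": (("receptor", "species", "lat", "lon"), sens.values)},
        coords={
            "receptor": list(sens.receptors),
            "species": list(sens.species),
            **_grid_coords(sens.grid),
        },
        attrs={"units": "ug m-3 per Tg yr-1"},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_sensitivities(path: str | Path) -> SensitivityField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return SensitivityField(
        receptors=[str(r) for r in ds["receptor"].values],
        species=tuple(str(s) for s in ds["species"].values),
        values=ds["lambda_"].values,
        grid=_grid_from(ds),
    )


def write_masks(nc_path: str | Path, csv_path: str | Path, masks: CountryMaskSet) -> None:
    ds = xr.Dataset(
        {"fraction": (("country", "lat", "lon"), masks.fractions)},
        coords={"country": masks.country_ids, **_grid_coords(masks.grid)},
    )
    ds.to_netcdf(nc_path, engine=_ENGINE)
    masks.table.to_csv(csv_path, index=False)


def read_masks(nc_path: str | Path, csv_path: str | Path) -> CountryMaskSet:
    with xr.open_dataset(nc_path, engine=_ENGINE) as ds:
        ds.load()
    table = pd.read_csv(csv_path)
    return CountryMaskSet(grid=_grid_from(ds), fractions=ds["fraction"].values, table=table)


def _write_contrib(path, values, receptors, grid, attrs, var) -> None:
    ds = xr.Dataset(
        {var: (("receptor", "lat", "lon"), values)},
        coords={"receptor": list(receptors), **_grid_coords(grid)},
        attrs=attrs,
    )
    ds.to_netcdf(path, engine=_ENGINE)


def write_exposure_contribution(path: str | Path, dj: ExposureContribution) -> None:
    _write_contrib(
        path, dj.values, dj.receptors, dj.grid,
        {"units": "ug m-3", "scenario_id": dj.scenario_id,
         "baseline_id": dj.baseline_id},
        "delta_exposure",
    )


def read_exposure_contribution(path: str | Path) -> ExposureContribution:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return ExposureContribution(
        receptors=[str(r) for r in ds["receptor"].values],
        values=ds["delta_exposure"].values,
        grid=_grid_from(ds),
        scenario_id=str(ds.attrs["scenario_id"]),
        baseline_id=str(ds.attrs["baseline_id"]),
    )


def write_mortality_contribution(path: str | Path, d: MortalityContribution) -> None:
    _write_contrib(
        path, d.values, d.receptors, d.grid,
        {"units": "deaths yr-1", "scenario_id": d.scenario_id,
         "baseline_id": d.baseline_id, "bound": d.bound},
        "deaths_avoided",
    )


def read_mortality_contribution(path: str | Path) -> MortalityContribution:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return MortalityContribution(
        receptors=[str(r) for r in ds["receptor"].values],
        values=ds["deaths_avoided"].values,
        grid=_grid_from(ds),
        scenario_id=str(ds.attrs["scenario_id"]),
        baseline_id=str(ds.attrs["baseline_id"]),
        bound=str(ds.attrs["bound"]),
    )


def write_matrix(path: str | Path, matrix: ContributionMatrix) -> None:
    long = (
        matrix.values.rename_axis("source")
        .reset_index()
        .melt(id_vars="source", var_name="receptor", value_name="value")
    )
    long.to_csv(path, index=False)


def read_matrix(path: str | Path, quantity: str = "deaths") -> ContributionMatrix:
    long = pd.read_csv(path)
    wide = long.pivot(index="source", columns="receptor", values="value")
    wide.index.name = None
    wide.columns.name = None
    return ContributionMatrix(values=wide, quantity=quantity)


def write_field_csv(path: str | Path, field: np.ndarray) -> None:
    """CSV fallback for one 2-D gridded field: lat_index, lon_index, value."""
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValidationError("CSV fallback handles 2-D fields only")
    ii, jj = np.indices(field.shape)
    pd.DataFrame(
        {"lat_index": ii.ravel(), "lon_index": jj.ravel(), "value": field.ravel()}
    ).to_csv(path, index=False)


def read_field_csv(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    df = pd.read_csv(path)
    out = np.zeros(shape)
    out[df["lat_index"].to_numpy(), df["lon_index"].to_numpy()] = df["value"].to_numpy()
    return out


def write_health_tables(
    out_dir: str | Path, model: RiskModel, baseline_exposure: pd.Series
) -> dict[str, Path]:
    """Write rates.csv, rr_curves.csv and baseline_exposure.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rates = model.rates.merge(model.population, on=["country_id", "age_group"])
    paths = {
        "rates": out_dir / "rates.csv",
        "rr_curves": out_dir / "rr_curves.csv",
        "baseline_exposure": out_dir / "baseline_exposure.csv",
    }
    rates.to_csv(paths["rates"], index=False)
    rows = []
    for (outcome, age, bound), curve in sorted(model.curves.items()):
        for z, rr in zip(curve.exposures, curve.rr):
            rows.append(
                {"outcome": outcome, "age_group": age, "bound": bound,
                 "exposure": z, "rr": rr}
            )
    pd.DataFrame(rows).to_csv(paths["rr_curves"], index=False)
    baseline_exposure.rename_axis("country_id").rename("exposure").reset_index().to_csv(
        paths["baseline_exposure"], index=False
    )
    return paths


def read_health_tables(
    in_dir: str | Path, tmrel: float | None = None, year: int = 2040
) -> tuple[RiskModel, pd.Series]:
    in_dir = Path(in_dir)
    rates = pd.read_csv(in_dir / "rates.csv")
    rr = pd.read_csv(in_dir / "rr_curves.csv")
    exposure = pd.read_csv(in_dir / "baseline_exposure.csv").set_index("country_id")[
        "exposure"
    ]
    curves = {}
    for (outcome, age, bound), grp in rr.groupby(["outcome", "age_group", "bound"]):
        grp = grp.sort_values("exposure")
        curves[(outcome, age, bound)] = RRCurve(
            exposures=grp["exposure"].to_numpy(), rr=grp["rr"].to_numpy()
        )
    if tmrel is None:
        tmrel = float(min(c.tmrel for c in curves.values()))
    population = rates[["country_id", "age_group", "pop"]].drop_duplicates(
        subset=["country_id", "age_group"]
    )
    model = RiskModel(
        curves=curves,
        rates=rates[["country_id", "outcome", "age_group", "bound", "y0"]],
        population=population,
        tmrel=tmrel,
        year=year,
    )
    return model, exposure
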