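"""Fractional country masks on a lat-lon grid.

A mask set assigns each grid cell a fraction in [0, 1] per country; the
per-cell sum over countries may be below 1 (the remainder is ocean or
otherwise unclaimed territory, which downstream attribution reports as an
explicit "unattributed" pseudo-source rather than dropping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import Grid

#: Pseudo-source label for emissions in cells not claimed by any country.
UNATTRIBUTED = "__unattributed__"

_TABLE_COLUMNS = ["country_id", "name", "region", "hdi", "gdp_rank"]


@dataclass
class CountryMaskSet:
    """Per-country fractional masks plus the country attribute table.

    Parameters
    ----------
    grid : Grid
        The grid the fractions are defined on.
    fractions : ndarray, shape (n_countries, n_lat, n_lon)
        Fraction of each cell belonging to each country.
    table : DataFrame
        One row per country with columns ``country_id, name, region, hdi,
        gdp_rank``; row order matches the leading axis of ``fractions``.
    """

    grid: Grid
    fractions: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 3 or self.fractions.shape[1:] != self.grid.shape:
            raise ValidationError(
                f"fractions shape {self.fractions.shape} does not match "
                f"(n_countries, {self.grid.n_lat}, {self.grid.n_lon})"
            )
        if not np.all(np.isfinite(self.fractions)):
            raise ValidationError("mask fractions must be finite")
        if self.fractions.min() < 0 or self.fractions.max() > 1 + 1e-12:
            raise ValidationError("mask fractions must lie in [0, 1]")
        if np.any(self.fractions.sum(axis=0) > 1 + 1e-9):
            raise ValidationError("per-cell mask fractions must sum to <= 1")
        missing = [c for c in _TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"country table missing columns {missing}")
        if len(self.table) != self.fractions.shape[0]:
            raise ValidationError("country table length != number of masks")
        self.table = self.table.reset_index(drop=True)

    @property
    def country_ids(self) -> list[str]:
        return list(self.table["country_id"])

    @property
    def n_countries(self) -> int:
        return len(self.table)

    def index_of(self, country_id: str) -> int:
        ids = self.country_ids
        try:
            return ids.index(country_id)
        except ValueError:
            raise ValidationError(f"unknown country {country_id!r}") from None

    def fraction(self, country_id: str) -> np.ndarray:
        return self.fractions[self.index_of(country_id)]

    def coverage(self) -> np.ndarray:
        """Per-cell total country fraction (1 - coverage is unattributed)."""
        return self.fractions.sum(axis=0)

    def group_fraction(self, members: list[str]) -> np.ndarray:
        """Combined fraction field of a set of countries (e.g. a region)."""
        if not members:
            raise ValidationError("empty country group")
        idx = [self.index_of(c) for c in members]
        return self.fractions[idx].sum(axis=0)

    def region_members(self, region: str) -> list[str]:
        sel = self.table.loc[self.table["region"] == region, "country_id"]
        if sel.empty:
            raise ValidationError(f"unknown region {region!r}")
        return list(sel)

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())
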