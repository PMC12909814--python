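"""Source-receptor attribution of exposure changes.

The receptor-side sensitivity field lambda gives the linearized response of
a country's population-weighted PM2.5 exposure (ug m^-3) to annual
precursor emissions (Tg yr^-1) in each grid cell. Contracting it with a
scenario emission delta yields the per-source-cell contribution to each
receptor's exposure change; summing cells against fractional country masks
yields a source-country x receptor-country contribution matrix, with an
explicit "unattributed" row collecting ocean / unclaimed-cell fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emissions import EmissionDelta, _check_species
from .errors import ValidationError
from .grid import Grid
from .masks import UNATTRIBUTED, CountryMaskSet


@dataclass
class SensitivityField:
    """Adjoint-style sensitivities lambda[receptor, species, lat, lon].

    Units: ug m^-3 of receptor population-weighted exposure per Tg yr^-1
    emitted in the source cell.
    """

    receptors: list[str]
    species: tuple[str, ...]
    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        if not self.receptors:
            raise ValidationError("receptor list must be non-empty")
        self.species = _check_species(self.species)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.receptors), len(self.species)) + self.grid.shape
        if self.values.shape != expected:
            raise ValidationError(
                f"lambda shape {self.values.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("sensitivities must be finite")

    def for_receptor(self, receptor: str) -> np.ndarray:
        try:
            i = self.receptors.index(receptor)
        except ValueError:
            raise ValidationError(f"unknown receptor {receptor!r}") from None
        return self.values[i]


@dataclass
class ExposureContribution:
    """Per-cell contribution dJ[receptor, lat, lon] to exposure change.

    Signed, in ug m^-3; negative values are improvements (emission cuts).
    """

    receptors: list[str]
    values: np.ndarray
    grid: Grid
    scenario_id: str
    baseline_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.receptors),) + self.grid.shape
        if self.values.shape != expected:
            raise ValidationError(f"dJ shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("contributions must be finite")

    def receptor_total(self, receptor: str) -> float:
        i = self.receptors.index(receptor)
        return float(self.values[i].sum())


@dataclass
class ContributionMatrix:
    """Source-country x receptor-country contribution totals.

    ``values`` is a DataFrame indexed by source (country ids plus the
    ``__unattributed__`` pseudo-source) with receptor-country columns.
    The diagonal entries are domestic contributions.
    """

    values: pd.DataFrame
    quantity: str = "exposure"  # or "deaths"
    scenario_id: str = ""
    bound: str = "central"

    @property
    def sources(self) -> list[str]:
        return list(self.values.index)

    @property
    def receptors(self) -> list[str]:
        return list(self.values.columns)

    def lookup(self, source: str, receptor: str) -> float:
        if source not in self.values.index:
            raise ValidationError(f"unknown source {source!r}")
        if receptor not in self.values.columns:
            raise ValidationError(f"unknown receptor {receptor!r}")
        return float(self.values.loc[source, receptor])

    def receptor_total(self, receptor: str) -> float:
        return float(self.values[receptor].sum())

    def domestic(self, receptor: str) -> float:
        return self.lookup(receptor, receptor)

    def unattributed(self, receptor: str) -> float:
        return self.lookup(UNATTRIBUTED, receptor)


def attribute_exposure(
    lam: SensitivityField, delta: EmissionDelta
) -> ExposureContribution:
    """Contract sensitivities with an emission delta.

    dJ[m, I] = sum_k lambda[m, k, I] * dE[k, I]; exactly linear in the
    delta, so per-cell contributions sum to the receptor's total exposure
    change.
    """
    if not lam.grid.matches(delta.grid):
        raise ValidationError("sensitivity and delta grids differ")
    if set(lam.species) != set(delta.species):
        raise ValidationError(
            f"species mismatch: {lam.species} vs {delta.species}"
        )
    order = [delta.species.index(k) for k in lam.species]
    d = delta.values[order]
    dj = np.einsum("mkij,kij->mij", lam.values, d)
    return ExposureContribution(
        receptors=list(lam.receptors),
        values=dj,
        grid=lam.grid,
        scenario_id=delta.scenario_id,
        baseline_id=delta.baseline_id,
    )


def aggregate_sources(
    contrib, masks: CountryMaskSet, quantity: str = "exposure",
    bound: str = "central",
) -> ContributionMatrix:
    """Sum per-cell contributions into a source-country x receptor matrix.

    Accepts any per-cell contribution object with ``receptors``, ``values``
    of shape (n_receptors, n_lat, n_lon) and ``grid`` (exposure or deaths).
    Fractional cells split proportionally to the mask fractions; the
    remainder of each cell goes to the ``__unattributed__`` pseudo-source so
    column sums reproduce receptor totals exactly.
    """
    if not masks.grid.matches(contrib.grid):
        raise ValidationError("mask grid does not match contribution grid")
    field = contrib.values  # (m, lat, lon)
    by_country = np.einsum("nij,mij->nm", masks.fractions, field)
    residual_frac = 1.0 - masks.coverage()
    unatt = np.einsum("ij,mij->m", residual_frac, field)
    values = pd.DataFrame(
        np.vstack([by_country, unatt[None, :]]),
        index=masks.country_ids + [UNATTRIBUTED],
        columns=list(contrib.receptors),
    )
    return ContributionMatrix(
        values=values,
        quantity=quantity,
        scenario_id=getattr(contrib, "scenario_id", ""),
        bound=bound,
    )
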