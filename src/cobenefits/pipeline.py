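"""End-to-end orchestration: world -> deltas -> attribution -> health ->
inequality metrics, with a manifest for reproducibility.

A run is described by a declarative :class:`RunConfig` (typically a YAML
file). Every stage is deterministic given the config seed, so rerunning
the same config reproduces identical outputs; the manifest records the
config hash, seed and a sha256 checksum of every file written. A
conservation audit (source aggregation vs receptor totals) runs on every
scenario/bound and aborts the run if the residual exceeds tolerance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .attribution import aggregate_sources, attribute_exposure
from .emissions import scenario_delta
from .errors import AuditError, ConfigurationError, ValidationError
from .health import BOUNDS, deaths_avoided
from .masks import UNATTRIBUTED
from .metrics import build_report
from .synthetic import ScenarioSpec, SyntheticWorld, WorldConfig, generate_scenarios, generate_world

log = logging.getLogger(__name__)

CONSERVATION_TOL = 1e-10


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    baseline_id: str = "baseline"
    year: int = 2040
    bounds: tuple[str, ...] = BOUNDS
    out_dir: str = "run_output"
    strata_k: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.scenarios:
            self.scenarios = default_scenarios(self.world)
        ids = [s.scenario_id for s in self.scenarios]
        if self.baseline_id not in ids:
            raise ConfigurationError(
                f"baseline_id {self.baseline_id!r} not among scenarios {ids}"
            )
        base = next(s for s in self.scenarios if s.scenario_id == self.baseline_id)
        if base.reductions is not None:
            raise ConfigurationError("the baseline scenario must have no reductions")
        bad = [b for b in self.bounds if b not in BOUNDS]
        if bad:
            raise ConfigurationError(f"unknown bounds {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        world = WorldConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in dict(raw.get("world", {})).items()
        })
        scenarios = [
            ScenarioSpec(scenario_id=s["scenario_id"], reductions=s.get("reductions"))
            for s in raw.get("scenarios", [])
        ]
        return cls(
            world=world,
            scenarios=scenarios,
            baseline_id=raw.get("baseline_id", "baseline"),
            year=int(raw.get("year", 2040)),
            bounds=tuple(raw.get("bounds", BOUNDS)),
            out_dir=str(raw.get("out_dir", "run_output")),
            strata_k=raw.get("strata_k"),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def to_dict(self) -> dict:
        return {
            "world": {
                "n_lat": self.world.n_lat, "n_lon": self.world.n_lon,
                "lat_bounds": list(self.world.lat_bounds),
                "lon_bounds": list(self.world.lon_bounds),
                "n_countries": self.world.n_countries,
                "n_regions": self.world.n_regions,
                "seed": self.world.seed,
                "wind_skew": self.world.wind_skew,
                "kernel_scale": self.world.kernel_scale,
                "land_fraction": self.world.land_fraction,
            },
            "scenarios": [
                {"scenario_id": s.scenario_id, "reductions": s.reductions}
                for s in self.scenarios
            ],
            "baseline_id": self.baseline_id,
            "year": self.year,
            "bounds": list(self.bounds),
            "out_dir": self.out_dir,
            "strata_k": self.strata_k,
            "log_level": self.log_level,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()


def default_scenarios(world: WorldConfig) -> list[ScenarioSpec]:
    """A baseline plus two mitigation scenarios of increasing ambition.

    The 'strong' scenario cuts 60% of every country's emissions; the
    'moderate' one cuts 25%. Stand-ins for deep- and weak-mitigation
    futures differenced against a no-mitigation baseline.
    """
    return [
        ScenarioSpec("baseline", None),
        ScenarioSpec("moderate", 0.25),
        ScenarioSpec("strong", 0.60),
    ]


def audit_conservation(matrix, deaths) -> float:
    """Max relative residual between matrix column sums and receptor totals."""
    worst = 0.0
    for receptor in matrix.receptors:
        total = deaths.receptor_total(receptor)
        col = matrix.receptor_total(receptor)
        scale = max(abs(total), 1e-300)
        worst = max(worst, abs(col - total) / scale)
    return worst


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage, write outputs and return the manifest dict.

    Writes per-scenario/bound tf/exc/strata tables, a cross-scenario
    summary, the synthetic-world inputs, a comparison table against the
    first mitigation scenario, and ``manifest.json``.
    """
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    world = generate_world(config.world)
    scenarios = generate_scenarios(
        world.grid, world.masks, config.world, config.scenarios, year=config.year
    )
    by_id = {s.scenario_id: s for s in scenarios}
    baseline = by_id[config.baseline_id]

    written: list[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path)
        written.append(path)

    cio.write_sensitivities(out / "sensitivities.nc", world.sensitivities)
    cio.write_masks(out / "masks.nc", out / "countries.csv", world.masks)
    for p in cio.write_health_tables(out, world.risk_model, world.baseline_exposure).values():
        written.append(Path(p))
    written += [out / "sensitivities.nc", out / "masks.nc", out / "countries.csv"]

    summaries = []
    reports: dict[str, dict[str, object]] = {}
    for sid, scen in by_id.items():
        if sid == config.baseline_id:
            continue
        stage_t = time.time()
        delta = scenario_delta(scen, baseline)
        dj = attribute_exposure(world.sensitivities, delta)
        reports[sid] = {}
        for bound in config.bounds:
            deaths = deaths_avoided(
                dj, world.baseline_exposure, world.risk_model, bound
            )
            matrix = aggregate_sources(deaths, world.masks, quantity="deaths", bound=bound)
            residual = audit_conservation(matrix, deaths)
            if residual > CONSERVATION_TOL:
                raise AuditError(
                    f"conservation residual {residual:.3e} exceeds "
                    f"{CONSERVATION_TOL:.1e} for scenario {sid}, bound {bound}"
                )
            report = build_report(deaths, matrix, world.masks, k=config.strata_k)
            reports[sid][bound] = report
            tag = f"{sid}_{bound}"
            _write(f"tf_{tag}.csv", report.tf)
            _write(f"tf_regional_{tag}.csv", report.regional_tf)
            _write(f"exc_{tag}.csv", report.pairs.set_index(["source", "receptor"]))
            _write(f"strata_{tag}.csv", report.strata)
            summaries.append(
                report.summary().to_frame().T.assign(
                    conservation_residual=residual
                )
            )
        log.info("scenario %s done in %.2fs", sid, time.time() - stage_t)

    summary = pd.concat(summaries, ignore_index=True)
    _write("summary.csv", summary.set_index(["scenario", "bound"]))

    central = {
        sid: bundle.get("central") or next(iter(bundle.values()))
        for sid, bundle in reports.items()
    }
    if len(central) >= 2:
        comparison = compare_scenarios(central)
        _write("comparison.csv", comparison)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.world.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(
            {k: manifest[k] for k in ("config_hash", "seed", "outputs")},
            fh, indent=2, sort_keys=True,
        )
    return manifest


def compare_scenarios(reports: Mapping[str, object], reference: str | None = None) -> pd.DataFrame:
    """Cross-scenario receptor comparison: totals, ratios and TF changes.

    ``reports`` maps scenario id -> InequalityReport on identical worlds;
    ratios are scenario total / reference total per receptor and TF deltas
    are absolute and relative against the reference scenario (the first by
    default).
    """
    if len(reports) < 2:
        raise ValidationError("need at least two scenarios to compare")
    ids = sorted(reports)
    ref = reference if reference is not None else ids[0]
    if ref not in reports:
        raise ValidationError(f"reference {ref!r} not among scenarios")
    ref_tf = reports[ref].tf
    rows = []
    for sid in ids:
        tf = reports[sid].tf
        if list(tf.index) != list(ref_tf.index):
            raise ValidationError("scenario reports computed on different worlds")
        for receptor in tf.index:
            tot, ref_tot = tf.loc[receptor, "total"], ref_tf.loc[receptor, "total"]
            tfv, ref_tfv = tf.loc[receptor, "tf"], ref_tf.loc[receptor, "tf"]
            rows.append(
                {
                    "scenario": sid,
                    "reference": ref,
                    "receptor": receptor,
                    "total": tot,
                    "ratio_vs_reference": tot / ref_tot if ref_tot != 0 else np.nan,
                    "tf": tfv,
                    "tf_delta": tfv - ref_tfv,
                    "tf_rel_change": (tfv - ref_tfv) / ref_tfv if ref_tfv else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["scenario", "receptor"])
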