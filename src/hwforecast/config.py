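"""Run configuration and the end-to-end forecast pipeline.

`RunConfig` names the input CSVs and the knobs that matter for a run
(horizon, CHPS mode, interval z, seed); `run_forecast` loads everything,
projects facilities, translates them into requirements with predictive
bounds, and writes the full report set plus a machine-readable manifest.
Outputs are staged in a temporary directory and moved into place at the
end, so a failed run never leaves partial outputs behind.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as hio
from .errors import ConfigError
from .projection import project, transition_flows
from .staffing import compute_requirements, sar_report
from .uncertainty import monte_carlo_interval, predictive_interval

__all__ = ["RunConfig", "load_config", "run_forecast"]

_CHPS_MODES = ("markov", "population")
_INTERVAL_MODES = ("scenario", "monte_carlo")


@dataclass
class RunConfig:
    """Everything a forecast run needs.

    Paths may be ``None`` when the corresponding stage is not wanted:
    population (CHPS demarcation), construction, workload change, roster
    (SAR report) are all optional.
    """

    baseline_census: str
    transition_table: str
    norms: str | None = None
    construction: str | None = None
    population: str | None = None
    workload_change: str | None = None
    roster: str | None = None
    output_dir: str = "forecast_out"
    baseline_year: int = 2016
    horizon: int = 10
    chps_mode: str = "markov"          #: "population" demarcates CHPS from the series
    chps_divisor: float = 1500.0
    z: float = 1.96
    interval_mode: str = "scenario"    #: or "monte_carlo"
    n_draws: int = 500                 #: Monte-Carlo draws (monte_carlo mode only)
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.horizon < 1:
            raise ConfigError(f"horizon must be >= 1, got {self.horizon}")
        if self.chps_mode not in _CHPS_MODES:
            raise ConfigError(f"chps_mode must be one of {_CHPS_MODES}, got {self.chps_mode!r}")
        if self.interval_mode not in _INTERVAL_MODES:
            raise ConfigError(
                f"interval_mode must be one of {_INTERVAL_MODES}, got {self.interval_mode!r}")
        if self.chps_mode == "population" and self.population is None:
            raise ConfigError("chps_mode='population' needs a population CSV")
        if not (self.z > 0):
            raise ConfigError(f"z must be > 0, got {self.z}")
        for name in ("baseline_census", "transition_table", "norms", "construction",
                     "population", "workload_change", "roster"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p}")
        return self


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML/JSON run configuration, applying keyword overrides."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw).validate()
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_forecast(config: RunConfig) -> dict[str, str]:
    """Run the whole pipeline and write the report set.

    Writes (long-format canonical + published-shape renderings):
    ``census.csv``, ``census_national.csv``, ``flows.csv``,
    ``requirements.csv`` (with lower/upper bounds),
    ``requirements_national.csv``, ``sar.csv`` (when a roster is given) and
    ``manifest.json`` recording the config, seed and SHA-256 of every input.

    Returns a mapping output-name -> written path.
    """
    config.validate()

    baseline = hio.read_baseline_census(config.baseline_census, config.baseline_year)
    tp = hio.read_transition_table(config.transition_table)
    cons = hio.read_construction(config.construction) if config.construction else None
    pop = (hio.read_population(config.population, config.chps_divisor)
           if config.chps_mode == "population" else None)
    norms = hio.read_norms(config.norms) if config.norms else None
    workload = (hio.read_workload_change(config.workload_change)
                if config.workload_change else None)
    roster = hio.read_roster(config.roster) if config.roster else None

    census = project(baseline, tp, cons=cons, pop=pop, horizon=config.horizon)
    flows = transition_flows(census, tp)

    requirements = None
    if norms is not None:
        if config.interval_mode == "monte_carlo":
            requirements = monte_carlo_interval(
                baseline, tp, cons=cons, pop=pop, norms=norms,
                horizon=config.horizon, n_draws=config.n_draws,
                seed=config.seed, workload=workload)
        else:
            requirements = predictive_interval(
                baseline, tp, cons=cons, pop=pop, norms=norms,
                horizon=config.horizon, z=config.z, workload=workload)

    outdir = Path(config.output_dir)
    written: dict[str, str] = {}
    with tempfile.TemporaryDirectory(prefix="hwforecast-") as tmp:
        tmpdir = Path(tmp)

        hio.write_census(census, tmpdir / "census.csv")
        hio.render_census_national(census).to_csv(tmpdir / "census_national.csv")
        hio.render_flows(flows).to_csv(tmpdir / "flows.csv")
        if requirements is not None:
            hio.write_requirements(requirements, tmpdir / "requirements.csv")
            hio.render_requirements_national(requirements).to_csv(
                tmpdir / "requirements_national.csv")
            if roster is not None:
                sar = sar_report(roster, requirements, config.baseline_year)
                sar.to_csv(tmpdir / "sar.csv", index=False)

        inputs = {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("baseline_census", "transition_table", "norms", "construction",
                         "population", "workload_change", "roster")
            if getattr(config, name) is not None
        }
        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "inputs": inputs,
            "outputs": sorted(p.name for p in tmpdir.iterdir()) + ["manifest.json"],
        }
        with open(tmpdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        # stage complete: move everything into place
        outdir.mkdir(parents=True, exist_ok=True)
        for src in sorted(tmpdir.iterdir()):
            dest = outdir / src.name
            shutil.move(str(src), dest)
            written[src.name] = str(dest)
    return written
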