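"""Run configuration: hierarchical YAML parsing, validation, defaults.

The packaged default configuration reproduces the published base-year input
table (prevalences, undiagnosed fractions, population, crude mortality)
and supplies an illustrative forward parameter set for the 2007-2035 run.
Unknown keys are rejected by name; missing required keys and out-of-range
values fail with the offending key named.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .calibration import BaseYearInputs, build_base_year
from .projection import ModelParameters, ScenarioSpec
from .rates import ProbabilitySet, compute_ageing_index, forecast_probabilities
from .states import StateVector

__all__ = ["RunConfiguration", "load_configuration", "default_config_path"]

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {
        "base_year",
        "horizon",
        "rates",
        "mortality",
        "population_growth",
        "scenario",
        "uncertainty",
        "seed",
    },
    "base_year": {
        "year",
        "population",
        "crude_mortality_per_1000",
        "raw_prevalence",
        "persistence_fraction",
        "undiagnosed",
        "stage4_count",
        "stage5_count",
    },
    "horizon": {"start", "end"},
    "rates": {
        "base_probabilities",
        "rr",
        "ageing_form",
        "reference_window",
        "elderly",
        "within_stage_detection",
    },
    "rates.elderly": {"start_year", "start_share", "end_year", "end_share"},
    "mortality": {"crude_rate_start_per_1000", "crude_rate_end_per_1000"},
    "scenario": {"incidence_change", "detection_change"},
    "uncertainty": {"n_draws", "cv"},
}

_REQUIRED = {
    "": {"base_year", "horizon", "rates", "mortality"},
    "base_year": {
        "year",
        "population",
        "crude_mortality_per_1000",
        "raw_prevalence",
        "persistence_fraction",
        "undiagnosed",
    },
    "horizon": {"start", "end"},
    "rates": {"base_probabilities", "rr", "elderly"},
    "rates.elderly": {"start_year", "start_share", "end_year", "end_share"},
    "mortality": {"crude_rate_start_per_1000", "crude_rate_end_per_1000"},
}


def default_config_path() -> Path:
    return Path(str(resources.files("ckdproj").joinpath("data/default_config.yaml")))


def _check_keys(section: dict, path: str) -> None:
    allowed = _SCHEMA.get(path)
    if allowed is not None:
        unknown = set(section) - allowed
        if unknown:
            where = path or "top level"
            raise ValueError(f"unknown configuration key(s) {sorted(unknown)} in {where}")
    required = _REQUIRED.get(path, set())
    missing = required - set(section)
    if missing:
        where = path or "top level"
        raise ValueError(f"missing required key(s) {sorted(missing)} in {where}")
    for key, value in section.items():
        sub = f"{path}.{key}" if path else key
        if isinstance(value, dict) and sub in _SCHEMA:
            _check_keys(value, sub)


@dataclass
class RunConfiguration:
    """Validated run configuration with derived model objects on demand."""

    raw: dict
    text: str
    path: Path | None = None

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def horizon(self) -> tuple[int, int]:
        h = self.raw["horizon"]
        return int(h["start"]), int(h["end"])

    def base_year_inputs(self) -> BaseYearInputs:
        b = self.raw["base_year"]
        return BaseYearInputs(
            raw_prevalence={str(k): float(v) for k, v in b["raw_prevalence"].items()},
            persistence_fraction=float(b["persistence_fraction"]),
            population=float(b["population"]),
            crude_mortality=float(b["crude_mortality_per_1000"]) / 1000.0,
            undiagnosed={str(k): float(v) for k, v in b["undiagnosed"].items()},
        )

    def base_state(self) -> StateVector:
        b = self.raw["base_year"]
        return build_base_year(
            self.base_year_inputs(),
            stage4_count=float(b.get("stage4_count", 24293)),
            stage5_count=float(b.get("stage5_count", 8434)),
            year=int(b["year"]),
        )

    def elderly_series(self) -> dict[int, float]:
        e = self.raw["rates"]["elderly"]
        y0, y1 = int(e["start_year"]), int(e["end_year"])
        s0, s1 = float(e["start_share"]), float(e["end_share"])
        if y1 <= y0:
            raise ValueError("rates.elderly: end_year must exceed start_year")
        return {
            y: s0 + (s1 - s0) * (y - y0) / (y1 - y0) for y in range(y0, y1 + 1)
        }

    def base_probabilities(self) -> ProbabilitySet:
        return ProbabilitySet(
            **{k: float(v) for k, v in self.raw["rates"]["base_probabilities"].items()}
        )

    def annual_probabilities(self) -> dict[int, "ProbabilitySet"]:
        rates = self.raw["rates"]
        window = tuple(rates.get("reference_window", (2010, 2014)))
        ageing = compute_ageing_index(
            self.elderly_series(),
            reference_window=window,
            form=rates.get("ageing_form", "relative"),
        )
        lo, hi = self.horizon
        return forecast_probabilities(self.base_probabilities(), ageing, (lo, hi - 1))

    def death_totals(self) -> dict[int, float]:
        lo, hi = self.horizon
        m = self.raw["mortality"]
        r0 = float(m["crude_rate_start_per_1000"]) / 1000.0
        r1 = float(m["crude_rate_end_per_1000"]) / 1000.0
        pop0 = float(self.raw["base_year"]["population"])
        growth = float(self.raw.get("population_growth", 0.0))
        totals = {}
        for year in range(lo, hi + 1):
            frac = (year - lo) / (hi - lo) if hi > lo else 0.0
            rate = r0 + (r1 - r0) * frac
            totals[year] = rate * pop0 * (1.0 + growth) ** (year - lo)
        return totals

    def model_parameters(self) -> ModelParameters:
        rr = {str(k): float(v) for k, v in self.raw["rates"]["rr"].items()}
        return ModelParameters(
            base_state=self.base_state(),
            probabilities=self.annual_probabilities(),
            rr=rr,
            death_totals=self.death_totals(),
            population_growth=float(self.raw.get("population_growth", 0.0)),
            within_stage_detection=bool(
                self.raw["rates"].get("within_stage_detection", False)
            ),
            horizon=self.horizon,
        )

    def scenario(self) -> ScenarioSpec:
        s = self.raw.get("scenario", {})
        incidence = {}
        for key, rate in (s.get("incidence_change") or {}).items():
            src, dst = str(key).split("->")
            incidence[(src.strip(), dst.strip())] = float(rate)
        detection = {
            str(k): float(v) for k, v in (s.get("detection_change") or {}).items()
        }
        return ScenarioSpec(incidence, detection, self.horizon)

    def uncertainty(self) -> tuple[dict[str, float], int]:
        u = self.raw.get("uncertainty", {})
        cv = {str(k): float(v) for k, v in (u.get("cv") or {}).items()}
        return cv, int(u.get("n_draws", 200))


def _validate_ranges(raw: dict) -> None:
    b = raw["base_year"]
    for stage, p in b["raw_prevalence"].items():
        if not (0.0 <= float(p) <= 1.0):
            raise ValueError(f"base_year.raw_prevalence[{stage}] = {p} outside [0, 1]")
    for stage, u in b["undiagnosed"].items():
        if not (0.0 <= float(u) <= 1.0):
            raise ValueError(f"base_year.undiagnosed[{stage}] = {u} outside [0, 1]")
    if float(b["population"]) <= 0:
        raise ValueError("base_year.population must be positive")
    if not (0.0 <= float(b["persistence_fraction"]) <= 1.0):
        raise ValueError("base_year.persistence_fraction outside [0, 1]")
    lo, hi = int(raw["horizon"]["start"]), int(raw["horizon"]["end"])
    if hi <= lo:
        raise ValueError("horizon.end must exceed horizon.start")


def load_configuration(path: Path | str | None = None) -> RunConfiguration:
    """Load and validate a YAML run configuration (packaged default if None)."""
    if path is None:
        path = default_config_path()
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        missing = sorted(_REQUIRED[""])
        raise ValueError(f"empty or scalar configuration; required keys: {missing}")
    _check_keys(raw, "")
    _validate_ranges(raw)
    config = RunConfiguration(raw, text, path)
    logger.info(
        "loaded configuration %s (seed=%d, horizon=%s)", path, config.seed, config.horizon
    )
    return config
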