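"""Run configuration: parsing, validation and strategy-string grammar."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .cohort import CohortParams
from .cutoffs import CutoffModel

__all__ = ["RunConfig", "EquitySpec", "ConfigError", "validate_config", "parse_strategy"]


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


def parse_strategy(spec: str) -> CutoffModel:
    """Parse a strategy string: ``fixed:55``, ``floating:96``, ``hybrid:96:60``.

    The hybrid form is percentile first, back-up fixed value second.
    """
    parts = [p.strip() for p in str(spec).split(":")]
    try:
        if parts[0] == "fixed" and len(parts) == 2:
            return CutoffModel(mode="fixed", fixed_value=float(parts[1]))
        if parts[0] == "floating" and len(parts) == 2:
            return CutoffModel(mode="floating", percentile=float(parts[1]))
        if parts[0] == "hybrid" and len(parts) == 3:
            return CutoffModel(mode="hybrid", percentile=float(parts[1]), fixed_value=float(parts[2]))
    except ValueError as exc:
        raise ConfigError([f"strategy {spec!r}: {exc}"]) from exc
    raise ConfigError(
        [f"strategy {spec!r}: expected 'fixed:<ng/mL>', 'floating:<q>' or 'hybrid:<q>:<ng/mL>'"]
    )


class EquitySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    group: str = "race"
    reference: str = "White"
    outcomes: list[str] = Field(
        default_factory=lambda: ["delayed_or_missed", "missed_only", "delayed_only"]
    )

    @model_validator(mode="after")
    def _check(self) -> "EquitySpec":
        from .equity import OUTCOME_CONTRASTS

        bad = [o for o in self.outcomes if o not in OUTCOME_CONTRASTS]
        if bad:
            raise ValueError(f"unknown outcome contrast(s) {bad}")
        return self


class CohortSource(BaseModel):
    """Either a registry CSV path or parameters for synthetic generation."""

    model_config = ConfigDict(extra="forbid")

    registry: str | None = None
    params: CohortParams | None = None
    fixture: bool = False  # use the built-in deterministic cohort fixture

    @model_validator(mode="after")
    def _check(self) -> "CohortSource":
        given = sum(x is not None and x is not False for x in (self.registry, self.params, self.fixture))
        if given != 1:
            raise ValueError("cohort needs exactly one of: registry, params, fixture")
        return self


class RunConfig(BaseModel):
    """Fully-resolved pipeline configuration.

    Defaults mirror the screening programme being modelled: fixed cut-off
    55 ng/mL, floating percentile 95, trim threshold 170 ng/mL.
    """

    model_config = ConfigDict(extra="forbid")

    cohort: CohortSource
    strategies: list[str] = Field(default_factory=lambda: ["fixed:55"], min_length=1)
    panels: list[str] = Field(min_length=1)
    equity: EquitySpec = Field(default_factory=EquitySpec)
    output_dir: str = "nbs-run"
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("strategies")
    @classmethod
    def _check_strategies(cls, specs: list[str]) -> list[str]:
        for spec in specs:
            try:
                parse_strategy(spec)._validate()
            except (ConfigError, ValueError) as exc:
                detail = "; ".join(exc.errors) if isinstance(exc, ConfigError) else str(exc)
                raise ValueError(f"strategy {spec!r}: {detail}") from exc
        return specs

    @field_validator("log_level")
    @classmethod
    def _check_log_level(cls, level: str) -> str:
        if level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log_level {level!r}")
        return level

    def strategy_models(self) -> list[CutoffModel]:
        return [parse_strategy(s) for s in self.strategies]


def _flatten_pydantic_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']}")
    return out


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config, reporting all violations at once.

    Relative paths (registry, panels, output_dir) are resolved against the
    config file's directory. Unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError([f"cannot parse {path.name}: {exc}"]) from exc
    if not isinstance(data, dict):
        raise ConfigError([f"{path.name}: top level must be a mapping"])

    try:
        cfg = RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_flatten_pydantic_errors(exc)) from exc

    base = path.parent.resolve()

    def absolutize(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    update: dict = {"panels": [absolutize(p) for p in cfg.panels],
                    "output_dir": absolutize(cfg.output_dir)}
    if cfg.cohort.registry is not None:
        update["cohort"] = cfg.cohort.model_copy(update={"registry": absolutize(cfg.cohort.registry)})
    cfg = cfg.model_copy(update=update)

    errors = [f"panels: file not found: {p}" for p in cfg.panels if not Path(p).is_file()]
    if cfg.cohort.registry is not None and not Path(cfg.cohort.registry).is_file():
        errors.append(f"cohort.registry: file not found: {cfg.cohort.registry}")
    if errors:
        raise ConfigError(errors)
    return cfg
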