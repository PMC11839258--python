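"""Run configuration: one YAML document drives the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .synthetic import SyntheticCohortSpec

_KNOWN_SECTIONS = {"seed", "input", "layout", "decomposition", "stability",
                   "stats"}


@dataclass
class DecompositionSettings:
    k_retained: int = 5
    cutoff_hz: float = 7.0
    filter_order: int = 3
    loo: bool = True
    loo_threshold: float = 0.9
    rvar_scope: str = "trial"


@dataclass
class StabilitySettings:
    mode: str = "fixed"  # "fixed" | "adaptive"
    tau: int = 10
    m: int = 4
    units: str = "per_second"
    use_filtered: bool = False
    evolve_steps: int | None = None


@dataclass
class StatsSettings:
    alpha: float = 0.05
    alpha_posthoc: float = 0.006
    run_posthoc: bool = True
    run_shapiro: bool = True


@dataclass
class InputSettings:
    kind: str = "synthetic"  # "synthetic" | "csv"
    synthetic: dict = field(default_factory=dict)
    cohort_csv: str | None = None
    metadata_csv: str | None = None
    fs_hz: float = 150.0


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run."""

    seed: int
    input: InputSettings
    layout: tuple[str, ...] | None = None
    decomposition: DecompositionSettings = field(
        default_factory=DecompositionSettings)
    stability: StabilitySettings = field(default_factory=StabilitySettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    @classmethod
    def from_dict(cls, raw: dict | None) -> "RunConfig":
        if not raw:
            raise ValidationError(
                "empty configuration; required fields missing: "
                "seed, input.kind"
            )
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValidationError(f"unknown config sections: {sorted(unknown)}")
        missing = [f for f in ("seed", "input") if f not in raw]
        if missing:
            raise ValidationError(f"config missing required fields: {missing}")
        inp = InputSettings(**raw["input"])
        if inp.kind not in ("synthetic", "csv"):
            raise ValidationError(f"input.kind must be synthetic|csv, got {inp.kind!r}")
        if inp.kind == "csv" and not inp.cohort_csv:
            raise ValidationError("input.kind=csv requires input.cohort_csv")
        layout = raw.get("layout")
        cfg = cls(
            seed=int(raw["seed"]),
            input=inp,
            layout=tuple(layout) if layout else None,
            decomposition=DecompositionSettings(**raw.get("decomposition", {})),
            stability=StabilitySettings(**raw.get("stability", {})),
            stats=StatsSettings(**raw.get("stats", {})),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["layout"] is not None:
            d["layout"] = list(d["layout"])
        return d

    def synthetic_spec(self) -> SyntheticCohortSpec:
        kwargs = dict(self.input.synthetic)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("fs_hz", self.input.fs_hz)
        if self.layout is not None:
            kwargs.setdefault("marker_layout", self.layout)
        return SyntheticCohortSpec(**kwargs)
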