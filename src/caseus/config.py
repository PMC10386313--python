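"""Run configuration: one structured document driving every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .simulate import SeasonEffects, StudyDesign


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration shared by the CLI subcommands.

    All randomness in a run flows from ``seed``. Fractions follow the
    validation protocol defaults: ~85% of complete samples per month to
    calibration, about a third of partial samples fixed as external
    validation, 20% of complete samples held out for imputation validation.
    """

    seed: int = 0
    n_iterations: int = 20
    orders: list[int] = field(default_factory=lambda: list(range(1, 9)))
    preprocessing: str = "autoscale"
    calibration_complete_fraction: float = 0.85
    external_partial_fraction: float = 1.0 / 3.0
    holdout_fraction: float = 0.2
    design: StudyDesign = field(default_factory=StudyDesign)
    effects: SeasonEffects = field(default_factory=SeasonEffects)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not 0 < self.calibration_complete_fraction < 1:
            raise ConfigError("calibration_complete_fraction must be in (0, 1)")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError("holdout_fraction must be in (0, 1)")
        if self.preprocessing != "autoscale":
            raise ConfigError(f"unknown preprocessing policy {self.preprocessing!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            dd = dict(d["design"])
            for key in ("months", "complete_counts", "partial_counts"):
                if key in dd:
                    dd[key] = tuple(dd[key])
            d["design"] = StudyDesign(**dd)
        if "effects" in d and isinstance(d["effects"], dict):
            d["effects"] = SeasonEffects(**d["effects"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["design"]["months"] = list(d["design"]["months"])
        d["design"]["complete_counts"] = list(d["design"]["complete_counts"])
        d["design"]["partial_counts"] = list(d["design"]["partial_counts"])
        for key in ("class_offsets", "loadings", "baseline_means"):
            val = d["effects"].get(key)
            if val is None:
                d["effects"].pop(key, None)
            elif key == "class_offsets":
                d["effects"][key] = {m: [float(x) for x in v] for m, v in val.items()}
            else:
                d["effects"][key] = [
                    [float(x) for x in row] if hasattr(row, "__len__") else float(row)
                    for row in val
                ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
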