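"""Pipeline configuration: TOML loading with explicit threshold validation."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

from .dose_classification import ClassificationThresholds
from .mating_analysis import FusionConfig
from .trace_io import QCConfig


class ConfigError(ValueError):
    """A configuration file is missing or malformed."""


#: threshold keys a config file must spell out under [thresholds]
REQUIRED_THRESHOLDS = {
    "expressing_fraction": 0.2,   # of the population-averaged output
    "response_fraction": 0.2,     # of the cell's own maximal output
    "fusion_jump": 50.0,          # AU, tdiRFP step defining fusion
    "fusion_flat": 10.0,          # AU, max rise of a non-fusing cell
    "min_track_frames": 10,       # mating-mode track-length floor
    "late_delay_min": 15.0,       # minutes, late-class delay bound
}


@dataclass
class PipelineConfig:
    """Everything the two workflows need, with standard defaults."""

    columns: dict[str, str] = field(default_factory=dict)  # dialect map
    qc: QCConfig = field(default_factory=QCConfig)
    expressing_fraction: float = 0.2
    response_fraction: float = 0.2
    fusion: FusionConfig = field(default_factory=FusionConfig)
    classification: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    stimulation_time: float = 0.0

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls()


def load_config(path) -> PipelineConfig:
    """Parse a TOML config file.

    The [thresholds] table must spell out every analysis threshold (missing
    keys are a startup error, so a config file is always a complete record of
    the run).  [io.columns] maps canonical column names to file headers;
    [qc] overrides quality-control settings.
    """
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as e:
            raise ConfigError(f"cannot parse {path}: {e}") from e

    th = data.get("thresholds", {})
    missing = [k for k in REQUIRED_THRESHOLDS if k not in th]
    if missing:
        raise ConfigError(
            f"config {path} is missing threshold key(s): {', '.join(missing)}"
        )

    qc_kwargs = data.get("qc", {})
    try:
        qc = QCConfig(**qc_kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"bad [qc] section: {e}") from e

    cls_kwargs = data.get("classification", {})
    cls_kwargs.setdefault("late_delay_min", float(th["late_delay_min"]))
    try:
        classification = ClassificationThresholds(**cls_kwargs)
    except TypeError as e:
        raise ConfigError(f"bad [classification] section: {e}") from e

    return PipelineConfig(
        columns=dict(data.get("io", {}).get("columns", {})),
        qc=qc,
        expressing_fraction=float(th["expressing_fraction"]),
        response_fraction=float(th["response_fraction"]),
        fusion=FusionConfig(
            jump=float(th["fusion_jump"]),
            flat=float(th["fusion_flat"]),
            min_track_frames=int(th["min_track_frames"]),
        ),
        classification=classification,
        stimulation_time=float(data.get("stimulation_time", 0.0)),
    )
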