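"""Run configuration: defaults, JSON config files, flag overrides.

Keys are dotted strings grouped by pipeline stage.  Unknown keys are
rejected so typos fail loudly, and the effective configuration is echoed
verbatim into every JSON run report for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .errors import ConfigError


@dataclass
class RunConfig:
    # preprocess
    sharpen_sigma: float = 2.0
    sharpen_amount: float = 1.0
    background_radius_rows: int = 50
    sharpen_enabled: bool = True
    background_enabled: bool = True
    # detect
    lane_prominence_frac: float = 0.2
    lane_min_separation_cols: int = 20
    band_threshold: float | str = "auto"  # "auto" => 5*MAD*1.4826
    band_min_distance_rows: int = 4
    smooth_window: int = 5
    # calibrate
    extrapolation_frac: float = 0.10
    # quantify
    short_threshold_kb: float = 1.6
    # run
    seed: int = 0
    log_level: str = "INFO"


#: dotted JSON key -> RunConfig attribute
_KEY_MAP = {
    "preprocess.sharpen_sigma": "sharpen_sigma",
    "preprocess.sharpen_amount": "sharpen_amount",
    "preprocess.background_radius_rows": "background_radius_rows",
    "preprocess.sharpen_enabled": "sharpen_enabled",
    "preprocess.background_enabled": "background_enabled",
    "detect.lane_prominence_frac": "lane_prominence_frac",
    "detect.lane_min_separation_cols": "lane_min_separation_cols",
    "detect.band_threshold": "band_threshold",
    "detect.band_min_distance_rows": "band_min_distance_rows",
    "detect.smooth_window": "smooth_window",
    "calibrate.extrapolation_frac": "extrapolation_frac",
    "quantify.short_threshold_kb": "short_threshold_kb",
    "run.seed": "seed",
    "run.log_level": "log_level",
}

_ATTR_TO_KEY = {v: k for k, v in _KEY_MAP.items()}


def config_from_dict(data: dict, base: RunConfig | None = None) -> RunConfig:
    """Build a RunConfig from a dict of dotted keys, rejecting unknowns."""
    cfg = dataclasses.replace(base) if base else RunConfig()
    for key, value in data.items():
        if key not in _KEY_MAP:
            raise ConfigError(f"unknown config key {key!r}")
        setattr(cfg, _KEY_MAP[key], value)
    if cfg.band_threshold != "auto":
        try:
            cfg.band_threshold = float(cfg.band_threshold)
        except (TypeError, ValueError):
            raise ConfigError(
                f"detect.band_threshold must be 'auto' or a number, "
                f"got {cfg.band_threshold!r}"
            ) from None
    if cfg.smooth_window % 2 == 0:
        raise ConfigError("detect.smooth_window must be odd")
    return cfg


def config_from_file(path: str, base: RunConfig | None = None) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config file must hold a JSON object")
    return config_from_dict(data, base=base)


def config_to_dict(cfg: RunConfig) -> dict:
    """Dotted-key dict view, as echoed into run reports."""
    return {_ATTR_TO_KEY[f.name]: getattr(cfg, f.name)
            for f in dataclasses.fields(cfg)}
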