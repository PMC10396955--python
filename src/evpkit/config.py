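"""Runtime configuration (TOML).

A single optional config file adjusts the comparison weights, the scale
constants, presentation rounding and the bond-perception tolerance::

    bond_tolerance = 0.45
    [weights]
    abs_theta = 2.0
    [scales]
    r = 0.2
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .compare_report import SCALE_CONSTANTS
from .exceptions import InputError, ValidationError
from .scaffolds import DEFAULT_BOND_TOLERANCE


@dataclass
class Config:
    weights: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in SCALE_CONSTANTS}
    )
    scales: dict[str, float] = field(default_factory=lambda: dict(SCALE_CONSTANTS))
    bond_tolerance: float = DEFAULT_BOND_TOLERANCE
    distance_decimals: int = 2
    angle_decimals: int = 0


def load_config(path) -> Config:
    path = Path(path)
    try:
        data = tomllib.loads(path.read_text())
    except FileNotFoundError:
        raise InputError(f"no such config file: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise InputError(f"{path}: invalid TOML ({exc})") from None
    cfg = Config()
    for key in ("weights", "scales"):
        table = data.get(key, {})
        target = getattr(cfg, key)
        for name, value in table.items():
            if name not in SCALE_CONSTANTS:
                raise ValidationError(
                    f"{path}: unknown parameter {name!r} under [{key}]"
                )
            target[name] = float(value)
    if "bond_tolerance" in data:
        cfg.bond_tolerance = float(data["bond_tolerance"])
        if cfg.bond_tolerance < 0:
            raise ValidationError("bond_tolerance must be >= 0")
    cfg.distance_decimals = int(data.get("distance_decimals", cfg.distance_decimals))
    cfg.angle_decimals = int(data.get("angle_decimals", cfg.angle_decimals))
    return cfg
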