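"""Pipeline configuration: defaulted, validated, TOML round-trippable."""

from __future__ import annotations

import copy
import tomllib
from pathlib import Path

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "cultnet_out",
    "culture": {
        "kind": "aggregated",  # 'aggregated' | 'homogeneous'
        "n_aggregates": 100,
        "modules": 5,
        "p_within": 0.35,
        "p_between": 0.02,
        "grid": 40,
        "h": 0.7,
        "surroundings_removed": False,
    },
    "dynamics": {
        "recording_s": 1200.0,
    },
    "imaging": {
        "fps": 50.0,
        "rise_s": 0.1,
        "decay_s": 1.0,
        "noise_sd": 0.02,
        "baseline_au": 100.0,
        "amplitude_pct": 20.0,
    },
    "signal": {
        "percentile": 0.1,
    },
    "bursts": {
        "window_s": 0.2,
    },
    "connectivity": {
        "markov_order": 2,
        "instant_feedback": True,
        "bin_frames": 1,
        "z_min": 1.0,
    },
    "damage": {
        "scheme": "bc_attack",  # 'bc_attack' | 'degree_attack' | 'random'
        "steps": 8,
        "recovery_strength": 0.5,
        "cut_angle": 0.0,
        "cut_width_um": 500.0,
    },
}


class PipelineConfig:
    """Validated configuration for the end-to-end pipeline.

    Every field has a default; unknown sections or keys raise.  Values
    are accessed as ``cfg['section']['key']`` or ``cfg.section['key']``.
    """

    def __init__(self, overrides: dict | None = None):
        data = copy.deepcopy(DEFAULTS)
        for key, val in (overrides or {}).items():
            if key not in data:
                raise KeyError(f"unknown config section or key {key!r}")
            if isinstance(data[key], dict):
                if not isinstance(val, dict):
                    raise TypeError(f"section {key!r} must be a table")
                for k2, v2 in val.items():
                    if k2 not in data[key]:
                        raise KeyError(f"unknown key {key}.{k2}")
                    data[key][k2] = v2
            else:
                data[key] = val
        self.data = data

    def __getitem__(self, key):
        return self.data[key]

    def __getattr__(self, key):
        data = self.__dict__.get("data", {})
        if key in data:
            return data[key]
        raise AttributeError(key)

    def __eq__(self, other) -> bool:
        return isinstance(other, PipelineConfig) and self.data == other.data

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as f:
            return cls(tomllib.load(f))

    def to_toml(self, path: str | Path) -> Path:
        path = Path(path)
        lines: list[str] = []
        top = {k: v for k, v in self.data.items() if not isinstance(v, dict)}
        for k, v in top.items():
            lines.append(f"{k} = {_toml_value(v)}")
        for section, table in self.data.items():
            if isinstance(table, dict):
                lines.append(f"\n[{section}]")
                for k, v in table.items():
                    lines.append(f"{k} = {_toml_value(v)}")
        path.write_text("\n".join(lines) + "\n")
        return path


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")
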