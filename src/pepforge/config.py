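"""Run configuration (desk vs paper profiles) and deterministic report
writers.

The ``paper`` profile carries the published sampling sizes (500 runs x
10,000 steps for conformational sampling; 100 runs x 2,000 steps for
in-site affinity sampling).  The ``desk`` profile scales these down so
the full pipeline runs interactively on one CPU; every stochastic stage
reads its seed from the configuration so outputs are reproducible
byte-for-byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

PROFILES = {
    "desk": {
        "sampling": {"runs": 20, "steps_per_run": 500},
        "boltzmann": {"runs": 10, "steps_per_run": 100},
    },
    "paper": {
        "sampling": {"runs": 500, "steps_per_run": 10000},
        "boltzmann": {"runs": 100, "steps_per_run": 2000},
    },
}

_VALID_KEYS = {"profile", "seeds", "overrides", "output_dir"}
_STAGES = ("sampling", "boltzmann", "toy", "titration")


@dataclass
class RunConfig:
    profile: str = "desk"
    seeds: dict[str, int] = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    output_dir: str = "."

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; "
                             f"valid: {sorted(PROFILES)}")
        for stage in _STAGES:
            self.seeds.setdefault(stage, 0)

    def stage(self, name: str) -> dict:
        out = dict(PROFILES[self.profile].get(name, {}))
        out.update(self.overrides.get(name, {}))
        return out


def load_config(path: str | None = None, profile: str | None = None,
                seed: int | None = None) -> RunConfig:
    """Load a YAML configuration; unknown keys are rejected by name."""
    data = {}
    if path is not None:
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        unknown = set(data) - _VALID_KEYS
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; "
                f"valid keys: {sorted(_VALID_KEYS)}")
    if profile is not None:
        data["profile"] = profile
    cfg = RunConfig(**data)
    if seed is not None:
        cfg.seeds = {k: seed for k in cfg.seeds}
    return cfg


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def report(results, path: str, fmt: str = "json") -> str:
    """Write results deterministically (sorted keys, 6 significant
    digits); identical inputs produce identical bytes."""
    path = str(path)
    if fmt == "json":
        def default(o):
            try:
                return float(o)
            except (TypeError, ValueError):
                return str(o)

        def round_floats(obj):
            if isinstance(obj, dict):
                return {k: round_floats(obj[k]) for k in sorted(obj)}
            if isinstance(obj, (list, tuple)):
                return [round_floats(x) for x in obj]
            if isinstance(obj, float):
                return float(format(obj, ".6g"))
            return obj

        with open(path, "w") as f:
            json.dump(round_floats(results), f, indent=2, sort_keys=True,
                      default=default)
            f.write("\n")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        rows = results if isinstance(results, list) else [results]
        if not rows:
            raise ValueError("nothing to write")
        cols = sorted(rows[0])
        with open(path, "w") as f:
            f.write(sep.join(cols) + "\n")
            for row in rows:
                f.write(sep.join(_format_value(row.get(c, ""))
                                 for c in cols) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
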