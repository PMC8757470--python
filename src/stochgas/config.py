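"""Run configuration: YAML schema, validation, and constraint construction.

The configuration is a versioned YAML document with four sections (``gas``,
``pchb``, ``dynamics`` and top-level paths/seed).  Unknown keys are rejected
up front so typos fail before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .gas_constraints import (
    Constraints,
    CumulativeConstraints,
    GASPartition,
    LocalConstraints,
    band_constraints,
    validate,
)

_TOP_KEYS = {
    "version", "fcidump", "output_dir", "seed", "log_level",
    "gas", "pchb", "dynamics",
}
_GAS_KEYS = {
    "spaces", "constraint_kind", "min", "max", "neutral", "n_exc",
    "n_elec", "ms2",
}
_PCHB_KEYS = {"gas", "p_double", "memory_cap_gb"}
_DYNAMICS_KEYS = {
    "time_step", "target_population", "initial_population", "shift_damping",
    "shift_interval", "initial_shift", "initiator", "n_add", "adaptive",
    "adaptive_offset_frac", "adaptive_offset", "forgetting_half_life",
    "core_size", "max_iterations", "equilibration",
}


class ConfigError(ValueError):
    """Raised for schema violations; the CLI maps it to exit code 2."""


@dataclass
class RunConfig:
    raw: dict
    fcidump: Optional[str] = None
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"
    gas: dict = field(default_factory=dict)
    pchb: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {name}: {', '.join(sorted(unknown))}"
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def parse_config(raw: Any) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    version = raw.get("version", 1)
    if version != 1:
        raise ConfigError(f"unsupported config version {version}")
    gas = raw.get("gas", {}) or {}
    pchb = raw.get("pchb", {}) or {}
    dynamics = raw.get("dynamics", {}) or {}
    _check_keys(gas, _GAS_KEYS, "gas")
    _check_keys(pchb, _PCHB_KEYS, "pchb")
    _check_keys(dynamics, _DYNAMICS_KEYS, "dynamics")
    return RunConfig(
        raw=raw,
        fcidump=raw.get("fcidump"),
        output_dir=raw.get("output_dir", "."),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        gas=gas,
        pchb=pchb,
        dynamics=dynamics,
    )


def gas_from_config(
    gas: dict,
) -> tuple[GASPartition, Constraints, int]:
    """Build (partition, constraints, N) from a ``gas`` config section.

    Either explicit ``min``/``max`` arrays or ``neutral`` + ``n_exc`` bands
    must be given; ``constraint_kind`` selects local or cumulative semantics.
    """
    if "spaces" not in gas:
        raise ConfigError("gas section needs 'spaces'")
    partition = GASPartition(gas["spaces"])
    kind = gas.get("constraint_kind", "local")
    if kind not in ("local", "cumulative"):
        raise ConfigError(f"unknown constraint_kind {kind!r}")
    if "neutral" in gas:
        if "n_exc" not in gas:
            raise ConfigError("'neutral' requires 'n_exc'")
        constraints = band_constraints(
            partition, gas["neutral"], int(gas["n_exc"]), kind
        )
        n_elec = int(gas.get("n_elec", sum(gas["neutral"])))
    elif "min" in gas and "max" in gas:
        if kind == "local":
            constraints = LocalConstraints(gas["min"], gas["max"])
        else:
            constraints = CumulativeConstraints(gas["min"], gas["max"])
        if "n_elec" in gas:
            n_elec = int(gas["n_elec"])
        elif kind == "cumulative":
            n_elec = int(gas["max"][-1])
        else:
            raise ConfigError("local min/max constraints need 'n_elec'")
    else:
        raise ConfigError("gas section needs min/max or neutral/n_exc")
    problems = validate(partition, constraints, n_elec)
    if problems:
        raise ConfigError("invalid GAS constraints: " + "; ".join(problems))
    return partition, constraints, n_elec
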