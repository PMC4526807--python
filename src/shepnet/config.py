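"""Run configuration: YAML round-trip, validation, parameter resolution.

A run is described by a single structured config (experiment name, seed,
network-parameter overrides, paradigm timing, grid, experiment options).
Unknown keys are rejected rather than ignored so typos cannot silently
change a simulation.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dynamics import NetworkParams
from .grids import TonotopicGrid
from .stimuli import TrialTiming

__all__ = ["RunConfig", "load_config", "validate_params", "make_timing", "make_grid"]

#: NetworkParams fields a config may override.
_PARAM_KEYS = {
    "tau_e", "tau_i", "tau_fr", "tau_fd", "theta_e", "k_e", "theta_i", "k_i",
    "a_ee", "a_ei", "a_ie", "gamma_f", "gamma_e", "gamma_i",
    "sigma_ee", "sigma_ei", "sigma_ie", "tuning_regime",
}
#: Fields the broad regime sets atomically.
_BROAD_OVERRIDES = {"sigma_ee": 0.05, "sigma_ei": 0.2, "a_ee": 1.5}


def validate_params(raw: dict | None) -> NetworkParams:
    """Build NetworkParams from a raw mapping, filling printed defaults.

    The broad tuning regime applies its three overrides (sigma_ee, sigma_ei,
    a_ee) atomically; explicitly setting one of them to a conflicting value
    alongside ``tuning_regime: broad`` is an error.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown network parameter(s): {sorted(unknown)}")
    regime = raw.get("tuning_regime", "narrow")
    if regime == "broad":
        for key, val in _BROAD_OVERRIDES.items():
            if key in raw and raw[key] != val:
                raise ValueError(
                    f"contradictory override: {key}={raw[key]} conflicts with "
                    f"tuning_regime=broad ({key}={val})"
                )
        merged = {**_BROAD_OVERRIDES, **raw}
        return NetworkParams(**merged)
    return NetworkParams(**raw)


def make_timing(raw: dict | None) -> TrialTiming:
    raw = dict(raw or {})
    allowed = {f.name for f in fields(TrialTiming)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown timing key(s): {sorted(unknown)}")
    return TrialTiming(**raw)


def make_grid(raw: dict | None) -> TonotopicGrid:
    raw = dict(raw or {})
    allowed = {f.name for f in fields(TonotopicGrid)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown grid key(s): {sorted(unknown)}")
    return TonotopicGrid(**raw)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: str
    seed: int = 0
    trials: int = 100
    out_dir: str = "results"
    plot: bool = False
    params: dict = field(default_factory=dict)
    timing: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        # Validate eagerly so bad configs fail before any simulation.
        validate_params(self.params)
        make_timing(self.timing)
        make_grid(self.grid)

    @property
    def network_params(self) -> NetworkParams:
        return validate_params(self.params)

    @property
    def trial_timing(self) -> TrialTiming:
        return make_timing(self.timing)

    @property
    def tonotopic_grid(self) -> TonotopicGrid:
        return make_grid(self.grid)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown top-level keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "experiment" not in raw:
        raise ValueError("config must name an experiment")
    return RunConfig(**raw)
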