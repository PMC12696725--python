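"""Study configuration for the synthetic cohort and trace generator.

Unit conventions
----------------
The allometric coefficient ``a`` is defined with the metabolic rate in
**mL CO2 h^-1** and mass in **g**, i.e. ``rate [mL/h] = a * mass[g]^b``.
All internal rate computations and the processed output are in mL min^-1
(divide by 60). This convention is used everywhere a coefficient is
reported or consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

HOSTS: tuple[str, ...] = ("Urtica", "Salix", "Ribes")
STAGES: tuple[str, ...] = ("instar3", "instar4", "pupa")
LARVAL_STAGES: tuple[str, ...] = ("instar3", "instar4")

#: measured individuals per (stage, host): the study's replication structure
DEFAULT_REPLICATES: dict[tuple[str, str], int] = {
    ("instar3", "Urtica"): 49,
    ("instar3", "Salix"): 52,
    ("instar3", "Ribes"): 56,
    ("instar4", "Urtica"): 88,
    ("instar4", "Salix"): 97,
    ("instar4", "Ribes"): 109,
    ("pupa", "Urtica"): 18,
    ("pupa", "Salix"): 21,
    ("pupa", "Ribes"): 29,
}


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class TraceParams:
    """Shape of a single simulated analyzer trace.

    The injected bolus is a Gaussian excess over a drifting baseline; its
    area carries the CO2 volume, so the shape itself never enters the
    area-based processing. Times in seconds, signal in ppm CO2.
    """

    flow_rate_ml_min: float = 100.0
    baseline_ppm: float = 5.0
    drift_ppm_per_s: float = 0.002
    noise_sd_ppm: float = 0.5
    bolus_width_s: float = 10.0
    sample_interval_s: float = 1.0
    reference_duration_s: float = 120.0
    injection_time_s: float = 150.0
    trace_duration_s: float = 300.0
    #: CO2 volume (mL) present in every syringe, animals and controls alike
    #: (residual air not removed by scrubbing); cancels in the control
    #: subtraction. Zero here; SimulationConfig sets a small positive value.
    ambient_co2_ml: float = 0.0

    def validate(self) -> None:
        if self.flow_rate_ml_min <= 0:
            raise ConfigError("flow_rate_ml_min must be > 0")
        if self.noise_sd_ppm < 0 or self.bolus_width_s <= 0:
            raise ConfigError("noise_sd_ppm must be >= 0 and bolus_width_s > 0")
        if self.sample_interval_s <= 0:
            raise ConfigError("sample_interval_s must be > 0")
        if self.reference_duration_s < 5 * self.sample_interval_s:
            raise ConfigError("reference window must contain at least 5 samples")
        if self.injection_time_s < self.reference_duration_s:
            raise ConfigError("injection must not precede the reference window")
        if self.ambient_co2_ml < 0:
            raise ConfigError("ambient_co2_ml must be >= 0")


def _per_host(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {h: float(value[h]) for h in HOSTS}
    return {h: float(value) for h in HOSTS}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic split-brood study.

    Defaults reproduce the study design: 15 full-sib families split across
    three host plants, replicate counts per developmental stage and host as
    in the replication table, and a host-dependent allometry
    ``rate = a_host * mass^b`` with a common exponent.
    """

    n_families: int = 15
    replicates: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    scaling_exponent_b: float = 0.84
    #: mL CO2 h^-1 at 1 g (see module docstring for the unit convention)
    scaling_coefficient_a: dict[str, float] = field(
        default_factory=lambda: {"Urtica": 0.43, "Salix": 0.39, "Ribes": 0.44}
    )
    #: extra multiplicative factor on the rate, per host (experimental knob)
    rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {h: 1.0 for h in HOSTS}
    )
    #: SD of the family random intercept on the natural-log rate scale
    family_sd: float = 0.05
    #: SD of individual lognormal noise on the rate (natural-log scale)
    residual_sd: float = 0.10
    #: median fresh mass (g) per stage; host-invariant by default
    mass_median_g: dict[tuple[str, str], float] = field(default_factory=dict)
    #: lognormal sigma of mass (log scale)
    mass_sigma_log: float = 0.25
    #: median development time (days from hatching) per (stage, host)
    devtime_median_days: dict[tuple[str, str], float] = field(default_factory=dict)
    devtime_sigma_log: float = 0.12
    #: mL pushed through the analyzer, per stage (7 mL for 3rd instars,
    #: 10 mL for 4th instars and pupae)
    injected_volume_ml: dict[str, float] = field(
        default_factory=lambda: {"instar3": 7.0, "instar4": 10.0, "pupa": 10.0}
    )
    syringe_volume_ml: float = 20.0
    incubation_min: float = 60.0
    trace: TraceParams = field(
        default_factory=lambda: TraceParams(ambient_co2_ml=0.01)
    )
    #: animal sessions sharing one control syringe
    batch_size: int = 8
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"F": 0.4, "M": 0.4, "unknown": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mass_median_g:
            base = {"instar3": 0.045, "instar4": 0.16, "pupa": 0.30}
            self.mass_median_g = {
                (s, h): base[s] for s in STAGES for h in HOSTS
            }
        if not self.devtime_median_days:
            # ordered Urtica < Salix < Ribes at every stage; 4th-instar
            # medians chosen so median growth cost is ~equal for
            # Urtica/Salix and elevated on Ribes
            base = {
                "instar3": {"Urtica": 9.0, "Salix": 10.0, "Ribes": 12.4},
                "instar4": {"Urtica": 12.0, "Salix": 13.3, "Ribes": 16.5},
                "pupa": {"Urtica": 20.0, "Salix": 21.5, "Ribes": 24.5},
            }
            self.devtime_median_days = {
                (s, h): base[s][h] for s in STAGES for h in HOSTS
            }

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_families <= 0:
            raise ConfigError("n_families must be > 0")
        for key, n in self.replicates.items():
            if n <= 0:
                raise ConfigError(f"replicate count for {key} must be > 0")
        for stage in STAGES:
            for host in HOSTS:
                if (stage, host) not in self.replicates:
                    raise ConfigError(f"missing replicate count for {(stage, host)}")
        for host in HOSTS:
            n4 = self.replicates[("instar4", host)]
            for stage in ("instar3", "pupa"):
                if self.replicates[(stage, host)] > n4:
                    raise ConfigError(
                        f"{stage} count on {host} exceeds the 4th-instar roster"
                    )
        if any(a <= 0 for a in self.scaling_coefficient_a.values()):
            raise ConfigError("scaling_coefficient_a must be > 0 for every host")
        if any(m <= 0 for m in self.rate_multiplier.values()):
            raise ConfigError("rate_multiplier must be > 0 for every host")
        if self.family_sd < 0 or self.residual_sd < 0:
            raise ConfigError("family_sd and residual_sd must be >= 0")
        if self.mass_sigma_log < 0 or self.devtime_sigma_log < 0:
            raise ConfigError("lognormal sigmas must be >= 0")
        for stage, vol in self.injected_volume_ml.items():
            if not 0 < vol <= self.syringe_volume_ml:
                raise ConfigError(
                    f"injected volume for {stage} must be in (0, syringe_volume]"
                )
        if self.incubation_min <= 0:
            raise ConfigError("incubation_min must be > 0")
        if self.batch_size <= 0:
            raise ConfigError("batch_size must be > 0")
        self.trace.validate()

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        # tuple keys are not YAML-representable: nest as stage -> host
        for name in ("replicates", "mass_median_g", "devtime_median_days"):
            flat = d[name]
            nested: dict[str, dict[str, float]] = {}
            for (stage, host), v in flat.items():
                nested.setdefault(stage, {})[host] = v
            d[name] = nested
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for name in ("replicates", "mass_median_g", "devtime_median_days"):
            if name in d and d[name]:
                nested = d[name]
                d[name] = {
                    (stage, host): v
                    for stage, hosts in nested.items()
                    for host, v in hosts.items()
                }
        if "trace" in d and isinstance(d["trace"], Mapping):
            d["trace"] = TraceParams(**d["trace"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def null_host_config(**overrides) -> SimulationConfig:
    """A configuration with no host differences whatsoever.

    Equal allometric coefficients and identical mass/development-time
    distributions across hosts; used for type-I-error calibration and as
    the base for single-effect experiments.
    """
    cfg = SimulationConfig(**overrides)
    a = cfg.scaling_coefficient_a["Urtica"]
    cfg.scaling_coefficient_a = {h: a for h in HOSTS}
    cfg.mass_median_g = {
        (s, h): cfg.mass_median_g[(s, "Urtica")] for s in STAGES for h in HOSTS
    }
    cfg.devtime_median_days = {
        (s, h): cfg.devtime_median_days[(s, "Urtica")] for s in STAGES for h in HOSTS
    }
    return cfg
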