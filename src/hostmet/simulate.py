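"""Synthetic split-brood cohorts and raw respirometry traces.

The generator emulates the study design the analysis assumes: full-sib
families split evenly across three host plants (split-brood), per-host
rosters defined at the 4th instar, with 3rd-instar and pupal measurements
taken on seeded subsets of the same individuals. Latent metabolic rates
follow a host-dependent allometry with a common mass-scaling exponent,

    rate [mL CO2 / h] = a_host * mass[g]^b * exp(family + residual),

with a Normal family random intercept and Normal per-measurement residual
on the natural-log scale. Each measurement becomes a syringe session: a
drifting, noisy baseline followed by a Gaussian injection bolus whose
excess area carries exactly the CO2 volume implied by the latent rate,
plus one empty-syringe control per measurement batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import HOSTS, STAGES, SimulationConfig, TraceParams
from .respirometry import RespirometrySession

__all__ = ["StudyDataset", "generate_cohort", "generate_trace",
           "generate_study", "write_study"]

COHORT_COLUMNS = [
    "individual_id", "family_id", "host", "stage",
    "dev_time_days", "mass_g", "sex", "true_vco2_ml_min",
]


@dataclass
class StudyDataset:
    """A complete simulated study: tidy cohort + raw sessions."""

    cohort: pd.DataFrame
    sessions: list[RespirometrySession]
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        write_study(self, out_dir)


def _family_assignment(n_individuals: int, n_families: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Round-robin families; the remainder goes to a seeded shuffle."""
    base = np.repeat(np.arange(n_families), n_individuals // n_families)
    extra = rng.permutation(n_families)[: n_individuals % n_families]
    return np.concatenate([base, extra])


def generate_cohort(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Draw one cohort of measurement records.

    Returns a tidy frame with one row per (individual, stage) measurement;
    per-(stage, host) row counts equal the configured replicates. The
    latent rate is returned in mL min^-1 under the package's mL h^-1
    coefficient convention (see :mod:`hostmet.config`).
    """
    config.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    fam_effects = rng.normal(0.0, config.family_sd, size=config.n_families)
    b = config.scaling_exponent_b

    rows = []
    for host in HOSTS:
        n4 = config.replicates[("instar4", host)]
        families = _family_assignment(n4, config.n_families, rng)
        z_dev = rng.normal(size=n4)
        z_mass = rng.normal(size=n4)
        sexes = rng.choice(
            list(config.sex_probs), size=n4, p=list(config.sex_probs.values())
        )
        subsets = {"instar4": np.arange(n4)}
        for stage in ("instar3", "pupa"):
            n_s = config.replicates[(stage, host)]
            subsets[stage] = np.sort(rng.choice(n4, size=n_s, replace=False))
        a_host = (config.scaling_coefficient_a[host]
                  * config.rate_multiplier[host])
        for stage in STAGES:
            med_t = config.devtime_median_days[(stage, host)]
            med_m = config.mass_median_g[(stage, host)]
            for i in subsets[stage]:
                # shared per-individual quantiles keep development time and
                # mass ordered across stages within an individual
                dev = med_t * np.exp(config.devtime_sigma_log * z_dev[i])
                mass = med_m * np.exp(config.mass_sigma_log * z_mass[i])
                resid = rng.normal(0.0, config.residual_sd)
                rate_ml_h = (a_host * mass**b
                             * np.exp(fam_effects[families[i]] + resid))
                rows.append(
                    {
                        "individual_id": f"{host}_{i:03d}",
                        "family_id": f"fam_{families[i]:02d}",
                        "host": host,
                        "stage": stage,
                        "dev_time_days": dev,
                        "mass_g": mass,
                        "sex": sexes[i],
                        "true_vco2_ml_min": rate_ml_h / 60.0,
                    }
                )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def generate_trace(
    true_vco2_ml_min: float,
    params: TraceParams,
    seed=None,
    *,
    session_id: str = "S0000",
    individual_id: str = "control",
    syringe_volume_ml: float = 20.0,
    injected_volume_ml: float = 10.0,
    incubation_min: float = 60.0,
    is_control: bool = False,
    control_session_id: str | None = None,
    stage: str | None = None,
) -> RespirometrySession:
    """Synthesize one analyzer trace for a known production rate.

    The injected air carries ``(rate x incubation + ambient) x
    injected/syringe`` mL of CO2; this volume is laid down as a Gaussian
    excess over the baseline so that the (fraction x flow) time integral
    of the bolus reproduces it exactly (up to trapezoid error).
    """
    if true_vco2_ml_min < 0:
        raise ValueError("true_vco2_ml_min must be >= 0")
    params.validate()
    rng = np.random.default_rng(seed)
    width = params.bolus_width_s
    center = params.injection_time_s + 5.0 * width
    duration = max(params.trace_duration_s, center + 6.0 * width)
    t = np.arange(0.0, duration + params.sample_interval_s / 2,
                  params.sample_interval_s)

    syringe_co2_ml = true_vco2_ml_min * incubation_min + params.ambient_co2_ml
    analyzer_ml = syringe_co2_ml * injected_volume_ml / syringe_volume_ml
    # ppm*s of excess area carrying that volume at the given carrier flow
    area_ppm_s = analyzer_ml * 1e6 * 60.0 / params.flow_rate_ml_min
    height = area_ppm_s / (width * np.sqrt(2.0 * np.pi))

    signal = params.baseline_ppm + params.drift_ppm_per_s * t
    signal = signal + height * np.exp(-0.5 * ((t - center) / width) ** 2)
    if params.noise_sd_ppm > 0:
        signal = signal + rng.normal(0.0, params.noise_sd_ppm, size=t.size)

    return RespirometrySession(
        session_id=session_id,
        individual_id=individual_id,
        time_s=t,
        co2_ppm=signal,
        flow_rate_ml_min=params.flow_rate_ml_min,
        syringe_volume_ml=syringe_volume_ml,
        injected_volume_ml=injected_volume_ml,
        incubation_min=incubation_min,
        injection_time_s=params.injection_time_s,
        is_control=is_control,
        control_session_id=control_session_id,
        stage=stage,
    )


def generate_study(config: SimulationConfig, seed=None) -> StudyDataset:
    """Cohort plus raw sessions: one trace per measurement, one control
    per batch of ``config.batch_size`` animals (batched within stage, so
    every session in a batch shares the injected volume)."""
    config.validate()
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    cohort_ss, trace_ss = root.spawn(2)
    cohort = generate_cohort(config, cohort_ss)

    n_batches = 0
    for stage in STAGES:
        n_stage = sum(config.replicates[(stage, h)] for h in HOSTS)
        n_batches += -(-n_stage // config.batch_size)
    seeds = iter(trace_ss.spawn(len(cohort) + n_batches))

    sessions: list[RespirometrySession] = []
    i_session = 0
    i_control = 0
    for stage in STAGES:
        records = cohort[cohort["stage"] == stage]
        injected = config.injected_volume_ml[stage]
        for start in range(0, len(records), config.batch_size):
            batch = records.iloc[start:start + config.batch_size]
            control_id = f"C{i_control:04d}"
            i_control += 1
            sessions.append(
                generate_trace(
                    0.0, config.trace, next(seeds),
                    session_id=control_id, individual_id="control",
                    syringe_volume_ml=config.syringe_volume_ml,
                    injected_volume_ml=injected,
                    incubation_min=config.incubation_min,
                    is_control=True, stage=stage,
                )
            )
            for _, rec in batch.iterrows():
                sessions.append(
                    generate_trace(
                        rec["true_vco2_ml_min"], config.trace, next(seeds),
                        session_id=f"S{i_session:04d}",
                        individual_id=rec["individual_id"],
                        syringe_volume_ml=config.syringe_volume_ml,
                        injected_volume_ml=injected,
                        incubation_min=config.incubation_min,
                        control_session_id=control_id,
                        stage=stage,
                    )
                )
                i_session += 1
    return StudyDataset(cohort=cohort, sessions=sessions, config=config)


def write_study(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write cohort.csv plus per-session trace CSVs and JSON sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_path = out_dir / "cohort.csv"
    dataset.cohort.to_csv(cohort_path, index=False)
    trace_dir = out_dir / "traces"
    for session in dataset.sessions:
        session.write(trace_dir)
    dataset.config.to_yaml(out_dir / "config_used.yaml")
    return {"cohort": cohort_path, "traces": trace_dir}
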