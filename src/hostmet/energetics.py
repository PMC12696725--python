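"""Growth rate and growth cost: the study's two derived statistics.

Growth rate is log(mass in mg) per day of development — the mass is
converted to milligrams so the logarithm (and hence the rate) stays
positive for larvae lighter than a gram. Growth cost extrapolates the
measured CO2 production rate over the whole development and expresses it
per gram of attained mass:

    growth_cost [mL/g] = dev_time[d] / mass[g] * 24 * 60 * vco2[mL/min],

so a lower value means less respired carbon per unit of growth. The
logarithm base for the growth rate is selectable (natural by default);
the choice rescales the rate but not any host comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["growth_rate", "growth_cost", "attach_metrics"]

logger = logging.getLogger(__name__)

_LOGS = {"natural": np.log, "10": np.log10, "base10": np.log10}


def growth_rate(mass_g, dev_time_days, log_base: str = "natural"):
    """log(mass x 1000) / development time, in log-mg per day."""
    mass_g = np.asarray(mass_g, dtype=float)
    dev_time_days = np.asarray(dev_time_days, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("mass_g must be > 0")
    if np.any(dev_time_days <= 0):
        raise ValueError("dev_time_days must be > 0")
    try:
        log = _LOGS[log_base]
    except KeyError:
        raise ValueError(f"log_base must be 'natural' or '10', got {log_base!r}")
    return log(mass_g * 1000.0) / dev_time_days


def growth_cost(dev_time_days, mass_g, vco2_ml_min):
    """CO2 volume respired per gram of mass gain, mL g^-1.

    The per-minute rate is extrapolated over the development time
    (24 x 60 minutes per day) and divided by the attained mass. Negative
    rates (possible after control subtraction of near-zero signals) yield
    negative costs and are left to QC rather than truncated.
    """
    mass_g = np.asarray(mass_g, dtype=float)
    dev_time_days = np.asarray(dev_time_days, dtype=float)
    vco2_ml_min = np.asarray(vco2_ml_min, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("mass_g must be > 0")
    if np.any(dev_time_days <= 0):
        raise ValueError("dev_time_days must be > 0")
    return dev_time_days / mass_g * 24.0 * 60.0 * vco2_ml_min


def attach_metrics(
    cohort: pd.DataFrame,
    vco2: pd.DataFrame,
    log_base: str = "natural",
) -> pd.DataFrame:
    """Left-join processed rates onto the cohort and add both metrics.

    Joins on (individual_id, stage) when both tables carry a stage
    column, else on individual_id alone. Rows without a matching rate keep
    missing vco2/growth_cost — never dropped. Duplicate join keys on
    either side are a data-integrity error. A join report is logged.
    """
    keys = ["individual_id"]
    if "stage" in cohort.columns and "stage" in vco2.columns:
        keys = ["individual_id", "stage"]
    for name, df in (("cohort", cohort), ("vco2", vco2)):
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicate {keys} keys in {name} table")
    vcols = keys + [c for c in ("vco2_ml_min", "qc_flags") if c in vco2.columns]
    merged = cohort.merge(vco2[vcols], on=keys, how="left", validate="1:1")
    assert len(merged) == len(cohort)

    merged["growth_rate"] = growth_rate(
        merged["mass_g"], merged["dev_time_days"], log_base=log_base
    )
    have_rate = merged["vco2_ml_min"].notna()
    merged["growth_cost_ml_per_g"] = np.nan
    if have_rate.any():
        merged.loc[have_rate, "growth_cost_ml_per_g"] = growth_cost(
            merged.loc[have_rate, "dev_time_days"],
            merged.loc[have_rate, "mass_g"],
            merged.loc[have_rate, "vco2_ml_min"],
        )
    logger.info(
        "attach_metrics: %d cohort rows, %d with a processed rate, %d without",
        len(merged), int(have_rate.sum()), int((~have_rate).sum()),
    )
    return merged
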