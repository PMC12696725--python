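"""Stop-flow syringe respirometry: raw analyzer traces to V̇CO2.

An animal is sealed in a syringe of known volume for a fixed incubation,
after which part of the incubated air is injected through a CO2 analyzer.
The CO2 produced appears as a bolus of excess signal over the scrubbed-air
baseline. Processing follows the standard calculation chain:

1. fit a baseline to the pre-injection reference segment and subtract it;
2. convert ppm to dimensionless air fractions (ppm x 1e-6);
3. multiply by the carrier flow rate and integrate over time, giving the
   CO2 volume that passed the analyzer;
4. subtract the paired empty-syringe control, scale by
   (syringe volume / injected volume) to account for the unsampled air,
   and divide by the incubation time.

The result is the CO2 production rate in mL min^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RespirometrySession",
    "BaselineFit",
    "VCO2Result",
    "fit_baseline",
    "to_fraction",
    "integrate_bolus",
    "compute_vco2",
    "detect_bolus_window",
    "process_session",
    "TraceProcessor",
    "read_session",
    "read_session_dir",
]


class WindowError(ValueError):
    """Integration or reference window incompatible with the trace."""


@dataclass
class RespirometrySession:
    """One syringe injection run: the raw trace plus its metadata."""

    session_id: str
    individual_id: str  # "control" for empty-syringe runs
    time_s: np.ndarray
    co2_ppm: np.ndarray
    flow_rate_ml_min: float
    syringe_volume_ml: float
    injected_volume_ml: float
    incubation_min: float
    injection_time_s: float
    is_control: bool = False
    control_session_id: str | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.co2_ppm.shape:
            raise ValueError("time_s and co2_ppm must be 1-D arrays of equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if self.flow_rate_ml_min <= 0:
            raise ValueError("flow_rate_ml_min must be > 0")
        if not 0 < self.injected_volume_ml <= self.syringe_volume_ml:
            raise ValueError("need 0 < injected_volume_ml <= syringe_volume_ml")
        if self.incubation_min <= 0:
            raise ValueError("incubation_min must be > 0")

    # -- plain-text persistence (trace CSV + JSON sidecar) --------------
    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"time_s": self.time_s, "co2_ppm": self.co2_ppm}).to_csv(
            out_dir / f"{self.session_id}.csv", index=False
        )
        meta = {
            "session_id": self.session_id,
            "individual_id": self.individual_id,
            "flow_rate_ml_min": self.flow_rate_ml_min,
            "syringe_volume_ml": self.syringe_volume_ml,
            "injected_volume_ml": self.injected_volume_ml,
            "incubation_min": self.incubation_min,
            "injection_time_s": self.injection_time_s,
            "is_control": self.is_control,
            "control_session_id": self.control_session_id,
            "stage": self.stage,
        }
        with open(out_dir / f"{self.session_id}.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def read_session(trace_dir: str | Path, session_id: str) -> RespirometrySession:
    trace_dir = Path(trace_dir)
    with open(trace_dir / f"{session_id}.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(trace_dir / f"{session_id}.csv")
    return RespirometrySession(
        time_s=df["time_s"].to_numpy(),
        co2_ppm=df["co2_ppm"].to_numpy(),
        **meta,
    )


def read_session_dir(trace_dir: str | Path) -> list[RespirometrySession]:
    """Load every session (sidecar-discovered) in a directory, sorted by id."""
    trace_dir = Path(trace_dir)
    ids = sorted(p.stem for p in trace_dir.glob("*.json"))
    return [read_session(trace_dir, sid) for sid in ids]


# ----------------------------------------------------------------------
@dataclass
class BaselineFit:
    """Reference (scrubbed-air) signal model, evaluable at any time."""

    kind: str  # "linear" or "constant"
    intercept_ppm: float
    slope_ppm_per_s: float
    window: tuple[float, float]
    residual_sd_ppm: float

    def predict(self, time_s: np.ndarray) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        return self.intercept_ppm + self.slope_ppm_per_s * t


def fit_baseline(
    session: RespirometrySession,
    reference_window: tuple[float, float] | None = None,
    kind: str = "linear",
) -> BaselineFit:
    """Fit the pre-injection reference segment.

    The default window runs from the start of the trace to the injection
    marker. A first-degree polynomial absorbs analyzer drift; ``constant``
    uses the window mean.
    """
    if reference_window is None:
        reference_window = (float(session.time_s[0]), float(session.injection_time_s))
    t0, t1 = reference_window
    if t1 > session.injection_time_s:
        raise WindowError("reference window must precede the injection")
    mask = (session.time_s >= t0) & (session.time_s <= t1)
    if mask.sum() < 5:
        raise WindowError("reference window must contain at least 5 samples")
    t = session.time_s[mask]
    y = session.co2_ppm[mask]
    if kind == "constant":
        intercept, slope = float(np.mean(y)), 0.0
    elif kind == "linear":
        slope, intercept = np.polyfit(t, y, 1)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    resid = y - (intercept + slope * t)
    dof = max(mask.sum() - (1 if kind == "constant" else 2), 1)
    sd = float(np.sqrt(np.sum(resid**2) / dof))
    return BaselineFit(kind, float(intercept), float(slope), (t0, t1), sd)


def to_fraction(co2_ppm):
    """ppm CO2 -> dimensionless air fraction (ppm x 1e-6)."""
    return np.asarray(co2_ppm, dtype=float) * 1e-6


def integrate_bolus(
    session: RespirometrySession,
    baseline: BaselineFit,
    integration_window: tuple[float, float],
) -> float:
    """Baseline-excess (fraction x flow) integral over the window, in mL.

    The excess signal is converted to an air fraction and multiplied by the
    carrier flow (mL min^-1); integrating over time (minutes, trapezoidal
    rule) yields the CO2 volume that passed the analyzer.
    """
    t0, t1 = integration_window
    if t1 <= t0:
        raise WindowError("integration window must have positive length")
    if t0 > session.time_s[-1] or t1 < session.time_s[0]:
        raise WindowError("integration window lies outside the trace")
    mask = (session.time_s >= t0) & (session.time_s <= t1)
    if mask.sum() < 2:
        raise WindowError("integration window must contain at least 2 samples")
    t_min = session.time_s[mask] / 60.0
    excess_frac = to_fraction(session.co2_ppm[mask] - baseline.predict(session.time_s[mask]))
    return float(np.trapezoid(excess_frac * session.flow_rate_ml_min, t_min))


@dataclass
class VCO2Result:
    """Processed CO2 production rate with its intermediate quantities."""

    vco2_ml_min: float
    integrated_volume_ml: float
    control_volume_ml: float
    syringe_volume_ml: float
    injected_volume_ml: float
    incubation_min: float
    window: tuple[float, float] | None = None
    baseline_model: str = "linear"
    qc_flags: list[str] = field(default_factory=list)


def compute_vco2(
    sample_volume_ml: float,
    control_volume_ml: float,
    syringe_volume_ml: float,
    injected_volume_ml: float,
    incubation_min: float,
) -> VCO2Result:
    """Control-corrected syringe CO2 volume -> production rate (mL min^-1).

    The control is subtracted first, then the volume is scaled by
    (syringe / injected) to account for the air left in the syringe, and
    finally divided by the incubation time.
    """
    if injected_volume_ml <= 0:
        raise ValueError("injected_volume_ml must be > 0")
    if syringe_volume_ml < injected_volume_ml:
        raise ValueError("syringe_volume_ml must be >= injected_volume_ml")
    if incubation_min <= 0:
        raise ValueError("incubation_min must be > 0")
    corrected = sample_volume_ml - control_volume_ml
    total = corrected * (syringe_volume_ml / injected_volume_ml)
    rate = total / incubation_min
    flags = ["negative_volume"] if corrected < 0 else []
    return VCO2Result(
        vco2_ml_min=float(rate),
        integrated_volume_ml=float(sample_volume_ml),
        control_volume_ml=float(control_volume_ml),
        syringe_volume_ml=float(syringe_volume_ml),
        injected_volume_ml=float(injected_volume_ml),
        incubation_min=float(incubation_min),
        qc_flags=flags,
    )


def detect_bolus_window(
    session: RespirometrySession,
    baseline: BaselineFit,
    k: float = 3.0,
    pad_samples: int = 5,
) -> tuple[float, float] | None:
    """Contiguous region of baseline excess > k x noise-SD around the bolus.

    The noise SD comes from the reference-fit residuals; on noiseless
    traces a tiny relative threshold is used instead so the full bolus is
    captured. Returns ``None`` when no sample after the injection marker
    exceeds the threshold (no detectable bolus).
    """
    excess = session.co2_ppm - baseline.predict(session.time_s)
    post = session.time_s >= session.injection_time_s
    if not post.any():
        return None
    peak_idx_post = int(np.argmax(np.where(post, excess, -np.inf)))
    peak = excess[peak_idx_post]
    threshold = k * baseline.residual_sd_ppm
    if threshold <= 0:
        threshold = 1e-6 * max(peak, 0.0)
    if peak <= threshold or peak <= 0:
        return None
    above = excess > threshold
    lo = peak_idx_post
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx_post
    n = above.size
    while hi < n - 1 and above[hi + 1]:
        hi += 1
    lo = max(lo - pad_samples, 0)
    hi = min(hi + pad_samples, n - 1)
    return (float(session.time_s[lo]), float(session.time_s[hi]))


def process_session(
    session: RespirometrySession,
    control_session: RespirometrySession,
    window: tuple[float, float] | None = None,
    baseline: str = "linear",
    k: float = 3.0,
) -> VCO2Result:
    """Full chain: baseline -> fraction -> flow integral -> rate.

    Both the animal trace and its paired control are baselined against
    their own reference segments and integrated over the same window (the
    auto-detected bolus region of the animal trace, unless given). An
    undetectable bolus is a QC failure: the record is flagged
    ``no_bolus_detected`` and reported with rate 0, never dropped.
    """
    base_s = fit_baseline(session, kind=baseline)
    base_c = fit_baseline(control_session, kind=baseline)
    flags: list[str] = []
    if window is None:
        window = detect_bolus_window(session, base_s, k=k)
        if window is None:
            # controls legitimately lack a bolus when the ambient CO2 is
            # below the noise floor; anything else is a QC failure
            win_c = detect_bolus_window(control_session, base_c, k=k)
            window = win_c
            if not session.is_control:
                flags.append("no_bolus_detected")
        if window is None:
            result = compute_vco2(
                0.0, 0.0, session.syringe_volume_ml,
                session.injected_volume_ml, session.incubation_min,
            )
            result.qc_flags = flags or ["no_bolus_detected"]
            result.baseline_model = baseline
            return result
    vol_s = integrate_bolus(session, base_s, window)
    vol_c = integrate_bolus(control_session, base_c, window)
    result = compute_vco2(
        vol_s, vol_c, session.syringe_volume_ml,
        session.injected_volume_ml, session.incubation_min,
    )
    result.window = window
    result.baseline_model = baseline
    result.qc_flags = flags + result.qc_flags
    return result


class TraceProcessor(BaseEstimator, TransformerMixin):
    """Batch trace-to-rate transformer.

    Parameters
    ----------
    baseline : {"linear", "constant"}
        Reference-segment model subtracted from each trace.
    k : float
        Bolus-detection threshold in units of the reference noise SD.
    window : tuple of (float, float), optional
        Fixed integration window (seconds); auto-detected per trace when
        ``None``.
    """

    def __init__(self, baseline: str = "linear", k: float = 3.0,
                 window: tuple[float, float] | None = None):
        self.baseline = baseline
        self.k = k
        self.window = window

    def fit(self, X: Sequence[RespirometrySession], y=None):
        if self.baseline not in ("linear", "constant"):
            raise ValueError("baseline must be 'linear' or 'constant'")
        self.n_sessions_ = len(X)
        return self

    def transform(self, X: Sequence[RespirometrySession]) -> pd.DataFrame:
        """Process animal sessions against their paired controls.

        Returns a tidy table with one row per non-control session:
        session_id, individual_id, stage, vco2_ml_min, integrated and
        control volumes, and semicolon-joined QC flags.
        """
        controls = {s.session_id: s for s in X if s.is_control}
        rows = []
        for s in X:
            if s.is_control:
                continue
            if s.control_session_id not in controls:
                raise ValueError(
                    f"session {s.session_id}: control {s.control_session_id!r} "
                    "not found"
                )
            res = process_session(
                s, controls[s.control_session_id],
                window=self.window, baseline=self.baseline, k=self.k,
            )
            rows.append(
                {
                    "session_id": s.session_id,
                    "individual_id": s.individual_id,
                    "stage": s.stage,
                    "vco2_ml_min": res.vco2_ml_min,
                    "integrated_volume_ml": res.integrated_volume_ml,
                    "control_volume_ml": res.control_volume_ml,
                    "qc_flags": ";".join(res.qc_flags),
                }
            )
        return pd.DataFrame(rows)
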