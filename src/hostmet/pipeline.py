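"""End-to-end pipeline: simulate -> process -> metrics -> fit -> report.

Every run is fully determined by a configuration and a single seed; the
per-stage outputs (cohort.csv, traces/, vco2.csv, metrics.csv, fits.json)
are plain text, and a manifest records their SHA-256 hashes together with
QC counters so a finished run can be verified and summarized later.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import HOSTS, LARVAL_STAGES, SimulationConfig
from .energetics import attach_metrics
from .models import LinearMixedModel, MassScalingModel
from .respirometry import TraceProcessor, read_session_dir
from .simulate import generate_study, write_study

__all__ = ["RunManifest", "run_all", "make_report",
           "fit_growth_rate", "fit_vco2_model", "fit_growth_cost",
           "fit_mass_scaling_table", "fit_all_models"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    out_dir: str
    version: str
    config_hash: str
    files: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    qc: dict[str, int] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def verify_files(self, root: Path) -> list[str]:
        """Names of files that are missing or whose hash changed."""
        bad = []
        for rel, digest in self.files.items():
            p = root / rel
            if not p.exists() or _sha256(p) != digest:
                bad.append(rel)
        return bad


# ----------------------------------------------------------------------
# model-fitting helpers shared by the pipeline and the `fit` CLI command

def _prepare(metrics: pd.DataFrame) -> pd.DataFrame:
    d = metrics.copy()
    hosts = [h for h in HOSTS if h in set(d["host"])] or sorted(set(d["host"]))
    d["host"] = pd.Categorical(d["host"], categories=hosts)
    if "stage" in d.columns:
        stages = [s for s in ("instar3", "instar4", "pupa")
                  if s in set(d["stage"])]
        d["stage"] = pd.Categorical(d["stage"], categories=stages)
    if "mass_g" in d.columns:
        d["ln_mass"] = np.log(d["mass_g"].to_numpy(dtype=float))
    return d


def fit_growth_rate(metrics: pd.DataFrame) -> LinearMixedModel:
    """Host effect on 4th-instar growth rate, family random intercept."""
    d = _prepare(metrics)
    d = d[d["stage"] == "instar4"] if "stage" in d.columns else d
    return LinearMixedModel("growth_rate ~ host").fit(d)


def fit_vco2_model(metrics: pd.DataFrame) -> LinearMixedModel:
    """Host x larval stage + ln(mass) on the raw production rate, with an
    individual-in-family nested random intercept (larval stages only)."""
    d = _prepare(metrics)
    d = d[d["stage"].isin(LARVAL_STAGES)]
    d["stage"] = d["stage"].cat.remove_unused_categories()
    return LinearMixedModel(
        "vco2_ml_min ~ host * stage + ln_mass", nested="individual_id"
    ).fit(d)


def fit_growth_cost(metrics: pd.DataFrame) -> LinearMixedModel:
    """Host effect on 4th-instar growth cost, family random intercept."""
    d = _prepare(metrics)
    d = d[d["stage"] == "instar4"] if "stage" in d.columns else d
    return LinearMixedModel("growth_cost_ml_per_g ~ host").fit(d)


def fit_mass_scaling_table(metrics: pd.DataFrame) -> MassScalingModel:
    """Common-slope allometry on the larval measurements."""
    d = _prepare(metrics)
    if "stage" in d.columns:
        d = d[d["stage"].isin(LARVAL_STAGES)]
    return MassScalingModel().fit(d)


def _lmm_payload(model: LinearMixedModel, factor: str = "host") -> dict:
    return {
        "fixed_effects": model.fixed_effects_.to_dict(orient="records"),
        "random_variances": model.random_variances_,
        "wald_chi2": model.wald_table_.to_dict(orient="records"),
        "contrasts": model.contrasts(factor).to_dict(orient="records"),
        "converged": model.converged_,
        "n_obs": int(model.result_.nobs),
    }


def fit_all_models(metrics: pd.DataFrame) -> dict:
    """The four fitted analyses as a JSON-serializable dictionary."""
    scaling = fit_mass_scaling_table(metrics)
    payload = {
        "mass_scaling": {
            "exponent_b": scaling.exponent_b_,
            "coefficients_a_ml_per_h": scaling.coefficients_a_,
            "interaction_lrt": scaling.interaction_lrt_,
            "host_test": scaling.host_test_,
            "slope_test": scaling.slope_test_,
            "n_obs": scaling.n_obs_,
            "n_excluded": scaling.n_excluded_,
        },
        "growth_rate": _lmm_payload(fit_growth_rate(metrics)),
        "vco2": _lmm_payload(fit_vco2_model(metrics)),
        "growth_cost": _lmm_payload(fit_growth_cost(metrics)),
    }
    return payload


# ----------------------------------------------------------------------
def run_all(config: SimulationConfig, seed: int, out_dir: str | Path) -> RunManifest:
    """Execute every stage into ``out_dir`` and return the manifest.

    Stages: simulate (cohort + raw traces), process (traces -> V̇CO2),
    metrics (growth rate / growth cost), fit (all four models). Any stage
    failure aborts with the stage named; earlier outputs are preserved.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.validate()
    manifest = RunManifest(
        seed=int(seed), out_dir=str(out_dir), version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
    )

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        study = generate_study(config, seed)
        write_study(study, out_dir)
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
        logger.info("simulate: %d cohort rows, %d sessions",
                    len(study.cohort), len(study.sessions))

        stage = "process"
        t0 = time.perf_counter()
        sessions = read_session_dir(out_dir / "traces")
        vco2 = TraceProcessor().fit(sessions).transform(sessions)
        vco2.to_csv(out_dir / "vco2.csv", index=False)
        manifest.qc["sessions_flagged"] = int(
            (vco2["qc_flags"].fillna("") != "").sum()
        )
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
        logger.info("process: %d sessions, %d flagged",
                    len(vco2), manifest.qc["sessions_flagged"])

        stage = "metrics"
        t0 = time.perf_counter()
        metrics = attach_metrics(study.cohort, vco2)
        if len(metrics) != len(study.cohort):
            raise RuntimeError("row loss while attaching metrics")
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        manifest.qc["rows_missing_vco2"] = int(metrics["vco2_ml_min"].isna().sum())
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)

        stage = "fit"
        t0 = time.perf_counter()
        fits = fit_all_models(metrics)
        with open(out_dir / "fits.json", "w") as fh:
            json.dump(fits, fh, indent=1, sort_keys=True)
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for rel in ("cohort.csv", "vco2.csv", "metrics.csv", "fits.json",
                "config_used.yaml"):
        manifest.files[rel] = _sha256(out_dir / rel)
    manifest.write(out_dir / "manifest.json")
    return manifest


# ----------------------------------------------------------------------
def _fmt_table(records: list[dict], columns: list[str]) -> str:
    if not records:
        return "  (no data)\n"
    df = pd.DataFrame(records)
    cols = [c for c in columns if c in df.columns]
    return df[cols].to_string(index=False, float_format=lambda v: f"{v:.6g}") + "\n"


def make_report(run_dir: str | Path) -> tuple[str, bool]:
    """Human-readable summary of a finished run.

    Returns (text, ok); ``ok`` is False when data are missing or any
    recorded file hash no longer matches (tampered or incomplete run).
    """
    run_dir = Path(run_dir)
    lines: list[str] = ["Host-plant energetics pipeline report",
                        "=" * 38, ""]
    ok = True
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        return "\n".join(lines + ["ERROR: no manifest.json (incomplete run)"]), False
    manifest = RunManifest.read(manifest_path)
    lines += [f"seed: {manifest.seed}",
              f"package version: {manifest.version}",
              f"config hash: {manifest.config_hash[:16]}…"]
    bad = manifest.verify_files(run_dir)
    if bad:
        ok = False
        lines.append(f"INTEGRITY FAILURE: modified or missing files: {', '.join(bad)}")
    else:
        lines.append("file hashes: verified")
    lines.append("")

    lines.append("QC summary")
    lines.append("-" * 10)
    if manifest.qc:
        for k, v in sorted(manifest.qc.items()):
            lines.append(f"  {k}: {v}")
    else:
        lines.append("  (no data)")
    lines.append("")

    fits_path = run_dir / "fits.json"
    if not fits_path.exists():
        lines.append("ERROR: fits.json missing — no model results")
        return "\n".join(lines), False
    with open(fits_path) as fh:
        fits = json.load(fh)

    ms = fits.get("mass_scaling", {})
    lines.append("Mass scaling (ln rate ~ ln mass + host)")
    lines.append("-" * 39)
    if ms and ms.get("n_obs", 0) > 0:
        lines.append(f"  exponent b: {ms['exponent_b']:.4f}")
        for h, a in ms["coefficients_a_ml_per_h"].items():
            lines.append(f"  a[{h}]: {a:.4f} mL/h at 1 g")
        ilrt = ms["interaction_lrt"]
        lines.append(
            f"  mass x host interaction LRT: chi2={ilrt['chi2']:.3f} "
            f"df={ilrt['df']} p={ilrt['p']:.4g}"
        )
        lines.append(f"  n = {ms['n_obs']} (excluded: {ms['n_excluded']})")
    else:
        lines.append("  (no data)")
        ok = False
    lines.append("")

    for key, title in (("growth_rate", "Growth rate ~ host + (1|family)"),
                       ("vco2", "V̇CO2 ~ host x stage + ln mass + (1|family/individual)"),
                       ("growth_cost", "Growth cost ~ host + (1|family)")):
        lines.append(title)
        lines.append("-" * len(title))
        payload = fits.get(key)
        if not payload or not payload.get("fixed_effects"):
            lines.append("  (no data)")
            ok = False
            lines.append("")
            continue
        lines.append("  Fixed effects:")
        lines.append(_fmt_table(payload["fixed_effects"],
                                ["term", "estimate", "se"]))
        lines.append("  Type-II Wald chi-square tests:")
        lines.append(_fmt_table(payload["wald_chi2"], ["term", "chi2", "df", "p"]))
        lines.append("  Tukey-adjusted pairwise host contrasts:")
        lines.append(_fmt_table(payload["contrasts"],
                                ["contrast", "estimate", "se", "z",
                                 "p_unadjusted", "p_tukey"]))
        rv = payload.get("random_variances", {})
        lines.append("  Random-effect variances: "
                     + ", ".join(f"{k}={v:.4g}" for k, v in rv.items()))
        lines.append("")
    return "\n".join(lines), ok
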