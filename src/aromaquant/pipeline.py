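"""End-to-end runs: quantification and odor profiling over CSV inputs.

``run_quantify`` takes a registry, per-batch calibration curves and observed
peak areas, fits response factors and the RF-vs-ECN model, and writes a
dual-unit concentration table plus a calibration QC report.  ``run_profile``
takes a concentration table and the registry and writes the aggregation
reports: group sums, relative composition, major-compound set, odor activity
values with relative proportions, and trend fits.  Both are deterministic
functions of (inputs, config) and write a manifest of input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import odor, profile, trends
from .registry import Compound, load_registry_csv

__all__ = ["RunConfig", "run_quantify", "run_profile", "format_value"]

logger = logging.getLogger(__name__)

#: QC norms: calibration replicate CV and curve linearity flags.
CV_WARN_PERCENT = 4.0
R2_WARN = 0.99


@dataclass
class RunConfig:
    """Inputs and knobs for a pipeline run."""

    registry_csv: Path
    out_dir: Path
    calibration_csv: Path | None = None
    areas_csv: Path | None = None
    concentrations_csv: Path | None = None
    dt_csv: Path | None = None
    daily_totals_csv: Path | None = None
    molar_volume: float = cal.DEFAULT_MOLAR_VOLUME
    threshold_policy: str = "max"
    rc_cutoff: float = 0.05
    include_bdl_in_sums: bool = False
    include_bdl_in_oav: bool = False
    rf_estimator: str = "zero_intercept"
    geometry: cal.SamplingGeometry = field(default_factory=cal.SamplingGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rc_cutoff > 0:
            raise ValueError("rc_cutoff must be > 0")


def format_value(x: float) -> str:
    """Report formatting: 3 significant figures, scientific below 1."""
    if pd.isna(x):
        return ""
    if x == 0:
        return "0"
    return f"{x:#.3g}" if abs(x) >= 1 else f"{x:.2E}"


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(config: RunConfig, out_dir: Path, inputs: list[Path]) -> None:
    manifest = {
        "inputs": {str(p): _sha256(p) for p in inputs if p is not None},
        "molar_volume": config.molar_volume,
        "threshold_policy": config.threshold_policy,
        "rc_cutoff": config.rc_cutoff,
        "seed": config.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def fit_standard_rfs(calibration_df: pd.DataFrame,
                     estimator: str = "zero_intercept") -> pd.DataFrame:
    """Per-standard mean RF with QC stats from per-batch calibration curves.

    Input columns: compound, batch_day, loading_ng, area.  Output columns:
    compound, rf, r2, cv_percent, rse_percent, n_batches, plus QC flags.
    """
    rows = []
    for name, sub in calibration_df.groupby("compound"):
        fits = [cal.fit_calibration_curve(
                    list(zip(b["loading_ng"], b["area"])), name, estimator)
                for _, b in sub.groupby("batch_day")]
        rfs = [f.rf for f in fits]
        rf_mean = float(np.mean(rfs))
        r2_mean = float(np.mean([f.r2 for f in fits]))
        cv = cal.rf_cv(rfs) if len(rfs) > 1 else 0.0
        rse = cal.rf_rse(rfs) if len(rfs) > 1 else 0.0
        rows.append(dict(compound=name, rf=rf_mean, r2=r2_mean,
                         cv_percent=cv, rse_percent=rse, n_batches=len(rfs),
                         cv_flag=cv > CV_WARN_PERCENT, r2_flag=r2_mean < R2_WARN))
    report = pd.DataFrame(rows)
    for _, r in report[report.cv_flag | report.r2_flag].iterrows():
        logger.warning("calibration QC: %s CV=%.2f%% R2=%.4f", r.compound,
                       r.cv_percent, r.r2)
    return report


def run_quantify(config: RunConfig):
    """Quantify observed areas into a dual-unit concentration table.

    Standards are quantified with their own mean RF; ECN-eligible compounds
    without a standard use the RF predicted from the RF-vs-ECN regression;
    compounds that are neither (non-C/H/O without a standard) are reported
    as missing with a warning, never extrapolated.
    """
    for name in ("calibration_csv", "areas_csv"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"run_quantify requires {name} ({p})")
    registry = load_registry_csv(config.registry_csv)
    by_name = {c.name: c for c in registry}
    cal_df = pd.read_csv(config.calibration_csv)
    areas = pd.read_csv(config.areas_csv)
    if areas.empty:
        raise ValueError(f"{config.areas_csv}: no peak areas to quantify")

    report = fit_standard_rfs(cal_df, config.rf_estimator)
    rf_direct = dict(zip(report["compound"], report["rf"]))
    standards = [(cal.compute_ecn(by_name[n].moieties), rf)
                 for n, rf in rf_direct.items()
                 if n in by_name and by_name[n].ecn_eligible]
    model = cal.fit_rf_vs_ecn(standards)

    rows, skipped = [], []
    for _, r in areas.iterrows():
        c = by_name.get(r["compound"])
        if c is None:
            skipped.append(r["compound"])
            continue
        if c.name in rf_direct:
            rf = rf_direct[c.name]
        elif c.ecn_eligible:
            rf = cal.predict_rf(model, cal.compute_ecn(c.moieties))
        else:
            skipped.append(c.name)
            continue
        ugm3 = cal.quantify(r["area"], rf, config.geometry)
        rows.append(dict(
            compound=c.name, group=c.group, day=int(r["day"]),
            conc_ppb=cal.ugm3_to_ppb(ugm3, c.mw, config.molar_volume),
            conc_ugm3=ugm3, bdl=False))
    if skipped:
        logger.warning("skipped %d area rows without RF route: %s",
                       len(skipped), sorted(set(skipped)))
    conc = profile.validate_concentration_table(pd.DataFrame(rows))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conc.to_csv(out / "concentrations.csv", index=False)
    report.to_csv(out / "calibration_report.csv", index=False)
    pd.DataFrame([dict(slope=model.slope, intercept=model.intercept,
                       r2=model.r2, n_standards=model.n_standards)]
                 ).to_csv(out / "rf_ecn_model.csv", index=False)
    _write_manifest(config, out, [config.registry_csv, config.calibration_csv,
                                  config.areas_csv])
    return conc, report, model


def run_profile(config: RunConfig):
    """Aggregate a concentration table into RC / OAV / trend reports."""
    if config.concentrations_csv is None or not Path(config.concentrations_csv).exists():
        raise FileNotFoundError(
            f"run_profile requires concentrations_csv ({config.concentrations_csv})")
    registry = load_registry_csv(config.registry_csv)
    conc = profile.validate_concentration_table(
        pd.read_csv(config.concentrations_csv))

    if config.daily_totals_csv and Path(config.daily_totals_csv).exists():
        tot = pd.read_csv(config.daily_totals_csv)
        totals = dict(zip(tot["day"].astype(int), tot["total_ugm3"]))
    else:  # whole profile = the table itself
        totals = (conc[~conc["bdl"]].groupby("day")["conc_ugm3"].sum().to_dict())

    sums = profile.group_sums(conc, include_bdl=config.include_bdl_in_sums)
    rc = profile.relative_composition(conc, totals)
    major = profile.select_major(rc, config.rc_cutoff)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sums.to_csv(out / "group_sums.csv", index=False)
    rc.to_csv(out / "relative_composition.csv", index=False)
    major.to_csv(out / "major_compounds.csv", index=False)

    results = {"group_sums": sums, "relative_composition": rc,
               "major_compounds": major}

    has_thresholds = any(c.has_threshold for c in registry)
    if not has_thresholds:
        logger.warning("no odor thresholds in registry: OAV stage skipped")
    else:
        oav_table = odor.build_oav_table(conc, registry, config.threshold_policy,
                                         config.include_bdl_in_oav)
        rp = pd.concat([odor.relative_proportion(oav_table, d)
                        for d in sorted(conc["day"].unique())
                        if odor.sum_oav(oav_table, day=d) > 0],
                       ignore_index=True)
        oav_sums = {int(d): odor.sum_oav(oav_table, day=int(d))
                    for d in sorted(conc["day"].unique())}
        oav_table.to_csv(out / "oav.csv", index=False)
        rp.to_csv(out / "relative_proportion.csv", index=False)
        results["oav"] = oav_table
        results["rp"] = rp
        results["oav_sums"] = oav_sums

        fit_rows = []
        positive = {d: v for d, v in oav_sums.items() if v > 0}
        if len(positive) >= 3:
            f = trends.intensity_trend(list(positive), list(positive.values()))
            fit_rows.append(dict(fit="log10_sum_oav_vs_day", slope=f.slope,
                                 intercept=f.intercept, r2=f.r2, p=f.p_value, n=f.n))
            results["intensity_fit"] = f
        if config.dt_csv and Path(config.dt_csv).exists():
            dt = pd.read_csv(config.dt_csv)
            dt_map = dict(zip(dt["day"].astype(int), dt["dt_ratio"]))
            common = sorted(set(dt_map) & set(positive))
            if len(common) >= 3:
                f = trends.oav_dt_correlation(
                    {d: positive[d] for d in common},
                    {d: dt_map[d] for d in common})
                fit_rows.append(dict(fit="log10_sum_oav_vs_log10_dt",
                                     slope=f.slope, intercept=f.intercept,
                                     r2=f.r2, p=f.p_value, n=f.n))
                results["dt_fit"] = f
        if fit_rows:
            pd.DataFrame(fit_rows).to_csv(out / "trend_fits.csv", index=False)

    _write_manifest(config, out, [config.registry_csv,
                                  Path(config.concentrations_csv)])
    return results
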