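"""Configuration-driven orchestration of the full analysis.

``run_case`` carries one vessel from geometry (synthetic or imported
shear fields) through boundary conditions, the analytic shear engine and
the per-segment metric summary, writing every intermediate artifact with
a provenance manifest. ``run_cohort_study`` repeats this over a synthetic
cohort with case-to-case anatomical and flow variation, joins the
per-case summaries to generated outcomes, and runs the association
stages (adjusted OLS with BH correction, Cox PH, ROC cutoff,
Kaplan-Meier).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .centerline import (
    CenterlinePolyline,
    add_flow_extensions,
    curvature_profile,
    resample_centerline,
    split_branches,
    tortuosity,
    trim_extensions,
)
from .engine import (
    DEFAULT_N_TIMEPOINTS,
    SteadyWSSField,
    WSSTimeSeriesField,
    load_external_wss_series,
    synthesize_steady_wss_field,
    synthesize_wss_field,
)
from .flow import (
    DEFAULT_N_MODES,
    FluidProperties,
    OutletResistanceSpec,
    fourier_decompose,
    reconstruct_waveform,
    regurgitant_fraction,
    resistance_network,
    steady_inflow,
)
from .metrics import HemodynamicSummary, summarize_case
from .stats import (
    bh_adjust,
    dichotomize_by_median_time,
    exclude_interscan_pvr,
    fit_cox,
    fit_linear_outcome,
    km_curve,
    roc_optimal_cutoff,
)
from .synthetic import (
    CohortSpec,
    WaveformSpec,
    default_pa_spec,
    make_flow_waveform,
    make_pa_bifurcation,
)

#: steady-protocol metadata retained for parity with solver practice
STEADY_DURATION_S = 2.5
SOLVER_TIMESTEP_S = 1e-4
PULSATILE_N_CYCLES = 5


@dataclass
class RunConfig:
    """Protocol constants and paths for one run.

    Defaults encode the analysis protocol: 0.1 cm centerline resampling,
    10 Fourier modes for the inlet waveform, 20 output timepoints per
    cycle, 2 indexed Wood units at each branch outlet (1 iWU total), and
    standard blood properties (rho = 1.06 g/cm^3, mu = 0.04 g/(cm s)).
    """

    mode: str = "synthetic"  # or "import"
    outdir: str = "pahemo_run"
    import_files: list[str] = field(default_factory=list)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    resistances_iwu: dict[str, float] = field(
        default_factory=lambda: {"LPA": 2.0, "RPA": 2.0}
    )
    bsa: float = 1.0
    n_fourier_modes: int = DEFAULT_N_MODES
    n_output_timepoints: int = DEFAULT_N_TIMEPOINTS
    centerline_step: float = 0.1
    heart_rate: float = 75.0
    forward_volume: float = 100.0
    regurgitant_fraction: float = 0.40
    add_extensions: bool = True
    seed: int = 0
    # stats options
    linear_outcome: str = "RVEDVi"
    bh_family: str = "per_outcome"  # or "global"

    def steady_protocol_steps(self) -> int:
        return int(round(STEADY_DURATION_S / SOLVER_TIMESTEP_S))


def _geometry_metrics(
    centerlines: dict[str, CenterlinePolyline], step: float
) -> dict[str, dict[str, float]]:
    """Curvature/tortuosity per branch path (inlet -> branch outlet)."""
    out: dict[str, dict[str, float]] = {}
    mpa = centerlines["MPA"]
    for branch in ("LPA", "RPA"):
        path = CenterlinePolyline(
            np.vstack([mpa.points, centerlines[branch].points[1:]])
        )
        resampled = resample_centerline(path, step)
        prof = curvature_profile(resampled)
        tort = tortuosity(resampled)
        out[branch] = {
            "mean_curvature": prof.mean_kappa,
            "tortuosity": tort.tortuosity,
            "path_length": tort.path_length,
        }
    return out


def run_case(
    config: RunConfig,
    case_id: str = "case",
    pa_spec=None,
    waveform_spec: WaveformSpec | None = None,
    write_artifacts: bool = True,
) -> tuple[HemodynamicSummary, dict]:
    """One vessel through the whole pipeline; returns (summary, manifest)."""
    outdir = Path(config.outdir) / case_id
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "case_id": case_id,
        "seed": config.seed,
        "protocol": {
            "centerline_step_cm": config.centerline_step,
            "n_fourier_modes": config.n_fourier_modes,
            "n_output_timepoints": config.n_output_timepoints,
            "steady_duration_s": STEADY_DURATION_S,
            "solver_timestep_s": SOLVER_TIMESTEP_S,
            "steady_protocol_steps": config.steady_protocol_steps(),
            "pulsatile_n_cycles": PULSATILE_N_CYCLES,
            "resistances_iwu": config.resistances_iwu,
            "density_g_cm3": config.fluid.density,
            "viscosity_g_cm_s": config.fluid.viscosity,
            "iwu_convention": "iWU = WU x BSA; absolute = iWU / BSA",
        },
    }

    if config.mode == "import":
        missing = [f for f in config.import_files if not Path(f).exists()]
        if missing:
            raise FileNotFoundError(f"missing import files: {missing}")
        field_p = load_external_wss_series(config.import_files)
        if field_p.labeling is None:
            raise ValueError("imported series lacks segment labels")
        inflow = None
        summary = summarize_case(None, field_p, inflow_at_timepoints=None)
        manifest["mode"] = "import"
        if write_artifacts:
            summary.to_tidy().to_csv(outdir / "summary.csv", index=False)
            pio.write_sidecar(outdir / "manifest.json", manifest)
        return summary, manifest

    # -- synthetic path ------------------------------------------------------
    if pa_spec is None:
        pa_spec = default_pa_spec()
    if waveform_spec is None:
        waveform_spec = WaveformSpec(
            heart_rate=config.heart_rate,
            forward_volume=config.forward_volume,
            regurgitant_fraction=config.regurgitant_fraction,
        )

    mesh, centerlines, truth_labeling = make_pa_bifurcation(pa_spec)
    radii = {
        "MPA": pa_spec.mpa.radii(centerlines["MPA"].arclength),
        "LPA": pa_spec.lpa.radii(centerlines["LPA"].arclength),
        "RPA": pa_spec.rpa.radii(centerlines["RPA"].arclength),
    }
    labeling = split_branches(mesh, centerlines, radii=radii)
    manifest["label_agreement_with_truth"] = float(
        np.mean(labeling.labels == truth_labeling.labels)
    )

    if config.add_extensions:
        junction = centerlines["LPA"].points[0]
        mpa_radius = pa_spec.mpa.radii(np.array([0.0]))[0]
        ext_mesh, ext_labeling = add_flow_extensions(
            mesh,
            labeling,
            exclude_near=junction,
            exclude_radius=2.0 * mpa_radius,
        )
    else:
        ext_mesh, ext_labeling = mesh, labeling

    geom = _geometry_metrics(centerlines, config.centerline_step)
    manifest["geometry"] = geom

    waveform = make_flow_waveform(waveform_spec)
    ff = fourier_decompose(waveform, config.n_fourier_modes)
    net_sv = waveform.net_volume()
    q_steady = steady_inflow(net_sv, waveform_spec.heart_rate)
    manifest["waveform"] = {
        "heart_rate_bpm": waveform_spec.heart_rate,
        "forward_volume_ml": waveform.forward_volume(),
        "net_volume_ml": net_sv,
        "regurgitant_fraction": regurgitant_fraction(waveform),
        "steady_inflow_ml_s": q_steady,
    }

    total_r, fractions = resistance_network(
        OutletResistanceSpec(config.resistances_iwu, bsa=config.bsa)
    )
    manifest["resistance"] = {
        "total_iwu": total_r,
        "flow_fractions": fractions,
    }

    field_p = synthesize_wss_field(
        ext_mesh, ext_labeling, centerlines, ff, config.fluid,
        flow_fractions=fractions, n_timepoints=config.n_output_timepoints,
    )
    field_s = synthesize_steady_wss_field(
        ext_mesh, ext_labeling, centerlines, q_steady, config.fluid,
        flow_fractions=fractions,
    )

    # trim extensions before any segment metric
    keep = ext_labeling.analysis_mask()
    from .centerline import SegmentLabeling

    trimmed = SegmentLabeling(
        labels=ext_labeling.labels[keep], areas=ext_labeling.areas[keep]
    )
    pulsatile = WSSTimeSeriesField(
        wall_points=field_p.wall_points[keep],
        areas=field_p.areas[keep],
        times=field_p.times,
        vectors=field_p.vectors[keep],
        labeling=trimmed,
    )
    steady = SteadyWSSField(
        wall_points=field_s.wall_points[keep],
        areas=field_s.areas[keep],
        scalars=trim_extensions(field_s.scalars, ext_labeling),
        labeling=trimmed,
    )

    inflow_at_tp = reconstruct_waveform(ff, pulsatile.times)
    summary = summarize_case(steady, pulsatile, inflow_at_timepoints=inflow_at_tp)
    for branch, g in geom.items():
        summary.values.setdefault(branch, {}).update(
            {"mean_curvature": g["mean_curvature"], "tortuosity": g["tortuosity"]}
        )
    summary.metadata.update(manifest["protocol"])

    if write_artifacts:
        pio.write_stl(outdir / "wall.stl", mesh)
        pio.write_vtp_surface(
            outdir / "wall.vtp", mesh, point_data={"Label": labeling.labels}
        )
        for name, line in centerlines.items():
            pio.write_centerline_csv(outdir / f"centerline_{name}.csv", line)
        pio.write_waveform_csv(outdir / "waveform.csv", waveform)
        pio.write_wss_series(outdir / "wss_series", pulsatile)
        summary.to_tidy().to_csv(outdir / "summary.csv", index=False)
        pio.write_sidecar(outdir / "manifest.json", manifest)
    return summary, manifest


def _varied_case_specs(rng: np.random.Generator, config: RunConfig):
    """Anatomy and flow jittered around the cohort-typical defaults."""
    # curvature x radius stays below 1 so tubes cannot self-intersect
    pa = default_pa_spec(
        mpa_radius=rng.uniform(1.2, 1.8),
        lpa_radius=rng.uniform(0.55, 0.85),
        rpa_radius=rng.uniform(0.85, 1.2),
        lpa_curvature=rng.uniform(0.7, 1.1),
        rpa_curvature=rng.uniform(0.45, 0.75),
    )
    wf = WaveformSpec(
        heart_rate=rng.uniform(60.0, 100.0),
        forward_volume=rng.uniform(60.0, 120.0),
        regurgitant_fraction=float(np.clip(rng.normal(0.40, 0.10), 0.0, 0.7)),
    )
    return pa, wf


def run_cohort_study(
    config: RunConfig,
    n_cases: int = 12,
    cohort_spec: CohortSpec | None = None,
    predictors: tuple[str, ...] = ("WSS_steady_avg", "taWSS_avg", "OSI_avg"),
    regions: tuple[str, ...] = ("whole", "MPA", "LPA", "RPA"),
    write_artifacts: bool = True,
) -> dict:
    """Synthetic cohort end to end: cases, summaries, association stages.

    Per-case hemodynamic summaries become the predictor table; outcomes
    and event times come from the synthetic cohort generator so that
    every estimated association has a known truth. Returns a dict of
    result tables; the audit log records every exclusion.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    rng = np.random.default_rng(config.seed)
    outdir = Path(config.outdir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n_cases):
        pa, wf = _varied_case_specs(rng, config)
        summary, _ = run_case(
            config, case_id=f"case_{i:03d}", pa_spec=pa, waveform_spec=wf,
            write_artifacts=False,
        )
        row: dict = {"case_id": f"case_{i:03d}"}
        for region in regions:
            for metric, value in summary.values.get(region, {}).items():
                row[f"{region}:{metric}"] = value
        rows.append(row)
    case_table = pd.DataFrame(rows)

    if cohort_spec is None:
        cohort_spec = CohortSpec(n_patients=n_cases, seed=int(rng.integers(2**31)))
    cohort, survival = make_synthetic_cohort_with_predictors(
        cohort_spec, case_table, regions, predictors
    )

    audit: list[dict] = []
    cohort_lin, entry = exclude_interscan_pvr(cohort)
    audit.append(entry)

    predictor_cols = [
        c for c in case_table.columns if c != "case_id" and cohort[c].notna().all()
    ]
    linear_rows = []
    for col in predictor_cols:
        try:
            res = fit_linear_outcome(cohort_lin, cohort_spec.outcome, col)
        except ValueError as exc:
            audit.append({"stage": "linear", "predictor": col, "skipped": str(exc)})
            continue
        linear_rows.append(
            {
                "outcome": cohort_spec.outcome,
                "predictor": col,
                "effect_estimate": res.effect_estimate,
                "unadjusted_p": res.unadjusted_p,
            }
        )
    linear_table = pd.DataFrame(linear_rows)
    if not linear_table.empty:
        linear_table["adjusted_p"] = bh_adjust(linear_table["unadjusted_p"].to_numpy())

    cox_rows = []
    km_tables: dict[str, dict] = {}
    if survival["event"].sum() == 0:
        audit.append({"stage": "cox", "skipped": "zero events in cohort"})
    else:
        for col in predictor_cols:
            try:
                res = fit_cox(survival, col)
            except (ValueError, RuntimeError) as exc:
                audit.append({"stage": "cox", "predictor": col, "skipped": str(exc)})
                continue
            cox_rows.append(
                {
                    "predictor": col,
                    "hazard_ratio": res.hazard_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "schoenfeld_ok": res.schoenfeld_ok,
                }
            )
            if res.p < 0.05:
                labels = dichotomize_by_median_time(survival)
                scores = survival.loc[labels.index, col]
                cut, sens, spec_, direction = roc_optimal_cutoff(
                    scores.to_numpy(), labels.to_numpy()
                )
                group = np.where(
                    survival[col] >= cut, "above_cutoff", "below_cutoff"
                )
                km_tables[col] = {
                    "cutoff": cut,
                    "sensitivity": sens,
                    "specificity": spec_,
                    "direction": direction,
                    "curves": km_curve(survival, group),
                }
    cox_table = pd.DataFrame(cox_rows)

    results = {
        "case_table": case_table,
        "cohort": cohort,
        "survival": survival,
        "linear": linear_table,
        "cox": cox_table,
        "km": km_tables,
        "audit": audit,
    }
    if write_artifacts:
        case_table.to_csv(outdir / "case_summaries.csv", index=False)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        survival.to_csv(outdir / "survival.csv", index=False)
        linear_table.to_csv(outdir / "linear_results.csv", index=False)
        cox_table.to_csv(outdir / "cox_results.csv", index=False)
        for col, km in km_tables.items():
            for grp, curve in km["curves"].items():
                safe = col.replace(":", "_")
                curve.to_csv(outdir / f"km_{safe}_{grp}.csv", index=False)
        (outdir / "audit.json").write_text(json.dumps(audit, indent=2, default=str))
        pio.write_sidecar(
            outdir / "manifest.json",
            {"n_cases": n_cases, "seed": config.seed, "config": str(asdict(config))},
        )
    return results


def make_synthetic_cohort_with_predictors(
    spec: CohortSpec,
    case_table: pd.DataFrame,
    regions,
    predictors,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort whose hemodynamic predictors are the computed case metrics.

    Outcomes and hazards follow the spec's effect maps applied to the
    (centered) computed predictors; unrelated spec predictors are ignored.
    """
    from .synthetic import RV_METRIC_BASELINES

    rng = np.random.default_rng(spec.seed)
    n = len(case_table)
    sex = (rng.random(n) < 0.59).astype(int)
    age1 = np.clip(rng.normal(12.0, 5.0, n), 1.0, 40.0)
    age2 = age1 + np.clip(rng.normal(3.5, 1.0, n), 0.5, None)
    cohort = pd.DataFrame(
        {"case_id": case_table["case_id"], "sex": sex,
         "age_at_cmr1": age1, "age_at_cmr2": age2}
    )
    for col in case_table.columns:
        if col != "case_id":
            cohort[col] = case_table[col].to_numpy()

    anchor, _ = RV_METRIC_BASELINES.get(spec.outcome, (0.0, 1.0))
    lin = np.full(n, anchor, dtype=float)
    log_hr = np.zeros(n)
    for name, coef in spec.linear_effects.items():
        if name in cohort:
            x = cohort[name].to_numpy()
            lin += coef * (x - x.mean())
    for name, lh in spec.log_hazards.items():
        if name in cohort:
            x = cohort[name].to_numpy()
            log_hr += lh * (x - x.mean())
    cohort[spec.outcome] = lin + rng.normal(0.0, spec.noise_sd, n)
    cohort["pvr_between_scans"] = (rng.random(n) < 0.1).astype(int)

    lam0 = np.log(2.0) / spec.baseline_median_days
    lam = lam0 * np.exp(log_hr)
    event_time = rng.exponential(1.0 / lam)
    if 0 < spec.censoring_rate < 1:
        lam_c = lam.mean() * spec.censoring_rate / (1.0 - spec.censoring_rate)
        censor_time = rng.exponential(1.0 / lam_c, n)
    elif spec.censoring_rate == 0:
        censor_time = np.full(n, np.inf)
    else:
        censor_time = event_time * rng.uniform(0.1, 0.99, n)
    observed = np.minimum(event_time, censor_time)
    survival = pd.DataFrame(
        {
            "case_id": case_table["case_id"],
            "time_to_event": np.maximum(observed, 1.0),
            "event": (event_time <= censor_time).astype(int),
            "sex": sex,
            "age_at_cmr": age1,
        }
    )
    for col in case_table.columns:
        if col != "case_id":
            survival[col] = case_table[col].to_numpy()
    return cohort, survival
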