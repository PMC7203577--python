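"""End-to-end orchestration of the synthetic progression study.

``run_synthetic_study`` drives the whole pipeline on generated data: a
healthy shape cohort plus n synthetic amyloid patients, each with a
baseline and a follow-up scan whose ground-truth stiffness and wall
thickness evolve according to a per-case progression scenario.  Every
stage writes plain-text artifacts (VTK meshes, CSV tables, JSON metadata)
into the output directory and is deterministic under the configured seeds;
rerunning a stage rewrites its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, io as avio, markers as mk, shapes, tables
from .forward import ReducedOrderInflation
from .inference import (
    MaterialParameterEstimator,
    propagate_markers,
    residual_bootstrap,
)
from .mechanics import uniaxial_fiber_response
from .synthetic import (
    DEFAULT_AMYLOID_TRUTH,
    CohortSpec,
    NoiseModel,
    generate_diastolic_series,
    generate_shape_cohort,
)
from .template import LVTemplateSpec, generate_template

__all__ = ["RunConfig", "run_synthetic_study", "reproduce_reference_tables"]


@dataclass
class RunConfig:
    """Study configuration; round-trips losslessly through YAML."""

    seed: int = 0
    n_cases: int = 2
    scenarios: tuple = ("Recovery", "Worsening")  # cycled over cases

    # synthetic mechanics data
    n_time: int = 13
    sigma_volume_rel: float = 0.02
    sigma_strain_abs: float = 0.01
    mech_n_circ: int = 20
    mech_n_long: int = 6
    mech_n_trans: int = 3
    endo_base_radius: float = 1.9
    epi_base_radius: float = 3.0
    apex_to_base_length: float = 8.0

    # pressure scaling
    p_edm: float = 19.0
    mean_ratio: float = 2.678

    # inference
    w_v: float = 1.0
    w_E: float = 1.0
    n_starts: int = 5
    max_nfev: int = 200
    xi_tol: float = 1e-3
    n_boot: int = 200
    refit_max_nfev: int = 40
    refit_restarts: int = 1
    n_propagate: int = 25
    lambda_max: float = 1.15

    # shape stage
    n_healthy: int = 26
    healthy_thickness_median: float = 0.77
    amyloid_thickness_median: float = 1.11
    thickness_sd: float = 0.08
    size_sd: float = 0.04
    shape_n_long: int = 143
    variance_threshold: float = 0.95

    output_dir: str = "study_output"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(d["scenarios"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["scenarios"] = tuple(d.get("scenarios", ("Recovery", "Worsening")))
        return cls(**d)


# ---------------------------------------------------------------------------
# scenario definitions: multiplicative changes from baseline to follow-up


_SCENARIO_EFFECTS = {
    # (stiffness factor on a-type constants, wall-thickness factor)
    "Recovery": (0.55, 0.92),
    "Stable": (1.0, 1.0),
    "Worsening": (1.9, 1.10),
}


def _case_seed(base_seed: int, case: int, tag: int) -> int:
    return int((base_seed * 1_000_003 + case * 101 + tag) % (2**31 - 1))


def _mech_template(cfg: RunConfig, thickness_scale: float = 1.0):
    spec = LVTemplateSpec(
        endo_base_radius=cfg.endo_base_radius,
        epi_base_radius=cfg.endo_base_radius
        + (cfg.epi_base_radius - cfg.endo_base_radius) * thickness_scale,
        apex_to_base_length=cfg.apex_to_base_length,
        n_circ=cfg.mech_n_circ,
        n_long=cfg.mech_n_long,
        n_trans=cfg.mech_n_trans,
    )
    return geometry.assign_fibers(generate_template(spec))


def _simulate_case(cfg: RunConfig, case: int):
    """Baseline + follow-up synthetic scans for one case."""
    rng = np.random.default_rng(_case_seed(cfg.seed, case, 0))
    scenario = cfg.scenarios[(case - 1) % len(cfg.scenarios)]
    stiff_f, thick_f = _SCENARIO_EFFECTS[scenario]

    jitter = float(np.exp(0.15 * rng.standard_normal()))
    truth_base = DEFAULT_AMYLOID_TRUTH.scaled(jitter)
    truth_follow = truth_base.scaled(stiff_f)

    records = {}
    records["baseline"] = generate_diastolic_series(
        _mech_template(cfg, 1.0),
        truth_base,
        n_time=cfg.n_time,
        noise=NoiseModel(cfg.sigma_volume_rel, cfg.sigma_strain_abs,
                         _case_seed(cfg.seed, case, 1)),
    )
    records["followup"] = generate_diastolic_series(
        _mech_template(cfg, thick_f),
        truth_follow,
        n_time=cfg.n_time,
        noise=NoiseModel(cfg.sigma_volume_rel, cfg.sigma_strain_abs,
                         _case_seed(cfg.seed, case, 2)),
    )
    return scenario, records


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Generate all synthetic cases; write templates and observations."""
    cases = {}
    for case in range(1, cfg.n_cases + 1):
        scenario, records = _simulate_case(cfg, case)
        cdir = outdir / f"case_{case:02d}"
        cdir.mkdir(parents=True, exist_ok=True)
        for scan, rec in records.items():
            avio.write_vtk(cdir / f"{scan}_template.vtk", rec.template)
            pd.DataFrame(
                {"frame": np.arange(rec.n_time) + 1, "volume_mL": rec.volumes_obs}
            ).to_csv(cdir / f"{scan}_volumes.csv", index=False, float_format="%.9g")
            obs = rec.ecc_obs
            rows = [
                (j + 1, k + 1, r + 1, obs[k, r, j], rec.ell_obs[k, r, j])
                for j in range(obs.shape[2])
                for k in range(obs.shape[0])
                for r in range(obs.shape[1])
            ]
            pd.DataFrame(
                rows, columns=["frame", "layer", "region", "E_cc", "E_ll"]
            ).to_csv(cdir / f"{scan}_strains.csv", index=False, float_format="%.9g")
            (cdir / f"{scan}_meta.json").write_text(
                json.dumps(
                    {
                        "p_ed_mmHg": rec.p_ed,
                        "truth_params": rec.truth_params.as_array().tolist(),
                        "noise_seed": rec.noise.seed,
                        "scenario": scenario,
                    },
                    indent=2,
                )
            )
        cases[case] = (scenario, records)
    return cases


def stage_fit(cfg: RunConfig, outdir: Path, cases: dict) -> dict:
    """Two-step fits plus residual bootstrap for every scan."""
    fits = {}
    for case, (scenario, records) in cases.items():
        cdir = outdir / f"case_{case:02d}"
        fits[case] = {}
        for tag_idx, (scan, rec) in enumerate(records.items()):
            model = ReducedOrderInflation()
            est = MaterialParameterEstimator(
                forward_model=model,
                w_v=cfg.w_v, w_E=cfg.w_E,
                n_starts=cfg.n_starts, max_nfev=cfg.max_nfev,
                xi_tol=cfg.xi_tol,
                random_state=_case_seed(cfg.seed, case, 10 + tag_idx),
            )
            est.fit(rec.as_case_data())
            boot = residual_bootstrap(
                est, rec.as_case_data(),
                n_boot=cfg.n_boot,
                seed=_case_seed(cfg.seed, case, 20 + tag_idx),
                refit_max_nfev=cfg.refit_max_nfev,
                refit_restarts=cfg.refit_restarts,
            )
            (cdir / f"{scan}_fit.json").write_text(est.result_.to_json())
            pd.DataFrame(
                boot.draws,
                columns=["a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs"],
            ).to_csv(cdir / f"{scan}_bootstrap.csv", index=False,
                     float_format="%.9g")
            # simulate at fitted parameters for curves and markers
            res = model.solve(
                rec.template, est.params_,
                np.linspace(0, rec.p_ed, cfg.n_time), bc=rec.bc,
            )
            avio.write_curve_csv(cdir / f"{scan}_pv.csv", res.curve)
            avio.write_curve_csv(
                cdir / f"{scan}_stress_stretch.csv",
                uniaxial_fiber_response(est.params_, cfg.lambda_max),
            )
            fits[case][scan] = (est, boot, res)
    return fits


def stage_shapes(cfg: RunConfig, outdir: Path, cases: dict) -> dict:
    """Healthy cohort, classification metrics, patient shape trajectories."""
    rng = np.random.default_rng(_case_seed(cfg.seed, 0, 30))
    cohort = generate_shape_cohort(
        CohortSpec(
            n_healthy=cfg.n_healthy,
            n_amyloid=max(2, cfg.n_cases),
            healthy_thickness_median=cfg.healthy_thickness_median,
            amyloid_thickness_median=cfg.amyloid_thickness_median,
            thickness_sd=cfg.thickness_sd,
            size_sd=cfg.size_sd,
            seed=_case_seed(cfg.seed, 0, 31),
            n_long=cfg.shape_n_long,
        )
    )
    metrics = {
        m: shapes.loocv_classify(cohort, method=m, variance=cfg.variance_threshold)
        for m in ("lda", "kernel_svm")
    }
    meshes = cohort.meta["meshes"]
    th = [geometry.median_wall_thickness(m) for m in meshes]
    healthy_th = [t for t, l in zip(th, cohort.labels) if l == "healthy"]
    amyloid_th = [t for t, l in zip(th, cohort.labels) if l == "amyloid"]
    p_mood = shapes.moods_median_test(healthy_th, amyloid_th)

    # trajectories: each synthetic patient moves toward (recovery) or away
    # from (worsening) the healthy group through its follow-up thickness
    traj_rows = []
    amyloid_idx = np.flatnonzero(cohort.labels == "amyloid")
    for case in range(1, cfg.n_cases + 1):
        scenario = cfg.scenarios[(case - 1) % len(cfg.scenarios)]
        _, thick_f = _SCENARIO_EFFECTS[scenario]
        subject = int(amyloid_idx[(case - 1) % len(amyloid_idx)])
        base_mesh = meshes[subject]
        t_base = th[subject]
        spec = CohortSpec(
            n_healthy=2, n_amyloid=2,
            healthy_thickness_median=cfg.healthy_thickness_median,
            amyloid_thickness_median=max(t_base * thick_f, 0.1),
            thickness_sd=0.0, size_sd=0.0, seed=0, n_long=cfg.shape_n_long,
        )
        from .synthetic import _cohort_template

        follow_mesh = _cohort_template(spec, max(t_base * thick_f, 0.1), 1.0)
        d_base, extra = shapes.lda_distance(
            cohort, subject, variance=cfg.variance_threshold,
            extra_rows=follow_mesh.surface_coordinates()[None],
        )
        d_follow = extra[0]
        traj_rows.append(
            (case, d_base, d_follow, shapes.shape_trajectory(d_base, d_follow))
        )
    traj = pd.DataFrame(
        traj_rows, columns=["case", "d_baseline", "d_followup", "direction"]
    )
    traj.to_csv(outdir / "shape_trajectories.csv", index=False,
                float_format="%.6g")
    summary = {
        "loocv": {
            m: {
                "TP": r.TP, "FP": r.FP, "FN": r.FN, "TN": r.TN,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "f1": r.f1,
            }
            for m, r in metrics.items()
        },
        "median_thickness_healthy_cm": float(np.median(healthy_th)),
        "median_thickness_amyloid_cm": float(np.median(amyloid_th)),
        "moods_median_p": p_mood,
    }
    (outdir / "shape_summary.json").write_text(json.dumps(summary, indent=2))
    return {"summary": summary, "trajectories": traj}


def stage_markers(cfg: RunConfig, outdir: Path, cases, fits, shape_out) -> pd.DataFrame:
    """Seven markers per scan, percent changes with bootstrap SDs, calls."""
    traj = shape_out["trajectories"].set_index("case")
    rows = []
    for case, (scenario, records) in cases.items():
        direction = traj.loc[case, "direction"]
        shape_dir = "toward_healthy" if direction == "down" else "away_from_healthy"
        vectors = {}
        for scan, rec in records.items():
            est, boot, res = fits[case][scan]
            model = est.forward_model
            vectors[scan] = mk.compute_markers(
                rec.template,
                [rec.template.with_points(f) for f in res.frames],
                res.curve,
                est.params_,
                shape_dir=shape_dir,
                model=model,
                lambda_max=cfg.lambda_max,
            )
        record = mk.progression_record(vectors["baseline"], vectors["followup"])
        prop = propagate_markers(
            fits[case]["baseline"][1], fits[case]["followup"][1],
            records["baseline"].as_case_data(), records["followup"].as_case_data(),
            shape_dir,
            model=fits[case]["baseline"][0].forward_model,
            lambda_max=cfg.lambda_max,
            n_use=cfg.n_propagate,
        )
        row = {"case": case, "scenario": scenario, "shape_dir": direction}
        for name in mk.MARKER_NAMES[:-1]:
            row[f"{name}_pct"] = record.pct_change[name]
            row[f"{name}_sd"] = prop.pct_sd[name]
            row[f"{name}_call"] = record.calls[name]
        row["shape_call"] = record.calls["shape"]
        row["recovery_score"] = record.recovery_score
        row["score_sd"] = prop.score_sd
        row["prob_stable_or_recovery"] = prop.prob_stable_or_recovery
        row["predicted_status"] = record.predicted_status
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "marker_changes.csv", index=False, float_format="%.6g")
    return df


def stage_score(cfg: RunConfig, outdir: Path, marker_df: pd.DataFrame) -> pd.DataFrame:
    """Table of recovery scores, predictions and the synthetic truth labels."""
    out = marker_df[
        ["case", "recovery_score", "score_sd", "predicted_status", "scenario"]
    ].copy()
    out = out.rename(columns={"scenario": "synthetic_truth"})
    preds = list(out["predicted_status"])
    labels = list(out["synthetic_truth"])
    out["agrees"] = [
        (p == "stable_or_recovery") == (c in ("Recovery", "Stable"))
        for p, c in zip(preds, labels)
    ]
    out.to_csv(outdir / "scores.csv", index=False, float_format="%.6g")
    return out


def run_synthetic_study(cfg: RunConfig, output_dir=None) -> dict:
    """Run every stage; returns the collected stage outputs."""
    outdir = Path(output_dir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    cases = stage_simulate(cfg, outdir)
    fits = stage_fit(cfg, outdir, cases)
    shape_out = stage_shapes(cfg, outdir, cases)
    marker_df = stage_markers(cfg, outdir, cases, fits, shape_out)
    scores = stage_score(cfg, outdir, marker_df)
    report = {
        "n_cases": cfg.n_cases,
        "n_agreement": int(scores["agrees"].sum()),
        "shape_summary": shape_out["summary"],
        "scores": scores.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return {
        "cases": cases,
        "fits": fits,
        "shapes": shape_out,
        "markers": marker_df,
        "scores": scores,
        "report": report,
    }


def reproduce_reference_tables(output_dir=None) -> dict:
    """Offline reproduction of the reference cohort arithmetic (see
    :mod:`amylv.tables`); optionally writes the recomputed tables as CSV."""
    rep = tables.reference_report()
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("pressures", "vratio_changes", "marker_calls", "scores",
                    "predictions"):
            rep[key].to_csv(outdir / f"reference_{key}.csv", index=False)
        summary = {
            k: v for k, v in rep.items() if not isinstance(v, pd.DataFrame)
        }
        (outdir / "reference_summary.json").write_text(json.dumps(summary, indent=2))
    return rep
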