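"""Synthetic LV data: diastolic mesh series and two-class shape cohorts.

Every downstream stage of the package (strain extraction, parameter
inference, markers, shape statistics) is testable without clinical images:
this module generates truncated prolate-spheroid templates, inflates them
with the reduced-order forward model under a linear diastolic pressure ramp
with known ground-truth material parameters, and perturbs the derived
observations (chamber volumes, regional strains) with seeded measurement
noise.  Noise is applied to the observations rather than to node positions
because the inverse problem consumes only volumes and regional strains --
matching the error model assumed by the residual bootstrap.

Shape cohorts emulate the healthy / amyloid contrast through the wall
thickness (population medians 0.77 vs 1.11 cm) plus a global size
variation; each subject lives on the shared template topology so meshes
are co-registered by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mesh import LVMesh
from .template import LVTemplateSpec, generate_template
from . import geometry
from .forward import BasalBC, ReducedOrderInflation
from .inference import CaseData, scale_pressure
from .mechanics import DEFAULT_HEALTHY, MaterialParameters, PressureVolumeCurve

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "CaseRecord",
    "ShapeDataset",
    "DEFAULT_AMYLOID_TRUTH",
    "generate_diastolic_series",
    "generate_shape_cohort",
]

#: stiffness of a synthetic amyloid-like ventricle: the healthy constants
#: with all stress-like parameters scaled up so that inflating the default
#: thick-walled template to its scaled end-diastolic pressure fills the
#: cavity by roughly a third (a physiological diastolic filling fraction)
DEFAULT_AMYLOID_TRUTH = DEFAULT_HEALTHY.scaled(8.0)


def closure_consistent_truth(
    a: float = 0.5, b: float = 5.0, a_fs: float = 0.25
) -> MaterialParameters:
    """Ground truth that is a fixed point of the two-step procedure.

    The second group equals the healthy constants pinned in step 1, *and*
    those constants satisfy the closure regressions: a_f is solved from
    a_s = closure_as(a_f, a_fs) at the healthy a_s, and b_f from the xi
    implied by the healthy (b_s, b_fs) pair.  Zero-noise data generated
    from this truth admits exact recovery by the two-step estimator.
    """
    from .inference import _REG_A, _REG_B
    from .mechanics import HEALTHY_SECOND_GROUP as H

    k1, k2 = _REG_A
    a_s = H["a_s"]
    a_f = (a_s**2 + k2 * a_fs * a_s) / (k1 * a_fs)
    k3, k4 = _REG_B
    xi = (k4 - H["b_s"] / H["b_fs"]) / k3
    b_f = H["b_s"] * xi
    return MaterialParameters(
        a=a, b=b, a_f=a_f, b_f=b_f,
        a_s=a_s, b_s=H["b_s"], a_fs=a_fs, b_fs=H["b_fs"],
    )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise on derived observations.

    ``sigma_volume_rel`` is the relative SD on chamber volumes (about 2%
    for cine-derived volumes); ``sigma_strain_abs`` the absolute SD on
    regional Green--Lagrange strains.  The reference frame (frame 0) is by
    definition noise-free: it *is* the reconstructed template.
    """

    sigma_volume_rel: float = 0.02
    sigma_strain_abs: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.sigma_volume_rel < 0 or self.sigma_strain_abs < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class CaseRecord:
    """One synthetic subject-scan: ground truth plus noisy observations."""

    template: LVMesh
    series: list  # ground-truth deformed meshes, one per frame
    curve: PressureVolumeCurve  # noise-free forward-model p-V curve
    p_ed: float
    truth_params: MaterialParameters
    volumes_true: np.ndarray
    ecc_true: np.ndarray
    ell_true: np.ndarray
    volumes_obs: np.ndarray
    ecc_obs: np.ndarray
    ell_obs: np.ndarray
    noise: NoiseModel
    bc: BasalBC = field(default_factory=BasalBC)

    @property
    def n_time(self) -> int:
        return len(self.volumes_true)

    def as_case_data(self) -> CaseData:
        return CaseData(
            mesh=self.template,
            p_ed=self.p_ed,
            volumes=self.volumes_obs,
            ecc=self.ecc_obs,
            ell=self.ell_obs,
            bc=self.bc,
        )


def generate_diastolic_series(
    template: LVMesh,
    truth: MaterialParameters,
    p_ed: Optional[float] = None,
    n_time: int = 13,
    noise: NoiseModel = NoiseModel(),
    bc: Optional[BasalBC] = None,
    model: Optional[ReducedOrderInflation] = None,
    n_layer: int = 3,
    n_reg: int = 20,
) -> CaseRecord:
    """Forward-simulate a diastolic series with known truth parameters.

    The pressure ramps linearly from 0 at early diastole to ``p_ed`` at end
    diastole over ``n_time`` frames.  When ``p_ed`` is omitted it is scaled
    from the template's wall-to-cavity volume ratio.  Noise perturbs the
    derived volume/strain observations only; ground-truth meshes are kept.
    """
    if n_time < 2:
        raise ValueError("n_time must be at least 2")
    if template.fiber is None:
        template = geometry.assign_fibers(template)
    if p_ed is None:
        v_ratio = geometry.wall_volume(template) / geometry.chamber_volume(template)
        p_ed = scale_pressure(v_ratio)
    bc = bc or BasalBC()
    model = model or ReducedOrderInflation()
    pressures = np.linspace(0.0, p_ed, n_time)
    res = model.solve(template, truth, pressures, bc=bc)
    strains = geometry.regional_strains(
        res.frames, template, n_layer=n_layer, n_reg=n_reg
    )
    vols = np.asarray(res.curve.volumes)

    record = CaseRecord(
        template=template,
        series=[template.with_points(f) for f in res.frames],
        curve=res.curve,
        p_ed=float(p_ed),
        truth_params=truth,
        volumes_true=vols,
        ecc_true=strains.E_cc,
        ell_true=strains.E_ll,
        volumes_obs=vols.copy(),
        ecc_obs=strains.E_cc.copy(),
        ell_obs=strains.E_ll.copy(),
        noise=noise,
        bc=bc,
    )
    return with_observation_noise(record, noise)


def with_observation_noise(record: CaseRecord, noise: NoiseModel) -> CaseRecord:
    """Apply (or re-apply) seeded measurement noise to a record's
    observations, leaving the ground truth untouched.

    Repeated Monte-Carlo studies can forward-simulate once and draw many
    noisy datasets from the same ground truth; the noise application is
    identical to :func:`generate_diastolic_series` with the same seed.
    """
    import dataclasses

    rng = np.random.default_rng(noise.seed)
    vols = record.volumes_true
    n_time = len(vols)
    v_obs = vols.copy()
    ecc_obs = record.ecc_true.copy()
    ell_obs = record.ell_true.copy()
    if n_time > 1:
        v_obs[1:] = vols[1:] * (
            1.0 + noise.sigma_volume_rel * rng.standard_normal(n_time - 1)
        )
        ecc_obs[:, :, 1:] += noise.sigma_strain_abs * rng.standard_normal(
            ecc_obs[:, :, 1:].shape
        )
        ell_obs[:, :, 1:] += noise.sigma_strain_abs * rng.standard_normal(
            ell_obs[:, :, 1:].shape
        )
    return dataclasses.replace(
        record, volumes_obs=v_obs, ecc_obs=ecc_obs, ell_obs=ell_obs, noise=noise
    )


# ---------------------------------------------------------------------------
# shape cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Two-class shape cohort (healthy vs thick-walled amyloid-like)."""

    n_healthy: int = 26
    n_amyloid: int = 7
    healthy_thickness_median: float = 0.77
    amyloid_thickness_median: float = 1.11
    thickness_sd: float = 0.08
    size_sd: float = 0.04
    seed: int = 0
    n_circ: int = 20
    n_long: int = 143
    endo_base_radius: float = 2.2
    apex_to_base_length: float = 8.0

    def __post_init__(self):
        if self.n_healthy < 2 or self.n_amyloid < 2:
            raise ValueError("need at least 2 subjects per class")
        if self.healthy_thickness_median <= 0 or self.amyloid_thickness_median <= 0:
            raise ValueError("thickness medians must be positive")
        if self.thickness_sd < 0 or self.size_sd < 0:
            raise ValueError("spread parameters must be non-negative")


@dataclass
class ShapeDataset:
    """Subjects x vertex-coordinate matrix with class labels."""

    X: np.ndarray  # (n_subjects, 3 * n_surface_vertices)
    labels: np.ndarray  # 'healthy' / 'amyloid'
    subject_ids: np.ndarray
    scans: np.ndarray  # 'baseline' / 'followup'
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.X)

    def rows(self, mask) -> "ShapeDataset":
        return ShapeDataset(
            self.X[mask], self.labels[mask], self.subject_ids[mask],
            self.scans[mask], dict(self.meta),
        )

    def to_csv(self, path, metadata_path=None) -> None:
        """Write the shape matrix as CSV (columns named v<k>_x/y/z) plus
        optional JSON metadata (ids, labels, scans, seed)."""
        import json
        import pandas as pd

        n_vert = self.X.shape[1] // 3
        cols = [
            f"v{k}_{axis}" for k in range(n_vert) for axis in ("x", "y", "z")
        ]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "subject", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "scan", self.scans)
        df.to_csv(path, index=False, float_format="%.9g")
        if metadata_path is not None:
            meta = {
                "subject_ids": list(map(str, self.subject_ids)),
                "labels": list(map(str, self.labels)),
                "scans": list(map(str, self.scans)),
                "n_surface_vertices": int(n_vert),
                "seed": self.meta.get("seed"),
            }
            import pathlib

            pathlib.Path(metadata_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "ShapeDataset":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            X=df.drop(columns=["subject", "label", "scan"]).to_numpy(),
            labels=df["label"].to_numpy(),
            subject_ids=df["subject"].to_numpy(),
            scans=df["scan"].to_numpy(),
        )


def _cohort_template(spec: CohortSpec, thickness: float, scale: float) -> LVMesh:
    tspec = LVTemplateSpec(
        endo_base_radius=spec.endo_base_radius * scale,
        epi_base_radius=(spec.endo_base_radius + thickness) * scale,
        apex_to_base_length=spec.apex_to_base_length * scale,
        wall_thickness_profile=lambda ell, t=thickness * scale: t,
        n_circ=spec.n_circ,
        n_long=spec.n_long,
        n_trans=1,  # surfaces only matter for shape analysis
    )
    return generate_template(tspec)


def generate_shape_cohort(spec: CohortSpec) -> ShapeDataset:
    """Generate a co-registered two-class cohort of LV surface meshes.

    Thickness varies normally around the class median (normal, so median =
    mean) and a global size factor varies around 1; every subject shares
    the template topology and vertex ordering.
    """
    rng = np.random.default_rng(spec.seed)
    rows, labels, ids = [], [], []
    meshes = []
    for cls, n, med in (
        ("healthy", spec.n_healthy, spec.healthy_thickness_median),
        ("amyloid", spec.n_amyloid, spec.amyloid_thickness_median),
    ):
        for i in range(n):
            t = med + spec.thickness_sd * rng.standard_normal()
            t = max(t, 0.15 * med)
            g = max(1.0 + spec.size_sd * rng.standard_normal(), 0.5)
            mesh = _cohort_template(spec, t, g)
            rows.append(mesh.surface_coordinates())
            meshes.append(mesh)
            labels.append(cls)
            ids.append(f"{cls}-{i + 1}")
    X = np.asarray(rows)
    return ShapeDataset(
        X=X,
        labels=np.asarray(labels),
        subject_ids=np.asarray(ids),
        scans=np.asarray(["baseline"] * len(rows)),
        meta={
            "seed": spec.seed,
            "meshes": meshes,
            "surface_vertices": X.shape[1] // 3,
        },
    )
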