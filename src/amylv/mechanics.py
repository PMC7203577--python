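"""Holzapfel--Ogden passive myocardium: energy, stress, pseudo-uniaxial tests.

The orthotropic strain-energy density (kPa, relative to the reference
state so that psi(I) = 0) is

    psi = a/(2b) [exp(b (I1 - 3)) - 1]
        + sum_{i=f,s} a_i/(2 b_i) [exp(b_i (max(I4i, 1) - 1)^2) - 1]
        + a_fs/(2 b_fs) [exp(b_fs I8fs^2) - 1]

with I1 = tr C, I4f = f0.C f0, I4s = s0.C s0, I8fs = f0.C s0 and
C = F^T F.  The fiber and sheet terms only engage under tension
(max(I4, 1)), reflecting that collagen-reinforced directions carry no
load in compression.  a-type parameters are stresses in kPa; b-type
parameters are dimensionless exponents; all eight are strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MaterialParameters",
    "HEALTHY_SECOND_GROUP",
    "DEFAULT_HEALTHY",
    "PressureVolumeCurve",
    "StressStretchCurve",
    "invariants",
    "strain_energy",
    "second_pk_stress",
    "first_pk_stress",
    "cauchy_stress",
    "uniaxial_fiber_response",
    "average_slope",
    "principal_stress",
    "principal_log_strain",
    "diastolic_work",
]

MMHG_TO_KPA = 0.133322

# second-group constants for healthy volunteers (used as fixed values in
# the first optimisation step): a_s in kPa, b_s and b_fs dimensionless
HEALTHY_SECOND_GROUP = {"a_s": 0.5426, "b_s": 1.5998, "b_fs": 3.3900}

_EXP_CLIP = 80.0  # caps exponents so trial parameter sets cannot overflow


@dataclass(frozen=True)
class MaterialParameters:
    """The eight Holzapfel--Ogden constants (a-type kPa, b-type unitless)."""

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float

    def __post_init__(self):
        for k, v in asdict(self).items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"material parameter {k} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a, self.b, self.a_f, self.b_f, self.a_s, self.b_s, self.a_fs, self.b_fs]
        )

    @classmethod
    def from_array(cls, arr) -> "MaterialParameters":
        a, b, a_f, b_f, a_s, b_s, a_fs, b_fs = (float(v) for v in arr)
        return cls(a, b, a_f, b_f, a_s, b_s, a_fs, b_fs)

    def scaled(self, stiffness: float) -> "MaterialParameters":
        """Scale all stress-like (a-type) constants by a common factor."""
        return MaterialParameters(
            self.a * stiffness, self.b, self.a_f * stiffness, self.b_f,
            self.a_s * stiffness, self.b_s, self.a_fs * stiffness, self.b_fs,
        )


#: plausible healthy baseline parameter set (a-type values of a few tenths
#: of a kPa to ~1 kPa and moderate exponents, with the fixed healthy
#: second group); used as the default truth in synthetic studies
DEFAULT_HEALTHY = MaterialParameters(
    a=0.24, b=5.08, a_f=1.27, b_f=4.15,
    a_s=HEALTHY_SECOND_GROUP["a_s"], b_s=HEALTHY_SECOND_GROUP["b_s"],
    a_fs=0.22, b_fs=HEALTHY_SECOND_GROUP["b_fs"],
)


@dataclass
class PressureVolumeCurve:
    """Diastolic filling curve: pressures in mmHg, cavity volumes in mL."""

    pressures: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.pressures.shape != self.volumes.shape:
            raise ValueError("pressures and volumes must have equal length")
        if len(self.pressures) and (
            self.pressures[0] < 0 or np.any(np.diff(self.pressures) < 0)
        ):
            raise ValueError("pressures must be non-decreasing from 0")


@dataclass
class StressStretchCurve:
    """Myofiber-direction Cauchy stress (kPa) against axial stretch."""

    stretches: np.ndarray
    stresses: np.ndarray

    def __post_init__(self):
        self.stretches = np.asarray(self.stretches, dtype=float)
        self.stresses = np.asarray(self.stresses, dtype=float)
        if self.stretches.shape != self.stresses.shape:
            raise ValueError("stretches and stresses must have equal length")


# ---------------------------------------------------------------------------


def _as_batch(F, f0, s0):
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    F = F.reshape(-1, 3, 3)
    f0 = np.broadcast_to(np.asarray(f0, dtype=float).reshape(-1, 3), (len(F), 3))
    s0 = np.broadcast_to(np.asarray(s0, dtype=float).reshape(-1, 3), (len(F), 3))
    return F, f0, s0, single


def invariants(F, f0, s0):
    """I1, I4f, I4s, I8fs of the right Cauchy--Green tensor C = F^T F."""
    F, f0, s0, single = _as_batch(F, f0, s0)
    C = np.einsum("eki,ekj->eij", F, F)
    i1 = np.trace(C, axis1=1, axis2=2)
    i4f = np.einsum("ei,eij,ej->e", f0, C, f0)
    i4s = np.einsum("ei,eij,ej->e", s0, C, s0)
    i8 = np.einsum("ei,eij,ej->e", f0, C, s0)
    if single:
        return float(i1[0]), float(i4f[0]), float(i4s[0]), float(i8[0])
    return i1, i4f, i4s, i8


def strain_energy(F, f0, s0, params: MaterialParameters):
    """Strain-energy density (kPa), zero in the reference configuration."""
    F, f0, s0, single = _as_batch(F, f0, s0)
    if np.any(np.linalg.det(F) <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    i1, i4f, i4s, i8 = invariants(F, f0, s0)
    p = params
    e1 = np.exp(np.minimum(p.b * (i1 - 3.0), _EXP_CLIP))
    psi = p.a / (2 * p.b) * (e1 - 1.0)
    for a_i, b_i, i4 in ((p.a_f, p.b_f, i4f), (p.a_s, p.b_s, i4s)):
        t = np.maximum(i4, 1.0) - 1.0  # tension-only switch
        psi = psi + a_i / (2 * b_i) * (np.exp(np.minimum(b_i * t * t, _EXP_CLIP)) - 1.0)
    psi = psi + p.a_fs / (2 * p.b_fs) * (
        np.exp(np.minimum(p.b_fs * i8 * i8, _EXP_CLIP)) - 1.0
    )
    return float(psi[0]) if single else psi


def second_pk_stress(F, f0, s0, params: MaterialParameters):
    """Second Piola--Kirchhoff stress S = 2 dpsi/dC (no pressure term)."""
    F, f0, s0, single = _as_batch(F, f0, s0)
    i1, i4f, i4s, i8 = invariants(F, f0, s0)
    p = params
    e1 = np.exp(np.minimum(p.b * (i1 - 3.0), _EXP_CLIP))
    S = p.a * e1[:, None, None] * np.eye(3)[None]
    for a_i, b_i, i4, v in ((p.a_f, p.b_f, i4f, f0), (p.a_s, p.b_s, i4s, s0)):
        t = np.maximum(i4, 1.0) - 1.0
        coef = 2.0 * a_i * t * np.exp(np.minimum(b_i * t * t, _EXP_CLIP))
        S = S + coef[:, None, None] * np.einsum("ei,ej->eij", v, v)
    coef = p.a_fs * i8 * np.exp(np.minimum(p.b_fs * i8 * i8, _EXP_CLIP))
    sym = np.einsum("ei,ej->eij", f0, s0) + np.einsum("ei,ej->eij", s0, f0)
    S = S + coef[:, None, None] * sym
    return S[0] if single else S


def first_pk_stress(F, f0, s0, params: MaterialParameters):
    """First Piola--Kirchhoff stress P = dpsi/dF = F S."""
    F, f0, s0, single = _as_batch(F, f0, s0)
    S = second_pk_stress(F, f0, s0, params)
    S = S.reshape(-1, 3, 3)
    P = np.einsum("eik,ekj->eij", F, S)
    return P[0] if single else P


def cauchy_stress(F, f0, s0, params: MaterialParameters, p_hydro=0.0):
    """Cauchy stress sigma = (2/J) F (dpsi/dC) F^T - p_hydro I (kPa)."""
    F, f0, s0, single = _as_batch(F, f0, s0)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    S = second_pk_stress(F, f0, s0, params).reshape(-1, 3, 3)
    sig = np.einsum("eik,ekl,ejl->eij", F, S, F) / J[:, None, None]
    sig = sig - np.asarray(p_hydro).reshape(-1, 1, 1) * np.eye(3)[None]
    return sig[0] if single else sig


# ---------------------------------------------------------------------------
# pseudo-uniaxial response


def _uniaxial_stress_at(lam: float, params: MaterialParameters) -> float:
    """Axial Cauchy stress at stretch lam for a homogeneous incompressible
    sample with fibers along the loading axis and the sheet along one
    transverse axis; transverse Cauchy stresses are zero."""
    f0 = np.array([1.0, 0.0, 0.0])
    s0 = np.array([0.0, 1.0, 0.0])

    def transverse_gap(l2):
        l3 = 1.0 / (lam * l2)
        F = np.diag([lam, l2, l3])
        S = second_pk_stress(F, f0, s0, params)
        # sigma_ii = lam_i^2 S_ii for diagonal F (J = 1)
        return l2 * l2 * S[1, 1] - l3 * l3 * S[2, 2]

    lo, hi = 0.2, 2.0
    glo, ghi = transverse_gap(lo), transverse_gap(hi)
    if glo * ghi > 0:
        raise RuntimeError(f"uniaxial transverse solve failed at stretch {lam:.4f}")
    l2 = brentq(transverse_gap, lo, hi, xtol=1e-12)
    l3 = 1.0 / (lam * l2)
    F = np.diag([lam, l2, l3])
    S = second_pk_stress(F, f0, s0, params)
    # p from sigma_33 = 0
    return float(lam * lam * S[0, 0] - l3 * l3 * S[2, 2])


def uniaxial_fiber_response(
    params: MaterialParameters, lambda_max: float = 1.15, n_points: int = 40
) -> StressStretchCurve:
    """Stress-stretch curve of a pseudo uniaxial test along the myofiber
    direction (perfectly aligned fibers, incompressible, traction-free
    transverse faces)."""
    if lambda_max <= 1.0:
        raise ValueError("lambda_max must exceed 1")
    lams = np.linspace(1.0, lambda_max, n_points)
    sig = np.empty_like(lams)
    sig[0] = 0.0
    for i, lam in enumerate(lams[1:], start=1):
        sig[i] = _uniaxial_stress_at(float(lam), params)
    return StressStretchCurve(lams, sig)


def average_slope(curve: StressStretchCurve) -> float:
    """Average stiffness f-bar (kPa): secant slope of sigma(lambda) over the
    curve's stretch span."""
    lam0, lam1 = curve.stretches[0], curve.stretches[-1]
    if lam1 <= lam0:
        raise ValueError("curve must span a positive stretch range")
    return float((curve.stresses[-1] - curve.stresses[0]) / (lam1 - lam0))


# ---------------------------------------------------------------------------


def principal_stress(sigma) -> float:
    """Largest principal (eigen) value of a symmetric stress tensor."""
    sigma = np.asarray(sigma)
    vals = np.linalg.eigvalsh(sigma)
    return vals[..., -1] if sigma.ndim > 2 else float(vals[-1])


def principal_log_strain(F) -> float:
    """Largest principal logarithmic strain: ln of the largest principal
    stretch of (F^T F)^(1/2)."""
    F = np.asarray(F)
    single = F.ndim == 2
    Fb = F.reshape(-1, 3, 3)
    C = np.einsum("eki,ekj->eij", Fb, Fb)
    lam2 = np.linalg.eigvalsh(C)[:, -1]
    e1 = 0.5 * np.log(lam2)
    return float(e1[0]) if single else e1.reshape(F.shape[:-2])


def diastolic_work(curve: PressureVolumeCurve) -> float:
    """Filling work W = integral p dV (mmHg mL), trapezoidal rule."""
    if len(curve.pressures) < 2:
        raise ValueError("need at least two frames")
    return float(np.trapezoid(curve.pressures, curve.volumes))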