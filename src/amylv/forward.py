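"""Reduced-order diastolic inflation of the LV.

The full-resolution finite-element problem is replaced by a Ritz-style
reduced model: the wall deformation is restricted to a smooth, low
dimensional kinematic family and quasi-static equilibrium at each pressure
step is found by minimising the total potential

    Pi(q) = sum_e V_e [ psi(F_e) + kappa/2 (J_e - 1)^2 ] - p * V_cavity(q)

where psi is the Holzapfel--Ogden energy, the quadratic term enforces
near-incompressibility by penalty (kappa = kappa_factor * a), and the last
term is the potential of the endocardial pressure load on the closed
cavity.  Deformation gradients are evaluated per hexahedral element by the
same least-squares fit used for image-derived strains, so synthetic data
and inverse analyses share one discrete kinematics.

The kinematic family (generalised coordinates q):

    u_xy = [ g0(ell) + g1(ell) s + g2(ell) s^2 ] * (x, y)
    u_z  = zeta(ell) * (z - z_base)

with ell the longitudinal coordinate (0 base, 1 apex), s the transmural
coordinate (1 endo, 0 epi), g0 a polynomial vanishing at the base (the
epicardial basal edge is fixed in-plane unless a prescribed edge motion is
supplied) and u_z vanishing identically on the basal plane, which realises
the basal-plane boundary conditions: prescribed (default zero) in-plane
displacement of the epicardial edge, zero long-axis displacement of every
basal node, remaining basal nodes free in-plane.

Internally the solver works in kPa and cm; pressure--volume output is in
mmHg and mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .mesh import LVMesh, hex_volumes, triangulate_quads
from . import mechanics as mech
from .mechanics import MMHG_TO_KPA, MaterialParameters, PressureVolumeCurve

__all__ = ["BasalBC", "ForwardResult", "ReducedOrderInflation", "inflate_lv"]


@dataclass
class BasalBC:
    """Basal-plane boundary conditions.

    ``edge_radial_displacement`` is the prescribed radial in-plane motion
    (cm) of the epicardial basal edge at end-diastole, ramped linearly with
    pressure; zero for synthetic data.
    """

    edge_radial_displacement: float = 0.0


class ForwardModelError(RuntimeError):
    """Raised when the quasi-static solve fails to converge."""

    def __init__(self, message, step=None, residual=None):
        super().__init__(message)
        self.step = step
        self.residual = residual


@dataclass
class ForwardResult:
    """Deformed node positions per pressure step plus the p-V curve."""

    frames: list  # list of (N, 3) arrays, frame 0 = reference
    curve: PressureVolumeCurve
    coords: np.ndarray  # generalised coordinates per frame
    converged: bool
    grad_norms: np.ndarray
    mean_abs_j_minus_1: float


class ReducedOrderInflation:
    """Reduced-order quasi-static inflation model (pluggable forward model).

    Parameters
    ----------
    kappa_factor : bulk penalty = kappa_factor * a (near-incompressibility)
    n_g0, n_g1, n_g2, n_z : polynomial orders of the kinematic family
    gtol, maxiter : L-BFGS stopping controls per pressure step
    """

    def __init__(
        self,
        kappa_factor: float = 1000.0,
        n_g0: int = 3,
        n_g1: int = 3,
        n_g2: int = 2,
        n_z: int = 3,
        gtol: float = 1e-8,
        maxiter: int = 2000,
        grad_norm_tol: float = 1e-4,
        use_batched: bool = True,
    ):
        self.kappa_factor = kappa_factor
        self.n_g0 = n_g0
        self.n_g1 = n_g1
        self.n_g2 = n_g2
        self.n_z = n_z
        self.gtol = gtol
        self.maxiter = maxiter
        self.grad_norm_tol = grad_norm_tol
        self.use_batched = use_batched
        self._cache_key = None

    @property
    def n_dofs(self) -> int:
        return self.n_g0 + self.n_g1 + self.n_g2 + self.n_z

    def reset_warm_state(self) -> None:
        """Drop cached per-step Hessians (warm-start state).

        Call before a reproducible computation: warm caches only change the
        optimisation path, but solutions are converged to finite tolerance,
        so path differences leak into the last digits.
        """
        self._H_cache = {}

    # ------------------------------------------------------------------
    def _prepare(self, mesh: LVMesh):
        key = id(mesh)
        if self._cache_key == key:
            return
        if mesh.fiber is None or mesh.sheet is None:
            raise ValueError("mesh needs fiber/sheet vectors (assign_fibers)")
        X = mesh.points
        hexes = mesh.hexes
        Xe = X[hexes]
        D = Xe - Xe.mean(axis=1, keepdims=True)
        M = np.einsum("eni,enj->eij", D, D)
        self._G = np.einsum("eij,enj->eni", np.linalg.inv(M), D)  # (E, 8, 3)
        self._Vref = hex_volumes(X, hexes)
        if np.any(self._Vref <= 0):
            raise ValueError("reference mesh has non-positive element volumes")

        # displacement basis B: x(q) = X + B @ q  (N, 3, nq)
        ell = mesh.node_ell
        s = mesh.node_s
        xy = X[:, :2]
        dz = (X[:, 2] - mesh.base_z)[:, None]
        cols = []
        for k in range(1, self.n_g0 + 1):  # g0: vanishes at the base
            cols.append((ell**k)[:, None] * xy)
        # transmural factors vanish on the epicardium (s = 0 there), so the
        # epicardial basal edge stays at its prescribed in-plane position
        for k in range(self.n_g1):
            cols.append(((ell**k) * s)[:, None] * xy)
        for k in range(self.n_g2):
            cols.append(((ell**k) * s**2)[:, None] * xy)
        zcols = []
        for k in range(self.n_z):
            zcols.append((ell**k)[:, None] * dz)
        B = np.zeros((len(X), 3, len(cols) + len(zcols)))
        for j, c in enumerate(cols):
            B[:, :2, j] = c
        for j, c in enumerate(zcols):
            B[:, 2, len(cols) + j] = c[:, 0]
        # orthonormalise the basis columns (same span, same boundary
        # conditions, far better conditioning for the quasi-Newton solver)
        nq = B.shape[2]
        Q, R = np.linalg.qr(B.reshape(-1, nq))
        if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
            raise ValueError("kinematic basis is rank deficient on this mesh")
        self._B = np.ascontiguousarray(Q.reshape(len(X), 3, nq))

        # prescribed basal-edge motion shape: w(ell, s) * (x, y), w(0, 0) = 1
        # (s = 0 on the epicardium); radial unit magnitude at the edge
        rho_edge = np.linalg.norm(X[mesh.epi_basal_ring, :2], axis=1).mean()
        w = ((1.0 - ell) ** 2 * (1.0 - s) ** 2)[:, None]
        self._B_edge = np.zeros((len(X), 3))
        self._B_edge[:, :2] = w * xy / rho_edge

        # cavity triangulation (endo surface + basal fan), oriented so the
        # reference signed volume is positive
        ring = mesh.endo_basal_ring
        fan = np.stack(
            [np.repeat(ring[0], len(ring) - 2), ring[1:-1], ring[2:]], axis=1
        )
        tris = np.concatenate([triangulate_quads(mesh.endo_faces), fan], axis=0)
        v = self._signed_volume(X, tris)
        if v < 0:
            tris = tris[:, ::-1]
        self._cav_tris = tris
        self._f0 = mesh.fiber
        self._s0 = mesh.sheet
        # structure tensors, fixed per element
        self._ff = np.einsum("ei,ej->eij", mesh.fiber, mesh.fiber)
        self._ss = np.einsum("ei,ej->eij", mesh.sheet, mesh.sheet)
        self._fs = np.einsum("ei,ej->eij", mesh.fiber, mesh.sheet)
        self._fs = self._fs + np.transpose(self._fs, (0, 2, 1))
        self._hexes = hexes
        self._X = X
        self._N = len(X)
        self._H_cache = {}
        for attr in ("_BH", "_Btri", "_Xtri", "_Bedge_hex", "_Bedge_tri"):
            if hasattr(self, attr):
                delattr(self, attr)
        self._cache_key = key

    @staticmethod
    def _signed_volume(pts, tris):
        a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0

    # ------------------------------------------------------------------
    def _energy_grad_batch(self, Q, p_kpas, params, kappa, edge_amps):
        """Potential and gradient for a batch of pressure steps at once.

        ``Q`` is (m, nq); returns (W, G) with W (m,) and G (m, nq).  One
        vectorised pass over m x E elements replaces m separate evaluations,
        amortising the numpy call overhead across the whole pressure ramp.
        """
        if not hasattr(self, "_BH"):
            self._BH = self._B[self._hexes]  # (E, 8, 3, nq)
            t = self._cav_tris
            self._Btri = tuple(self._B[t[:, k]] for k in range(3))  # (T,3,nq)
            self._Xtri = tuple(self._X[t[:, k]] for k in range(3))
            self._Bedge_hex = self._B_edge[self._hexes]
            self._Bedge_tri = tuple(self._B_edge[t[:, k]] for k in range(3))

        Q = np.asarray(Q, dtype=float)
        m = len(Q)
        xe = (
            self._X[self._hexes][None]
            + np.einsum("enik,mk->meni", self._BH, Q)
            + edge_amps[:, None, None, None] * self._Bedge_hex[None]
        )
        d = xe - xe.mean(axis=2, keepdims=True)
        F = np.einsum("meni,enj->meij", d, self._G)
        K = np.empty_like(F)
        K[:, :, 0] = np.cross(F[:, :, 1], F[:, :, 2])
        K[:, :, 1] = np.cross(F[:, :, 2], F[:, :, 0])
        K[:, :, 2] = np.cross(F[:, :, 0], F[:, :, 1])
        J = np.einsum("meij,meij->me", F, K) / 3.0
        bad = np.any(J <= 0, axis=1)
        J = np.where(J <= 0, 1.0, J)

        p_ = params
        C = np.einsum("meki,mekj->meij", F, F)
        i1 = np.trace(C, axis1=2, axis2=3)
        i4f = np.einsum("meij,eij->me", C, self._ff)
        i4s = np.einsum("meij,eij->me", C, self._ss)
        i8 = 0.5 * np.einsum("meij,eij->me", C, self._fs)
        clip = 80.0
        e1 = np.exp(np.minimum(p_.b * (i1 - 3.0), clip))
        t4f = np.maximum(i4f, 1.0) - 1.0
        t4s = np.maximum(i4s, 1.0) - 1.0
        ef = np.exp(np.minimum(p_.b_f * t4f * t4f, clip))
        es = np.exp(np.minimum(p_.b_s * t4s * t4s, clip))
        e8 = np.exp(np.minimum(p_.b_fs * i8 * i8, clip))
        psi = (
            p_.a / (2 * p_.b) * (e1 - 1.0)
            + p_.a_f / (2 * p_.b_f) * (ef - 1.0)
            + p_.a_s / (2 * p_.b_s) * (es - 1.0)
            + p_.a_fs / (2 * p_.b_fs) * (e8 - 1.0)
        )
        S = (p_.a * e1)[..., None, None] * np.eye(3)[None, None]
        S = S + (2.0 * p_.a_f * t4f * ef)[..., None, None] * self._ff[None]
        S = S + (2.0 * p_.a_s * t4s * es)[..., None, None] * self._ss[None]
        S = S + (p_.a_fs * i8 * e8)[..., None, None] * self._fs[None]
        P = np.matmul(F, S)
        P += (kappa * (J - 1.0))[..., None, None] * K

        W = np.einsum("e,me->m", self._Vref, psi + 0.5 * kappa * (J - 1.0) ** 2)
        contrib = np.einsum("e,meij,enj->meni", self._Vref, P, self._G)
        G = np.einsum("meni,enik->mk", contrib, self._BH)

        # cavity term
        a = self._Xtri[0][None] + np.einsum("tik,mk->mti", self._Btri[0], Q) \
            + edge_amps[:, None, None] * self._Bedge_tri[0][None]
        b = self._Xtri[1][None] + np.einsum("tik,mk->mti", self._Btri[1], Q) \
            + edge_amps[:, None, None] * self._Bedge_tri[1][None]
        c = self._Xtri[2][None] + np.einsum("tik,mk->mti", self._Btri[2], Q) \
            + edge_amps[:, None, None] * self._Bedge_tri[2][None]
        cbc = np.cross(b, c)
        vcav = np.einsum("mti,mti->m", a, cbc) / 6.0
        W = W - p_kpas * vcav
        gv = (
            np.einsum("mti,tik->mk", cbc, self._Btri[0])
            + np.einsum("mti,tik->mk", np.cross(c, a), self._Btri[1])
            + np.einsum("mti,tik->mk", np.cross(a, b), self._Btri[2])
        ) / 6.0
        G = G - p_kpas[:, None] * gv

        if np.any(bad):
            W = W.copy()
            W[bad] = 1e12 * (1.0 + np.sum(Q[bad] ** 2, axis=1))
            G[bad] = 2e12 * Q[bad]
        return W, G

    def _solve_batched(self, Q0, p_kpas, params, kappa, edge_amps, keys):
        """Damped-Newton sweeps over all pressure steps simultaneously.

        Uses the per-step cached Hessians (computing missing ones by batched
        finite differences) and per-step backtracking; steps that stall are
        reported for a sequential fallback.  Valid only with a good warm
        start for every step.
        """
        Q = np.asarray(Q0, dtype=float).copy()
        m, nq = Q.shape
        tol = self.grad_norm_tol * 1e-2

        def fd_hessians(mask, Gref):
            hstep = 1e-6
            Hs = np.zeros((m, nq, nq))
            for k in range(nq):
                Qp = Q.copy()
                Qp[mask, k] += hstep
                _, Gp = self._energy_grad_batch(
                    Qp[mask], p_kpas[mask], params, kappa, edge_amps[mask]
                )
                Hs[mask, :, k] = (Gp - Gref[mask]) / hstep
            return 0.5 * (Hs + np.transpose(Hs, (0, 2, 1)))

        W, G = self._energy_grad_batch(Q, p_kpas, params, kappa, edge_amps)
        H = np.zeros((m, nq, nq))
        have = np.zeros(m, dtype=bool)
        for i in range(m):
            cached = self._H_cache.get(keys[i])
            if cached is not None:
                H[i] = cached
                have[i] = True
        if not np.all(have):
            H_new = fd_hessians(~have, G)
            H[~have] = H_new[~have]

        since_refresh = np.zeros(m, dtype=int)
        stalled = np.zeros(m, dtype=bool)
        for _ in range(50):
            gn = np.max(np.abs(G), axis=1)
            active = (gn > tol * (1.0 + np.abs(W))) & ~stalled
            if not np.any(active):
                break
            refresh = active & (since_refresh >= 4)
            if np.any(refresh):
                H_new = fd_hessians(refresh, G)
                H[refresh] = H_new[refresh]
                since_refresh[refresh] = 0
            step = np.zeros_like(Q)
            for i in np.flatnonzero(active):
                Hi = H[i]
                delta = None
                lam = 0.0
                for _ in range(6):
                    try:
                        delta = np.linalg.solve(Hi + lam * np.eye(nq), -G[i])
                    except np.linalg.LinAlgError:
                        delta = -G[i]
                    if np.dot(delta, G[i]) < 0:
                        break
                    lam = 10.0 * lam if lam > 0 else 1e-3 * np.abs(np.diag(Hi)).max()
                else:
                    delta = -G[i]
                step[i] = delta
            t_vec = np.where(active, 1.0, 0.0)
            accepted = ~active
            slope = np.einsum("mk,mk->m", step, G)
            for _ in range(25):
                trial = Q + t_vec[:, None] * step
                W_t, G_t = self._energy_grad_batch(
                    trial, p_kpas, params, kappa, edge_amps
                )
                ok = accepted | (W_t < W + 1e-4 * t_vec * slope)
                newly = ok & ~accepted
                if np.any(newly):
                    Q[newly] = trial[newly]
                    W[newly] = W_t[newly]
                    G[newly] = G_t[newly]
                accepted |= ok
                if np.all(accepted):
                    break
                t_vec[~accepted] *= 0.5
            else:
                stalled |= ~accepted
            since_refresh[active] += 1

        gn = np.max(np.abs(G), axis=1)
        converged = gn <= self.grad_norm_tol * (1.0 + np.abs(W))
        for i in range(m):
            if converged[i]:
                self._H_cache[keys[i]] = H[i]
        return Q, W, gn, converged & ~stalled

    # ------------------------------------------------------------------
    def _energy_grad(self, q, p_kpa, params, kappa, edge_amp):
        """Total potential and its gradient w.r.t. q (kPa cm^3)."""
        x = self._X + self._B @ q + edge_amp * self._B_edge
        xe = x[self._hexes]
        d = xe - xe.mean(axis=1, keepdims=True)
        F = np.einsum("eni,enj->eij", d, self._G)
        # cofactor matrix K: J F^{-T} = K and J = (F : K) / 3
        K = np.empty_like(F)
        K[:, 0] = np.cross(F[:, 1], F[:, 2])
        K[:, 1] = np.cross(F[:, 2], F[:, 0])
        K[:, 2] = np.cross(F[:, 0], F[:, 1])
        J = np.einsum("eij,eij->e", F, K) / 3.0
        if np.any(J <= 0):
            return 1e12 * (1.0 + float(np.sum(q**2))), 2e12 * q

        # fused energy + first Piola-Kirchhoff stress (shared exponentials)
        p_ = params
        C = np.einsum("eki,ekj->eij", F, F)
        i1 = np.trace(C, axis1=1, axis2=2)
        i4f = np.einsum("eij,eij->e", C, self._ff)
        i4s = np.einsum("eij,eij->e", C, self._ss)
        i8 = 0.5 * np.einsum("eij,eij->e", C, self._fs)
        clip = 80.0
        e1 = np.exp(np.minimum(p_.b * (i1 - 3.0), clip))
        t4f = np.maximum(i4f, 1.0) - 1.0
        t4s = np.maximum(i4s, 1.0) - 1.0
        ef = np.exp(np.minimum(p_.b_f * t4f * t4f, clip))
        es = np.exp(np.minimum(p_.b_s * t4s * t4s, clip))
        e8 = np.exp(np.minimum(p_.b_fs * i8 * i8, clip))
        psi = (
            p_.a / (2 * p_.b) * (e1 - 1.0)
            + p_.a_f / (2 * p_.b_f) * (ef - 1.0)
            + p_.a_s / (2 * p_.b_s) * (es - 1.0)
            + p_.a_fs / (2 * p_.b_fs) * (e8 - 1.0)
        )
        S = (p_.a * e1)[:, None, None] * np.eye(3)[None]
        S = S + (2.0 * p_.a_f * t4f * ef)[:, None, None] * self._ff
        S = S + (2.0 * p_.a_s * t4s * es)[:, None, None] * self._ss
        S = S + (p_.a_fs * i8 * e8)[:, None, None] * self._fs
        P = np.matmul(F, S)
        P += (kappa * (J - 1.0))[:, None, None] * K

        W = float(np.sum(self._Vref * (psi + 0.5 * kappa * (J - 1.0) ** 2)))
        contrib = np.einsum("e,eij,enj->eni", self._Vref, P, self._G).reshape(-1, 3)
        hex_idx = self._hexes.ravel()
        gx = np.stack(
            [np.bincount(hex_idx, weights=contrib[:, k], minlength=self._N)
             for k in range(3)],
            axis=1,
        )

        # cavity volume and gradient
        t = self._cav_tris
        a, b, c = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
        vcav = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
        W -= p_kpa * vcav
        tri_idx = t.T.ravel()
        tri_contrib = np.concatenate(
            [np.cross(b, c), np.cross(c, a), np.cross(a, b)], axis=0
        ) / 6.0
        gv = np.stack(
            [np.bincount(tri_idx, weights=tri_contrib[:, k], minlength=self._N)
             for k in range(3)],
            axis=1,
        )
        gx -= p_kpa * gv

        gq = np.einsum("ni,nik->k", gx, self._B)
        return W, gq

    def _fd_hessian(self, q, gr, args):
        nq = len(q)
        hstep = 1e-6
        H = np.empty((nq, nq))
        for k in range(nq):
            qp = q.copy()
            qp[k] += hstep
            _, gp = self._energy_grad(qp, *args)
            H[:, k] = (gp - gr) / hstep
        return 0.5 * (H + H.T)

    def _newton(self, q0, args, cache_key=None):
        """Damped Newton on the reduced potential.

        The Hessian is built by finite differences of the analytic gradient
        (one gradient per generalised coordinate); steps are damped by
        backtracking on the potential, with Levenberg-style regularisation
        when the Hessian is not positive definite.  Hessians are cached per
        pressure step so warm restarts during parameter sweeps converge in
        one or two frozen-Hessian iterations.  Falls back to L-BFGS if
        Newton stalls.
        """
        q = np.asarray(q0, dtype=float).copy()
        nq = len(q)
        f, gr = self._energy_grad(q, *args)
        scale = 1.0 + abs(f)
        H = self._H_cache.get(cache_key)
        frozen = H is not None
        stall = 0
        for _ in range(60):
            gn = float(np.max(np.abs(gr)))
            if gn <= self.grad_norm_tol * 1e-2 * scale:
                if cache_key is not None:
                    self._H_cache[cache_key] = H
                return q, f, gn, True
            if H is None or (not frozen):
                H = self._fd_hessian(q, gr, args)
            elif stall >= 6:
                H = self._fd_hessian(q, gr, args)
                frozen = False
            stall += 1
            lam = 0.0
            for _ in range(8):
                try:
                    step = np.linalg.solve(H + lam * np.eye(nq), -gr)
                except np.linalg.LinAlgError:
                    step = -gr
                if np.dot(step, gr) < 0:
                    break
                lam = 10.0 * lam if lam > 0 else 1e-3 * np.abs(np.diag(H)).max()
            else:
                step = -gr
            t = 1.0
            for _ in range(30):
                f_new, g_new = self._energy_grad(q + t * step, *args)
                if f_new < f + 1e-4 * t * np.dot(step, gr):
                    break
                t *= 0.5
            else:
                break  # line search failed; polish below
            q = q + t * step
            f, gr = f_new, g_new
            scale = 1.0 + abs(f)

        res = minimize(
            self._energy_grad,
            q,
            args=args,
            jac=True,
            method="L-BFGS-B",
            options={"gtol": self.gtol, "ftol": 1e-14, "maxiter": self.maxiter},
        )
        if res.fun <= f:
            q, f, gr = res.x, res.fun, res.jac
        gn = float(np.max(np.abs(gr)))
        ok = np.isfinite(f) and gn <= self.grad_norm_tol * (1.0 + abs(f))
        if ok and cache_key is not None:
            self._H_cache[cache_key] = self._fd_hessian(q, gr, args)
        return q, f, gn, ok

    def cavity_volume(self, points) -> float:
        t = self._cav_tris
        a, b, c = points[t[:, 0]], points[t[:, 1]], points[t[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    # ------------------------------------------------------------------
    def solve(
        self,
        mesh: LVMesh,
        params: MaterialParameters,
        pressures_mmhg: Sequence[float],
        bc: Optional[BasalBC] = None,
        q_init: Optional[np.ndarray] = None,
        strict: bool = True,
    ) -> ForwardResult:
        """Quasi-static solve at each pressure of a non-decreasing ramp."""
        self._prepare(mesh)
        bc = bc or BasalBC()
        pressures = np.asarray(pressures_mmhg, dtype=float)
        if np.any(pressures < 0):
            raise ValueError("pressures must be non-negative")
        kappa = self.kappa_factor * params.a
        p_end = pressures.max() if len(pressures) else 0.0

        nq = self._B.shape[2]
        fracs = pressures / p_end if p_end > 0 else np.zeros_like(pressures)
        edge_amps = bc.edge_radial_displacement * fracs
        loaded = (pressures > 0) | (edge_amps != 0)

        q_sol = np.zeros((len(pressures), nq))
        gnorms = np.zeros(len(pressures))
        batched_done = np.zeros(len(pressures), dtype=bool)
        if (
            self.use_batched
            and q_init is not None
            and len(q_init) == len(pressures)
            and np.any(loaded)
        ):
            # warm restart: iterate every loaded step simultaneously
            idx = np.flatnonzero(loaded)
            Qb, Wb, gnb, okb = self._solve_batched(
                np.asarray(q_init)[idx],
                pressures[idx] * MMHG_TO_KPA,
                params,
                kappa,
                edge_amps[idx],
                keys=list(idx),
            )
            q_sol[idx] = Qb
            gnorms[idx] = gnb
            batched_done[idx] = okb

        frames, vols, qs = [], [], []
        q = np.zeros(nq)
        for i, p in enumerate(pressures):
            edge_amp = edge_amps[i]
            if not loaded[i]:
                qi = np.zeros(nq)
                gn = 0.0
            elif batched_done[i]:
                qi = q_sol[i]
                gn = gnorms[i]
            else:
                if batched_done.any() and np.any(q_sol[i]):
                    x0 = q_sol[i]  # partial batched progress
                elif q_init is not None and i < len(q_init):
                    x0 = np.asarray(q_init)[i]
                else:
                    x0 = q  # chain from the previous step
                args = (p * MMHG_TO_KPA, params, kappa, edge_amp)
                qi, fval, gn, ok = self._newton(x0, args, cache_key=i)
                if not ok:
                    if strict:
                        raise ForwardModelError(
                            f"inflation failed to converge at step {i} "
                            f"(p = {p:.3f} mmHg, |grad| = {gn:.3e})",
                            step=i,
                            residual=gn,
                        )
            q = qi
            x = self._X + self._B @ qi + edge_amp * self._B_edge
            frames.append(x)
            vols.append(self.cavity_volume(x))
            qs.append(qi)
            gnorms[i] = gn

        # incompressibility bookkeeping on the final frame
        xe = frames[-1][self._hexes]
        d = xe - xe.mean(axis=1, keepdims=True)
        F = np.einsum("eni,enj->eij", d, self._G)
        jdev = float(
            np.average(np.abs(np.linalg.det(F) - 1.0), weights=self._Vref)
        )
        curve = PressureVolumeCurve(pressures, np.asarray(vols))
        return ForwardResult(
            frames=frames,
            curve=curve,
            coords=np.asarray(qs),
            converged=True,
            grad_norms=np.asarray(gnorms),
            mean_abs_j_minus_1=jdev,
        )

    # convenience for stress-based markers -----------------------------
    def deformation_gradients(self, mesh: LVMesh, points: np.ndarray) -> np.ndarray:
        self._prepare(mesh)
        xe = points[self._hexes]
        d = xe - xe.mean(axis=1, keepdims=True)
        return np.einsum("eni,enj->eij", d, self._G)

    def cauchy_stress_field(
        self, mesh: LVMesh, points: np.ndarray, params: MaterialParameters
    ) -> np.ndarray:
        """Per-element Cauchy stress including the penalty (volumetric) part."""
        F = self.deformation_gradients(mesh, points)
        J = np.linalg.det(F)
        sig = mech.cauchy_stress(F, mesh.fiber, mesh.sheet, params)
        kappa = self.kappa_factor * params.a
        return sig + (kappa * (J - 1.0))[:, None, None] * np.eye(3)[None]


def inflate_lv(
    mesh: LVMesh,
    params: MaterialParameters,
    p_ed: float,
    n_time: int = 13,
    bc: Optional[BasalBC] = None,
    model: Optional[ReducedOrderInflation] = None,
):
    """Inflate an LV to end-diastolic pressure ``p_ed`` (mmHg) along a linear
    pressure ramp with ``n_time`` frames; returns (mesh series, p-V curve)."""
    if n_time < 2:
        raise ValueError("n_time must be at least 2")
    if p_ed < 0:
        raise ValueError("p_ed must be non-negative")
    model = model or ReducedOrderInflation()
    pressures = np.linspace(0.0, p_ed, n_time)
    result = model.solve(mesh, params, pressures, bc=bc)
    series = [mesh.with_points(f) for f in result.frames]
    return series, result.curve
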