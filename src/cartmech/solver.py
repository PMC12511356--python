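"""Quasi-static u-p poroelastic finite-element solver on hexahedral meshes.

Mixed displacement / pore-pressure formulation with equal-order trilinear
interpolation (C3D8P-style elements), backward-Euler time integration and
full Newton iterations with automatic time-step subdivision.  Kinematics are
total-Lagrangian finite strain by default; a small-strain switch recovers
linear Biot poroelasticity for verification against closed-form solutions.

Weak form per time step (backward Euler, incompressible constituents):

  momentum:      int P(F, p) : Grad(du) dV0  =  follower-pressure work
  mass balance:  int dp (J - J_n)/dt dV0 + int Grad(dp) . K(F) Grad(p) dV0 = 0

with ``P`` the first Piola total stress and ``K = J F^-1 k(J) F^-T`` the
pulled-back Darcy conductivity.  Drainage enters as Dirichlet ``p = 0`` on
free-draining boundary nodes; sealed boundaries are natural.  The default
articular condition is contact-dependent: faces carrying applied pressure
are sealed, the rest of the articular surface drains freely.

Element tangents are obtained by central finite differences of the stress
and transport response at each quadrature point (correctness over speed at
desk scale); the follower-load stiffness is analytic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cohort import LoadingHistory
from .material import FRPEParameters, MaterialModel
from .mesh import Mesh, SurfaceField, _DN_GP, _N_GP, _QDN_GP, _QN_GP, hex_shape_gradients

__all__ = [
    "BoundarySpec",
    "FieldHistory",
    "NumericsConfig",
    "SolverError",
    "PoroelasticSolver",
    "assemble_system",
    "run_stance_simulation",
    "solve_drained",
]

_I3 = np.eye(3)


class SolverError(RuntimeError):
    """Structured non-convergence error carrying solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class BoundarySpec:
    """Displacement and drainage boundary conditions.

    ``fixed_surface_sets`` lists surface sets whose nodes are fully fixed
    (default: the bone-side surface, attached to the subchondral bone).
    ``drainage`` maps each surface set to ``sealed``, ``free_draining`` or
    ``contact_dependent``; ``node_constraints`` allows extra per-component
    displacement fixing (e.g. roller sides for confined-compression
    benchmarks) as ``(node_ids, components)`` pairs.
    """

    fixed_surface_sets: tuple = ("bone",)
    drainage: dict = field(
        default_factory=lambda: {
            "articular": "contact_dependent",
            "rim": "sealed",
            "bone": "sealed",
        }
    )
    contact_seal_threshold: float = 0.01
    node_constraints: list = field(default_factory=list)


@dataclass
class NumericsConfig:
    tol_rel: float = 1e-6
    tol_abs: float = 1e-9
    max_newton: int = 25
    max_cuts: int = 5
    fd_step: float = 1e-6
    tangent: str = "analytic"  # "analytic" or "fd" (central differences)
    small_strain: bool = False
    store_full_history: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FieldHistory:
    """FE outputs over the stance phase.

    ``displacements``: (T, N, 3) mm; ``pore_pressures``: (T, N) MPa;
    ``F_centroid``: (T, E, 3, 3) deformation gradient at element centroids;
    ``diagnostics``: per-frame Newton/iteration records.
    """

    times: np.ndarray
    displacements: np.ndarray
    pore_pressures: np.ndarray
    F_centroid: np.ndarray
    diagnostics: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)


class _SmallStrainLaw:
    """Linearised counterpart of the FRPE law for verification problems.

    Stress ``sigma = lam tr(eps) I + 2 mu eps + fibril(eps) - p I`` with
    ``eps = sym(F - I)``; storage measure ``J := 1 + tr(eps)``; constant
    isotropic conductivity ``k0``.
    """

    def __init__(self, params: FRPEParameters, primary_dirs: np.ndarray):
        self.params = params
        self.primary = np.asarray(primary_dirs, dtype=float)

    def pk1_and_transport(self, F: np.ndarray, p_pore: np.ndarray):
        prm = self.params
        lam, mu = prm.lame
        eps = 0.5 * (F + np.swapaxes(F, -1, -2)) - _I3
        tr = np.einsum("...ii->...", eps)
        sig = lam * tr[..., None, None] * _I3 + 2.0 * mu * eps
        if prm.E0 > 0 or prm.Eeps > 0:
            a = self.primary[:, None, :]  # (E, 1, 3)
            ef = np.einsum("...i,...ij,...j->...", a, eps, np.broadcast_to(a, eps.shape[:-2] + (3,)))
            sf = np.where(ef > 0, prm.E0 * ef + prm.Eeps * ef * ef, 0.0)
            sig = sig + sf[..., None, None] * np.einsum("ei,ej->eij", self.primary, self.primary)[:, None]
        sig = sig - p_pore[..., None, None] * _I3
        J = 1.0 + tr
        K = np.broadcast_to(prm.k0 * _I3, F.shape).copy()
        return sig, J, K


class PoroelasticSolver:
    """Assembly and time stepping for one mesh + material + boundary spec."""

    def __init__(
        self,
        mesh: Mesh,
        params: FRPEParameters,
        bc: BoundarySpec | None = None,
        numerics: NumericsConfig | None = None,
    ):
        self.mesh = mesh
        self.params = params
        self.bc = bc or BoundarySpec()
        self.num = numerics or NumericsConfig()

        self.material = MaterialModel.for_mesh(mesh, params)
        self.law = (
            _SmallStrainLaw(params, self.material.primary) if self.num.small_strain else self.material
        )

        # reference-configuration quadrature data (fixed for total Lagrangian)
        xe = mesh.nodes[mesh.hexes]  # (E, 8, 3)
        jac = np.einsum("eai,gaj->egji", xe, _DN_GP)  # (E, G, 3, 3)
        detj = np.linalg.det(jac)
        if detj.min() <= 0:
            raise ValueError("mesh contains non-positive Jacobians")
        jinv = np.linalg.inv(jac)
        self.dNdX = np.einsum("gak,egkj->egaj", _DN_GP, jinv)  # (E, G, 8, 3)
        self.wdetJ = detj  # 2x2x2 Gauss weights are all 1
        dn_c = hex_shape_gradients(np.zeros((1, 3)))  # centroid
        jac_c = np.einsum("eai,gaj->egji", xe, dn_c)
        self.dNdX_c = np.einsum("gak,egkj->egaj", dn_c, np.linalg.inv(jac_c))[:, 0]  # (E, 8, 3)

        n = mesh.n_nodes
        self.n_u = 3 * n
        self.n_dof = 4 * n
        self.iu = (3 * mesh.hexes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
        self.ip = self.n_u + mesh.hexes  # (E, 8)

        edof = np.concatenate([self.iu, self.ip], axis=1)  # (E, 32)
        self._rows = np.repeat(edof[:, :, None], 32, axis=2).ravel()
        self._cols = np.repeat(edof[:, None, :], 32, axis=1).ravel()

        self.fixed_u_mask = np.zeros((n, 3), dtype=bool)
        for name in self.bc.fixed_surface_sets:
            ids = np.unique(mesh.faces[mesh.surface_sets[name]])
            self.fixed_u_mask[ids, :] = True
        for node_ids, comps in self.bc.node_constraints:
            for c in comps:
                self.fixed_u_mask[np.asarray(node_ids, dtype=int), c] = True

        self._set_nodes = {
            name: np.unique(mesh.faces[ids]) for name, ids in mesh.surface_sets.items()
        }
        self._lu = None
        self._lu_free: np.ndarray | None = None
        self._lu_age = 0
        self._lu_dt = 0.0
        # precomputed follower-load geometry per articular face
        self._face_nodes = mesh.faces  # (F, 4)

    # -- boundary-condition helpers --------------------------------------

    def drainage_nodes(self, frame: SurfaceField | None) -> np.ndarray:
        """Node ids with Dirichlet p = 0 for the given loading frame.

        Nodes belonging to a pressure-loaded face are sealed even when they
        also lie on a free-draining set (the contact patch covers them);
        without this, elements at the contact edge lose fluid support and
        collapse under load.
        """
        draining: list[np.ndarray] = []
        contact_sealed = np.empty(0, dtype=int)
        if frame is not None and any(m == "contact_dependent" for m in self.bc.drainage.values()):
            loaded = frame.face_ids[frame.values > self.bc.contact_seal_threshold]
            if len(loaded):
                contact_sealed = np.unique(self.mesh.faces[loaded])
        for name, mode in self.bc.drainage.items():
            if name not in self._set_nodes:
                continue
            if mode in ("free_draining", "contact_dependent"):
                draining.append(self._set_nodes[name])
            elif mode != "sealed":
                raise ValueError(f"unknown drainage mode {mode!r}")
        if not draining:
            return np.empty(0, dtype=int)
        return np.setdiff1d(np.unique(np.concatenate(draining)), contact_sealed)

    def free_dofs(self, frame: SurfaceField | None) -> np.ndarray:
        fixed = np.zeros(self.n_dof, dtype=bool)
        fixed[: self.n_u] = self.fixed_u_mask.ravel()
        fixed[self.n_u + self.drainage_nodes(frame)] = True
        return np.nonzero(~fixed)[0]

    # -- kinematics -------------------------------------------------------

    def _gp_fields(self, u: np.ndarray, p: np.ndarray):
        ue = u[self.mesh.hexes]  # (E, 8, 3)
        pe = p[self.mesh.hexes]  # (E, 8)
        F = _I3 + np.einsum("eai,egaj->egij", ue, self.dNdX)
        gradp = np.einsum("ea,egaj->egj", pe, self.dNdX)
        p_gp = np.einsum("ea,ga->eg", pe, _N_GP)
        return F, gradp, p_gp

    def deformation_gradient_centroid(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.mesh.hexes]
        return _I3 + np.einsum("eai,eaj->eij", ue, self.dNdX_c)

    # -- external load ----------------------------------------------------

    def _external_force(self, u: np.ndarray, frame: SurfaceField | None):
        """Nodal follower-pressure forces; (N, 3) array."""
        f = np.zeros((self.mesh.n_nodes, 3))
        if frame is None:
            return f, None
        mask = frame.values != 0.0
        if not mask.any():
            return f, None
        fids = frame.face_ids[mask]
        pext = frame.values[mask]
        conn = self._face_nodes[fids]  # (L, 4)
        coords = self.mesh.nodes[conn]
        if not self.num.small_strain:
            coords = coords + u[conn]
        tang = np.einsum("fai,gad->fgdi", coords, _QDN_GP)  # (L, 4gp, 2, 3)
        c = np.cross(tang[:, :, 0, :], tang[:, :, 1, :])  # (L, 4gp, 3) outward n*da
        fe = -np.einsum("f,ga,fgi->fai", pext, _QN_GP, c, optimize=True)  # (L, 4, 3)
        np.add.at(f, conn, fe)
        return f, (fids, pext, conn, coords, tang, c)

    def _load_stiffness(self, load_ctx):
        """Analytic follower-load stiffness d f_ext / d u (COO triplets)."""
        if load_ctx is None or self.num.small_strain:
            return None
        fids, pext, conn, coords, tang, c = load_ctx
        L = len(fids)
        t1 = tang[:, :, 0, :]
        t2 = tang[:, :, 1, :]
        dfdx = np.zeros((L, 4, 3, 4, 3))
        ek = np.eye(3)
        for k in range(3):
            # dc/dx_{b,k} at each gp: D1_b (e_k x t2) + D2_b (t1 x e_k)
            c1 = np.cross(ek[k], t2)  # (L, 4gp, 3)
            c2 = np.cross(t1, ek[k])
            dc = (
                _QDN_GP[None, :, :, 0, None] * c1[:, :, None, :]
                + _QDN_GP[None, :, :, 1, None] * c2[:, :, None, :]
            )  # (L, 4gp, b, 3)
            dfdx[:, :, :, :, k] = -np.einsum("f,ga,fgbi->faib", pext, _QN_GP, dc, optimize=True)
        rows = np.repeat((3 * conn[:, :, None] + np.arange(3)).reshape(L, 12, 1), 12, axis=2)
        cols = np.repeat((3 * conn[:, :, None] + np.arange(3)).reshape(L, 1, 12), 12, axis=1)
        return rows.ravel(), cols.ravel(), dfdx.reshape(L, 12, 12).ravel()

    # -- residual and Jacobian -------------------------------------------

    def residual(self, u: np.ndarray, p: np.ndarray, J_n: np.ndarray, dt: float, frame: SurfaceField | None):
        """Unreduced residual vector of length 4 * n_nodes."""
        F, gradp, p_gp = self._gp_fields(u, p)
        P, J, K = self.law.pk1_and_transport(F, p_gp)
        r = np.zeros(self.n_dof)
        ru = np.einsum("eg,egij,egaj->eai", self.wdetJ, P, self.dNdX, optimize=True)
        flux = np.einsum("egjl,egl->egj", K, gradp)
        rp = np.einsum("eg,ga,eg->ea", self.wdetJ, _N_GP, (J - J_n) / dt) + np.einsum(
            "eg,egaj,egj->ea", self.wdetJ, self.dNdX, flux
        , optimize=True)
        np.add.at(r, self.iu.reshape(-1, 8, 3), ru.reshape(-1, 8, 3))
        np.add.at(r, self.ip, rp)
        fext, load_ctx = self._external_force(u, frame)
        r[: self.n_u] -= fext.ravel()
        return r, load_ctx

    def _tangents_fd(self, F, p_gp, gradp):
        """Central-difference tangents of the constitutive response."""
        h = self.num.fd_step
        E, G = F.shape[:2]
        stack = np.empty((19,) + F.shape)
        for m in range(9):
            k, l = divmod(m, 3)
            dF = np.zeros((3, 3))
            dF[k, l] = h
            stack[2 * m] = F + dF
            stack[2 * m + 1] = F - dF
        stack[18] = F
        P_all, J_all, K_all = self.law.pk1_and_transport(
            stack, np.broadcast_to(p_gp, (19,) + p_gp.shape)
        )
        A = np.empty((E, G, 3, 3, 3, 3))
        dJdF = np.empty((E, G, 3, 3))
        dwdF = np.empty((E, G, 3, 3, 3))
        for m in range(9):
            k, l = divmod(m, 3)
            A[:, :, :, :, k, l] = (P_all[2 * m] - P_all[2 * m + 1]) / (2 * h)
            dJdF[:, :, k, l] = (J_all[2 * m] - J_all[2 * m + 1]) / (2 * h)
            dwdF[:, :, :, k, l] = np.einsum(
                "egjl,egl->egj", (K_all[2 * m] - K_all[2 * m + 1]) / (2 * h), gradp
            )
        return A, dJdF, dwdF, J_all[18], K_all[18]

    def _tangents_analytic(self, F, p_gp, gradp):
        """Closed-form tangents of the FRPE law (finite-strain path)."""
        from .material import _det3, _inv3

        prm = self.params
        lam, mu = prm.lame
        E, G = F.shape[:2]
        J = _det3(F)
        if np.any(J <= prm.j_floor):
            raise FloatingPointError("J at or below admissibility floor")
        Fi = _inv3(F, J)  # Finv
        lnJ = np.log(J)

        eye = _I3
        # neo-Hookean: P = mu (F - F^-T) + lam lnJ F^-T
        A = (
            mu * np.einsum("ik,jl->ijkl", eye, eye)[None, None]
            + (mu - lam * lnJ[..., None, None, None, None])
            * np.einsum("...jk,...li->...ijkl", Fi, Fi, optimize=True)
            + lam * np.einsum("...ji,...lk->...ijkl", Fi, Fi, optimize=True)
        )
        # fibril families: P_f = J w sf/lam2 * v (x) a0
        if prm.E0 > 0 or prm.Eeps > 0:
            mat = self.material
            V = np.einsum("egij,efj->egfi", F, mat._fam_dirs, optimize=True)
            lam2 = np.einsum("...i,...i->...", V, V)
            eps = 0.5 * np.log(lam2)
            act = eps > 0
            sf = np.where(act, prm.E0 * eps + prm.Eeps * eps * eps, 0.0)
            dsf = np.where(act, prm.E0 + 2.0 * prm.Eeps * eps, 0.0)
            g = mat._fam_w * sf / lam2 * J[..., None]  # (E, G, f)
            # dg/dF_kl = w [ J Finv_lk sf + J v_k a_l (dsf - 2 sf) / lam2 ] / lam2
            dg = (
                mat._fam_w[:, None, None]
                * J[..., None, None, None]
                / lam2[..., None, None]
                * (
                    sf[..., None, None] * np.swapaxes(Fi, -1, -2)[..., None, :, :]
                    + ((dsf - 2.0 * sf) / lam2)[..., None, None]
                    * np.einsum("egfk,efl->egfkl", V, mat._fam_dirs, optimize=True)
                )
            )  # (E, G, f, k, l)
            A = A + np.einsum("egfkl,egfi,efj->egijkl", dg, V, mat._fam_dirs, optimize=True)
            A = A + np.einsum(
                "egf,ik,efl,efj->egijkl",
                g,
                eye,
                mat._fam_dirs,
                mat._fam_dirs,
                optimize=True,
            )
        # pressure: P_p = -p J F^-T
        pJ = p_gp * J
        A = A - pJ[..., None, None, None, None] * (
            np.einsum("...ji,...lk->...ijkl", Fi, Fi, optimize=True)
            - np.einsum("...jk,...li->...ijkl", Fi, Fi, optimize=True)
        )
        dJdF = J[..., None, None] * np.swapaxes(Fi, -1, -2)
        # transport: K = c G, c = k0 J^(M+1), G = Finv Finv^T
        c = prm.k0 * J ** (prm.M + 1.0)
        Gt = np.einsum("...jm,...lm->...jl", Fi, Fi)
        K = c[..., None, None] * Gt
        q = np.einsum("...jl,...l->...j", Gt, gradp)
        s = np.einsum("...lk,...l->...k", Fi, gradp)
        dwdF = c[..., None, None, None] * (
            (prm.M + 1.0) * np.einsum("...lk,...j->...jkl", Fi, q, optimize=True)
            - np.einsum("...jk,...l->...jkl", Fi, q, optimize=True)
            - np.einsum("...jl,...k->...jkl", Gt, s, optimize=True)
        )
        return A, dJdF, dwdF, J, K

    def _tangents_small(self, F, p_gp, gradp):
        """Analytic tangents of the linearised law."""
        prm = self.params
        lam, mu = prm.lame
        E, G = F.shape[:2]
        eye = _I3
        A0 = (
            lam * np.einsum("ij,kl->ijkl", eye, eye)
            + mu * np.einsum("ik,jl->ijkl", eye, eye)
            + mu * np.einsum("il,jk->ijkl", eye, eye)
        )
        A = np.broadcast_to(A0, (E, G, 3, 3, 3, 3)).copy()
        if prm.E0 > 0 or prm.Eeps > 0:
            a = self.material.primary  # (E, 3)
            eps = 0.5 * (F + np.swapaxes(F, -1, -2)) - eye
            ef = np.einsum("ei,egij,ej->eg", a, eps, a, optimize=True)
            dsf = np.where(ef > 0, prm.E0 + 2.0 * prm.Eeps * ef, 0.0)
            aa = np.einsum("ei,ej->eij", a, a)
            A = A + dsf[..., None, None, None, None] * np.einsum(
                "eij,ekl->eijkl", aa, aa
            )[:, None]
        _, J, K = self.law.pk1_and_transport(F, p_gp)
        dJdF = np.broadcast_to(eye, (E, G, 3, 3))
        dwdF = np.zeros((E, G, 3, 3, 3))
        return A, dJdF, dwdF, J, K

    def jacobian(self, u: np.ndarray, p: np.ndarray, J_n: np.ndarray, dt: float, frame: SurfaceField | None):
        """Unreduced sparse Jacobian of the residual (4n x 4n, CSC)."""
        F, gradp, p_gp = self._gp_fields(u, p)
        E, G = F.shape[:2]
        if self.num.small_strain:
            A, dJdF, dwdF, J, K = self._tangents_small(F, p_gp, gradp)
        elif self.num.tangent == "fd":
            A, dJdF, dwdF, J, K = self._tangents_fd(F, p_gp, gradp)
        else:
            A, dJdF, dwdF, J, K = self._tangents_analytic(F, p_gp, gradp)

        # dP/dp: total stress carries -p I; pulled back -> -J F^-T (finite
        # strain) or -I (small strain)
        if self.num.small_strain:
            dPdp = np.broadcast_to(-_I3, F.shape)
        else:
            dPdp = -J[..., None, None] * np.swapaxes(np.linalg.inv(F), -1, -2)

        w = self.wdetJ
        dN = self.dNdX
        # T1[a, i, k, l] = w dN[a, j] A[i, j, k, l]; then contract with dN over
        # (g, l) — both as batched matmuls (BLAS) for speed
        Amat = np.ascontiguousarray(A.transpose(0, 1, 3, 2, 4, 5)).reshape(E * G, 3, 27)
        wdN = (w[..., None, None] * dN).reshape(E * G, 8, 3)
        T1 = np.matmul(wdN, Amat).reshape(E, G, 8, 3, 3, 3)  # (e, g, a, i, k, l)
        T1r = np.ascontiguousarray(T1.transpose(0, 2, 3, 4, 1, 5)).reshape(E, 72, G * 3)
        dNr = np.ascontiguousarray(dN.transpose(0, 1, 3, 2)).reshape(E, G * 3, 8)
        Kuu = np.matmul(T1r, dNr).reshape(E, 8, 3, 3, 8)  # (e, a, i, k, b)
        Kuu = np.ascontiguousarray(Kuu.transpose(0, 1, 2, 4, 3)).reshape(E, 24, 24)
        Kup = np.einsum("eg,egaj,egij,gb->eaib", w, dN, dPdp, _N_GP, optimize=True).reshape(E, 24, 8)
        Kpu = (
            np.einsum("eg,ga,egkl,egbl->eabk", w / dt, _N_GP, dJdF, dN, optimize=True)
            + np.einsum("eg,egaj,egjkl,egbl->eabk", w, dN, dwdF, dN, optimize=True)
        ).reshape(E, 8, 24)
        Kpp = np.einsum("eg,egaj,egjl,egbl->eab", w, dN, K, dN, optimize=True)

        blocks = np.zeros((E, 32, 32))
        blocks[:, :24, :24] = Kuu
        blocks[:, :24, 24:] = Kup
        blocks[:, 24:, :24] = Kpu
        blocks[:, 24:, 24:] = Kpp

        rows, cols, data = [self._rows], [self._cols], [blocks.ravel()]
        _, load_ctx = self._external_force(u, frame)
        ls = self._load_stiffness(load_ctx)
        if ls is not None:
            lr, lc, ld = ls
            rows.append(lr)
            cols.append(lc)
            data.append(-ld)  # r_u = f_int - f_ext
        Jmat = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof),
        )
        return Jmat.tocsc()

    # -- nonlinear solve ---------------------------------------------------

    def solve_step(
        self,
        u_n: np.ndarray,
        p_n: np.ndarray,
        J_n: np.ndarray,
        frame: SurfaceField | None,
        dt: float,
        predictor: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        """One backward-Euler step; returns (u, p, diagnostics dict).

        Newton iterations until the residual norm drops below
        ``max(tol_abs * scale, tol_rel * ||r0||)``; on failure the caller is
        expected to subdivide the step (see :meth:`advance`).
        """
        free = self.free_dofs(frame)
        u = u_n.copy() if predictor is None else predictor[0].copy()
        p = p_n.copy() if predictor is None else predictor[1].copy()
        p[self.drainage_nodes(frame)] = 0.0
        u[self.fixed_u_mask] = 0.0

        scale = 1.0
        if frame is not None and frame.values.size:
            scale = max(1.0, float(np.abs(frame.values).max()))
        history = []
        r_prev = np.inf
        for it in range(self.num.max_newton):
            try:
                r, _ = self.residual(u, p, J_n, dt, frame)
            except FloatingPointError:
                self._lu = None
                raise SolverError("inadmissible state (J at fluid lockout)", {"newton": history})
            rn = float(np.linalg.norm(r[free]))
            history.append(rn)
            if it == 0:
                r0 = max(rn, 1e-30)
            if rn < max(self.num.tol_abs * scale, self.num.tol_rel * r0):
                return u, p, {"iterations": it, "residuals": history}
            if rn > 1e3 * r0 or not np.isfinite(rn):
                self._lu = None
                raise SolverError("Newton diverged", {"newton": history, "dt": dt})
            # quasi-Newton: reuse the factorised Jacobian across iterations
            # (and frames with the same drainage pattern); refresh on stall
            reassemble = (
                self._lu is None
                or self._lu_free is None
                or not np.array_equal(self._lu_free, free)
                or not 0.67 < dt / self._lu_dt < 1.5
                or (it > 0 and rn > 0.5 * r_prev)
                or self._lu_age >= 15
            )
            if reassemble:
                try:
                    J = self.jacobian(u, p, J_n, dt, frame)
                except FloatingPointError:
                    self._lu = None
                    raise SolverError("inadmissible state during Jacobian", {"newton": history})
                self._lu = spla.splu(J[free][:, free].tocsc())
                self._lu_free = free.copy()
                self._lu_age = 0
                self._lu_dt = dt
            dx = self._lu.solve(r[free])
            if not np.all(np.isfinite(dx)):
                self._lu = None
                raise SolverError("linear solve produced non-finite update", {"newton": history})
            full = np.zeros(self.n_dof)
            full[free] = dx
            du = full[: self.n_u].reshape(-1, 3)
            dp = full[self.n_u :]
            # backtrack if the full update overshoots into an inadmissible
            # state (element inversion / fluid lockout)
            alpha = 1.0
            for _ in range(8):
                u_try = u - alpha * du
                if self.num.small_strain or self._admissible(u_try):
                    break
                alpha *= 0.5
            else:
                self._lu = None
                raise SolverError(
                    "update rejected: inadmissible state at all step lengths",
                    {"newton": history, "dt": dt},
                )
            u = u - alpha * du
            p = p - alpha * dp
            self._lu_age += 1
            r_prev = rn
        self._lu = None
        raise SolverError(
            f"Newton failed to converge in {self.num.max_newton} iterations",
            {"newton": history, "dt": dt},
        )

    def advance(
        self,
        u_n,
        p_n,
        J_n,
        frame_from: SurfaceField | None,
        frame_to: SurfaceField,
        dt: float,
        predictor: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        """Advance one loading frame with automatic dt halving (<= max_cuts)."""
        for level in range(self.num.max_cuts + 1):
            nsub = 2**level
            try:
                u, p = u_n, p_n
                Jn = J_n
                total_iters = 0
                for s in range(1, nsub + 1):
                    frac = s / nsub
                    vals_from = frame_from.values if frame_from is not None else 0.0
                    vals = (1 - frac) * vals_from + frac * frame_to.values
                    sub = SurfaceField(frame_to.face_ids, vals, frame_to.frame_time)
                    pred = predictor if (nsub == 1 and predictor is not None) else None
                    try:
                        u, p, diag = self.solve_step(u, p, Jn, sub, dt / nsub, predictor=pred)
                    except SolverError:
                        if pred is None:
                            raise
                        u, p, diag = self.solve_step(u, p, Jn, sub, dt / nsub, predictor=None)
                    total_iters += diag["iterations"]
                    Jn = self._gp_volume_ratio(u)
                return u, p, Jn, {"iterations": total_iters, "subdivisions": nsub}
            except SolverError as err:
                last_err = err
                continue
        raise SolverError(
            f"step failed after {self.num.max_cuts} dt halvings: {last_err}",
            getattr(last_err, "diagnostics", {}),
        )

    def _admissible(self, u: np.ndarray, margin: float = 1.02) -> bool:
        """Cheap check that all quadrature-point J stay above the lockout floor."""
        from .material import _det3

        ue = u[self.mesh.hexes]
        F = _I3 + np.einsum("eai,egaj->egij", ue, self.dNdX, optimize=True)
        return bool(_det3(F).min() > margin * self.params.j_floor)

    def _gp_volume_ratio(self, u: np.ndarray) -> np.ndarray:
        F, _, _ = self._gp_fields(u, np.zeros(self.mesh.n_nodes))
        if self.num.small_strain:
            return 1.0 + np.einsum("egii->eg", F - _I3)
        return np.linalg.det(F)


def assemble_system(
    mesh: Mesh,
    params: FRPEParameters,
    u: np.ndarray,
    p: np.ndarray,
    J_n: np.ndarray | None,
    dt: float,
    bc: BoundarySpec | None = None,
    frame: SurfaceField | None = None,
    numerics: NumericsConfig | None = None,
):
    """Unreduced residual vector and sparse Jacobian at a trial solution."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    solver = PoroelasticSolver(mesh, params, bc, numerics)
    if J_n is None:
        J_n = np.ones((mesh.n_elements, 8))
    r, _ = solver.residual(u, p, J_n, dt, frame)
    J = solver.jacobian(u, p, J_n, dt, frame)
    return r, J


def run_stance_simulation(
    mesh: Mesh,
    params: FRPEParameters,
    loading: LoadingHistory,
    bc: BoundarySpec | None = None,
    numerics: NumericsConfig | None = None,
) -> FieldHistory:
    """Advance the cartilage model through all loading frames.

    Deterministic (no randomness); one converged state per frame.  The
    provenance block records the numerics configuration hash.
    """
    num = numerics or NumericsConfig()
    solver = PoroelasticSolver(mesh, params, bc, num)
    n, E, T = mesh.n_nodes, mesh.n_elements, loading.n_frames

    times = loading.times
    disp = np.zeros((T, n, 3))
    pore = np.zeros((T, n))
    Fc = np.tile(_I3, (T, E, 1, 1))
    diagnostics: list[dict] = []

    u = np.zeros((n, 3))
    p = np.zeros(n)
    J_n = np.ones((E, 8))
    frame0 = loading.pressure_frames[0]
    if np.abs(frame0.values).max() > 0:
        # loading does not start from rest: ramp the first frame on quasi-statically
        zero = SurfaceField(frame0.face_ids, np.zeros_like(frame0.values), frame0.frame_time)
        dt0 = times[1] - times[0] if T > 1 else 1.0
        u, p, J_n, diag = solver.advance(u, p, J_n, zero, frame0, dt0)
        diagnostics.append({"frame": 0, **diag})
    else:
        diagnostics.append({"frame": 0, "iterations": 0, "subdivisions": 1})
    disp[0], pore[0] = u, p
    Fc[0] = solver.deformation_gradient_centroid(u)

    u_prev, p_prev, dt_prev = u.copy(), p.copy(), None
    for i in range(1, T):
        dt = times[i] - times[i - 1]
        pred = None
        if dt_prev is not None and dt_prev > 0:
            fac = dt / dt_prev
            pred = (u + fac * (u - u_prev), p + fac * (p - p_prev))
        u_prev, p_prev, dt_prev = u, p, dt
        u, p, J_n, diag = solver.advance(
            u, p, J_n, loading.pressure_frames[i - 1], loading.pressure_frames[i], dt,
            predictor=pred,
        )
        disp[i], pore[i] = u, p
        Fc[i] = solver.deformation_gradient_centroid(u)
        diagnostics.append({"frame": i, **diag})

    Jmin = np.linalg.det(Fc).min() if not num.small_strain else None
    prov = {
        "config_hash": num.config_hash(),
        "n_elements": E,
        "n_frames": T,
        "min_J": float(Jmin) if Jmin is not None else None,
        "loading_provenance": loading.provenance,
    }
    return FieldHistory(
        times=times,
        displacements=disp,
        pore_pressures=pore,
        F_centroid=Fc,
        diagnostics=diagnostics,
        provenance=prov,
    )


def save_field_history(fh: FieldHistory, path) -> None:
    """Persist a FieldHistory to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "cartmech-fields-v1"
        f.create_dataset("times", data=fh.times)
        f.create_dataset("displacements", data=fh.displacements)
        f.create_dataset("pore_pressures", data=fh.pore_pressures)
        f.create_dataset("F_centroid", data=fh.F_centroid)
        f.attrs["provenance"] = json.dumps(fh.provenance, sort_keys=True, default=str)
        f.attrs["diagnostics"] = json.dumps(fh.diagnostics, sort_keys=True, default=str)


def load_field_history(path) -> FieldHistory:
    import h5py

    with h5py.File(path, "r") as f:
        return FieldHistory(
            times=f["times"][...],
            displacements=f["displacements"][...],
            pore_pressures=f["pore_pressures"][...],
            F_centroid=f["F_centroid"][...],
            diagnostics=json.loads(f.attrs.get("diagnostics", "[]")),
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )


def export_frame_vtk(mesh: Mesh, fh: FieldHistory, frame: int, path) -> None:
    """Write one frame (displacement + pore pressure) as a legacy-ASCII VTK
    unstructured grid for visualisation."""
    from .mesh import write_mesh

    path = str(path)
    write_mesh(mesh, path, "vtk")
    u = fh.displacements[frame]
    p = fh.pore_pressures[frame]
    with open(path, "a") as f:
        f.write(f"POINT_DATA {mesh.n_nodes}\n")
        f.write("VECTORS displacement double\n")
        for row in u:
            f.write(" ".join(format(x, ".9g") for x in row) + "\n")
        f.write("SCALARS pore_pressure double 1\nLOOKUP_TABLE default\n")
        for x in p:
            f.write(format(x, ".9g") + "\n")


def solve_drained(
    mesh: Mesh,
    params: FRPEParameters,
    frame: SurfaceField,
    bc: BoundarySpec | None = None,
    numerics: NumericsConfig | None = None,
    n_increments: int = 5,
):
    """Static drained elastic solution (p = 0 everywhere) under one frame.

    The load is ramped in ``n_increments`` quasi-static increments; pore
    pressure is pinned to zero at every node (fully drained limit).
    """
    num = numerics or NumericsConfig()
    import copy

    bc = copy.deepcopy(bc) if bc is not None else BoundarySpec()
    bc.drainage = {name: "free_draining" for name in mesh.surface_sets}
    solver = PoroelasticSolver(mesh, params, bc, num)
    # pin every p dof: with all surfaces draining, interior nodes still carry
    # p; a huge dt removes the storage term so diffusion drives p to zero
    u = np.zeros((mesh.n_nodes, 3))
    p = np.zeros(mesh.n_nodes)
    J_n = np.ones((mesh.n_elements, 8))
    prev = SurfaceField(frame.face_ids, np.zeros_like(frame.values), frame.frame_time)
    for s in range(1, n_increments + 1):
        vals = frame.values * (s / n_increments)
        sub = SurfaceField(frame.face_ids, vals, frame.frame_time)
        u, p, diag = solver.solve_step(u, p, J_n, sub, dt=1e9, predictor=(u, p))
        J_n = solver._gp_volume_ratio(u)
        prev = sub
    return u, p
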