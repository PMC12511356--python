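"""Fibril-reinforced poroelastic (FRPE) constitutive law for articular cartilage.

The solid skeleton is split into a tension-only collagen-fibril network and a
compressible neo-Hookean non-fibrillar matrix (proteoglycan gel); the
interstitial fluid enters through the pore pressure ``p`` and a
deformation-dependent Darcy permeability.  Total Cauchy stress:

    sigma = sigma_nf(F) + sum_f w_f * sigma_f(eps_f) a_f (x) a_f  -  p I

with fibril strain ``eps_f = ln ||F a0_f||`` (logarithmic strain of the fibre
stretch, the convention of the commercial-FE workflows this model family is
used with), a piecewise fibril law that is zero in compression and
strain-stiffening in tension,

    sigma_f(eps) = E0 * eps + Eeps * eps**2        (eps > 0)

and permeability following the void-ratio power law

    k(J) = k0 * ((1 + e) / (1 + e0))**M,     e = J (1 + e0) - 1.

Units: mm, N, MPa, s; permeability in mm^4/(N s).

Default parameters are a literature-typical set for non-degenerated human
knee cartilage calibrated against unconfined-compression experiments (initial
fibril-network modulus 0.92 MPa, strain-dependent fibril modulus 150 MPa,
matrix modulus 0.215 MPa, Poisson ratio 0.15, k0 = 1.9e-3 mm^4/(N s),
fluid fraction 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FRPEParameters",
    "LINEAR_TEST_SET",
    "MaterialState",
    "MaterialModel",
    "nonfibrillar_stress",
    "nonfibrillar_energy",
    "fibril_stress_1d",
    "fibril_directions",
    "secondary_directions",
    "total_effective_stress",
    "permeability",
    "material_tangent",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class FRPEParameters:
    """Constitutive constants of the FRPE law.

    Attributes
    ----------
    E0 : initial fibril-network modulus, MPa.
    Eeps : strain-dependent fibril-network modulus, MPa.
    Enf : non-fibrillar matrix Young modulus, MPa.
    nu_nf : non-fibrillar Poisson ratio.
    k0 : initial permeability, mm^4/(N s).
    M : permeability exponent (dimensionless).
    fluid_fraction : initial fluid volume fraction n_f0; void ratio
        e0 = n_f0 / (1 - n_f0).
    C : primary-to-secondary fibril density ratio.
    fibril_architecture : ``"arcade"`` (Benninghoff-style depth-dependent
        primary direction plus an isotropic secondary set),
        ``"homogeneous"`` (fixed primary direction everywhere plus the
        secondary set) or ``"single"`` (one primary family only — used for
        single-fibril verification problems).
    primary_direction : reference direction for the non-arcade architectures.
    """

    E0: float = 0.92
    Eeps: float = 150.0
    Enf: float = 0.215
    nu_nf: float = 0.15
    k0: float = 1.9e-3
    M: float = 1.2
    fluid_fraction: float = 0.8
    C: float = 3.009
    fibril_architecture: str = "arcade"
    primary_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.E0, self.Eeps, self.Enf) < 0:
            raise ValueError("moduli must be non-negative")
        if not 0 <= self.nu_nf < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.k0 <= 0:
            raise ValueError("initial permeability must be positive")
        if not 0 < self.fluid_fraction < 1:
            raise ValueError("fluid fraction must lie in (0, 1)")

    @property
    def e0(self) -> float:
        return self.fluid_fraction / (1.0 - self.fluid_fraction)

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.Enf * self.nu_nf / ((1 + self.nu_nf) * (1 - 2 * self.nu_nf))
        mu = self.Enf / (2 * (1 + self.nu_nf))
        return lam, mu

    @property
    def j_floor(self) -> float:
        """Admissibility bound J > 1 - n_f0 (solid phase is incompressible)."""
        return 1.0 - self.fluid_fraction

    def with_(self, **kw) -> "FRPEParameters":
        return replace(self, **kw)


#: soft linear-elastic set used in solver verification problems
#: (fibrils off, high permeability is set per-benchmark)
LINEAR_TEST_SET = FRPEParameters(
    E0=0.0, Eeps=0.0, Enf=0.5, nu_nf=0.0, k0=1.0e-3, M=0.0, fluid_fraction=0.8,
    fibril_architecture="single", primary_direction=(0.0, 0.0, 1.0),
)


@dataclass
class MaterialState:
    """Pointwise state: deformation gradient, pore pressure, fibril directions."""

    F: np.ndarray
    p: float = 0.0
    directions: np.ndarray = field(default_factory=lambda: np.array([[0.0, 0.0, 1.0]]))
    weights: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    cached_stress: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if np.linalg.det(self.F) <= 0:
            raise ValueError("deformation gradient must have positive determinant")
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("fibril directions must be unit vectors")


def nonfibrillar_stress(F: np.ndarray, Enf: float, nu_nf: float) -> np.ndarray:
    """Cauchy stress of the compressible neo-Hookean matrix.

    ``sigma = (mu (B - I) + lam ln J I) / J``; reduces to isotropic linear
    elasticity with ``(Enf, nu_nf)`` for small strains.  Vectorised over
    leading axes of ``F`` (shape ``(..., 3, 3)``).
    """
    F = np.asarray(F, dtype=float)
    lam = Enf * nu_nf / ((1 + nu_nf) * (1 - 2 * nu_nf))
    mu = Enf / (2 * (1 + nu_nf))
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    B = F @ np.swapaxes(F, -1, -2)
    lnJ = np.log(J)[..., None, None]
    return (mu * (B - _I3) + lam * lnJ * _I3) / J[..., None, None]


def nonfibrillar_energy(F: np.ndarray, Enf: float, nu_nf: float) -> np.ndarray:
    """Stored-energy density of the neo-Hookean matrix (per reference volume)."""
    F = np.asarray(F, dtype=float)
    lam = Enf * nu_nf / ((1 + nu_nf) * (1 - 2 * nu_nf))
    mu = Enf / (2 * (1 + nu_nf))
    J = np.linalg.det(F)
    I1 = np.einsum("...ij,...ij->...", F, F)
    return 0.5 * mu * (I1 - 3.0) - mu * np.log(J) + 0.5 * lam * np.log(J) ** 2


def fibril_stress_1d(eps_f: np.ndarray | float, E0: float, Eeps: float) -> np.ndarray | float:
    """Tension-only strain-stiffening fibril law; zero for eps_f <= 0."""
    if E0 < 0 or Eeps < 0:
        raise ValueError("fibril moduli must be non-negative")
    eps = np.asarray(eps_f, dtype=float)
    out = np.where(eps > 0, E0 * eps + Eeps * eps * eps, 0.0)
    return out if out.ndim else float(out)


_GOLD = (1.0 + np.sqrt(5.0)) / 2.0
# six icosahedral vertex axes: an even angular spread for the secondary network
_SECONDARY = np.array(
    [
        [0.0, 1.0, _GOLD],
        [0.0, -1.0, _GOLD],
        [1.0, _GOLD, 0.0],
        [-1.0, _GOLD, 0.0],
        [_GOLD, 0.0, 1.0],
        [_GOLD, 0.0, -1.0],
    ]
)
_SECONDARY /= np.linalg.norm(_SECONDARY, axis=1, keepdims=True)


def secondary_directions() -> np.ndarray:
    """Fixed icosahedral set of 6 unit axes for the secondary fibril network."""
    return _SECONDARY.copy()


def fibril_directions(
    depth_fraction: float,
    architecture: str = "arcade",
    surface_direction: np.ndarray | tuple = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """Primary fibril direction(s) at relative depth ``z/h`` in [0, 1].

    Arcade (Benninghoff) architecture: perpendicular to the surface (along
    depth) in the deep zone ``z/h < 0.5``, parallel to the surface for
    ``z/h > 0.8``, rotating linearly in the transitional zone between.
    ``surface_direction`` sets the in-plane direction the arcade bends into
    (split-line direction).
    """
    zh = float(depth_fraction)
    if not 0.0 <= zh <= 1.0:
        raise ValueError("depth fraction must lie in [0, 1]")
    s = np.asarray(surface_direction, dtype=float)
    s = s / np.linalg.norm(s)
    if architecture in ("homogeneous", "single"):
        return s[None, :]
    if architecture != "arcade":
        raise ValueError(f"unknown fibril architecture {architecture!r}")
    deep = np.array([0.0, 0.0, 1.0])
    if zh <= 0.5:
        return deep[None, :]
    if zh >= 0.8:
        return s[None, :]
    theta = 0.5 * np.pi * (zh - 0.5) / 0.3
    d = np.cos(theta) * deep + np.sin(theta) * s
    return (d / np.linalg.norm(d))[None, :]


def permeability(J: np.ndarray | float, params: FRPEParameters) -> np.ndarray | float:
    """Deformation-dependent permeability k(J), mm^4/(N s)."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= params.j_floor):
        raise ValueError(
            f"volume ratio J <= {params.j_floor:.3f} violates solid-phase incompressibility"
        )
    e = J * (1.0 + params.e0) - 1.0
    out = params.k0 * ((1.0 + e) / (1.0 + params.e0)) ** params.M
    return out if out.ndim else float(out)


def _fibril_cauchy(F: np.ndarray, dirs: np.ndarray, weights: np.ndarray, E0: float, Eeps: float) -> np.ndarray:
    """Summed fibril Cauchy stress for families ``dirs`` with ``weights``.

    ``F`` has shape (..., 3, 3); ``dirs`` either (nfam, 3) shared or
    (..., nfam, 3) per-point.
    """
    F = np.asarray(F, dtype=float)
    sig = np.zeros(F.shape)
    dirs = np.asarray(dirs, dtype=float)
    for f in range(dirs.shape[-2]):
        a0 = dirs[..., f, :]
        v = np.einsum("...ij,...j->...i", F, np.broadcast_to(a0, F.shape[:-2] + (3,)))
        lam2 = np.einsum("...i,...i->...", v, v)
        lam = np.sqrt(lam2)
        eps = np.log(lam)
        sf = np.where(eps > 0, E0 * eps + Eeps * eps * eps, 0.0)
        w = weights[f] if np.ndim(weights) == 1 else weights[..., f]
        sig += (w * sf / lam2)[..., None, None] * np.einsum("...i,...j->...ij", v, v)
    return sig


def total_effective_stress(state: MaterialState, params: FRPEParameters) -> np.ndarray:
    """Total Cauchy stress: fibrillar + non-fibrillar effective stress - p I."""
    sig = nonfibrillar_stress(state.F, params.Enf, params.nu_nf)
    if params.E0 > 0 or params.Eeps > 0:
        sig = sig + _fibril_cauchy(state.F, state.directions, state.weights, params.E0, params.Eeps)
    sig = sig - state.p * _I3
    state.cached_stress = sig
    return sig


def material_tangent(state: MaterialState, params: FRPEParameters, perturbation: float = 1e-6) -> np.ndarray:
    """Central-difference tangent ``d sigma_ij / d F_kl`` (4th-order, MPa)."""
    h = perturbation
    A = np.empty((3, 3, 3, 3))
    for k in range(3):
        for l in range(3):
            dF = np.zeros((3, 3))
            dF[k, l] = h
            sp = total_effective_stress(
                MaterialState(state.F + dF, state.p, state.directions, state.weights), params
            )
            sm = total_effective_stress(
                MaterialState(state.F - dF, state.p, state.directions, state.weights), params
            )
            A[:, :, k, l] = (sp - sm) / (2 * h)
    return A


def _det3(F: np.ndarray) -> np.ndarray:
    """Closed-form determinant of batched 3x3 matrices (faster than LAPACK
    dispatch for the solver's many small batches)."""
    return (
        F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
        - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
        + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0])
    )


def _inv3(F: np.ndarray, detF: np.ndarray) -> np.ndarray:
    """Closed-form (adjugate) inverse of batched 3x3 matrices."""
    inv = np.empty_like(F)
    inv[..., 0, 0] = F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1]
    inv[..., 0, 1] = F[..., 0, 2] * F[..., 2, 1] - F[..., 0, 1] * F[..., 2, 2]
    inv[..., 0, 2] = F[..., 0, 1] * F[..., 1, 2] - F[..., 0, 2] * F[..., 1, 1]
    inv[..., 1, 0] = F[..., 1, 2] * F[..., 2, 0] - F[..., 1, 0] * F[..., 2, 2]
    inv[..., 1, 1] = F[..., 0, 0] * F[..., 2, 2] - F[..., 0, 2] * F[..., 2, 0]
    inv[..., 1, 2] = F[..., 0, 2] * F[..., 1, 0] - F[..., 0, 0] * F[..., 1, 2]
    inv[..., 2, 0] = F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]
    inv[..., 2, 1] = F[..., 0, 1] * F[..., 2, 0] - F[..., 0, 0] * F[..., 2, 1]
    inv[..., 2, 2] = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return inv / detF[..., None, None]


class MaterialModel:
    """Vectorised FRPE evaluation bound to a mesh's per-element fibril layout.

    Precomputes the primary fibril direction per element (from relative depth
    of the element centroid) and the family weights, then evaluates total
    first-Piola stress, volume ratio and reference-pulled-back Darcy
    conductivity for all quadrature points at once.
    """

    def __init__(self, params: FRPEParameters, primary_dirs: np.ndarray):
        self.params = params
        self.primary = np.asarray(primary_dirs, dtype=float)  # (E, 3)
        if params.fibril_architecture == "single":
            self.secondary = np.empty((0, 3))
            self.w_primary = 1.0
            self.w_secondary = np.empty(0)
        else:
            self.secondary = secondary_directions()
            n_sec = self.secondary.shape[0]
            tot = params.C + n_sec
            self.w_primary = params.C / tot
            self.w_secondary = np.full(n_sec, 1.0 / tot)
        # fused per-element family table for the vectorised solver path
        E = self.primary.shape[0]
        nfam = 1 + self.secondary.shape[0]
        self._fam_dirs = np.empty((E, nfam, 3))
        self._fam_dirs[:, 0, :] = self.primary
        if self.secondary.size:
            self._fam_dirs[:, 1:, :] = self.secondary[None, :, :]
        self._fam_w = np.concatenate([[self.w_primary], self.w_secondary])

    @classmethod
    def for_mesh(cls, mesh, params: FRPEParameters) -> "MaterialModel":
        from .mesh import element_volumes  # local import to avoid cycle

        xe = mesh.nodes[mesh.hexes]
        cent = xe.mean(axis=1)
        zmin, zmax = mesh.nodes[:, 2].min(), mesh.nodes[:, 2].max()
        # per-column depth fraction: use element centroid against slab extremes
        zh = np.clip((cent[:, 2] - zmin) / max(zmax - zmin, 1e-12), 0.0, 1.0)
        dirs = np.empty((mesh.n_elements, 3))
        if params.fibril_architecture == "arcade":
            for e in range(mesh.n_elements):
                c = cent[e]
                r = np.array([c[0], c[1], 0.0])
                nrm = np.linalg.norm(r)
                s = r / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                dirs[e] = fibril_directions(zh[e], "arcade", s)[0]
        else:
            s = np.asarray(params.primary_direction, dtype=float)
            dirs[:] = s / np.linalg.norm(s)
        return cls(params, dirs)

    def cauchy_effective(self, F: np.ndarray) -> np.ndarray:
        """Effective (solid) Cauchy stress at (E, G, 3, 3) deformation gradients."""
        p = self.params
        sig = nonfibrillar_stress(F, p.Enf, p.nu_nf)
        if p.E0 > 0 or p.Eeps > 0:
            prim = self.primary[:, None, None, :]  # (E, 1, 1fam, 3)
            sig = sig + self.w_primary * _fibril_cauchy(F, prim, np.array([1.0]), p.E0, p.Eeps)
            if self.secondary.size:
                sig = sig + _fibril_cauchy(F, self.secondary, self.w_secondary, p.E0, p.Eeps)
        return sig

    def pk1_and_transport(self, F: np.ndarray, p_pore: np.ndarray):
        """First-Piola total stress, J, and pulled-back conductivity tensor.

        Parameters are quadrature-point arrays: ``F`` of shape
        (..., E, G, 3, 3), ``p_pore`` of shape (..., E, G).  Returns ``P``,
        ``J`` and ``K = J F^-1 k(J) F^-T``.
        """
        prm = self.params
        J = _det3(F)
        if np.any(J <= prm.j_floor):
            bad = int(np.argwhere(J <= prm.j_floor)[0][-2])  # element axis
            raise FloatingPointError(
                f"volume ratio at or below admissibility floor {prm.j_floor:.3f} "
                f"(first offending element: {bad})"
            )
        Finv = _inv3(F, J)
        lam, mu = prm.lame
        B = np.einsum("...ij,...kj->...ik", F, F)
        lnJ = np.log(J)
        sig = (mu * (B - _I3) + lam * lnJ[..., None, None] * _I3) / J[..., None, None]
        if prm.E0 > 0 or prm.Eeps > 0:
            # all fibril families in one pass: V[..., e, g, f, i] = F a0_f
            V = np.einsum("...egij,efj->...egfi", F, self._fam_dirs, optimize=True)
            lam2 = np.einsum("...i,...i->...", V, V)
            eps = 0.5 * np.log(lam2)
            coef = np.where(
                eps > 0, self._fam_w * (prm.E0 * eps + prm.Eeps * eps * eps) / lam2, 0.0
            )
            sig = sig + np.einsum("...f,...fi,...fj->...ij", coef, V, V, optimize=True)
        sig = sig - p_pore[..., None, None] * _I3
        P = J[..., None, None] * np.einsum("...ij,...kj->...ik", sig, Finv)
        k = prm.k0 * (J ** prm.M if prm.M != 0 else 1.0)
        K = (J * k)[..., None, None] * np.einsum("...ij,...kj->...ik", Finv, Finv)
        return P, J, K
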