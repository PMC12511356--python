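"""Solver verification benchmarks.

Two classical poroelastic checks plus a discretisation-convergence utility:

* Terzaghi consolidation — a laterally confined column loaded by a ramp-hold
  surface pressure, drained only at the top.  With fibrils off and small
  strains the solver must reproduce linear Biot consolidation; the exact
  series solution (with the ramp handled analytically term by term) is the
  oracle.
* Drained limit — after a long hold the transient solution must approach the
  static drained elastic solution (pore pressure everywhere ~ 0).
* Histogram convergence — reports how much the peak-strain histogram moves
  under time-step halving / mesh doubling.
"""

from __future__ import annotations

import numpy as np

from .cohort import LoadingHistory
from .material import LINEAR_TEST_SET, FRPEParameters
from .mesh import Mesh, SurfaceField, build_box_mesh, element_volumes
from .response import strain_triple_field
from .histograms import volume_weighted_histogram
from .solver import BoundarySpec, NumericsConfig, run_stance_simulation, solve_drained

__all__ = [
    "terzaghi_pressure",
    "run_terzaghi_benchmark",
    "run_drained_limit_benchmark",
    "histogram_convergence",
]


def terzaghi_pressure(
    z: np.ndarray,
    t: float,
    cv: float,
    L: float,
    p0: float,
    ramp_time: float = 0.0,
    n_terms: int = 400,
) -> np.ndarray:
    """Exact excess pore pressure of 1D consolidation under a ramp-hold load.

    Column occupies ``z in [0, L]`` with drainage at the top ``z = L`` and a
    sealed base; ``cv`` is the consolidation coefficient (mm^2/s).  The load
    rises linearly over ``ramp_time`` then holds at ``p0``; the ramp is
    superposed analytically per series term (valid for ``t >= ramp_time``).
    """
    z = np.asarray(z, dtype=float)
    if t < ramp_time:
        raise ValueError("ramp correction implemented for t >= ramp_time only")
    zeta = (L - z) / L  # distance from the drained boundary, normalised
    T = cv * t / L**2
    Tr = cv * ramp_time / L**2
    m = np.arange(n_terms)
    M = 0.5 * np.pi * (2 * m + 1)
    if Tr > 0:
        # ramp superposition per term: (e^{-M^2 (T-Tr)} - e^{-M^2 T}) / (M^2 Tr)
        x = M**2 * Tr
        amp = (2.0 / M) * np.where(
            x < 1e-8,
            np.exp(-(M**2) * (T - 0.5 * Tr)),
            (np.exp(-(M**2) * (T - Tr)) - np.exp(-(M**2) * T)) / x,
        )
    else:
        amp = (2.0 / M) * np.exp(-(M**2) * T)
    return p0 * np.einsum("m,mz->z", amp, np.sin(np.outer(M, zeta)))


def _column_times(t_ramp: float, t_end: float, samples: tuple) -> np.ndarray:
    """Ramp steps then geometrically growing hold steps hitting the samples."""
    times = list(np.linspace(0.0, t_ramp, 6))
    t = t_ramp
    dt = 0.3 * t_ramp
    for ts in sorted(samples) + [t_end]:
        while t < ts - 1e-9:
            dt = min(dt * 1.12, (ts - t))
            t = t + dt
            times.append(t)
        t = ts
    return np.unique(np.round(np.asarray(times), 9))


def run_terzaghi_benchmark(
    n_depth: int = 20,
    p0: float = 1e-3,
    sample_fracs: tuple = (0.05, 0.2, 0.5),
) -> dict:
    """Consolidating column vs the exact series solution.

    1 x 1 x ``n_depth``-element column, lateral motion suppressed, top
    free-draining, linear small-strain parameter set.  Returns the sampled
    profiles and the largest pointwise error as a fraction of the applied
    load.
    """
    L = 1.0
    params = LINEAR_TEST_SET
    H_c = params.Enf * (1 - params.nu_nf) / ((1 + params.nu_nf) * (1 - 2 * params.nu_nf))
    cv = params.k0 * H_c
    t_star = L**2 / cv
    t_ramp = 0.01 * t_star
    samples = tuple(f * t_star for f in sample_fracs)

    mesh = build_box_mesh(1.0, 1.0, L, 1, 1, n_depth)
    all_nodes = np.arange(mesh.n_nodes)
    bottom = np.unique(mesh.faces[mesh.surface_sets["bone"]])
    bc = BoundarySpec(
        fixed_surface_sets=(),
        drainage={"articular": "free_draining", "rim": "sealed", "bone": "sealed"},
        node_constraints=[(all_nodes, (0, 1)), (bottom, (2,))],
    )
    times = _column_times(t_ramp, samples[-1], samples)
    face_ids = mesh.articular_faces()
    frames = []
    for t in times:
        amp = p0 * min(t / t_ramp, 1.0)
        frames.append(SurfaceField(face_ids, np.full(len(face_ids), amp), float(t)))
    areas = np.ones(len(face_ids))
    loading = LoadingHistory(
        times=times, pressure_frames=frames,
        total_force_trace=np.array([f.values.sum() for f in frames]),
    )
    hist = run_stance_simulation(
        mesh, params, loading, bc, NumericsConfig(small_strain=True)
    )

    z = mesh.nodes[:, 2]
    errors = []
    profiles = {}
    for ts in samples:
        i = int(np.argmin(np.abs(times - ts)))
        p_fe = hist.pore_pressures[i]
        p_exact = terzaghi_pressure(z, times[i], cv, L, p0, ramp_time=t_ramp)
        errors.append(np.max(np.abs(p_fe - p_exact)) / p0)
        profiles[float(ts / t_star)] = {
            "z": z.tolist(),
            "fe": p_fe.tolist(),
            "exact": p_exact.tolist(),
        }
    return {
        "max_error_frac_of_load": float(max(errors)),
        "errors_per_time": [float(e) for e in errors],
        "cv": cv,
        "profiles": profiles,
    }


def run_drained_limit_benchmark(
    load: float = 0.1,
    params: FRPEParameters | None = None,
) -> dict:
    """Long-hold transient vs static drained solve on a small block.

    Uniform pressure on the articular surface, free-draining top/rim; the
    hold extends several consolidation times so the pore pressure decays to
    ~0 and displacements settle onto the drained elastic solution.  Returns
    the displacement RMS difference relative to the drained RMS and the peak
    residual pore pressure.
    """
    params = params or LINEAR_TEST_SET
    mesh = build_box_mesh(2.0, 2.0, 1.0, 3, 3, 3)
    bc = BoundarySpec(
        fixed_surface_sets=("bone",),
        drainage={"articular": "free_draining", "rim": "free_draining", "bone": "sealed"},
    )
    H_c = params.Enf * (1 - params.nu_nf) / ((1 + params.nu_nf) * (1 - 2 * params.nu_nf))
    cv = params.k0 * H_c
    t_star = 1.0 / cv  # depth 1 mm
    t_ramp = 0.02 * t_star
    times = _column_times(t_ramp, 4.0 * t_star, (t_star, 2.0 * t_star))
    face_ids = mesh.articular_faces()
    frames = [
        SurfaceField(face_ids, np.full(len(face_ids), load * min(t / t_ramp, 1.0)), float(t))
        for t in times
    ]
    loading = LoadingHistory(
        times=times, pressure_frames=frames,
        total_force_trace=np.array([f.values.sum() for f in frames]),
    )
    num = NumericsConfig(small_strain=params is LINEAR_TEST_SET)
    hist = run_stance_simulation(mesh, params, loading, bc, num)
    u_end = hist.displacements[-1]
    p_end = hist.pore_pressures[-1]

    u_drained, _ = solve_drained(
        mesh, params, SurfaceField(face_ids, np.full(len(face_ids), load)), bc, num
    )
    ref = np.sqrt(np.mean(u_drained**2))
    rms = np.sqrt(np.mean((u_end - u_drained) ** 2))
    return {
        "rms_diff_frac": float(rms / ref),
        "max_residual_pressure_frac": float(np.abs(p_end).max() / load),
    }


def histogram_convergence(
    mesh_coarse: Mesh,
    mesh_fine: Mesh,
    params: FRPEParameters,
    loading_builder,
    bc: BoundarySpec | None = None,
    numerics: NumericsConfig | None = None,
    measure: str = "compressive",
) -> dict:
    """L1 distance between peak-strain histograms at two discretisations.

    ``loading_builder(mesh)`` must return a LoadingHistory on the given mesh.
    Reports the histogram L1 difference in percentage points of volume.
    """
    from .material import MaterialModel
    from .response import elementwise_max_over_stance

    out = {}
    hists = []
    for mesh in (mesh_coarse, mesh_fine):
        loading = loading_builder(mesh)
        fh = run_stance_simulation(mesh, params, loading, bc, numerics)
        mat = MaterialModel.for_mesh(mesh, params)
        triples = [strain_triple_field(fh.F_centroid[i], mat.primary) for i in range(fh.n_frames)]
        peak = elementwise_max_over_stance(triples)
        vols = element_volumes(mesh)
        hists.append(volume_weighted_histogram(peak[measure], vols, measure=measure))
    out["l1_diff_pct"] = float(np.abs(hists[0].values - hists[1].values).sum())
    out["histograms"] = hists
    return out
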