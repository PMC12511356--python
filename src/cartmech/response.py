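"""Mechanical-response fields and loading summaries.

Three tissue-level response measures are extracted per element, all from the
logarithmic (Hencky) strain of the deformation gradient at the element
centroid:

* compressive strain — absolute minimum principal strain ``|eps3|``;
* fibril strain — log fibre stretch along the primary collagen direction,
  clamped at zero (tension-only reporting: a degradation driver cannot be
  negative);
* maximum shear strain — ``(eps1 - eps3) / 2``, the classical maximum shear
  of the strain state.

Loading summaries mirror the contact-mechanics quantities reported at the
two stance force peaks: centre of pressure (AP/ML), mean contact pressure
over the contacting area, total force and contact area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh, SurfaceField, face_areas_centroids

__all__ = [
    "StrainTriple",
    "PeakPair",
    "principal_log_strains",
    "compressive_strain",
    "max_shear_strain",
    "fibril_strain",
    "strain_triple_field",
    "detect_load_peaks",
    "elementwise_max_over_stance",
    "cop_and_mean_pressure",
]

MEASURES = ("compressive", "fibril", "max_shear")
EPOCHS = ("peak1", "peak2", "stance_max")


@dataclass
class StrainTriple:
    """Per-element response fields (arrays of length n_elements)."""

    compressive: np.ndarray
    fibril: np.ndarray
    max_shear: np.ndarray

    def __getitem__(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise KeyError(measure)
        return getattr(self, measure)


@dataclass
class PeakPair:
    """Frame indices/times of the first and second total-load peaks."""

    frame1: int
    frame2: int
    time1: float
    time2: float


def principal_log_strains(F: np.ndarray) -> np.ndarray:
    """Principal logarithmic strains, sorted descending.

    Eigenvalues of ``1/2 log(F^T F)``; vectorised over leading axes, returns
    shape ``(..., 3)`` with ``eps1 >= eps2 >= eps3``.
    """
    F = np.asarray(F, dtype=float)
    if np.any(np.linalg.det(F) <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    C = np.einsum("...ji,...jk->...ik", F, F)
    w = np.linalg.eigvalsh(C)  # ascending
    return 0.5 * np.log(w)[..., ::-1]


def compressive_strain(F: np.ndarray) -> np.ndarray | float:
    """Absolute minimum principal logarithmic strain."""
    eps = principal_log_strains(F)
    out = np.abs(eps[..., 2])
    return out if out.ndim else float(out)


def max_shear_strain(F: np.ndarray) -> np.ndarray | float:
    """Maximum shear strain (eps1 - eps3) / 2 of the log-strain state."""
    eps = principal_log_strains(F)
    out = 0.5 * (eps[..., 0] - eps[..., 2])
    return out if out.ndim else float(out)


def fibril_strain(F: np.ndarray, direction: np.ndarray) -> np.ndarray | float:
    """Log fibre stretch along reference direction(s), clamped at zero.

    ``direction`` is a unit vector, broadcastable against the leading axes
    of ``F``.
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(direction, dtype=float)
    if not np.allclose(np.linalg.norm(a0, axis=-1), 1.0, atol=1e-8):
        raise ValueError("fibril direction must be a unit vector")
    v = np.einsum("...ij,...j->...i", F, np.broadcast_to(a0, F.shape[:-2] + (3,)))
    lam = np.linalg.norm(v, axis=-1)
    out = np.maximum(np.log(lam), 0.0)
    return out if out.ndim else float(out)


def strain_triple_field(F_elements: np.ndarray, primary_dirs: np.ndarray) -> StrainTriple:
    """All three response measures for per-element deformation gradients."""
    eps = principal_log_strains(F_elements)
    return StrainTriple(
        compressive=np.abs(eps[..., 2]),
        fibril=np.asarray(fibril_strain(F_elements, primary_dirs)),
        max_shear=0.5 * (eps[..., 0] - eps[..., 2]),
    )


def detect_load_peaks(
    total_force_trace: np.ndarray,
    times: np.ndarray,
    smoothing_window: int = 0,
) -> PeakPair:
    """First/second peaks of the total tibiofemoral load trace.

    The largest local maximum in the first half of stance and the largest in
    the second half, after optional moving-average smoothing.  Deterministic;
    raises ``ValueError`` when either half lacks a local maximum (e.g. a
    monotone or unimodal trace) with a suggestion to inspect the trace.
    """
    y = np.asarray(total_force_trace, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size < 5:
        raise ValueError("trace too short for peak detection (need >= 5 samples)")
    if smoothing_window and smoothing_window > 1:
        kern = np.ones(smoothing_window) / smoothing_window
        y = np.convolve(y, kern, mode="same")
    interior = np.arange(1, y.size - 1)
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] > y[interior + 1])
    locmax = interior[is_max]
    mid = t[0] + 0.5 * (t[-1] - t[0])
    first = locmax[t[locmax] <= mid]
    second = locmax[t[locmax] > mid]
    if len(first) == 0 or len(second) == 0:
        raise ValueError(
            "second peak not found: the load trace does not show two stance "
            "peaks — inspect the trace (monotone or unimodal input?)"
        )
    i1 = int(first[np.argmax(y[first])])
    i2 = int(second[np.argmax(y[second])])
    return PeakPair(frame1=i1, frame2=i2, time1=float(t[i1]), time2=float(t[i2]))


def elementwise_max_over_stance(triples: list[StrainTriple]) -> StrainTriple:
    """Per-element, per-measure maximum across stance frames."""
    if not triples:
        raise ValueError("need at least one frame")
    return StrainTriple(
        compressive=np.max([tr.compressive for tr in triples], axis=0),
        fibril=np.max([tr.fibril for tr in triples], axis=0),
        max_shear=np.max([tr.max_shear for tr in triples], axis=0),
    )


def cop_and_mean_pressure(
    field: SurfaceField,
    mesh: Mesh,
    contact_threshold: float = 0.01,
) -> dict:
    """Centre of pressure and contact summaries for one pressure frame.

    Returns a dict with ``cop_ap``/``cop_ml`` (mm; pressure-weighted centroid
    over loaded faces), ``mean_pressure`` (MPa, over faces with
    ``p > contact_threshold``), ``total_force`` (N) and ``contact_area``
    (mm^2).  For an all-zero field the COP entries are ``None`` rather than
    NaN.
    """
    areas, cents = face_areas_centroids(mesh, field.face_ids)
    p = field.values
    pa = p * areas
    total_force = float(pa.sum())
    loaded = p > 0
    contacting = p > contact_threshold
    contact_area = float(areas[contacting].sum())
    mean_pressure = float(pa[contacting].sum() / contact_area) if contact_area > 0 else 0.0
    if not loaded.any() or total_force <= 0:
        return {
            "cop_ap": None,
            "cop_ml": None,
            "mean_pressure": mean_pressure,
            "total_force": total_force,
            "contact_area": contact_area,
        }
    cop = (pa[loaded, None] * cents[loaded, :2]).sum(axis=0) / pa[loaded].sum()
    return {
        "cop_ap": float(cop[0]),
        "cop_ml": float(cop[1]),
        "mean_pressure": mean_pressure,
        "total_force": total_force,
        "contact_area": contact_area,
    }
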