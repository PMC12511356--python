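"""Volume-weighted strain histograms, threshold exceedance and clustering.

Histograms express how much of the tissue volume experiences a given strain
level (percentage of total cartilage volume per strain bin); pressure
histograms are area-weighted over the contacting articular surface.  Subject
histograms are the feature vectors for an unsupervised two-cluster k-means
that separates progressor-like from non-progressor-like mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, SurfaceField, face_areas_centroids

__all__ = [
    "StrainHistogram",
    "ClusterResult",
    "default_bin_edges",
    "volume_weighted_histogram",
    "area_weighted_pressure_histogram",
    "threshold_exceedance_volume",
    "kmeans_two_clusters",
    "composition_table",
]

#: degeneration thresholds from the in-vitro literature: collagen-network
#: damage above fibril strain 0.1; proteoglycan depletion above maximum shear
#: strain 0.4 (0.5 in some protocols)
DEGENERATION_THRESHOLDS = {"fibril": 0.1, "max_shear": 0.4}


def default_bin_edges(measure: str) -> np.ndarray:
    """Default histogram bin edges per measure (strain, or pressure in MPa)."""
    if measure in ("compressive", "max_shear"):
        return np.round(np.arange(0.0, 0.5 + 1e-12, 0.01), 10)
    if measure == "fibril":
        return np.round(np.arange(0.0, 0.3 + 1e-12, 0.006), 10)
    if measure == "pressure":
        return np.round(np.arange(0.0, 10.0 + 1e-12, 0.25), 10)
    raise KeyError(measure)


@dataclass
class StrainHistogram:
    """Binned volume-weighted strain distribution (% of tissue volume)."""

    edges: np.ndarray
    values: np.ndarray
    measure: str = ""
    epoch: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.values.shape != (self.edges.size - 1,):
            raise ValueError("values must have one entry per bin")
        if np.any(self.values < -1e-12):
            raise ValueError("histogram values must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _binned_weights(x: np.ndarray, w: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [lo, hi); the last bin is closed.  Out-of-range mass is
    clipped into the end bins so the histogram always conserves mass."""
    xc = np.clip(x, edges[0], np.nextafter(edges[-1], -np.inf))
    idx = np.searchsorted(edges, xc, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    return np.bincount(idx, weights=w, minlength=edges.size - 1)


def volume_weighted_histogram(
    strains: np.ndarray,
    volumes: np.ndarray,
    edges: np.ndarray | None = None,
    measure: str = "compressive",
    epoch: str = "",
) -> StrainHistogram:
    """Histogram of per-element strains weighted by element volume, in % of
    total cartilage volume."""
    strains = np.asarray(strains, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if strains.shape != volumes.shape:
        raise ValueError("strains and volumes must have the same length")
    if np.any(volumes <= 0):
        raise ValueError("element volumes must be positive")
    if edges is None:
        edges = default_bin_edges(measure)
    vals = _binned_weights(strains, volumes, np.asarray(edges, dtype=float))
    vals = 100.0 * vals / volumes.sum()
    return StrainHistogram(edges=edges, values=vals, measure=measure, epoch=epoch)


def area_weighted_pressure_histogram(
    fld: SurfaceField,
    mesh: Mesh,
    edges: np.ndarray | None = None,
    contact_threshold: float = 0.01,
) -> StrainHistogram:
    """Contact-pressure histogram as % of the contacting articular area.

    Only faces with pressure above the contact threshold contribute; with no
    contact at all an all-zero histogram tagged ``no_contact`` is returned.
    """
    if edges is None:
        edges = default_bin_edges("pressure")
    areas, _ = face_areas_centroids(mesh, fld.face_ids)
    mask = fld.values > contact_threshold
    if not mask.any():
        return StrainHistogram(
            edges=edges, values=np.zeros(np.asarray(edges).size - 1), measure="pressure", epoch="no_contact"
        )
    vals = _binned_weights(fld.values[mask], areas[mask], np.asarray(edges, dtype=float))
    vals = 100.0 * vals / areas[mask].sum()
    return StrainHistogram(edges=edges, values=vals, measure="pressure")


def threshold_exceedance_volume(strains: np.ndarray, volumes: np.ndarray, threshold: float) -> float:
    """Percentage of tissue volume with strain strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    strains = np.asarray(strains, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    return float(100.0 * volumes[strains > threshold].sum() / volumes.sum())


@dataclass
class ClusterResult:
    """Two-cluster assignment of subjects plus provenance.

    ``labels`` are canonical: cluster 1 is the high-strain cluster (greater
    centroid mass above the feature-space midpoint), cluster 2 the other.
    """

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    composition: dict = field(default_factory=dict)
    seed: int = 0
    n_restarts: int = 0
    degenerate: bool = False


def _lloyd(X: np.ndarray, init: np.ndarray, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    """Plain Lloyd iterations with Euclidean distance for k = 2.

    Converged when assignments stop changing; equidistant points go to the
    lower cluster index.  Empty clusters are re-seeded at the point farthest
    from the surviving centroid.
    """
    cent = init.copy()
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d = ((X[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d, axis=1)  # argmin takes the lower index on ties
        for k in range(2):
            if not np.any(new_labels == k):
                far = int(np.argmax(d[:, 1 - k]))
                cent[k] = X[far]
                new_labels[far] = k
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in range(2):
            cent[k] = X[labels == k].mean(axis=0)
    d = ((X[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d[np.arange(X.shape[0]), labels].sum())
    return labels, cent, inertia


def _kmeanspp_init(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    i0 = int(rng.integers(X.shape[0]))
    d2 = ((X - X[i0]) ** 2).sum(axis=1)
    if d2.sum() <= 0:
        i1 = int(rng.integers(X.shape[0]))
    else:
        i1 = int(rng.choice(X.shape[0], p=d2 / d2.sum()))
    return X[[i0, i1]].astype(float).copy()


def kmeans_two_clusters(
    features: np.ndarray,
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterResult:
    """Two-cluster k-means (Lloyd + k-means++ restarts) on subject histograms.

    Deterministic given ``seed``; best of ``n_restarts`` by within-cluster
    sum of squares.  Labels are canonicalised so that cluster 1 (label 0 in
    ``labels``+1 convention; stored as 1/2) is the cluster whose centroid
    carries more mass above the feature-space midpoint — for strain
    histograms, the higher-strain (progressor-like) cluster.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two equal-length feature vectors")
    rng = np.random.default_rng(seed)
    degenerate = bool(np.allclose(X, X[0]))
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        labels, cent, inertia = _lloyd(X, _kmeanspp_init(X, rng))
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, cent, inertia)
    labels, cent, inertia = best

    # canonical orientation: cluster 1 = centroid with more mass in the upper
    # half of the feature axis (high-strain bins)
    mid = X.shape[1] // 2
    upper_mass = cent[:, mid:].sum(axis=1)
    if upper_mass[1] > upper_mass[0]:
        labels = 1 - labels
        cent = cent[::-1]
    return ClusterResult(
        labels=labels + 1,
        centroids=cent,
        inertia=inertia,
        seed=seed,
        n_restarts=n_restarts,
        degenerate=degenerate,
    )


def composition_table(assignments: np.ndarray, groups: list[str] | np.ndarray) -> dict:
    """Per-group cluster composition and progressor error rates.

    Percentages are rounded to one decimal.  The progressor-dominated cluster
    is the one holding the larger share of progressors; the false-positive
    rate is the percentage of non-progressors and controls falling in it, the
    false-negative rate the percentage of progressors falling outside it.
    """
    assignments = np.asarray(assignments)
    groups = np.asarray(groups)
    if assignments.shape != groups.shape:
        raise ValueError("assignments and groups must have the same length")
    table: dict = {"per_group": {}}
    present = [g for g in ("P", "NP", "C") if np.any(groups == g)]
    for g in present:
        mask = groups == g
        n = int(mask.sum())
        in1 = int(np.sum(assignments[mask] == 1))
        table["per_group"][g] = {
            "n": n,
            "cluster1_pct": round(100.0 * in1 / n, 1),
            "cluster2_pct": round(100.0 * (n - in1) / n, 1),
        }
    if "P" in table["per_group"]:
        p1 = table["per_group"]["P"]["cluster1_pct"]
        dom = 1 if p1 >= 50.0 else 2
        others = np.isin(groups, ("NP", "C"))
        n_oth = int(others.sum())
        fp = float(np.sum(assignments[others] == dom)) / n_oth * 100.0 if n_oth else 0.0
        fn = table["per_group"]["P"]["cluster2_pct" if dom == 1 else "cluster1_pct"]
        table["progressor_cluster"] = dom
        table["false_positive_pct"] = round(fp, 1)
        table["false_negative_pct"] = round(fn, 1)
    return table
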