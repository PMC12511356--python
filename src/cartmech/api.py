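"""Model/Results interface over the cartilage-mechanics pipeline.

Two levels, in the style of statistical modelling packages:

* :class:`StanceModel` — one subject: a mesh, an FRPE material and a stance
  loading history.  ``fit()`` runs the poroelastic FE simulation and returns
  a :class:`StanceResults` carrying the field history, the strain biomarkers
  at the two load peaks and the stance maximum, histograms and contact
  summaries.
* :class:`CohortStudy` — a synthetic cohort.  ``fit()`` simulates every
  subject, builds the per-subject histograms, clusters them into
  progressor-like vs non-progressor-like groups and runs the nonparametric
  group comparisons, returning a :class:`CohortStudyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortConfig, LoadingHistory, SubjectMeta, generate_cohort
from .histograms import (
    DEGENERATION_THRESHOLDS,
    ClusterResult,
    composition_table,
    default_bin_edges,
    kmeans_two_clusters,
    threshold_exceedance_volume,
    volume_weighted_histogram,
)
from .material import FRPEParameters, MaterialModel
from .mesh import Mesh, build_slab_mesh, element_volumes
from .response import (
    EPOCHS,
    MEASURES,
    PeakPair,
    StrainTriple,
    cop_and_mean_pressure,
    detect_load_peaks,
    elementwise_max_over_stance,
    strain_triple_field,
)
from .solver import BoundarySpec, FieldHistory, NumericsConfig, run_stance_simulation
from .stats import GroupComparison, compare_groups

__all__ = ["StanceModel", "StanceResults", "CohortStudy", "CohortStudyResults", "default_mesh"]


def default_mesh(n_radial: int = 10, n_circum: int = 14, n_depth: int = 4) -> Mesh:
    """Generic medial-tibial cartilage slab at desk-scale resolution."""
    return build_slab_mesh(16.0, 11.0, 2.5, n_radial, n_circum, n_depth)


class StanceModel:
    """Single-subject stance-phase cartilage simulation.

    ``epochs`` selects which reporting epochs are needed; when only
    ``peak1`` is requested the simulation stops at the first load peak
    (the poroelastic response is history dependent, so frames beyond the
    last epoch of interest never influence it).
    """

    def __init__(
        self,
        mesh: Mesh,
        loading: LoadingHistory,
        params: FRPEParameters | None = None,
        bc: BoundarySpec | None = None,
        numerics: NumericsConfig | None = None,
        epochs: tuple = EPOCHS,
    ):
        self.mesh = mesh
        self.loading = loading
        self.params = params or FRPEParameters()
        self.bc = bc or BoundarySpec()
        self.numerics = numerics or NumericsConfig()
        self.epochs = tuple(epochs)

    def fit(self) -> "StanceResults":
        peaks = detect_load_peaks(self.loading.total_force_trace, self.loading.times)
        loading = self.loading
        if set(self.epochs) == {"peak1"}:
            k = peaks.frame1 + 1
            loading = LoadingHistory(
                times=self.loading.times[:k],
                pressure_frames=self.loading.pressure_frames[:k],
                total_force_trace=self.loading.total_force_trace[:k],
                provenance=self.loading.provenance,
            )
        fh = run_stance_simulation(self.mesh, self.params, loading, self.bc, self.numerics)
        return StanceResults(self, fh, peaks=peaks)


class StanceResults:
    """FE outputs and derived biomarkers for one subject."""

    def __init__(self, model: StanceModel, field_history: FieldHistory, peaks: PeakPair | None = None):
        self.model = model
        self.field_history = field_history
        self.volumes = element_volumes(model.mesh)
        self._material = MaterialModel.for_mesh(model.mesh, model.params)
        self.peaks: PeakPair = peaks or detect_load_peaks(
            model.loading.total_force_trace, model.loading.times
        )
        frames = [
            strain_triple_field(field_history.F_centroid[i], self._material.primary)
            for i in range(field_history.n_frames)
        ]
        self.strain_epochs: dict[str, StrainTriple] = {"peak1": frames[self.peaks.frame1]}
        if self.peaks.frame2 < field_history.n_frames:
            self.strain_epochs["peak2"] = frames[self.peaks.frame2]
            self.strain_epochs["stance_max"] = elementwise_max_over_stance(frames)

    def histogram(self, measure: str = "compressive", epoch: str = "peak1", edges=None):
        tri = self.strain_epochs[epoch]
        return volume_weighted_histogram(
            tri[measure], self.volumes, edges=edges, measure=measure, epoch=epoch
        )

    def exceedance(self, measure: str, threshold: float | None = None, epoch: str = "stance_max") -> float:
        """% of cartilage volume above a degeneration threshold."""
        thr = DEGENERATION_THRESHOLDS.get(measure, 0.0) if threshold is None else threshold
        return threshold_exceedance_volume(self.strain_epochs[epoch][measure], self.volumes, thr)

    def contact_summary(self, epoch: str = "peak1") -> dict:
        idx = self.peaks.frame1 if epoch == "peak1" else self.peaks.frame2
        return cop_and_mean_pressure(self.model.loading.pressure_frames[idx], self.model.mesh)

    def summary(self) -> str:
        lines = [
            "Stance-phase cartilage simulation",
            "=" * 46,
            f"elements: {self.model.mesh.n_elements}   frames: {self.field_history.n_frames}",
            f"load peaks at t = {self.peaks.time1:.3f} s, {self.peaks.time2:.3f} s",
        ]
        for epoch in EPOCHS:
            if epoch not in self.strain_epochs:
                continue
            tri = self.strain_epochs[epoch]
            lines.append(
                f"{epoch:>10}:  max compressive {tri.compressive.max():.3f}  "
                f"max fibril {tri.fibril.max():.3f}  max shear {tri.max_shear.max():.3f}"
            )
        if "stance_max" in self.strain_epochs:
            for m, thr in DEGENERATION_THRESHOLDS.items():
                lines.append(
                    f"volume with {m} strain > {thr}: {self.exceedance(m):.1f} % (stance max)"
                )
        c1 = self.contact_summary("peak1")
        if c1["cop_ap"] is not None:
            lines.append(
                f"peak-1 contact: COP ({c1['cop_ap']:.1f}, {c1['cop_ml']:.1f}) mm, "
                f"mean pressure {c1['mean_pressure']:.2f} MPa, force {c1['total_force']:.0f} N"
            )
        return "\n".join(lines)


@dataclass
class CohortStudyResults:
    """Cohort-level clustering and group-comparison results."""

    metas: list[SubjectMeta]
    subject_results: list[StanceResults]
    clusterings: dict = field(default_factory=dict)  # (measure, epoch) -> ClusterResult
    comparisons: list[GroupComparison] = field(default_factory=list)
    config: CohortConfig | None = None

    @property
    def groups(self) -> np.ndarray:
        return np.array([m.group for m in self.metas])

    def clustering(self, measure: str = "compressive", epoch: str = "peak1") -> ClusterResult:
        return self.clusterings[(measure, epoch)]

    def summary(self) -> str:
        lines = ["Cohort clustering of strain histograms", "=" * 52]
        counts = {g: int((self.groups == g).sum()) for g in ("P", "NP", "C")}
        lines.append(
            f"subjects: {counts['P']} progressors, {counts['NP']} non-progressors, "
            f"{counts['C']} controls"
        )
        for (measure, epoch), cr in sorted(self.clusterings.items()):
            comp = cr.composition
            if "per_group" not in comp or "P" not in comp["per_group"]:
                continue
            lines.append(
                f"{measure:>12} @ {epoch:<10} cluster 1: "
                f"{comp['per_group']['P']['cluster1_pct']:.1f}% of P, "
                f"{comp['per_group'].get('NP', {}).get('cluster1_pct', 0.0):.1f}% of NP   "
                f"(FP {comp['false_positive_pct']:.1f}%, FN {comp['false_negative_pct']:.1f}%)"
            )
        for gc in self.comparisons:
            flags = ", ".join(f"{k}:{v}" for k, v in gc.flags().items())
            lines.append(
                f"{gc.variable:>24} @ {gc.epoch:<10} KW p = {gc.p_omnibus:.4f}   [{flags}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Deterministic JSON-serialisable summary (no timestamps)."""
        out: dict = {"subjects": [], "clusterings": {}, "comparisons": []}
        for m, res in zip(self.metas, self.subject_results):
            out["subjects"].append(
                {
                    "subject_id": m.subject_id,
                    "group": m.group,
                    "kl_baseline": m.kl_baseline,
                    "peak1_max_compressive": float(res.strain_epochs["peak1"].compressive.max()),
                    **(
                        {
                            "fibril_exceedance_pct": res.exceedance("fibril"),
                            "shear_exceedance_pct": res.exceedance("max_shear"),
                        }
                        if "stance_max" in res.strain_epochs
                        else {}
                    ),
                }
            )
        for (measure, epoch), cr in sorted(self.clusterings.items()):
            out["clusterings"][f"{measure}@{epoch}"] = {
                "labels": cr.labels.tolist(),
                "composition": cr.composition,
                "inertia": round(cr.inertia, 12),
            }
        for gc in self.comparisons:
            out["comparisons"].append(
                {
                    "variable": gc.variable,
                    "epoch": gc.epoch,
                    "H": round(gc.H, 10),
                    "p": round(gc.p_omnibus, 10),
                    "pairwise": {k: [round(v[0], 10), round(v[1], 10)] for k, v in gc.pairwise.items()},
                }
            )
        return out


class CohortStudy:
    """End-to-end synthetic-cohort analysis.

    Generates the cohort loading, simulates each subject with the FE model,
    builds volume-weighted strain histograms, clusters subjects per
    (measure, epoch) and compares contact/loading summaries across groups.
    """

    def __init__(
        self,
        config: CohortConfig | None = None,
        mesh: Mesh | None = None,
        params: FRPEParameters | None = None,
        bc: BoundarySpec | None = None,
        numerics: NumericsConfig | None = None,
        cluster_measures: list[tuple[str, str]] | None = None,
        cluster_seed: int = 0,
        n_restarts: int = 25,
        epochs: tuple = EPOCHS,
    ):
        self.config = config or CohortConfig()
        self.mesh = mesh if mesh is not None else default_mesh()
        self.params = params or FRPEParameters()
        self.bc = bc or BoundarySpec()
        self.numerics = numerics or NumericsConfig()
        self.epochs = tuple(epochs)
        self.cluster_measures = cluster_measures or [
            (m, e) for m in MEASURES for e in self.epochs
        ]
        self.cluster_seed = cluster_seed
        self.n_restarts = n_restarts

    def fit(self, progress: bool = False) -> CohortStudyResults:
        subjects = generate_cohort(self.config, self.mesh)
        metas = [m for m, _ in subjects]
        results: list[StanceResults] = []
        for i, (meta, loading) in enumerate(subjects):
            model = StanceModel(
                self.mesh, loading, self.params, self.bc, self.numerics, epochs=self.epochs
            )
            results.append(model.fit())
            if progress:
                print(f"  [{i + 1}/{len(subjects)}] {meta.subject_id} simulated")

        out = CohortStudyResults(metas=metas, subject_results=results, config=self.config)
        groups = out.groups
        for measure, epoch in self.cluster_measures:
            feats = np.stack([r.histogram(measure, epoch).values for r in results])
            cr = kmeans_two_clusters(feats, seed=self.cluster_seed, n_restarts=self.n_restarts)
            cr.composition = composition_table(cr.labels, groups)
            out.clusterings[(measure, epoch)] = cr

        # group comparisons of contact/loading summaries at the two peaks
        for epoch in ("peak1", "peak2"):
            for var in ("mean_pressure", "cop_ap", "cop_ml", "total_force"):
                vals = {g: [] for g in ("P", "NP", "C")}
                for m, r in zip(metas, results):
                    v = r.contact_summary(epoch)[var]
                    if v is not None:
                        vals[m.group].append(v)
                out.comparisons.append(compare_groups(var, epoch, vals))
        if "stance_max" in self.epochs:
            for measure, thr in DEGENERATION_THRESHOLDS.items():
                vals = {g: [] for g in ("P", "NP", "C")}
                for m, r in zip(metas, results):
                    vals[m.group].append(r.exceedance(measure, thr))
                out.comparisons.append(
                    compare_groups(f"{measure}_exceedance", "stance_max", vals)
                )
        return out
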