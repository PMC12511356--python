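"""Synthetic stance-phase loading cohorts.

Stands in for the musculoskeletal-model stage: generates per-subject time
series of contact-pressure fields over the articular surface of the tibial
cartilage mesh during stance, with the group structure the downstream
analysis assumes —

* two-peak temporal loading (early- and late-stance force peaks),
* higher peak pressure in progressors (``P``) than non-progressors (``NP``)
  and controls (``C``),
* a posterior shift of the centre of pressure (COP) in progressors at the
  first peak and a lateral shift at the second peak,
* inter-subject variability in magnitude and COP location.

All numeric defaults here are synthetic design values chosen to reproduce
that qualitative pattern; they are not measured quantities.

Determinism: one master seed; each subject draws from an independent
substream derived from ``(master_seed, subject_id)`` by hashing, so adding or
removing subjects never reshuffles the loading of existing ones.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mesh import Mesh, SurfaceField, face_areas_centroids

__all__ = [
    "SubjectMeta",
    "LoadingHistory",
    "CohortConfig",
    "temporal_envelope",
    "spatial_pressure_blob",
    "generate_subject",
    "generate_cohort",
    "save_loading",
    "load_loading",
]

GROUPS = ("P", "NP", "C")


@dataclass
class SubjectMeta:
    """Subject identity and emulated clinical metadata.

    Controls carry Kellgren-Lawrence grade 0; OA subjects (progressors and
    non-progressors) grade >= 1 in the medial compartment at baseline.
    """

    subject_id: str
    group: str
    kl_baseline: int = 0
    bmi: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.group == "C" and self.kl_baseline != 0:
            raise ValueError("controls must have KL grade 0")
        if self.group in ("P", "NP") and self.kl_baseline < 1:
            raise ValueError("OA subjects must have KL grade >= 1")


@dataclass
class LoadingHistory:
    """Per-subject stance loading: pressure frames plus total-force trace."""

    times: np.ndarray
    pressure_frames: list[SurfaceField]
    total_force_trace: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total_force_trace = np.asarray(self.total_force_trace, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.pressure_frames) != len(self.times):
            raise ValueError("one pressure frame per time required")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class CohortConfig:
    """Generator parameters; defaults define the study conditions.

    Pressures in MPa, lengths in mm, times in s.  COP offsets are (AP, ML)
    displacements of the contact-patch centre relative to ``base_center``:
    negative AP = posterior, negative ML = lateral.
    """

    n_per_group: dict = field(default_factory=lambda: {"P": 9, "NP": 11, "C": 10})
    stance_duration: float = 0.65
    n_frames: int = 50
    peak1_time_frac: float = 0.25
    peak2_time_frac: float = 0.75
    valley_depth_frac: float = 0.4
    group_peak_pressure_mean: dict = field(
        default_factory=lambda: {"P": 3.9, "NP": 3.0, "C": 3.0}
    )
    group_peak_pressure_sd: float = 0.35
    blob_sd: float = 4.5
    base_center: tuple[float, float] = (1.0, 0.0)
    group_cop_offset_peak1: dict = field(
        default_factory=lambda: {"P": (-3.0, 0.0), "NP": (0.0, 0.0), "C": (0.0, 0.0)}
    )
    group_cop_offset_peak2: dict = field(
        default_factory=lambda: {"P": (0.0, -2.0), "NP": (0.0, 0.0), "C": (0.0, 0.0)}
    )
    cop_jitter_sd: float = 1.0
    noise_sd: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.peak1_time_frac < self.peak2_time_frac < 1:
            raise ValueError("peak fractions must satisfy 0 < t1 < t2 < 1")
        if self.group_peak_pressure_sd < 0 or self.noise_sd < 0 or self.cop_jitter_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.blob_sd <= 0:
            raise ValueError("blob spatial sd must be positive")
        if not 0 <= self.valley_depth_frac < 1:
            raise ValueError("valley depth fraction must lie in [0, 1)")
        if any(v < 0 for v in self.group_peak_pressure_mean.values()):
            raise ValueError("group mean pressures must be non-negative")

    def equalized(self) -> "CohortConfig":
        """Copy with all group effects removed (null configuration)."""
        import copy

        cfg = copy.deepcopy(self)
        base_p = cfg.group_peak_pressure_mean["C"]
        cfg.group_peak_pressure_mean = {g: base_p for g in GROUPS}
        cfg.group_cop_offset_peak1 = {g: (0.0, 0.0) for g in GROUPS}
        cfg.group_cop_offset_peak2 = {g: (0.0, 0.0) for g in GROUPS}
        return cfg


def temporal_envelope(t_frac: np.ndarray | float, cfg: CohortConfig) -> np.ndarray | float:
    """Two-peak stance envelope in [0, 1].

    Four half-Hann (raised-cosine) segments joined with zero slope: rises
    0 -> 1 to the first peak, dips to ``1 - valley_depth_frac`` midway between
    the peaks, rises back to 1 at the second peak, and falls to 0 at toe-off.
    C1-smooth; exact unit maxima at the configured peak fractions.
    """
    t = np.asarray(t_frac, dtype=float)
    t1, t2 = cfg.peak1_time_frac, cfg.peak2_time_frac
    tm = 0.5 * (t1 + t2)
    v = 1.0 - cfg.valley_depth_frac
    out = np.zeros_like(t)

    seg = (t >= 0) & (t <= t1)
    out[seg] = np.sin(0.5 * np.pi * t[seg] / t1) ** 2
    seg = (t > t1) & (t <= tm)
    out[seg] = v + (1 - v) * np.cos(0.5 * np.pi * (t[seg] - t1) / (tm - t1)) ** 2
    seg = (t > tm) & (t <= t2)
    out[seg] = v + (1 - v) * np.sin(0.5 * np.pi * (t[seg] - tm) / (t2 - tm)) ** 2
    seg = (t > t2) & (t <= 1)
    out[seg] = np.cos(0.5 * np.pi * (t[seg] - t2) / (1 - t2)) ** 2
    return out if out.ndim else float(out)


def spatial_pressure_blob(
    center: tuple[float, float],
    sd: float,
    peak_pressure: float,
    mesh: Mesh,
    frame_time: float = 0.0,
) -> SurfaceField:
    """Gaussian contact patch on the articular surface, truncated at 3 sd.

    Pressure at each articular face is evaluated at the face centroid:
    ``p = peak * exp(-||c - center||^2 / (2 sd^2))`` using in-plane (x, y)
    distance, zero beyond 3 sd.
    """
    if sd <= 0:
        raise ValueError("blob sd must be positive")
    face_ids = mesh.articular_faces()
    _, cents = face_areas_centroids(mesh, face_ids)
    d2 = (cents[:, 0] - center[0]) ** 2 + (cents[:, 1] - center[1]) ** 2
    vals = peak_pressure * np.exp(-d2 / (2.0 * sd * sd))
    vals[d2 > (3.0 * sd) ** 2] = 0.0
    return SurfaceField(face_ids=face_ids, values=vals, frame_time=frame_time)


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable 31-bit substream seed from (master seed, subject id)."""
    digest = hashlib.sha256(f"{master_seed}:{subject_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _cop_path(t_frac: np.ndarray, c1: np.ndarray, c2: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """COP trajectory: holds c1 up to peak 1, smooth-steps to c2 by peak 2."""
    t1, t2 = cfg.peak1_time_frac, cfg.peak2_time_frac
    s = np.clip((t_frac - t1) / (t2 - t1), 0.0, 1.0)
    w = s * s * (3.0 - 2.0 * s)
    return c1[None, :] + w[:, None] * (c2 - c1)[None, :]


def generate_subject(meta: SubjectMeta, cfg: CohortConfig, mesh: Mesh) -> LoadingHistory:
    """Deterministic stance loading history for one subject.

    The subject's peak pressure is drawn from its group distribution, the
    per-peak COP from the group offsets plus jitter; every frame's field is a
    truncated Gaussian patch scaled by the temporal envelope and a small
    per-frame multiplicative noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.master_seed, meta.seed)))
    g = meta.group
    peak_p = cfg.group_peak_pressure_mean[g]
    if cfg.group_peak_pressure_sd > 0:
        peak_p = peak_p + cfg.group_peak_pressure_sd * rng.standard_normal()
    peak_p = max(peak_p, 0.05)

    base = np.asarray(cfg.base_center, dtype=float)
    c1 = base + np.asarray(cfg.group_cop_offset_peak1[g], dtype=float)
    c2 = base + np.asarray(cfg.group_cop_offset_peak2[g], dtype=float)
    if cfg.cop_jitter_sd > 0:
        c1 = c1 + cfg.cop_jitter_sd * rng.standard_normal(2)
        c2 = c2 + cfg.cop_jitter_sd * rng.standard_normal(2)

    t_frac = np.linspace(0.0, 1.0, cfg.n_frames)
    times = t_frac * cfg.stance_duration
    env = np.asarray(temporal_envelope(t_frac, cfg))
    centers = _cop_path(t_frac, c1, c2, cfg)
    frame_noise = (
        1.0 + cfg.noise_sd * rng.standard_normal(cfg.n_frames) if cfg.noise_sd > 0 else np.ones(cfg.n_frames)
    )

    face_ids = mesh.articular_faces()
    areas, _ = face_areas_centroids(mesh, face_ids)
    frames: list[SurfaceField] = []
    force = np.empty(cfg.n_frames)
    truncated_warning = False
    for i, (tf, t) in enumerate(zip(t_frac, times)):
        amp = peak_p * env[i] * max(frame_noise[i], 0.0)
        fld = spatial_pressure_blob(tuple(centers[i]), cfg.blob_sd, amp, mesh, frame_time=t)
        frames.append(fld)
        force[i] = float(np.dot(fld.values, areas))
        if amp > 0:
            # mass retained on the articular surface vs the full (untruncated) blob
            full_mass = amp * 2.0 * np.pi * cfg.blob_sd**2
            if force[i] < 0.5 * full_mass:
                truncated_warning = True

    prov = {
        "subject_id": meta.subject_id,
        "group": g,
        "seed": meta.seed,
        "master_seed": cfg.master_seed,
        "peak_pressure": peak_p,
        "cop_peak1": c1.tolist(),
        "cop_peak2": c2.tolist(),
        "blob_truncation_warning": truncated_warning,
    }
    return LoadingHistory(times=times, pressure_frames=frames, total_force_trace=force, provenance=prov)


def generate_cohort(
    cfg: CohortConfig,
    mesh: Mesh,
    n_P: int | None = None,
    n_NP: int | None = None,
    n_C: int | None = None,
    out_dir: str | Path | None = None,
) -> list[tuple[SubjectMeta, LoadingHistory]]:
    """Generate a full cohort; optionally persist loading files and a manifest.

    Default cohort composition is 9 progressors, 11 non-progressors and 10
    controls.  Subject seeds derive from the master seed by hashing the
    subject id, so the per-subject loading is stable under changes to cohort
    composition.
    """
    counts = {
        "P": cfg.n_per_group["P"] if n_P is None else n_P,
        "NP": cfg.n_per_group["NP"] if n_NP is None else n_NP,
        "C": cfg.n_per_group["C"] if n_C is None else n_C,
    }
    if min(counts.values()) < 0:
        raise ValueError("subject counts must be non-negative")

    kl_rng = np.random.default_rng(np.random.SeedSequence((cfg.master_seed, 0xC0F0)))
    subjects: list[tuple[SubjectMeta, LoadingHistory]] = []
    for g in GROUPS:
        for i in range(counts[g]):
            sid = f"{g}{i + 1:02d}"
            kl = 0 if g == "C" else int(kl_rng.integers(1, 4))
            bmi = float(np.round(25.0 + 3.0 * kl_rng.standard_normal(), 2))
            meta = SubjectMeta(
                subject_id=sid, group=g, kl_baseline=kl, bmi=bmi, seed=subject_seed(cfg.master_seed, sid)
            )
            subjects.append((meta, generate_subject(meta, cfg, mesh)))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "group", "kl_baseline", "bmi", "seed", "loading_file"])
            for meta, hist in subjects:
                fn = f"{meta.subject_id}_loading.h5"
                save_loading(hist, out_dir / fn)
                w.writerow([meta.subject_id, meta.group, meta.kl_baseline, meta.bmi, meta.seed, fn])
        cfg_dict = asdict(cfg)
        (out_dir / "cohort_config.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True))
    return subjects


def save_loading(hist: LoadingHistory, path: str | Path) -> None:
    """Persist a LoadingHistory to HDF5 (times, face ids, pressure matrix)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "cartmech-loading-v1"
        f.create_dataset("times", data=hist.times)
        f.create_dataset("face_ids", data=hist.pressure_frames[0].face_ids)
        f.create_dataset(
            "pressures", data=np.stack([fr.values for fr in hist.pressure_frames])
        )
        f.create_dataset("total_force", data=hist.total_force_trace)
        f.attrs["provenance"] = json.dumps(hist.provenance, sort_keys=True)


def load_loading(path: str | Path) -> LoadingHistory:
    import h5py

    with h5py.File(path, "r") as f:
        times = f["times"][...]
        face_ids = f["face_ids"][...]
        press = f["pressures"][...]
        force = f["total_force"][...]
        prov = json.loads(f.attrs.get("provenance", "{}"))
    frames = [
        SurfaceField(face_ids=face_ids, values=press[i], frame_time=float(times[i]))
        for i in range(len(times))
    ]
    return LoadingHistory(times=times, pressure_frames=frames, total_force_trace=force, provenance=prov)
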