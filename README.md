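# cartmech

Stance-phase cartilage mechanics biomarkers for knee-osteoarthritis
progression, at desk scale.

During walking, the medial tibial cartilage of patients with progressing
knee OA sees higher contact pressures and a posterolaterally shifted centre
of pressure than that of non-progressors and controls.  Contact pressure
alone, however, discriminates the groups poorly; *tissue-level* mechanical
responses — computed by a fibril-reinforced poroelastic (FRPE) finite-element
model of the cartilage — separate them much better.  `cartmech` implements
that pipeline end to end for researchers in computational biomechanics:

1. **Synthetic cohort generator** — per-subject stance-phase contact-pressure
   histories on a generic elliptic cartilage slab, with group effects in
   pressure magnitude and COP location standing in for a musculoskeletal
   simulation stage (no clinical data required).
2. **FRPE finite-element solver** — mixed displacement/pore-pressure (u–p)
   quasi-static solver on hexahedral meshes: tension-only strain-stiffening
   collagen fibrils (arcade architecture), neo-Hookean matrix, Darcy flow
   with deformation-dependent permeability
   `k = k0 ((1+e)/(1+e0))^M`, total-Lagrangian finite strain, follower
   pressure loads, contact-dependent drainage.
3. **Biomarker extraction** — per-element compressive strain |ε₃|, fibril
   strain ln‖F a₀‖ (clamped at 0), and maximum shear strain (ε₁−ε₃)/2 from
   Hencky principal strains, at the two stance load peaks and the stance
   maximum; COP, mean pressure and contact area per peak; the % of tissue
   volume above the degeneration thresholds (fibril strain 0.1, maximum
   shear strain 0.4).
4. **Histograms + clustering + statistics** — strain histograms as % of
   cartilage volume, two-cluster k-means on the subject histograms
   (progressor-like vs non-progressor-like), Kruskal–Wallis and pairwise
   Mann–Whitney U group comparisons.

See `docs/methods.md` for the model equations, parameter table, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from cartmech import CohortConfig, StanceModel, build_slab_mesh
from cartmech.cohort import SubjectMeta, generate_subject, subject_seed

mesh = build_slab_mesh(a=16, b=11, thickness=2.5,
                       n_radial=8, n_circum=12, n_depth=5)   # 480 hexes
cfg = CohortConfig(n_frames=20, master_seed=1)
meta = SubjectMeta("P01", "P", kl_baseline=1, seed=subject_seed(1, "P01"))
loading = generate_subject(meta, cfg, mesh)

res = StanceModel(mesh, loading).fit()
print(res.summary())
```

```
Stance-phase cartilage simulation
==============================================
elements: 480   frames: 20
load peaks at t = 0.171 s, 0.513 s
     peak1:  max compressive 0.369  max fibril 0.162  max shear 0.297
     peak2:  max compressive 0.350  max fibril 0.156  max shear 0.303
stance_max:  max compressive 0.369  max fibril 0.162  max shear 0.303
volume with fibril strain > 0.1: 3.7 % (stance max)
volume with max_shear strain > 0.4: 0.0 % (stance max)
peak-1 contact: COP (-2.6, -0.5) mm, mean pressure 0.88 MPa, force 429 N
```

This progressor subject peaks at ~0.37 compressive strain under the contact
patch, and 3.7% of the cartilage volume exceeds the collagen-degradation
threshold (fibril strain 0.1) at some point during stance.  A whole-cohort
analysis — 9 progressors, 11 non-progressors, 10 controls — clusters the
first-peak compressive-strain histograms into a progressor-dominated and a
control-like group:

```python
from cartmech import CohortStudy
study = CohortStudy(cfg, mesh=mesh, epochs=("peak1",),
                    cluster_measures=[("compressive", "peak1")]).fit()
print(study.clustering("compressive", "peak1").composition)
```

```
{'per_group': {'P':  {'n': 9,  'cluster1_pct': 100.0, 'cluster2_pct': 0.0},
               'NP': {'n': 11, 'cluster1_pct': 27.3,  'cluster2_pct': 72.7},
               'C':  {'n': 10, 'cluster1_pct': 30.0,  'cluster2_pct': 70.0}},
 'progressor_cluster': 1, 'false_positive_pct': 28.6, 'false_negative_pct': 0.0}
```

With the default planted group effects, every progressor lands in the
high-strain cluster; depending on the master seed, roughly 5-30% of the
other subjects fall in with them as false positives.

The same analysis is available as a config-driven pipeline and CLI:

```bash
cartmech pipeline run examples/pipeline_config.yaml
cartmech benchmark terzaghi          # solver consolidation oracle
cartmech cohort generate out/ --n-p 9 --n-np 11 --n-c 10
```

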