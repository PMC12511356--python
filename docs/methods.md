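# Methods

`cartmech` turns per-subject stance-phase contact-pressure histories on the
medial tibial cartilage into tissue-level strain biomarkers and an
unsupervised two-group classification.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not emulate.

## Constitutive model

Cartilage is modelled as a fibril-reinforced poroelastic (FRPE) mixture:

* **Non-fibrillar matrix** (proteoglycan gel): compressible neo-Hookean
  solid with Lamé constants derived from `(Enf, nu_nf)`.  Cauchy stress
  `sigma_nf = (mu (B - I) + lam ln J I) / J`.  The neo-Hookean form was
  chosen because its small-strain limit is exactly the isotropic law with
  `(Enf, nu_nf)`, which makes the linear verification limits closed-form.
* **Collagen fibril network**: tension-only, strain-stiffening one-dimensional
  law per fibril family, `sigma_f = E0 eps_f + Eeps eps_f^2` for `eps_f > 0`
  and zero otherwise, with fibril strain the logarithmic strain of the fibre
  stretch, `eps_f = ln ||F a0||` (the convention of the commercial-FE
  workflows this model family is normally run in).  One *primary* family per
  element follows a Benninghoff arcade: parallel to the depth axis in the
  deep zone (`z/h < 0.5`), parallel to the articular surface in the
  superficial zone (`z/h > 0.8`), rotating linearly between; the in-plane
  arcade direction points radially outward from the slab centre (a
  split-line surrogate).  A *secondary* isotropic network is represented by
  six fixed icosahedral axes.  Family weights are `C/(C + 6)` for the
  primary and `1/(C + 6)` per secondary axis, with density ratio `C`.
* **Fluid phase**: incompressible interstitial fluid with Darcy flow;
  deformation-dependent permeability `k = k0 ((1+e)/(1+e0))^M`, which with
  `e = J(1+e0) - 1` reduces to `k0 J^M`.  Volume ratios at or below the
  solid-phase incompressibility floor `J <= 1 - n_f0` are rejected by the
  solver as inadmissible.

Default constants are a literature-typical set for non-degenerated human
knee cartilage identified from unconfined-compression experiments:

| parameter | value | units | meaning |
|---|---|---|---|
| `E0`   | 0.92  | MPa | initial fibril-network modulus |
| `Eeps` | 150   | MPa | strain-dependent fibril-network modulus |
| `Enf`  | 0.215 | MPa | non-fibrillar matrix modulus |
| `nu_nf`| 0.15  | –   | non-fibrillar Poisson ratio |
| `k0`   | 1.9e-3| mm⁴/(N·s) | initial permeability |
| `M`    | 1.2   | –   | permeability exponent |
| `n_f0` | 0.8   | –   | initial fluid fraction |
| `C`    | 3.009 | –   | primary:secondary fibril density ratio |

A soft linear set (`LINEAR_TEST_SET`: fibrils off, `Enf = 0.5`, `nu = 0`) is
built in for verification problems with closed-form solutions.

## Finite-element formulation

Mixed displacement–pore-pressure (u–p) weak form on 8-node hexahedra with
equal-order trilinear interpolation for both fields (C3D8P-style),
total-Lagrangian finite strain, backward-Euler time integration:

* momentum: `∫ P(F, p) : Grad(δu) dV0 = follower-pressure virtual work`,
  with first Piola total stress `P = J (sigma_eff − p I) F⁻ᵀ`;
* mass balance: `∫ δp (J − Jₙ)/Δt dV0 + ∫ Grad(δp)·K Grad(p) dV0 = 0`,
  with pulled-back conductivity `K = J F⁻¹ k(J) F⁻ᵀ`.

Applied contact pressure acts as a follower traction on the deformed
articular faces (2×2 quadrature per face; analytic load stiffness).  The
bone-side surface is fully fixed.  Drainage: Dirichlet `p = 0` on
free-draining nodes, natural (no-flux) on sealed ones.  The articular
surface is *contact-dependent* by default — faces carrying applied pressure
above 0.01 MPa are sealed, the rest of the articular surface drains — and a
node covered by any loaded face is sealed even if a draining set also
touches it.  The rim and bone are sealed by default: the modelled
compartment continues into surrounding tissue, and pinning `p = 0` on rim
nodes would make edge elements under the tail of the contact patch
effectively drained, letting a ~0.2 MPa matrix carry multi-MPa load and
collapsing them onto the fluid-lockout floor.  All drainage conditions are
config-exposed.

Nonlinear solution: Newton's method with an analytic consistent tangent
(closed-form derivatives of the neo-Hookean, fibril, pressure and transport
terms).  A central-difference tangent is retained as a verification path
(`NumericsConfig(tangent="fd")` and the public `material_tangent`); the test
suite asserts the two agree and that the assembled Jacobian matches a
brute-force differentiation of the residual.  Robustness machinery:

* quasi-Newton reuse of the factorised Jacobian across iterations and
  frames (refreshed on slow contraction, drainage-pattern change, or a
  >1.5× time-step change);
* linear extrapolation predictor from the two previous frames;
* backtracking of the Newton update when a full step would cross the
  admissibility floor;
* automatic time-step halving (up to 5 levels) with linearly interpolated
  load substeps, then a structured error with the iteration history.

Convergence: residual norm below `max(tol_abs·scale, tol_rel·‖r0‖)` with
`tol_rel = 1e-6` by default.  Linear solves use sparse LU (COLAMD).

A small-strain switch linearises kinematics, storage (`tr ε`) and
permeability (constant `k0`) and applies loads on the reference geometry;
it recovers linear Biot poroelasticity exactly and is used for the
Terzaghi benchmark.

**Inf-sup caveat.** Equal-order u–p interpolation does not satisfy the
discrete inf-sup condition; near the undrained (incompressible) limit the
pore-pressure field can show node-to-node oscillations.  No stabilisation
is applied at desk scale; the Terzaghi benchmark bounds the practical
consequences (pore-pressure error < 2% of the applied load at the sampled
times), and the reported biomarkers derive from the deformation gradient,
which is less sensitive than the raw pressure field.

## Verification oracles

* **Terzaghi consolidation**: 1×1×20-element column, lateral motion
  suppressed, free-draining top, ramp-hold load; compared with the exact
  series solution, with the load ramp superposed analytically term by term.
  Time steps grow geometrically (ratio 1.12 after a 6-step ramp), chosen so
  the backward-Euler error stays well inside the 2% band.
* **Drained limit**: a long hold (4 consolidation times) must land on the
  static drained solve (all-draining, storage-free) within 0.5% displacement
  RMS.
* **Constitutive/strain closed forms**: small-strain isotropic limit,
  energy-gradient consistency, tension-only switch, permeability scalar
  law, Hencky-strain closed forms for uniaxial/shear/hydrostatic states.

## Response extraction

All biomarkers are evaluated from the deformation gradient at the element
centroid (one sampling point per element), using logarithmic (Hencky)
principal strains:

* compressive strain `|ε3|` (absolute minimum principal strain);
* maximum shear strain `(ε1 − ε3)/2` — the classical maximum shear of the
  strain state; chosen because no alternative formula is standard for this
  biomarker;
* fibril strain: log fibre stretch along the *primary* family only, clamped
  at zero (a degradation driver cannot be negative); secondary fibrils
  contribute to stress but not to the reported biomarker.

Epochs: the first and second peaks of the total tibiofemoral load trace
(largest local maximum in each half of stance, optional moving-average
smoothing) and the per-element maximum over the whole stance.  Because the
poroelastic response is history-dependent but causal, an analysis that needs
only first-peak quantities simulates frames up to the first peak only.

Contact summaries per peak: centre of pressure (pressure-weighted centroid
over loaded faces, AP/ML coordinates), mean pressure over the contacting
area (faces with `p >` 0.01 MPa), total force, contact area.

Degeneration thresholds applied post hoc: collagen-damage onset at fibril
strain 0.1 and proteoglycan-depletion onset at maximum shear strain 0.4
(0.5 in some protocols); the package reports the % of cartilage volume
exceeding each.

## Synthetic cohort

The generator stands in for the musculoskeletal stage and encodes the
statistical structure the downstream analysis is meant to detect:

* two-peak stance envelope (four half-Hann segments joined with zero slope;
  exact unit maxima at 25% and 75% of stance, valley 0.6);
* truncated-Gaussian contact patch (sd 4.5 mm, cut at 3 sd) whose centre
  smooth-steps from the first-peak COP to the second-peak COP;
* group effects: progressor mean peak pressure 3.9 MPa vs 3.0 MPa for
  non-progressors/controls (between-subject sd 0.35 MPa); progressors get a
  −3 mm AP (posterior) first-peak COP offset and a −2 mm ML (lateral)
  second-peak offset; COP jitter sd 1 mm; 5% multiplicative frame noise.
* stance duration 0.65 s, 50 frames by default (20 at reduced scale).

These magnitudes are **synthetic design values** chosen to reproduce the
qualitative progressor pattern (higher pressures, posterolateral COP shift)
at a separation detectable in a 30-subject cohort; they are not measured
quantities.  Cohort sizes default to 9 progressors / 11 non-progressors /
10 controls.  Randomness: one master seed; per-subject substreams hash
`(master_seed, subject_id)` so changing cohort composition never reshuffles
existing subjects.

What the generator does **not** emulate: muscle-force dynamics and
force-dependent kinematics, realistic contact-patch shapes (elastic
foundation contact produces non-Gaussian patches), load asymmetries between
compartments, gait-speed variability, within-group KL-grade structure, or
measurement noise in motion capture.  A passing planted-effect test shows
the pipeline recovers group structure *of the kind and size planted*; it
says nothing about effect sizes in real cohorts.

## Histograms, clustering, statistics

* Volume-weighted histograms: bin value = % of total cartilage volume in
  the bin; half-open bins, last bin closed; out-of-range mass is clipped
  into the end bins so mass is always conserved.  Default edges: 0–0.5 in
  0.01 steps (compressive, shear), 0–0.3 in 0.006 steps (fibril), pressure
  0–10 MPa in 0.25 MPa steps.  Bin ranges are a design choice; all edges
  configurable.
* Clustering: plain two-cluster Lloyd k-means with Euclidean distance on
  the histogram vectors (a fixed-length histogram makes "time-series"
  k-means mathematically plain k-means), k-means++ seeding, 25 restarts,
  best by within-cluster sum of squares, deterministic given the seed.
  Ties go to the lower cluster index; empty clusters are re-seeded at the
  farthest point.  Labels are canonical: cluster 1 is the centroid with
  more mass in the upper half of the feature axis — the high-strain,
  progressor-like cluster.  One clustering per (measure, epoch) pair by
  default, mirroring separate histogram panels; concatenation is possible
  by stacking features manually.
* Statistics: Kruskal–Wallis omnibus plus all three pairwise Mann–Whitney U
  contrasts (two-sided; exact enumeration for n ≤ 8 without ties, otherwise
  tie-corrected normal approximation), flags at 0.05 and 0.1, no
  multiple-testing correction (reported as-is).

## Problem sizes and determinism

Desk-scale defaults: 480-element slab mesh (8×12×5; a=16 mm, b=11 mm,
thickness 2.5 mm), 20–50 frames per stance.  The discretisation is
configurable up to the ~21k-element scale used in subject-specific studies;
the acceptance analyses and tests run at the reduced scale, where a full
stance solve takes seconds and a 30-subject cohort minutes.  The cohort
acceptance checks cluster first-peak compressive-strain histograms and
therefore simulate stance up to the first peak.  Every pipeline output is a
pure function of the config and master seed; summaries contain no
timestamps, and re-runs are byte-identical (per-subject FE results are
cached by config hash, so interrupted runs resume).

## Known limitations

* No contact resolution: pressures are applied, not computed — consistent
  with the decoupled FE stage being emulated.
* Equal-order elements without stabilisation (see inf-sup caveat above).
* One integration point per element for reporting understates intra-element
  strain gradients on coarse meshes.
* No fibril viscoelasticity, osmotic swelling, depth-dependent matrix
  moduli, or damage evolution; degeneration thresholds are applied post hoc.
* The elliptic slab is a generic geometry; subject-specific anatomy, menisci
  and the lateral compartment are out of scope.
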