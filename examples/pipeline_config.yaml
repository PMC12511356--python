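# Example cartmech pipeline configuration (desk scale).
# Units: mm, MPa, N, s; permeability mm^4/(N s).

mesh:
  a: 16.0              # AP semi-axis of the elliptic planform
  b: 11.0              # ML semi-axis
  thickness: 2.5       # slab thickness at the centre
  n_radial: 8
  n_circum: 12
  n_depth: 5           # 8*12*5 = 480 hexahedra
  thickness_profile: constant   # or center_thick

material:              # fibril-reinforced poroelastic constants
  E0: 0.92             # initial fibril-network modulus, MPa
  Eeps: 150.0          # strain-dependent fibril-network modulus, MPa
  Enf: 0.215           # non-fibrillar matrix modulus, MPa
  nu_nf: 0.15          # non-fibrillar Poisson ratio
  k0: 1.9e-3           # initial permeability, mm^4/(N s)
  M: 1.2               # permeability exponent
  fluid_fraction: 0.8  # initial fluid volume fraction
  C: 3.009             # primary:secondary fibril density ratio
  fibril_architecture: arcade

cohort:
  n_per_group: {P: 9, NP: 11, C: 10}
  stance_duration: 0.65     # s
  n_frames: 20
  peak1_time_frac: 0.25
  peak2_time_frac: 0.75
  valley_depth_frac: 0.4
  group_peak_pressure_mean: {P: 3.9, NP: 3.0, C: 3.0}   # MPa
  group_peak_pressure_sd: 0.35
  blob_sd: 4.5              # mm, spatial extent of the contact patch
  base_center: [1.0, 0.0]   # (AP, ML) mm
  group_cop_offset_peak1: {P: [-3.0, 0.0], NP: [0.0, 0.0], C: [0.0, 0.0]}
  group_cop_offset_peak2: {P: [0.0, -2.0], NP: [0.0, 0.0], C: [0.0, 0.0]}
  cop_jitter_sd: 1.0        # mm
  noise_sd: 0.05
  master_seed: 1

numerics:
  tol_rel: 1.0e-6
  tol_abs: 1.0e-9
  max_newton: 25
  max_cuts: 5
  tangent: analytic         # or fd (central-difference verification path)
  cache: true               # reuse per-subject FE results on re-runs

clustering:
  seed: 0
  n_restarts: 25
  measures:
    - [compressive, peak1]
    - [max_shear, peak1]
    - [fibril, peak1]
    - [fibril, stance_max]

output_dir: cartmech_results
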