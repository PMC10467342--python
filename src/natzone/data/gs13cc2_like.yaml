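# GS13-CC2-like reference scenario.
#
# A synthetic stand-in for an Arctic Mid-Ocean Ridge sediment column with a
# nitrate-ammonium transition zone near 2.3 m below the seafloor: O2 is
# depleted within decimeters, NO3- penetrates to ~2.5 m, NH4+ rises from a
# deep source below ~2 m, and the modeled anammox rate peaks inside the
# transition zone. Values are identical to the package defaults; this file
# exists so the scenario is explicit, citable and editable.
grid:
  extent_m: 4.0
  n_cells: 400
  spacing: uniform
  ratio: 1.0
porosity:
  phi0: 0.8
  phi_inf: null
  lam_m: null
transport:
  D0:
    O2: 0.0365
    NO3: 0.0345
    NH4: 0.035
  w: 5.0e-05
kinetics:
  R0: 2460.0
  z_att: 0.05
  r_NC: 0.1509433962264151
  k_nit: 500.0
  k_amx: 0.02
  K_O2: 1.0
  K_O2nit: 2.0
  K_NO3: 1.0
  Ki_O2: 2.0
boundaries:
  top:
    O2: 300.0
    NO3: 15.0
    NH4: 0.0
  bottom:
    O2:
      kind: neumann
      value: null
    NO3:
      kind: neumann
      value: null
    NH4:
      kind: dirichlet
      value: 55.0
solver:
  tol: 1.0e-10
  max_newton: 80
  max_halvings: 30
  max_ptc_steps: 400
  ptc_dt0: 0.001
  max_outer: 8
nat:
  eps_no3: 1.0
  eps_nh4: 1.0
fit:
  free:
  - k_amx
  bounds:
    k_amx:
    - 0.001
    - 5.0
  start:
    k_amx: 0.06
  seed: 0
  n_restarts: 3
  maxfev: null
synthetic:
  seed: 0
  sampling:
    start: 0.05
    stop: 3.95
    num: 40
  noise_sd:
    O2: 3.0
    NO3: 0.3
    NH4: 0.3
  community:
    seed: 0
    reads_per_sample: 20000
    taxa:
    - name: Ca_Bathyanammoxibiaceae
      amplitude: 0.074
      center: 2.3
      width: 0.25
      background: 0.0
    - name: Ca_Scalinduaceae
      amplitude: 0.003
      center: 2.3
      width: 0.3
      background: 0.0
    - name: Ca_Subterrananammoxibiaceae
      amplitude: 0.006
      center: 2.3
      width: 0.2
      background: 0.0
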