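# natzone

Steady-state porewater nitrogen-cycle modelling and nitrate-ammonium
transition-zone niche mapping for marine sediments.

## The problem

In organic-poor deep-sea sediments, nitrate diffusing down from the bottom
water meets ammonium diffusing up from deeper mineralization. The interval
where the two fronts meet — the **nitrate-ammonium transition zone (NAT
zone)** — is the habitat of anammox bacteria, which gain energy by
combining ammonium with a nitrate/nitrite-derived oxidant to form N2 gas.
Mapping where a candidate anammox clade sits relative to this zone is a
standard line of ecological evidence for its metabolism: a taxon whose
depth distribution is confined to the zone where the anammox reaction runs
is behaving like an anammox organism.

`natzone` packages that whole argument as a reproducible pipeline:

1. a **1-D steady-state reaction-transport model** of porewater O2, NO3−
   and NH4+ with aerobic mineralization, denitrification, nitrification and
   an explicit anammox pathway (lumped on nitrate,
   5 NH4+ + 3 NO3− → 4 N2);
2. **NAT-zone detection** from measured or modeled profiles (nitrate
   penetration depth to ammonium appearance depth, at configurable
   detection thresholds, 1 µM by default);
3. a **niche-confinement statistic**: the fraction of a taxon's summed
   relative abundance that falls at depths inside the zone, with a
   permutation p-value (exact enumeration up to 7 sampled depths, seeded
   Monte Carlo beyond);
4. **calibration** of kinetic/transport parameters to observed profiles by
   weighted least squares over forward model runs; and
5. a **synthetic-data generator** (noisy porewater profiles, multinomial
   16S-style family tables with Gaussian depth niches), so every stage is
   testable without any field data.

## The model

On 0 ≤ z ≤ L (meters below seafloor, positive down), each solute obeys

    d/dz [ −φ Ds dC/dz + φ w C ] = φ S(C),   Ds = D0 / (1 − ln φ²)

with porosity φ, Boudreau tortuosity correction, burial velocity w, and net
volumetric sources S from the reaction network:

| reaction | rate law | stoichiometry |
|---|---|---|
| aerobic mineralization | R_C(z)·O2/(O2+K_O2) | 1 O2 : 1 C, releases r_NC NH4+ |
| denitrification | R_C(z)·(1−monod)·NO3/(NO3+K_NO3)·Ki/(Ki+O2) | 0.8 NO3− : 1 C |
| nitrification | k_nit·NH4·O2/(O2+K_O2nit) | 2 O2 : 1 NH4+ → 1 NO3− |
| anammox | k_amx·NH4·NO3·Ki/(Ki+O2) | 0.6 NO3− : 1 NH4+ → 1.6 N2-N |

with R_C(z) = R0·exp(−z/z_att) a prescribed organic-carbon mineralization
profile. Discretization is finite-volume with exponential-fitting
(Scharfetter–Gummel) interface fluxes; the nonlinear steady state is found
by damped Newton iteration with a banded finite-difference Jacobian and a
pseudo-transient fallback. See `docs/methods.md` for assumptions,
parameter meanings and numerical details.

## Worked example

The packaged reference configuration (`natzone.reference_config_path()`)
describes a 4 m column resembling an Arctic Mid-Ocean Ridge sediment core:
oxygenated bottom water (300 µM O2, 15 µM NO3−), a deep ammonium source
(55 µM at 4 m), and kinetics placing the transition zone near 2.3 m.

```python
from natzone import SedimentNitrogenModel

model = SedimentNitrogenModel.from_reference()
res = model.solve()
print(res.summary())
```

prints

```
Steady-state sediment nitrogen model
====================================================
grid: 400 cells over 4 m
converged: True   relative residual: 1.504e-12   iterations: 14
depth-integrated anammox: 0.6433 mmol m^-2 yr^-1
depth-integrated denitrification: 0.4684 mmol m^-2 yr^-1
depth-integrated nitrification: 13.1672 mmol m^-2 yr^-1
NAT zone: [1.714, 2.878] m (midpoint 2.296 m, mode overlap)
anammox rate peak: 2.365 m
```

Reading this: oxygen is consumed within the top ~0.3 m; nitrate penetrates
to ~2.9 m where it falls below the 1 µM threshold; ammonium exceeds 1 µM
below ~1.7 m; the transition zone between those fronts is centred at
2.30 m and the modeled anammox rate peaks inside it at 2.37 m, integrating
to 0.64 mmol N m⁻² yr⁻¹ — the structural pattern observed in such cores.

The same pipeline runs from the shell:

```sh
natzone synth  --profiles-out profiles.csv --community-out community.csv
natzone natzone -p profiles.csv -o zone.json
natzone confine -a community.csv -z zone.json -o confinement.json --seed 7
```

The `confine` step reports, per taxon, the confinement index (fraction of
relative abundance inside the zone) and its permutation p-value; taxa whose
synthetic niches are centred in the zone come out with indices near 1 and
p ≈ 0.001, while the diffuse "other" fraction is not confined (p ≈ 1).

Calibration works the same way: `model.fit(observed, free=["k_amx"], ...)`
returns a results object whose `summary()` lists the fitted constants,
the weighted SSE and per-species residuals.

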