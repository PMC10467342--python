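# Methods

## Model

The package solves the steady-state early-diagenesis equation for three
dissolved species C ∈ {O2, NO3−, NH4+} on a 1-D sediment column:

    d/dz [ −φ(z) Ds dC/dz + φ(z) w C ] = φ(z) S_C(O2, NO3, NH4; z)

Depth z is meters below the sediment-water interface, positive downward;
concentrations are µM (mmol per m³ of porewater); time is in years.
Assumptions: steady state (profile shapes are diffusion-relaxed on the
decadal time scales of decimeter structures); molecular diffusion plus
constant burial advection as the only transport (no bioturbation or
bioirrigation — appropriate below the mixed layer of quiet deep-sea
sites); constant-with-depth burial velocity; tortuosity by Boudreau's
relation Ds = D0/(1 − ln φ²), the standard marine-diagenesis choice.
Porosity is constant by default, with an exponential compaction law
φ(z) = φ_inf + (φ0 − φ_inf)e^(−z/λ) available.

### Reaction network

Organic-carbon mineralization is prescribed, not modeled:
R_C(z) = R0·e^(−z/z_att). The aerobic pathway takes the Monod fraction
O2/(O2+K_O2) of it; denitrification takes (a Monod/inhibition-weighted
part of) the remainder; whatever neither pathway accepts is implicitly
handed to deeper electron acceptors (sulfate reduction and below), which
leave no tracked products here. Nitrification is first-order in NH4+ with
an O2 Monod factor. Anammox is written lumped on nitrate with
electron-balanced stoichiometry 5 NH4+ + 3 NO3− → 4 N2 and bimolecular
kinetics k_amx·NH4·NO3 under O2 inhibition Ki/(Ki+O2): nitrite — the true
anammox oxidant — is not carried, because porewater datasets of this kind
measure nitrate and ammonium only, and the lumped form preserves the
quantity of interest, the depth interval where the two measured substrates
co-occur. N2 is a diagnostic produced-nitrogen pool used only for the
fixed-N conservation check
S_N2N = −S_NO3 − S_NH4 + r_NC(R_O2C + R_denC).

Stoichiometric constants: 1 O2 per C respired; 0.8 NO3− per C denitrified
(5 CH2O : 4 NO3−); 2 O2 per NH4+ nitrified; per NH4+ anammoxed, 0.6 NO3−
consumed and 1.6 N released as N2. Organic N:C is Redfield 16/106.

### Parameters of the packaged reference scenario

A 4 m, 400-cell column emulating an Arctic Mid-Ocean Ridge core with its
nitrate-ammonium transition zone near 2.3 m:

| parameter | value | units | why |
|---|---|---|---|
| φ0 | 0.8 | – | typical pelagic clay |
| D0 (O2, NO3, NH4) | 0.0365, 0.0345, 0.0350 | m² yr⁻¹ | free-solution values near 0–4 °C |
| w | 5×10⁻⁵ | m yr⁻¹ | cm kyr⁻¹-scale accumulation |
| R0 | 2460 | µM-C yr⁻¹ | sets the O2 uptake; see feasibility note |
| z_att | 0.05 | m | reactive organic matter confined near the interface |
| r_NC | 16/106 | – | Redfield |
| k_nit | 500 | yr⁻¹ | keeps surface NH4+ below the 1 µM detection level |
| k_amx | 0.02 | µM⁻¹ yr⁻¹ | places a well-expressed rate peak in the zone |
| K_O2, K_O2nit, K_NO3, Ki_O2 | 1, 2, 1, 2 | µM | sub-/low-µM microbial affinities |
| top O2/NO3/NH4 | 300 / 15 / 0 | µM | deep Arctic bottom water |
| bottom | zero-gradient O2, NO3; fixed NH4 = 55 µM | | deep ammonium source |

This produces: O2 < 1 µM at 0.30 m; NO3− penetration (1 µM) at 2.88 m;
NH4+ appearance (1 µM) at 1.71 m; transition zone midpoint 2.30 m; a
single anammox rate peak at 2.37 m inside the zone; depth-integrated
anammox 0.64 mmol N m⁻² yr⁻¹.

**Feasibility note.** With a single-exponential R_C and oxygen consumed
essentially only by carbon oxidation and nitrification, a leak-free oxygen
front inside the reactive layer requires R0·z_att² to sit slightly above
Ds,O2·C_O2(0) (≈ 7.6 µM·m² here); below it a residual O2 flux escapes the
mineralization layer and drifts meters deep before meeting the ammonium
front. The reference values satisfy this with the front at ~0.3 m. A
side effect of the same structure is a small amount of NH4+ released just
below the oxic front, which supports a faint anammox ripple there — under
1% of the main peak. "Single interior maximum" is therefore checked with
a peak-prominence criterion (one maximum with prominence above 5% of the
global maximum, `scipy.signal.find_peaks`); the ripple sits an order of
magnitude below that floor.

## Numerics

Cell-centered finite volumes; interface fluxes by exponential fitting
(Scharfetter–Gummel), which is conservative, monotone, exact for constant
coefficients, and reduces to central differencing at low cell Péclet
number and upwinding at high. φ·Ds is distance-weighted harmonically
averaged at interfaces; Dirichlet boundaries enter through half-cell ghost
distances; the zero-gradient bottom drops the diffusive flux and keeps
advective outflow. Observed convergence on the reaction-diffusion
closed form is second order (measured slope ≈ 2.0 between 50/100/200
cells).

The steady state is solved by damped Newton iteration: banded
finite-difference Jacobian (interleaved state, bandwidth 3, so 7
perturbation colors), step-halving Armijo line search, and projection of
trial states onto the non-negative orthant. Projection, rather than
rejection of negative steps, is what makes the sharp oxic front tractable
— rejection stalls the line search where concentrations graze zero. On
stagnation the solver switches to pseudo-transient continuation (implicit
Euler steps with dt doubling on success, halving on failure) until the
Newton basin is re-entered. Default relative residual tolerance 1e−10;
the initial iterate interpolates linearly between boundary values. A
non-convergent solve returns a diagnostic state, never raises.

Degenerate inputs: rate laws are evaluated on non-negativity-clipped
states during iteration; a one-cell grid is supported (used by the
hand-solvable single-cell balance test); ties in the rate-peak locator
break to the shallowest cell.

## Zone detection and confinement statistics

The transition zone is bracketed between the nitrate penetration depth
(deepest point with NO3− ≥ ε, linearly interpolated at the final
down-crossing) and the ammonium appearance depth (first up-crossing of
ε), with ε = 1 µM by default — a typical porewater detection limit. If
nitrate never falls below its threshold, or ammonium never reaches its
own, the zone is reported as unresolvable rather than guessed. The
detection is invariant to super-sampling of the profiles.

Confinement of a taxon is the fraction of its summed relative abundance
at sampled depths inside the zone. Significance comes from unrestricted
permutation of abundances over depth labels: exact enumeration of all n!
assignments for n ≤ 7 depths, seeded Monte Carlo (default n = 999)
otherwise, with the add-one estimator p = (1 + #{≥ observed})/(N + 1), so
p can never fall below 1/(N+1). Exchangeability of depth labels is the
null; no spatial autocorrelation correction is attempted (a circular-shift
null would need regular spacing, which field cores do not have).

## Calibration

Weighted least squares: Σ ((C_model(z_i) − C_obs,i)/σ_i)², model values
linearly interpolated from cell centers to observation depths;
non-convergent forward runs return a 1e12 penalty. Minimization is
Nelder–Mead in log10 parameter space (all calibratable quantities are
positive rates, scales or concentrations) under bounds, with three
additional seeded restarts from perturbed starts; forward solves warm-start
from the previous converged state. Up to 6 parameters are accepted; more
than 3 triggers an identifiability warning — three porewater profiles
rarely constrain more. No uncertainty quantification is attempted
(weighted SSE only, no likelihood or priors).

## Synthetic data

`generate_observed` samples the forward solution at a user design of
depths and adds seeded Gaussian noise, truncated at zero. Default noise:
3 µM for O2 and 0.3 µM for NO3−/NH4+, typical electrode and colorimetric
precisions; truncation leaves a slight upward bias exactly at
zero-concentration depths, accepted because real data are reported
non-negative. `generate_community` draws a taxa × depths table: expected
proportions follow Gaussian depth niches A·e^(−(z−µ)²/2σ²) + b with a
residual "other" taxon absorbing the remaining probability, and observed
proportions are a multinomial draw at fixed read depth (default 20 000
reads/sample), the compositional noise structure of family-level 16S
summaries. The default community places three low-abundance taxa
(amplitudes 7.4%, 0.6%, 0.3%) with niches centred in the reference
scenario's transition zone.

What passing tests on these data do show: the pipeline detects zones,
localizes rate peaks, and flags confined taxa correctly when the
generating process matches the model family. What they do not show:
robustness to bioturbated or non-steady profiles, to taxa with bimodal or
skewed depth niches, to compositional artifacts of amplicon processing
(chimeras, copy-number variation), or to cores where the transition zone
is genuinely unresolvable — the detector's explicit error path covers the
last case, but no statistic is produced there by design.

## Known limitations

- Nitrite, DNRA, nitrate-dependent anaerobic methane/urea pathways are not
  modeled; anammox-on-nitrate is a deliberate lumping.
- The prescribed R_C(z) is single-exponential; real cores often need
  multi-G mineralization, and the leak-free-oxygen condition above is a
  symptom of that restriction.
- Identifiability of calibration is the user's responsibility; the
  recovery tests demonstrate it only for one- and two-parameter subsets
  under the documented designs.
- The permutation test treats depths as exchangeable; strongly
  autocorrelated abundance profiles will appear more significant than a
  spatially-aware null would report.
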