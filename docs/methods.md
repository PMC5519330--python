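# Model and methods

## The biophysical axon model

The package simulates an unmyelinated invertebrate motor axon — the
pyloric dilator (PD) axon of the lobster stomatogastric nervous system —
as a one-dimensional cable:

    (a / 2 R_i) ∂²V/∂x² = C_m ∂V/∂t + Σ I_ion + I_pump + I_app(t)

with radius a = 5 µm, length 1 cm, axial resistivity R_i = 80 Ω·cm,
specific capacitance C_m = 1 µF/cm² and specific membrane resistivity
R_m = 8 kΩ·cm² (leak conductance 0.125 mS/cm², passive length constant
λ = √(R_m a / 2R_i) = 1581 µm).  The cable is split into 101 identical
isopotential compartments with sealed (zero axial flux) ends.

Membrane currents are Hodgkin–Huxley form, I = ḡ mᵖ hq (V − E):

| current | ḡ (mS/cm²) | E (mV) | gates |
|---|---|---|---|
| I_Na (fast sodium)        | 14    | dynamic (Nernst) | m³h |
| I_Kd (delayed rectifier)  | 3     | −70 | m⁴ |
| I_Leak                    | 0.125 | −65 | — |
| I_A (transient potassium) | 5     | −70 | m³h |
| I_h control / dopamine    | 0.05 / 0.1 | −32 / −25 | m |
| I_Ks (slow potassium)     | 3     | −70 | m (τ = 5000 × τ_Kd) |

Steady states are sigmoids 1/(1+exp((V_half−V)/k)); time constants are
constants, reciprocal-cosh bells, or sigmoids (the tabulated typography
is read as τ = A/cosh(·): positivity and the sub-millisecond Na⁺
activation admit no other reading).  Model variants: `control`, `DA`
(doubled ḡ_h with a right-shifted, shallower activation curve —
the dopamine condition), `Ih_block` (ḡ_h = 0, the CsCl condition),
`HH_classic` (canonical squid parameters on the same cable) and
`Ks_substitute` (pump replaced by the slow K⁺ current).

The electrogenic Na⁺/K⁺ pump carries

    I_pump = I_max / (1 + exp(([Na⁺]_½ − [Na⁺]_in)/[Na⁺]_S)),

I_max = 2 mA/cm², [Na⁺]_½ = 78 mM, [Na⁺]_S = 2 mM, always outward, and
drives the per-compartment sodium balance d[Na⁺]_in/dt = −(I_Na +
3 I_pump)/(α F Vol) with α = 7.4, Vol = 7850 µm³ (one compartment) and
currents read as total compartment currents (density × 2πaΔx).  E_Na
follows the Nernst relation 58·log₁₀([Na⁺]_out/[Na⁺]_in).  [Na⁺]_out
(479 mM, marine-saline scale) and the initial [Na⁺]_in are
configuration: the defaults put the resting E_Na near +50 mV and the
standing pump current at the smallest value with a stable rest
(1.38 µA/cm² for `Ih_block`, 1.57 for `control`, 3.5 for `DA`; the
variants differ because the resting inward current each must balance
differs — see "Known limitations").

## Numerics

Voltage is advanced with a θ-implicit step (θ = 0.6, a mildly damped
trapezoidal rule) solved with the Thomas tridiagonal algorithm; gates
use exponential-Euler updates drawn from lookup tables of x_∞(V) and
exp(−dt/τ(V)) on a 0.05 mV grid (the exponential update is exact at
fixed voltage, which the single-gate relaxation property test asserts
against the closed form).  [Na⁺]_in advances every step; I_pump and
E_Na are refreshed every 1 ms (they ride on the slow sodium variable).
The default step is dt = 0.0125 ms: the printed Na⁺ activation time
constant is sub-microsecond at rest, so the spike foot's conductance
e-folds within a ~3 mV window and the observed delay converges only
first-order in dt; at 0.0125 ms halving the step changes a single-spike
delay by ~0.6 % (0.07 % for the classical HH variant), within the 1 %
contract.  Voltage blow-up (|V| > 200 mV) raises an error naming the
time and compartment.  The inner loop is compiled with numba.

Every stimulation protocol starts from `relax_to_rest`: 100 s of
stimulus-free integration with [Na⁺]_in held at its configured initial
value, which settles voltage and gates (the slowest gate, I_h, has
τ = 3.7 s) while leaving the slow subsystem at its configured starting
point.  The clamp is necessary: with the tabulated parameters the fully
coupled quiescent axon has no fixed point — the pump's own Na⁺ drain
(3 I_pump/(αFVol)) pushes its standing current below the level that
keeps the membrane subthreshold within ~100 s from any initial
[Na⁺]_in, after which the axon fires spontaneously.  During all
stimulation the pump and sodium dynamics run fully coupled.

## Protocols and measurement

Stimuli are 1 ms current pulses into compartment 0.  The default
amplitude is 4 nA, just above the 2–3.5 nA single-pulse rheobase of
this cable (input resistance ~16 MΩ at the sealed end, τ_m = 8 ms →
~1.2 mV per nA in 1 ms): a lone pulse always fires while pulses in the
deep relative-refractory zone (< ~10 ms after a spike) fail to
initiate, the regime of a threshold-level experimental drive.  Three
protocols: homogeneous Poisson trains (5/10/19 Hz nominal, 300 s, 2 ms
floor with redrawn intervals), paired conditioning/test pulses at a
log-spaced grid of intervals (10 ms – 10 s), and 300 one-per-second
parabolic bursts of 19 spikes sweeping 32 → 63 → 32 Hz (the parabola
over the 18 intervals is normalized so the two central intervals sit
exactly at the peak frequency).

Spikes are detected as upward −40 mV crossings at 0.3 and 0.7 of the
axon length (sub-sample timing by linear interpolation); the delay
between the sites is scaled by 9.5 to map the 0.4 cm span onto the
several-centimetre biological axon.  Per spike the series records
F_inst (reciprocal of the interval since the preceding spike-initiating
stimulus — identical to the stimulus interval whenever every pulse
fires), the trough voltage V_T before the spike and the peak voltage
V_P at the first recording site, and the four reciprocal Na⁺ gating
rates 1/α_m(V_T), 1/β_m(V_P), 1/α_h(V_T), 1/β_h(V_P).

## Analyses

- **STS**: mean delay D_mean and coefficient of variation CV-D in 20 s
  bins of stimulation time.
- **FTS**: unweighted least-squares quadratic of delay vs F_inst per
  epoch ("minute 1" = [0, 60) s, "minute 5" = [240, 300) s); the vertex
  gives (F_min, D_min) and κ_min = 2a, the second derivative, which
  equals the geometric curvature at the vertex where the slope
  vanishes (ms/Hz²).
- **Recovery cycle**: paired-pulse trials from identical rest states at
  a constant pump current equal to the minute-1 or minute-5 mean of the
  dynamic run; velocity = scaled site span / scaled delay; relative
  refractory (slower than the conditioning spike) and supernormal
  (faster) phases classified with a 0.1 % dead band.  A cubic in F_inst
  fitted to the curve predicts Poisson delays spike by spike; its R² is
  evaluated on spikes inside the fitted F_inst range (extrapolated
  spikes are flagged and excluded — the cubic has no support there).
- **Empirical regressions**: d = c₁x + c₂y + c₃ on feature pairs,
  minimized with Powell's conjugate-direction method from a zero start;
  the closed-form least-squares solution of the convex objective is
  always computed alongside and agrees to 10⁻⁶ (a fit contract that is
  itself tested).  The voltage regression uses reciprocal voltages
  (1/V_T, 1/V_P in mV); single-variable ablations drop the frozen
  feature from the design matrix (a frozen column is collinear with the
  intercept).
- **Published velocity equations**: the boundary-matching estimate
  v = √(d/(8 R_total R_i C_m²)) from the total membrane resistance at
  the spike peak (κ = R_total/R_rest ≈ 0.02 here, so the simplified
  form applies), and the analytic eighth-root expression
  v = ⅔ (r⁴ ᾱ_m³ ḡ_Na h₀ / (16 R_i⁴ C_m⁵))^⅛ with ᾱ_m = α_m(E_Na) −
  α_m(V_T) and h₀ = h_∞(V_T) (the steady-state reading of the resting
  inactivation; an instantaneous value can be passed instead).
- **Sensitivity**: every conductance, reversal and gating-τ of the
  spike-generating and modulatory currents scaled ±5 %/±10 % one at a
  time (same stimulus realization, paired design), runs at constant
  pump; sensitivity = OLS slope of fractional attribute change vs
  fractional parameter change across the five points.  E_Na scale
  factors multiply the Nernst output; τ factors scale the whole τ(V)
  curve.  The default battery uses a 60 s Poisson epoch: attributes at
  constant pump are stationary, so the shorter epoch adds noise but no
  bias.

## The surrogate generator

`synthetic_data` emulates the statistical structure of per-spike
features without the PDE solver: V_T = baseline − exponential drift
(amplitude 5 mV, τ = 120 s; the pump-like slow effect) + summation
kernel (4 mV·exp(−ISI/30 ms)); V_P = 25 mV − depression kernel
(8 mV·exp(−ISI/15 ms), Na⁺ inactivation); delay = c₁/V_T + c₂/V_P + c₃
(defaults 4000, 300, 90 — delays in the tens of ms) plus Gaussian noise
(0.3 ms).  The fast kernels scale with the slow drift
(`interaction_gain`, default 1): a purely additive V_T drift would
*shrink* delay variability under the reciprocal law (|c₁|/V_T² falls as
V_T hyperpolarizes), whereas the axon's variability grows because the
hyperpolarized membrane responds more strongly to the preceding
interval.  Because the delay law is exactly the regression's model
class, parameter recovery is testable end to end: zero noise returns
(c₁,c₂,c₃) to machine precision, and coefficients stay unbiased (3 SE
over 50 seeds) at default noise.  What surrogate-based tests do *not*
show: anything about membrane-potential waveforms, conduction failure,
or whether the biophysical model itself produces these feature laws —
that is what the cable simulations are for.

## Design choices where the design was open

- Boundary conditions: sealed ends (a finite nerve segment).
- Recording conventions: gate values, conductances, V_T and V_P are
  taken at the first recording site (0.3 L), the natural "electrode".
- State carries over between protocol segments with no reset.
- Delay from threshold crossings; peak-based delays agree within 2 %
  (tested), matching the equivalence noted for the original
  measurements.
- The quadratic FTS fits use unbinned, unweighted spikes.
- Fitted regression coefficients are reported but treated as
  protocol-dependent; the R² values are the reproducible quantities.

## Known limitations

Three related quantitative features of the original study do not
reproduce under the tabulated parameters, and the analysis of why is a
result in itself:

1. **No quiescent fixed point.**  The tabulated Na⁺ activation
   (V_half = −48 mV) and inactivation (V_half = −47 mV) midpoints
   overlap, producing a resting window current of −0.6 to −2.6 µA/cm²
   between −70 and −65 mV.  A stable rest therefore needs ≥ 1.2 µA/cm²
   of standing pump current (≥ 3 µA/cm² for the DA variant, whose
   resting I_h is large), but the quiescent sodium balance erodes any
   standing pump below that bound within ~100 s.  Hence the [Na⁺]_in
   clamp during the pre-run.
2. **Compressed pump dynamic range.**  Charge balance fixes the
   stimulated steady-state pump at |mean I_Na|/3 ≈ 1.7–2 µA/cm² at
   10 Hz (per-spike Na⁺ load ≈ 0.44 µC/cm², measured), only ~20–40 %
   above the stability bound — so the pump cannot rise "several-fold"
   during stimulation and the baseline hyperpolarizes by ~1–2 mV rather
   than ~5–7 mV.  D_mean rises and the delay–frequency relation has a
   clear interior minimum (F_min ≈ 30–40 Hz), but CV-D stays flat and
   the minute-5 curvatures κ_min come out ~5× smaller than the
   published 0.0059/0.0091/0.0032 ms/Hz² (their ordering,
   DA < control < ḡ_h = 0, is reproduced).  The recovery-cycle cubic
   predicts Poisson delays with R² ≈ 0.86–0.89 against the published
   0.939/0.937 — with the smaller delay variance, the same absolute
   residual costs more R².
3. **DA variant ectopy.**  The DA model's stimulated steady-state pump
   (~2.8 µA/cm²) sits below its own quiescent stability bound, so long
   10 Hz runs develop spontaneous spikes between stimuli; such spikes
   carry no F_inst and are excluded from the frequency analyses.

The printed 1 nA stimulus is also subthreshold for the printed cable
(rheobase 2–3 nA even for the classical HH variant); the 4 nA default
preserves the threshold-level character of the drive.

Problem sizes: the full protocol (100 s pre-run + 300 s Poisson) is
used for the headline analyses; unit tests use shorter epochs (the
constant-pump attributes are stationary, so short epochs estimate them
without bias), and the sensitivity battery defaults to 60 s epochs with
the full runs available through its parameters.
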