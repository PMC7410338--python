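# Methods

## Model

The axon is a uniform unmyelinated cylinder discretized into 50 µm
compartments (815 compartments over 4.075 cm).  Each compartment carries
Hodgkin–Huxley Na⁺, K⁺ and leak currents:

- capacitance C_m = 1 µF/cm², axial resistivity R_a = 28 Ω·cm,
  resting potential −60 mV;
- ḡ_Na = 0.48 S/cm² gated by m³h, ḡ_K = 1.088 S/cm² gated by n⁴,
  ḡ_leak = 0.0016 S/cm²;
- steady states x∞(V) = 1/(1+exp(−k(V½−V))) with
  (k, V½) = (−0.4, −36) for m, (1, −39.5) for h, (−0.125, −33) for n
  (units 1/mV, mV);
- time constants τ(V) = A·exp(k_τ(V−V½)) with (A, k_τ, V½) =
  (2 ms, −0.05, −40) for m, (40 ms, −0.025, −55) for h,
  (55 ms, −0.015, −28) for n, all at the 10 °C baseline.

Two non-printed constants were fixed by convention and calibration:
E_Na = +50 mV and E_K = −80 mV (standard values; the 10 °C calibration
targets are met without tuning them), and E_leak is always *solved* so that
the net membrane current at −60 mV with gates at steady state is exactly
zero, which pins the resting state (verified to < 10⁻¹² mV drift over
100 ms at all temperatures).

Gate exponents are configuration fields, not hard-coded.  m³h/n⁴ is the
default: with n¹ the steep n∞ would put ~36 mS/cm² of resting K⁺
conductance behind ḡ_K = 1.088 S/cm², forcing an unphysical E_leak near
+390 mV, and with m¹ the model conducts at 2.75 m/s instead of the ~1.28 m/s
calibration target.

The Na-activation time-constant slope defaults to k_τ = −0.05/mV, in line
with the other gates (−0.025, −0.015).  Slopes an order of magnitude steeper
make τ_m < 10⁻⁸ ms at suprathreshold voltages; activation then degenerates
to an instantaneous function of V, the depolarizing front becomes limited by
the space/time grid rather than by the physiology (measured velocity keeps
rising under grid refinement, 4→11 m/s and beyond), and no reasonable
parameter choice reaches the calibration targets.  With −0.05/mV the solution
converges cleanly and the 3 µm and 6 µm baselines come out at 1.275 and
1.813 m/s.

Temperature scaling: each of the six properties (ḡ_Na, ḡ_K, ḡ_leak, τ_m,
τ_h, τ_n) carries its own Q10.  At temperature T the factor
R = Q10^((T−10)/10) multiplies conductances (ḡ·R) and divides time
constants (τ/R), but only in compartments beyond the first 0.075 cm — the
stimulated segment stays at baseline so that AP initiation is
temperature-independent.  At 10 °C every R is 1, so all Q10 assignments are
exactly degenerate there; the sweep exploits this by simulating the baseline
once per diameter.

## Measurement

A 1 ms square current pulse, at twice the threshold found by bisection at
baseline, is injected into the first compartment.  Arrival times are the
first upward crossings of 0 mV (linearly interpolated between steps) at
0.575 cm and 2.575 cm from the stimulated end; velocity is the 2 cm span
over the time difference.  The simulation window is three times the
baseline transit time; if the distal site never crosses threshold in the
window the run is classified a biological propagation failure, kept distinct
from numerical divergence (NaN or |V| > 200 mV).  Velocity is insensitive to
the stimulus amplitude above threshold (< 0.5% for a 2× change) and to the
detection threshold, since full-height spikes traverse it in a fraction of a
time step.

## Numerics

The integrator is the staggered scheme standard in compartmental simulators:
gating variables live on half-integer time steps and are advanced by the
exact exponential update against their voltage-dependent steady state;
the voltage step treats the axial term with Crank–Nicolson and the ionic
term semi-implicitly (θ = 1/2), yielding a tridiagonal solve per step
(sealed ends) that is unconditionally stable for the stiff high-leak,
high-conductance variants at 30 °C.  The scheme is second-order: at the
default dt = 0.0125 ms the measured velocity sits within 0.2% of the dt→0
limit (halving dt moves it < 0.2%; halving dx < 0.7%).

The sweep kernel batches all 256 variants of one (diameter, temperature)
pair through a single numba-compiled loop.  Voltage-dependent gate
quantities are read from dense lookup tables (0.05 mV grid, linear
interpolation, one decay table per distinct temperature factor), which
removes ~10⁹ `exp` evaluations per batch; the batched solver agrees with an
independently written scipy-based one-model-at-a-time integrator to a few
parts in 10⁴ in velocity (cross-checked in the test suite on randomly drawn
variants).  A full 256-model × 6-temperature × 3-diameter sweep takes on
the order of two minutes on one core.

## Timing statistics

All inter-axon statistics extrapolate each model's measured velocity over a
4 cm functional distance: t(T) = 4 cm / v(T).  The delay of a (small,
large) model pair at T is
[t_small(T) − t_small(10)] − [t_large(T) − t_large(10)]; positive delays
mean the smaller axon's AP arrives late relative to the baseline timing.
Pairs in which either model failed to propagate are classified non-robust
but stay in every denominator.

A pair is temperature-robust when |delay| is below the criterion threshold.
The default is an absolute 1.3 ms at every temperature — the deviation that
"5% of control" evaluates to for these diameter pairs, since 5% of the mean
baseline transit time over 4 cm is 1.34 ms for 3v6 µm and 1.17–1.26 ms for
3v12 µm — with the fractional per-pair mode and an explicit per-temperature
mode retained for sensitivity analysis.  With the default, 10 587 of 65 536
3v6 pairs and 7 599 3v12 pairs are robust at 20 °C, falling to ~6 300 and
~3 700 at 30 °C.

Q10 ratios divide the smaller axon's property by the larger axon's.  This
orientation is forced by the geometry of the robust set: because velocity
rises with temperature, keeping the *absolute* arrival-time difference
constant requires the smaller (slower) axon to speed up *less* than the
larger one, so robust pairs are bounded above in the small/large τ_m ratio
(observed range 0.375–1.5 for 3v6, 0.375–4/3 for 3v12 at 20 °C) and
unbounded statements result from the opposite orientation.  Necessity and
sufficiency of a ratio interval are the fractions P(non-robust | outside)
and P(robust | inside); interval membership uses a 10⁻⁹ tolerance so grid
ratios like 4/3 compare reliably against printed bounds like 1.33 (and 8/3
against 2.67).

For ratios achievable by more than one (small, large) Q10 combination
(0.5, 0.75, 1, 4/3, 2 on the default grid), the high/low analysis ranks the
achievable combinations and reports the share of robust pairs in the upper
half; an unconstrained set gives 50% per bin.  The coefficient-of-variation
analysis compares the CV of one axon's property Q10 among robust pairs per
ratio bin against the uniform-grid baseline CV (≈ 0.3658 for
{1.5, 2, 3, 4}); values clearly below baseline flag properties that must be
coordinated at that ratio.

## Synthetic experimental data

No recordings ship with the package; the generator stands in for them and
is labelled synthetic throughout.  Each pyloric axon type (PD, LP, PY) gets
a velocity-temperature curve built from the logistic *shape* parameters of
sigmoid fits to such recordings (midpoints ≈ 12.5–13.2 °C, widths ≈
4.0–4.4 °C).  The printed fit offsets would put the raw curves below zero at
low temperature, so the generator anchors the curve at a positive cold-end
reference speed instead: v(T) = v₅·(1 + g·(σ(T) − σ(5))) with unit logistic
σ, v₅ defaults (LP 0.60 > PD 0.55 > PY 0.45 m/s, preserving the observed
velocity ordering) and gain g = 1.5 chosen once so the 5→25 °C velocity
ratio is ≈ 2.2, i.e. a velocity Q10 near the ≈1.5 these axons show.
Noise is multiplicative Gaussian per observation (default SD 5%) plus a
per-animal scale factor (SD 5%) emulating between-animal variability, over
N = 5 animals at 1 °C steps — sizes typical of such datasets.  What the
generator does *not* emulate: AP failures, history-dependent conduction,
waveform/amplitude information, and correlated noise across temperatures;
tests passing on synthetic data therefore validate the pipeline's
arithmetic and sign conventions, not any claim about real recordings.

The cycle-period model for the phase analysis is likewise synthetic:
period(T) = 1 s · 2^(−(T−10)/10) (a frequency Q10 of 2, typical of the
pyloric rhythm); a user-supplied period table is accepted wherever the
model is.  Phase deviation of a follower relative to the PD reference is
100·[Δt(T)/period(T) − Δt(10)/period(10)] with Δt the follower−PD
arrival-time difference over 4 cm; the reference neuron is identically zero
by construction, and rescaling all velocities by a common factor scales
deviations by its inverse.

## Q10 estimators

Endpoint: v(15)/v(5), exactly the Q10 of an exponential through the two
points.  Regression: Q10 = 10^(10·slope) from an OLS fit of log₁₀ v against
T, identical to the endpoint form on perfectly exponential data and
recovering a generating Q10 within 5% at 2% multiplicative noise over 21
points.  Windowed: the same slope over successive 5 °C increments,
equivalently (v₂/v₁)^(10/ΔT), which exposes the saturation of
sigmoid-shaped temperature responses as a Q10 that declines with
temperature.

## Known limitations

- The 12 µm baseline velocity is 2.57 m/s, exactly 2× the 3 µm value: for a
  uniform HH cable velocity scales as √d (the continuum rescaling is exact),
  so a ~2.1 m/s value for a 4× diameter cannot be produced by diameter alone
  under this model family.  Statistics involving the 12 µm axon inherit this
  (its 5%-of-baseline fractional threshold is 1.17 ms rather than ~1.26 ms).
- The calibrated model propagates everywhere on the default sweep grid;
  its propagation-failure boundary lies just beyond it (failures appear at
  ~35–40 °C or at leak Q10s above 4).  The 30 °C robustness counts are
  therefore upper estimates: a model family whose fragile high-τ_h corner
  fails at 30 °C would lose robust pairs to the failure rule.
- Single APs only: no repetitive firing, no history-dependent conduction,
  no myelination, branching or synaptic machinery.
- The Potassium kinetics are so slow (τ_n ≈ 36–89 ms) that K⁺ currents
  barely shape a single AP; repolarization is carried by Na⁺ inactivation
  and leak.  This is a property of the parameter set, not a numerical
  artifact, and it is why the K⁺ Q10s are held fixed in the sweep.
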