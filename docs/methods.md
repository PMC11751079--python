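# Methods

This note documents the models, conventions, and numerical choices behind
`hemoturb`, and what the synthetic-data generator does and does not emulate.

## Temporal frame and waveforms

The cardiac cycle is described by heart rate HR (BPM), period T = 60/HR (s),
and a grid of `n_phase_bins` equal half-open phase bins (default 50, the
resolution at which phase statistics are exported). Waveforms live on a
uniform periodic grid of `n_phase_bins × samples_per_bin` points (default
10 per bin), so phase bins always divide the sample grid evenly; the sample
at t = T is identified with t = 0.

**Smoothing.** Digitised Doppler traces are resampled onto the target grid
by periodic linear interpolation and smoothed with a second-order
Savitzky–Golay filter in wrap-around mode. The window spans 5% of the cycle
(odd, minimum 5 samples). This is deterministic, preserves local quadratic
structure (so systolic peaks are not flattened at first order), and enforces
q(0) = q(T) by construction. Negative (backflow) samples are retained as
physical; a `clip_negative` flag is available.

**Heart-rate rescaling.** Waveforms at other heart rates derive from the
measured baseline under a constant-stroke-volume rule: t → t·(HR₀/HR),
q → q·(HR/HR₀). The ejected volume per beat (trapezoidal cycle integral) is
invariant to machine precision and the shape as a function of cycle fraction
is unchanged, so the peak moves from 0.08 s at 120 BPM to 0.096 s at
100 BPM and 0.06 s at 160 BPM while staying at cycle fraction 0.16. Note
that constant stroke volume makes cardiac output *proportional* to HR; a
statement that they are inversely proportional is inconsistent with this
rule, and the printed peak-systole times confirm the constant-SV behaviour.
Cardiac output here therefore rises with HR.

**Inlet profile.** The inlet velocity profile is parabolic,
u(r) = 2·V̄(t)·(1 − r²/R²) with V̄ = Q/A on the equivalent-radius disc; its
flux integral reproduces Q(t) identically. Womersley profiles are out of
scope.

**Canonical waveform.** `default_inlet_waveform` is a smooth physiologic
pulse: half-cosine rise to the peak at cycle fraction 0.16, half-cosine fall
to end-systole at fraction 0.45, a short backflow dip (amplitude 12% of
peak, duration 10% of cycle), and quiescent diastole. With peak inlet
velocity 1.5 m/s and inlet area 99.63 mm² it gives a stroke volume of
16.2 ml — a plausible value for an infant. The peak lies exactly on the
default sample grid, so rescaling reproduces printed peak times exactly
rather than to grid precision.

## Windkessel outlets

Each outlet is a three-element Windkessel: proximal resistance r_p in series
with a parallel r_d–C pair referenced to p_out,

    p = p_d + q·r_p + p_out,      C·dp_d/dt = q − p_d/r_d.

The ODE is integrated by the implicit trapezoidal rule with step equal to
the waveform spacing — A-stable, hence safe for the stiff RC limits — and
cycles repeat until the cycle-mean pressure changes by < 0.1%, starting from
the mean-flow steady state to shorten the transient.

**Calibration.** Given a target mean arterial pressure (default from an
assumed 123/60 mmHg via MAP = diastolic + pulse/3 = 81 mmHg) and target
flow fractions, total peripheral resistance is R_tot = (MAP − p_out)/mean(Q)
and each outlet receives R_i = R_tot/split_i. Within an outlet, r_p is 5% of
R_i (characteristic-impedance heuristic) and compliance is set from a distal
decay constant r_d·C = 1.0 s (physiologic diastolic decay); both are
configurable, since the reference coefficients for the patient outlets are
not available. Flows divide across outlets by the equal-pressure-node
approximation, i.e. in proportion to branch conductance 1/(r_p + r_d), which
conserves mass exactly and reproduces the calibration split on
re-simulation. The 72.3% aggregate arch-branch fraction is distributed
2:1:1 over innominate, left common carotid, and left subclavian — only the
aggregate is constrained by data.

## Phase statistics

Samples are assigned to (cycle, bin) by t mod T with half-open bins; samples
within a bin of one cycle are averaged before cross-cycle statistics; the
first cycle is discarded by default (transient removal) and incomplete
trailing cycles dropped. The fluctuation RMS uses the population form (1/N),
matching the definition of the phase-average decomposition rather than an
unbiased-variance convention; at the N = 20 analysis depth the distinction
is ~2.5%. TKE contracts the component-wise RMS vector by its dot product
with itself (sum of squared component RMS values).

**Convergence protocol.** Phase-averaged KE and TKE at the peak-systole bin
are compared between the ensembles of the first N−1 and N cycles; both
relative changes must fall below 1%. The criterion is meant for spatially
aggregated (entity-summed or volume-integrated) energies; for a single probe
the 1/N sampling noise of a variance estimate only reaches 1% at
impractically large N. Identically zero energies are treated as trivially
converged; a zero reference with nonzero update raises an error.

## Spectra

E(f) = |DFT(u)|²/L, one-sided with non-DC/non-Nyquist bins doubled, so the
spectral sum equals Σu² (Parseval, asserted as an invariant). No taper is
applied by default — the definition has none, and the probe windows are
periodic to good approximation — with an optional Hann window for leakage
studies. Cycle-block Welch averaging (one block per analysis cycle, default
20) reduces chi-squared spectral scatter; the slope of log₁₀E vs log₁₀f over
a user-chosen band is fit by least squares, since the band over which an
inertial range exists is data-dependent and is therefore a required
parameter.

## WSS metrics

PAWSS is the magnitude of the phase-averaged vector (not the average of
magnitudes), TAWSS its cycle-time average; OSI's numerator uses the full
time-mean vector. This composition is self-consistent: OSI = 0 iff the
direction is fixed, and TransWSS ≤ TAWSS element-wise because the transverse
component of a vector never exceeds its magnitude. A printed definition of
the turbulent WSS that averages the fluctuations themselves would vanish
identically; TurWSS is therefore the RMS of the fluctuations, consistent
with its use as a positive field. TransWSS is computed from the
phase-averaged WSS series (an `instantaneous` source can be selected),
with the element-wise normal in n̂ × ŝ. For uniform periodic bins the
trapezoidal cycle integrals reduce to bin means, which is how they are
implemented.

Elements whose time-mean WSS vector vanishes relative to the typical
instantaneous magnitude (threshold 10⁻¹² relative) have no preferred
direction; TransWSS and OSI are reported as NaN there and excluded from
area-weighted segment averages, rather than biased to zero. Segment
averaging is area-weighted over |metric| per segment label; the tube
fixture's front/back mask is split by the x–z plane with a half-bin
azimuthal offset so the two segments have exactly equal areas.

## Synthetic data generator

The generator imposes statistics; it does not solve flow equations. It
emulates: (a) a periodic pulsatile mean proportional to the inlet waveform;
(b) zero-phase-mean Gaussian fluctuations with per-bin σ(t) = I(t)·V̄(t),
where the intensity envelope I(t) peaks at 1.5× the peak-systole fraction
(turbulence grows during systolic deceleration, lagging the mean-flow
energy) over a floor of 15% of the nominal intensity (default I₀ = 0.2);
(c) a −5/3 inertial-range spectrum, obtained by shaping white Gaussian
noise with a f^(−5/6) transfer amplitude inside a band and normalising to
unit expected variance — the expected ESD follows the power law exactly, so
ground-truth spectra are analytic; and (d) a wall field with a
jet-impingement patch (constant unidirectional shear), a symmetric-reversal
band (OSI exactly 0.5), a direction-switching band (TransWSS = τ/√2), and a
weak unidirectional background, all tangent to the surface by construction.

It does **not** emulate: spatial correlation between entities, non-Gaussian
(intermittent) fluctuations, cycle-to-cycle waveform variability, wall
motion, or any coupling between the velocity and wall-shear fields. Passing
recovery tests therefore demonstrates that the analysis chain measures what
it claims on data with known statistics — not that a physical flow has
those statistics.

All randomness derives from one seed through `numpy.random.default_rng`
(PCG64) with per-purpose child streams, so identical seeds give
bit-identical datasets across platforms.

## Problem sizes and tolerances

Defaults follow the study conditions: 50 phase bins, 21 generated cycles
(20 analysed), blood density 1060 kg/m³ and kinematic viscosity
3.78×10⁻⁶ m²/s, 120 BPM baseline with 100/120/160 BPM comparisons, and a
72.3% arch split against MAP 81 mmHg. The bundled pipeline and test suite
run probe signals at 10 kHz over 20 cycles and wall meshes of order 10³
elements — sizes chosen so a complete synthetic study executes in seconds
on one CPU while keeping every statistical check (CLT bounds at N = 20,
chi-squared spectral scatter over 20 blocks) meaningful. Statistical
recovery tests use seeded generators and tolerance bounds derived from the
relevant sampling distributions (normal for phase means, chi-squared for
variances and spectra).

## Known limitations

* The equal-pressure-node flow split ignores transient compliance currents
  between branches; per-cycle mass conservation is exact, instantaneous
  division is resistive.
* The Windkessel calibration reproduces target pressure and splits, not any
  particular reference coefficient set; r_p fraction and decay constant are
  modelling choices.
* WSS from near-wall velocity uses a first-order one-sided gradient; its
  accuracy degrades with wall distance.
* Reynolds numbers use the radius as length scale (configurable); published
  values based on other conventions differ by the corresponding factor.
* The synthetic fixture is a straight constricted tube; curvature- and
  branch-driven secondary flows of a real aortic arch are absent.
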