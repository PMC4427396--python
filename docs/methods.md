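# Methods

## The problem

MOLLI (Modified Look-Locker Inversion recovery) is the workhorse sequence
for myocardial T1 mapping: after each of three magnetization inversions,
single-shot b-SSFP images are acquired at one image per cardiac cycle in a
3-3-5 scheme, and the 11 samples are fitted pixel-wise to the exponential
`S(TI) = A − B·exp(−TI/T1*)` followed by the Look-Locker correction
`T1 = T1*(B/A − 1)`.  That correction is exact only for a continuously
RF-perturbed recovery; MOLLI's intermittent b-SSFP readouts interleaved
with free recovery make the apparent relaxation depend on T2, on the
achieved readout flip angle (hence B1+), and on the inversion efficacy η
of the adiabatic pulse.  The standard fit therefore underestimates T1,
increasingly so for long T1, high flip angle and imperfect inversion.

`mollimap` implements the corrective approach: simulate the full sequence
with the Bloch equations, treat T1 as the only free parameter, and fix
T2, α and η from separately measured maps.

## Forward model

Magnetization is propagated as `M_{k+1} = A·M_k + B` composed from three
elementary affine operators (module `bloch`): x-axis nutation `R_α`,
free precession `P(t)` by `2π·Δf·t`, and relaxation
`C(t) = diag(e^{−t/T2}, e^{−t/T2}, e^{−t/T1})` with offset
`(I − C)·[0,0,M0]`.  Each readout TR is modeled as pulse → TE of
evolution (echo sampled) → TR − TE of evolution.

One single-shot readout consists of a 5-pulse flip-angle ramp
(α/6, −α/3, α/2, −2α/3, 5α/6, one per TR) followed by a 69-pulse ±α train;
the reported signal is the transverse magnitude at the echo of the
k-space center line, signed by the polarity of Mz at readout start
(phase-sensitive convention; a magnitude mode emulates scanner magnitude
images).  With linear ordering and 75 % partial Fourier the center line
is pulse 24 of the train (`center_line_index = 23`); this is configurable
since vendors differ.

Timing: image center lines are locked to the cardiac phase grid
`c·RR + TI1` (constant R-R interval, 1000 ms = 60 bpm by default; ECG
jitter is not modeled).  Inversions are placed so the first image of
block *b* sees `TI_b = TI1 + (b−1)·ΔTI`; rest periods are free
relaxation.  The inversion itself is instantaneous — `Mz → −η·Mz` with
transverse spoiling — because the finite-pulse physics is summarized by
the scalar η computed in module `inversion`.

Off-resonance during the readout defaults to Δf = 0 (on-resonance b-SSFP
pass band); B0 maps feed only the inversion-efficacy computation.

The hot propagation loop is a scalar kernel (numba-compiled when
available, plain Python otherwise) that is algebraically identical to
composing the affine operators; the test suite verifies the equivalence
against brute-force fine-step integration (10 µs within readouts) to
1e−5 per sample.

## Inversion efficacy

The 10 ms adiabatic hyperbolic-secant inversion (nominal peak B1
16.1 µT) is integrated through the Bloch equations with relaxation
active, in the frame rotating with the swept pulse frequency; efficacy is
η = −Mz(end)/M0.  Two integrators (exact per-step rotation + relaxation
split, and RK4) agree to 1e−4; the default step is 5 µs, converged to
~2e−6.

The vendor publishes only duration and peak amplitude, so the HS1 shape
parameters are package choices, exposed in `AdiabaticPulse`: μ = 5 and
amplitude truncation 5 % at the pulse edges (β = acosh 20, sweep ≈
1.17 kHz).  This standard parameterization reproduces the pulse's
documented behavior — η ≈ 0.92 for myocardium-like tissue (T1 1180 ms,
T2 45 ms), a lossless-passage efficiency ≥ 0.99, and a flat adiabatic
plateau (η varies < 0.02 for B1 scales 0.8–1.2) — whereas a 1 % truncation
at the same μ gives a faster sweep and η ≈ 0.955.  η maps from measured
B0/B1+ maps are computed per pixel or via a (B0, B1) lookup grid
(10 Hz × 0.02 spacing; interpolation error < 0.002 on the plateau).
Downstream fitting uses the single scalar η = 0.92 by default, matching
the observed spatial homogeneity.

## Estimators

*Standard*: Levenberg-Marquardt fit of (A, B, T1*) on the TI-sorted
samples, initialized at A₀ = max S, B₀ = A₀ − min S, T1*₀ = TI of the
minimum |S|; Look-Locker correction applied afterwards.  For magnitude
data all 12 sign-flip prefixes are tried and the minimum-RSS fit kept.
Fits with A ≤ 0, T1* ≤ 0 or B/A ≤ 1 are flagged as failures.

*Simulation-based*: Nelder-Mead simplex over T1 alone (xatol 0.005 ms,
max 500 evaluations), re-simulating the full acquisition at each trial
T1 with T2, η and α fixed.  A global amplitude scale is solved in closed
form per evaluation — unavoidable for real data whose absolute scale is
unknown, and an explicit extension of the procedure.  Initialization is
the Look-Locker-corrected standard fit floored at 400 ms; results
outside [100, 5000] ms are flagged implausible.

A note on sensitivity: re-fitting a noiseless T1 = 1300 ms curve while
overestimating T2 by 3.1 ms (the T2-prepared b-SSFP bias at myocardial
T2) shifts T1 by ≈ 0.5 % at α = 35° and ≈ 0.3 % at the in vivo achieved
α = 24° in this model — the direction (underestimation) is robust across
fitting conventions, while the magnitude is roughly twice the 0.25 %
sometimes quoted for this effect.

## Auxiliary maps

T2 is fitted log-linearly (signal²-weighted) from T2-prepared b-SSFP
signals (prep times 0/25/75 ms) or multi-TE spin echo; with three points
this matches the information available and is deterministic.  The
T2-prepared readout inherits a positive T2 bias from the b-SSFP readout,
reproduced by the forward model.  The gold-standard phantom T1 uses a
3-parameter IR fit without Look-Locker correction (TR ≫ T1, one line per
inversion).

Bloch-Siegert B1+ mapping converts the ±Δω phase difference to peak B1
via `φ_diff = 2·K_BS·B1²`, with `K_BS = γ²∫B1_norm(t)²/(2Δω)dt` computed
numerically (1 µs steps) for a unit-peak Fermi envelope (Δω = 8 kHz,
8 ms, 600° flip; envelope constants t0 = 0.6·T/2, a = T/70, exposed in
config).  The achieved excitation angle is `α_nom·B1/B1_nom`.  The
half-difference convention for the two interleaved ±Δω phases is assumed.

## Monte Carlo study

Per sample: T1 ~ U(400, 2400) ms; simulate MOLLI at T2 42 ms, α 24°,
η 0.92, 60 bpm; add Gaussian noise; fit with both estimators, the
simulation fit receiving `T2 + N(0, 3 ms)` and `α + N(0, 2.5°)`
emulating map uncertainty.  Results are aggregated in 20 bins of true
T1 as relative bias and coefficient of variation of the normalized
estimate (std/mean of `est/true` per bin — normalizing removes the
spread contributed by the bin's own 100 ms width, which would otherwise
dominate both estimators equally).

SNR is defined relative to the brightest image of the series, the way
image SNR is measured on scanner data (default 50): defining it against
the equilibrium magnetization would make the b-SSFP images (amplitude
≈ 0.15·M0 at this operating point) effectively SNR ≈ 8, swamping both
estimators with noise no scanner protocol would tolerate.  The default sample count is 2000, which resolves
per-bin statistics to ~0.3 % at these settings; `n_samples` is a config
field for larger runs.

At the defaults the simulation fit's per-bin bias stays within ±1 % with
CoV ≈ 1.5–3 %, while the standard fit's bias grows from −9 % to −20 %
with T1 at CoV ≈ 1–2 % — the precision/accuracy trade-off the method
analysis predicts.

## Synthetic data

The digital phantom generator stands in for all scanner acquisitions.
`make_tube_phantom` reproduces the six-tube calibration object (T1
{2085, 1747, 1422, 1038, 706, 535} ms, T2 ≈ 42–43 ms) as circles on a
64×64 grid (configurable; 192×154 mirrors the scanner matrix), with a
seeded ±1 px center jitter and optional smooth B1+ gradient emulating
the in vivo right-to-left transmit pattern.  `acquire` forward-simulates
MOLLI / T2-prepared / Bloch-Siegert acquisitions per pixel (grouping
pixels with identical parameters) and adds Gaussian or Rician noise at a
configured image SNR.

What it emulates: per-pixel signal formation, protocol timing, noise
level, B1+ spatial structure.  What it does not: k-space/PSF effects and
partial-Fourier reconstruction (only the center-line timing is kept),
cardiac/respiratory motion and registration error, heart-rate
variability, off-resonance banding, magnetization transfer.  Passing
round-trip tests therefore demonstrates correctness of the estimators
under the model's own physics — an inverse-crime validation — plus the
systematic biases the model predicts, not robustness to every artifact
of real scanner data.

## Numerical choices and degenerate inputs

- Times ms, frequencies Hz, angles degrees at API boundaries.
- Empty operator composition = identity; α = 0 readout reduces to free
  relaxation and zero signal; flip angles driving any pulse past 360°
  are rejected as misconfiguration.
- Negative inversion-to-readout delay (TI shorter than the ramp +
  pre-center train) raises with the offending TI named.
- Nelder-Mead tolerance 0.005 ms on T1; standard fit capped at 2000
  function evaluations; polarity restoration evaluates every prefix.
- Non-decaying input to the T2 fitters returns `tau = inf, ok = False`
  rather than raising; non-positive signals raise.
- t2 > t1 tissue draws warn but simulate (the operators remain valid).

## Known limitations

- The simulation fit assumes the supplied T2/α/η are exact; their errors
  propagate (quantified by the Monte Carlo module).
- On-resonance readout only; ShMOLLI-style conditional fitting and joint
  (T1, T2) estimation are out of scope.
- The HS1 parameterization is a calibrated stand-in for the unpublished
  vendor pulse; absolute η for other pulses requires re-parameterizing
  `AdiabaticPulse`.
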