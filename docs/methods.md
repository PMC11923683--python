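# Methods

This note records the models implemented in `phonoid`, the defaults and why
they were chosen, the numerical decisions taken where the design was open,
and what the synthetic-data generators do and do not emulate.

## Stimuli

**Inverse-Fibonacci voltage.** `V(n) = V₀ / F(n+1)` with `F(1) = F(2) = 1`,
0-based step index `n`. Fibonacci numbers are computed as exact Python
integers, so sequences of 1000+ terms are not subject to overflow.

**Golden-ratio decay.** `V(n) = V₀·φ^(−n/scale)`, default `scale = 100`,
0-based index. With this convention a 1000-step sequence from 10 V ends at
`10·φ^(−9.99) ≈ 0.081698 V`; terms exactly `scale` steps apart are in golden
ratio, and `log V` is linear in `n` with slope `−ln φ / scale`. The 0-based
convention is deliberate: it is the one under which the canonical 1000-step
endpoint value above is exact.

**Fibonacci tone bank.** Pure sinusoids at (144, 233, 377, 610, 987,
1597) Hz, 5 s each by default. Component amplitudes default to equal weights
before peak normalization: the modest input-power roll-off observed across
144–987 Hz in real recordings (~28%) is inconsistent with a steep synthesis
weighting, so any roll-off is attributed to acquisition, not synthesis;
`amplitudes` is a parameter for users who want otherwise. The combined
waveform supports both superposition (default — the combined signal is
defined as a sum) and concatenation, and is renormalized to peak 1.
For CSV interchange with 2 kHz acquisition chains the tone set must be
restricted to components below 1 kHz (the CLI exposes `--freqs`).

**Fractal soundscape.** Harmonics `fₙ = f₀·φⁿ`, `n = 0..10`, `f₀ = 220 Hz`,
each with a random phase drawn uniformly from `[0, 2π)` using one seeded
generator per call (default seed 0, documented). At the default 44.1 kHz
rate the 10th harmonic (≈27.1 kHz) exceeds Nyquist and is dropped with a
logged warning; frequency folding is deliberately not offered. Amplitude
modulation uses the envelope `(1 − d/2) + (d/2)·sin(2π f_mod t)` with
`f_mod = f₀/φ⁵ ≈ 19.84 Hz` and depth `d = 1` by default — the simplest law
producing the intended slow temporal structure; the exact modulation law is
otherwise unconstrained, so the depth is configurable. Output is
peak-normalized to ±1.

**Serialization.** CSV is `index,value` for step sequences and
`time_s,value` for sampled signals; WAV is 16-bit PCM mono, written with
`scipy.io.wavfile`, round-tripping within one quantization step.

## RC response model

The proteinoid sample is modelled as a resistance R in parallel with a
capacitance C. Reference values measured for an L-Glu:L-Phe preparation are
R = 128 Ω and C = 2.888 µF, giving τ = RC = 369.664 µs. The response to the
golden-ratio drive is

    V_c(t_n) = V₀ · φ^(−n/scale) · (1 − e^(−t_n/τ)),   t_n = n·dt.

The drive is defined on a step index while τ is physical, so the mapping
between them must be explicit: `dt` (default 1 ms) is a model parameter, and
the φ-exponent uses `n/scale` while the charging term uses `t_n = n·dt`.
This preserves both the decay law and the charging law without asserting a
time unit neither defines.

Impedance uses the parallel topology, `|Z| = R/√(1+(2πfRC)²)` with phase
`−atan(2πfRC)`: a DC magnitude equal to R requires `|Z| ≤ R`, which rules
out the series form. Note that with τ = 369.664 µs this model gives
≈116 Ω and ≈−25° at 200 Hz; a reported pair of (89 Ω, −42°) at 200 Hz is
not consistent with that time constant under either RC topology and is not
reproduced.

## Signal metrics

Noise is defined as `output − input` throughout. SNR is
`10·log₁₀(mean(x²)/mean((y−x)²))`, returning `+inf` for identical signals.
PSNR (whose reference is otherwise unspecified) uses the stimulus peak:
`20·log₁₀(max|x|/RMSE)`. Welch PSD defaults: Hann window, segment length
`min(1024, N/4)` rounded down to a power of two, 50% overlap, constant
detrend, density scaling (integral ≈ variance). Cross-correlation is
mean-removed with global-energy (coefficient) normalization — not per-lag —
so values lie in [−1, 1]; positive lag means the output is delayed.

The transfer estimate is `H = S_xy/(S_xx + ε·max S_xx)` (Welch cross/auto
spectra, ε = 1e−10 by default); the impulse response is its inverse real
FFT on the Hermitian-extended grid. The window, overlap, detrend and
regularization are all exposed because exact kernel recovery (used as a
round-trip check) requires a single full-length rectangular segment and no
detrending. The bispectrum is the direct segment-averaged estimator
`mean[X(f₁)X(f₂)X*(f₁+f₂)]`, zeroed where `f₁+f₂` exceeds Nyquist; its
magnitude peaks at quadratically phase-coupled frequency pairs and is
suppressed by ≥10× when the phases are independent. The paired t-test
returns p = 1 for identical signals and p = 0 (degenerate) for a nonzero
constant difference.

## Information dynamics

All estimators are plug-in (maximum-likelihood) over equal-width histogram
bins; the default is 16 bins over the data range, with Freedman–Diaconis
(`n_bins="fd"`) as an option. Under independence the plug-in MI bias is
≈`(bins−1)²/(2N ln 2)`; an optional Miller–Madow correction subtracts the
first-order bias per entropy term. Bin-count guidance from the test
calibration: 16 bins lose ≈0.1 bits of a ρ = 0.9 Gaussian dependence to
quantization; 32–64 bins recover the Gaussian closed form
`−½log₂(1−ρ²)` within a few percent at n = 10⁵.

Transfer entropy uses embedding `k = l = history` (default 1) at unit lag —
a documented limitation, as no embedding is otherwise prescribed. Band
limiting applies a 4th-order zero-phase (forward–backward) Butterworth
filter; an open-ended band such as “>100 Hz” becomes a high-pass at 100 Hz.
Coherence is Welch-based with a default segment length guaranteeing at
least eight averaged segments, since a single segment degenerates to
γ² ≡ 1 (and is rejected). Normalized MI per band is `I(X_f;Y_f)/H(X_f)`
with MI and entropy from the same binning, `NaN`-flagged when the filtered
input is constant.

The capacity bound `I_max = log₂(1+SNR)` accepts dB or linear SNR behind an
explicit flag. Transfer efficiency is `η = 100·I/I_max`. (For reference, a
published (I, I_max) pair of (0.0801, 1.23) bits gives η ≈ 6.5%; note that
log₂(1+SNR) at 0.19 dB is ≈1.03 bits, not 1.23 — the pair is used as
printed, the chain from SNR is not asserted.)

## Particle dynamics

The Euler–Maruyama update per particle is

    r ← r + α·S(t)·û·dt + σ·√dt·N(0,1)  (per axis),

where `S(t)` is the normalized drive interpolated to simulation time and
`û` is a fixed random unit heading per particle. The drift enters as a
scalar gain on a vector equation, so a direction convention is required:
per-particle fixed headings keep the ensemble isotropic while the signal
modulates speed, matching the intended "signal modulates individual
movement" behaviour. Defaults: 100 particles uniform in a 1000 × 1000 nm
box, reflecting walls (specular fold), `dt = 0.01 s`, `t_end = 50 s`,
`α = 20 nm/s`, `σ = 30 nm/√s` — chosen so the equilibrium fluctuations of
the mean inter-particle distance are a few percent of its mean. For uniform
dispersal in an L × L box the mean pairwise distance is 0.52141·L
(≈521 nm here); a reported ≈650 nm mean in the same box size is mutually
inconsistent with uniform dispersal and is recorded as such, not targeted.

With α = 0 the per-axis MSD is `σ²τ`, so the 2-D diffusion coefficient
under `MSD = 4Dτ` is `D = σ²/2`.

## Trajectory statistics

MSD is the combined time-and-ensemble average over all start times
(overlapping windows) by default; pure ensemble (t = 0 origins) and pure
time averages are available. Overlapping origins were chosen because they
use all data and are the common default in single-particle tracking.

The confined-diffusion fit is unweighted least squares of
`y₀ + A·e^(R₀τ)` (per-lag pair counts available as optional weights),
initialized with `y₀ ← max(MSD)`, `A ← MSD(first) − y₀`,
`R₀ ← −ln2 / (lag at half-saturation)`, with a small multi-start ladder;
a flat curve returns a flagged degenerate result. Reported fit quality:
R², adjusted R², and reduced χ² (residual-variance based, no per-point
errors assumed). The diffusion coefficient is defined from the model's
initial slope, `D = A·R₀/(2·dim)`; this is the only definition consistent
with the fitted functional form (a previously published D value for this
kind of fit is not derivable from its own fitted parameters and is not
reproduced). The power-law fit `MSD = K·τ^α` is linear regression in
log–log space; α ≈ 1 is normal diffusion, α < 1 subdiffusive/confined,
α ≈ 2 ballistic.

Step ratios `R_i = |Δr_{i+1}|/|Δr_i|` drop zero-length denominators (and
count them); `keep_singular` keeps infinite ratios for users who want the
unfiltered distribution, whose mean is dominated by near-zero denominator
steps — the reason a step-ratio mean can be orders of magnitude above its
median (e.g. mean ≈12 versus median ≈0.99) in real tracking data.

## Morphometry

Summaries use the sample sd (n−1). The KS test runs against the Gaussian
fitted from the sample by default (no Lilliefors correction — matching
common practice, with the caveat that p-values are then conservative);
passing explicit (µ, σ) tests against a known generating distribution and
restores calibrated, uniform null p-values. Jarque–Bera comes from sample
skewness/kurtosis. KDE uses Silverman bandwidth. Size ratios are taken
larger/smaller over all unordered pairs, so the distribution is ≥1 and the
φ reference is one-sided; ratios are scale-invariant by construction. The
ratio computation is O(n²) and intended for populations up to a few
thousand spheres.

## Synthetic-data generators

`gen_response_recording` is a gain/DC/noise model behind a first-order RC
low-pass (exponential-smoother discretization, exact identity as τ → 0).
Defaults (gain 0.0108, DC −0.0104 V, noise sd 1 mV, τ = 369.664 µs) place
the synthetic outputs in the amplitude regime of real recordings — output
sd ≈ 1% of input sd with a small negative DC shift — without claiming to
replicate any specific recording.

`gen_confined_trajectories` draws stationary 2-D Ornstein–Uhlenbeck motion
with relaxation rate `θ = −R₀` and per-axis variance `y₀/4`, which gives
exactly the target ensemble MSD `y₀(1 − e^(R₀τ))`. The exact OU transition
is used, so the frame interval introduces no discretization bias. Defaults
(`y₀ = 3853 µm²`, `R₀ = −12.90 s⁻¹`, 200 particles, 400 frames at 5 ms)
match the confined-diffusion regime reported for proteinoid microspheres,
with a characteristic time 1/|R₀| ≈ 77 ms well resolved by the frame rate.

`gen_sphere_diameters` draws from a normal distribution truncated at zero
(defaults µ = 1581.27 nm, σ = 302.02 nm, n = 200 — the population size
behind the reference histograms is unreported, and 200 is a realistic SEM
measurement count). `gen_golden_walk` is the positive control for the
step-ratio analysis: consecutive step lengths in exact ratio φ with random
turning angles.

**What the generators do not emulate:** electrochemical nonlinearity
(voltage-dependent conductances), inter-particle interactions and
hydrodynamics, drift or vignetting in imaging, localization-error
correlation, and non-Gaussian diameter populations. Passing tests therefore
demonstrate estimator correctness on data satisfying each method's
assumptions, not robustness of the conclusions to real-recording artifacts.

## Problem sizes and determinism

Statistical tests use n = 10⁴–10⁵ samples for information estimators,
150–500 particles × 300–400 frames for trajectory statistics, and 20-seed
replicate ladders for fit-recovery and null-calibration checks — sizes at
which the targeted tolerances (10–15%) sit several standard errors from
failure. Every stochastic component takes an explicit integer seed and is
bit-reproducible; the acceptance script derives all stage seeds from a
single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* Histogram information estimators are biased for small n and sensitive to
  the bin count; TE uses a fixed unit-lag embedding.
* The RC model is linear; no conductance nonlinearity is included (its
  functional form is unspecified in the source material).
* The exponential MSD fit assumes a single confinement scale; heterogeneous
  populations will blur y₀ and R₀.
* The plain KS test with estimated parameters is conservative; use explicit
  reference parameters for calibrated inference.
* Reflecting boundaries use a single specular fold per step, accurate when
  step lengths are small relative to the box.
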