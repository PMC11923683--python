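# phonoid

Stimulus synthesis and response analysis for proteinoid protocell ensembles.

Proteinoids — thermal proteins that self-assemble into micron-scale
microspheres — behave electrically like leaky capacitors and respond to
structured electrical and acoustic stimulation. `phonoid` provides the full
computational workflow for probing such ensembles with Fibonacci- and
golden-ratio-structured stimuli:

* **Stimuli** — inverse-Fibonacci voltage steps `V(n) = V₀/F(n+1)`,
  golden-ratio decay `V(n) = V₀·φ^(−n/scale)` (φ = (1+√5)/2), a Fibonacci
  tone bank (144, 233, 377, 610, 987, 1597 Hz) and a fractal soundscape with
  harmonics at `fₙ = f₀·φⁿ`, serialized to CSV or 16-bit WAV.
* **RC response model** — time constant τ = RC, the capacitive response
  `V_c(t) = V₀·φ^(−n/scale)·(1 − e^(−t/τ))` and parallel-RC impedance
  `|Z| = R/√(1+(2πfRC)²)`.
* **Signal metrics** — SNR, Welch PSD, normalized cross-correlation,
  RMSE/MAE/PSNR/Pearson, power at selected frequencies, empirical frequency
  and impulse response, bispectrum (quadratic phase coupling), spectrogram,
  paired t-test.
* **Information dynamics** — histogram mutual information `I(X;Y)`, the
  Shannon bound `I_max = log₂(1+SNR)`, transfer efficiency `η = I/I_max`,
  band-limited transfer entropy `T_{X→Y}`, magnitude-squared coherence and
  normalized MI per band.
* **Particle dynamics** — Euler–Maruyama simulation of signal-modulated
  Brownian microspheres, `dr = α·S(t)·û dt + σ dW`, with inter-particle
  distance statistics.
* **Trajectory statistics** — time-and-ensemble MSD, confined-diffusion fit
  `MSD(τ) = y₀ + A·e^(R₀τ)`, power-law fit `MSD = K·τ^α`, diffusion
  coefficient `D = A·R₀/(2·dim)`, and step-size ratios versus φ.
* **Morphometry** — microsphere diameter summaries, a normality battery
  (KS, Jarque–Bera, Q–Q, KDE, ECDF gap) and all-pairs size ratios versus φ.
* **Synthetic data** — seeded generators for responses, confined (OU)
  trajectories, diameter populations and golden-ratio walks, so the whole
  pipeline runs without laboratory recordings.

## Worked example

```python
from phonoid import (time_constant, golden_ratio_decay, efficiency)
from phonoid.synthetic_data import gen_confined_trajectories
from phonoid.tracking_stats import msd, fit_exponential

tau = time_constant(128.0, 2.888e-6)            # reference L-Glu:L-Phe cell
print(f"time constant: {tau * 1e6:.3f} us")

decay = golden_ratio_decay(10.0, 1000, scale=100.0)
print(f"decay endpoint: {decay.values[-1]:.6f} V")

print(f"efficiency: {efficiency(0.0801, 1.23):.1f} %")

traj = gen_confined_trajectories(n_particles=300, frames=400,
                                 y0=3853.0, R0=-12.90, seed=1)
fit = fit_exponential(msd(traj, max_lag=200))
print(f"fitted plateau y0: {fit.params['y0']:.0f} um^2")
print(f"fitted rate R0: {fit.params['R0']:.2f} 1/s")
print(f"characteristic time: {fit.characteristic_time * 1e3:.1f} ms")
```

Output:

```
time constant: 369.664 us
decay endpoint: 0.081698 V
efficiency: 6.5 %
fitted plateau y0: 3974 um^2
fitted rate R0: -12.18 1/s
characteristic time: 82.1 ms
```

The time constant is exact (R·C); the 1000-step golden-ratio decay from
10 V lands at ≈0.0817 V; a measured mutual information of 0.0801 bits
against a 1.23-bit capacity bound is ≈6.5% transfer efficiency; and a
confined-diffusion ensemble generated with plateau 3853 µm² and rate
−12.90 s⁻¹ is recovered by the exponential MSD fit to within sampling
error, with characteristic confinement time 1/|R₀| of roughly 80 ms.

## Command line

```bash
phonoid stimulus phi-decay --v0 10 --n 1000 --out decay.csv
phonoid stimulus fib-tones --fs 2000 --freqs 144,233,377,610,987 --out tones.csv
phonoid simulate-response --n 1000 --out response.csv
phonoid synth response --stimulus tones.csv --out out.csv --seed 1
phonoid analyze --input tones.csv --output out.csv --report metrics.json
phonoid info --input tones.csv --output out.csv --bands 0-10,30-50,100- --report info.json
phonoid run --config run.yaml      # full stimulus -> response -> report pipeline
```

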