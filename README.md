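# cyclorhythm

Statistical processing of multichannel EEG recorded under repeated
mental-control trials in a brain–computer interface (BCI) session, built
on the model of a **vector of cyclic rhythmically connected random
processes**: all `N` channels share one rhythm function `T(t, n)` — the
time shift mapping instant `t` to its single-phase counterpart `n`
trials (cycles) later — and the joint distributions are invariant under
`t ↦ t + T(t, n)`. Each cycle splits into a *passivity* zone (no mental
action) and an *activity* zone (the operator performs the mental
command). When trial durations vary, `T(t, n) ≠ n·T` and the rhythm is
irregular; the regular case collapses to an ordinary cyclostationary
process.

The package is for signal-processing researchers and BCI developers who
want cycle-aligned, higher-order statistics of irregular-rhythm
recordings with a fully controlled synthetic test bed:

- **rhythm** — cycle/zone annotations, the discrete rhythm
  `T(t̃ₘₖ, 1) = t̃ₘ₊₁,ₖ − t̃ₘₖ` at the boundary knots, its
  piecewise-linear interpolant (per-zone slope `g = ΔT/Δt̃` and
  intercept, always `g > −1`), evaluation for any `n`, validation.
- **preprocess** — 3rd-order Butterworth notch at 50 Hz (or 60 Hz) and
  5th-order 1–17 Hz bandpass, zero-phase by default.
- **estimators** — cycle-aligned estimates on a phase grid `t ∈ Wc₁`:
  mean `m̂(t) = (1/M) Σₙ ξ(t + T(t,n))`, dispersion, initial and central
  moment functions of order `k`, and mixed initial/central moment
  functions across channels and lagged arguments with the printed
  `1/(M−M₁+1)` and `1/(M−M₁)` normalizations.
- **spectral_features** — one-sided DFT of each estimate; Bessel's
  inequality justifies keeping the smallest prefix of coefficients whose
  cumulative energy reaches a threshold (95% by default), shrinking the
  feature dimension from hundreds of phase values to a few tens.
- Activity-vs-passivity **sensitivity**: mean absolute distance (MAD)
  between the two zone estimates of each characteristic, in time and in
  frequency — higher-order moments score highest.
- **simulator** — synthetic recordings with shared irregular rhythm,
  zone-dependent harmonic mean/noise profiles, Gaussian or skewed noise,
  AR(1) inter-cycle dependence and shared cross-channel noise, with
  closed-form ground-truth moments.

## Worked example

```python
import cyclorhythm as cr

cfg = cr.SimulationConfig()            # 3 channels, 50 cycles, 250 Hz
rec, ann, gt = cr.simulate(cfg, seed=42)

rf = cr.build_rhythm_interpolant(ann)
print("rhythm valid:", cr.validate_rhythm(rf).passed)

grid = cr.PhaseGrid.from_recording(rec, ann, "zone2")   # activity zone
est = cr.estimate_initial_moment(rec, rf, grid, channel=0, order=4)
print(f"4th-order initial moment on {est.values.size} phases, "
      f"phase-mean {est.values.mean():.2f} {est.units}")

fv = cr.select_leading(cr.spectrum_of_estimate(est), threshold=0.95)
print(f"feature vector: K={fv.k} coefficients carry "
      f"{100*fv.energy_captured:.1f}% of the spectral energy")

report = cr.sensitivity_report(rec, rf, ann)
print(report.time_domain.round(3))
```

prints

```
rhythm valid: True
4th-order initial moment on 541 phases, phase-mean 70.56 uV^4
feature vector: K=3 coefficients carry 97.5% of the spectral energy
                                             ch1     ch2     ch3
Initial moments of fourth order           39.121  39.349  37.517
Central moment functions of fourth order   0.788   0.761   0.721
Initial moments of third order            10.246  10.220   9.746
Initial moments of second order            2.625   2.599   2.481
Variance                                   0.155   0.156   0.153
Mathematical expectation                   0.587   0.576   0.552
```

The rhythm interpolant reproduces every knot exactly; the 4th-order
initial moment of the activity zone needs only 3 leading Fourier
coefficients for 97.5% of its energy; and the MAD table shows the
higher-order initial moments separating activity from passivity far more
strongly than the mean or variance — the motivation for using them as
BCI features.

The same pipeline is available from the shell:

```sh
cyclorhythm simulate --seed 42 --out rec.csv --ann ann.json
cyclorhythm preprocess rec.csv filtered.csv
cyclorhythm estimate --kind initial --order 4 --zone activity --channel 1 rec.csv ann.json est.csv
cyclorhythm features --threshold 0.95 est.csv features.json
cyclorhythm sensitivity rec.csv ann.json report.csv
```

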