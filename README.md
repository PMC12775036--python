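# aperio

Can a consumer-grade EEG headset measure **aperiodic (1/f) brain
activity** in schoolchildren as dependably as a research-grade laboratory
system? `aperio` implements the full comparison pipeline for that
question, for researchers validating portable EEG or studying the
aperiodic component as a marker of cortical excitation/inhibition
balance: synthetic two-cohort resting-state EEG with known ground truth,
preprocessing, spectral parameterization, split-half reliability,
bootstrap equivalence testing, signal-quality metrics, cross-validated
predictability, and the association between aperiodic activity and
mathematical ability.

## The model

The EEG power spectrum over 1–40 Hz is decomposed into an aperiodic
component and oscillatory peaks:

```
log10 P(f) = b − χ·log10 f + Σᵢ PWᵢ · exp(−(f − CFᵢ)² / (2σᵢ²)),   σᵢ = BWᵢ/2
```

with offset `b` (log10 µV²/Hz at 1 Hz), exponent `χ` (log-log slope
magnitude; flatter ↔ more cortical excitability), and ≤ 5 Gaussian peaks
with bandwidths in [1, 8] Hz. Spectra come from Welch's method
(1024-sample Hann windows, 75% overlap). Reliability of the extracted
parameters is quantified by the split-half intraclass correlation
ICC(2,1) (two-way random effects, absolute agreement); between-system
fit quality is compared with a bootstrap TOST: the systems count as
equivalent only if the 90% percentile CI of the mean difference lies
inside a pre-declared bound ±Δ. The brain–behavior analysis correlates
the frontal aperiodic composite — the mean of offset and exponent at
F3/F4 — with a timed arithmetic score (Pearson r with Fisher CI,
Fisher-Z cohort comparison, supplementary simple mediation via working
memory). Details and all numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

```python
from aperio import (device_profile, synth_recording, preprocess_recording,
                    welch_psd, fit_spectrum)
from aperio.synth import SpectralParams, Peak

truth = SpectralParams(offset=1.0, exponent=1.5, peaks=(Peak(10, 0.6, 2.0),))
profile = device_profile("emotiv_like")          # 128 Hz consumer headset
rec, _ = synth_recording({c: (truth, truth) for c in profile.channels},
                         profile, duration_s=240, seed=1)
clean, retained = preprocess_recording(rec)      # 0.1 Hz HP, 50 Hz notch, rejection
fit = fit_spectrum(welch_psd(clean, "F3"))
print(f"offset {fit.offset:.3f}  exponent {fit.exponent:.3f}  "
      f"peaks {fit.n_peaks}  R2 {fit.r2:.3f}")
```

prints

```
offset 1.015  exponent 1.493  peaks 5  R2 0.995
```

— the generator's offset 1.0 and exponent 1.5 are recovered to ~0.01
despite line noise, drift, a hardware bump near 32 Hz, and artifact
bursts; the extra peaks absorb the injected 32 Hz bump so it cannot bias
the slope.

The full two-cohort analysis is a sequence of numbered drivers:

```bash
python analysis/01_simulate_and_fit.py --seed 0   # cohorts -> fits/retention/behavior tables
python analysis/02_equivalence.py     --seed 0    # Table-1-style bootstrap TOST
python analysis/03_reliability.py     --seed 0    # ICC(2,1) + ΔICC bootstrap
python analysis/04_quality.py                     # line noise, drift, stability
python analysis/05_crossval.py        --seed 0    # GP / RF vs. cell-mean floor
python analysis/06_association.py     --seed 0    # composite-math correlation
```

Each writes its tables under `results/` and narrates its findings, e.g.
stage 3 on the default synthetic cohorts (ρ_half = 0.9):

```
consumer  F3 exponent  ICC = 0.908 [0.865, 0.938] (n=93)
research  F3 exponent  ICC = 0.912 [0.852, 0.949] (n=52)
          F3 exponent  dICC = -0.004 [-0.059, +0.057] p = 0.910
```

— both simulated systems reach excellent split-half reliability and the
bootstrap finds no credible difference, mirroring the qualitative pattern
reported for real consumer- vs. research-grade recordings.

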