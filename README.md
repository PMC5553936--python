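# phasebind

Does the phase of a movement-locked brain rhythm predict, trial by trial,
whether a near-threshold stimulus is perceived correctly?  `phasebind` is a
statistical pipeline for exactly this question: experiments in which
participants prepare and execute a timed hand movement while brief visual
stimuli are flashed at dense, jittered times around movement onset, yielding
per-trial binary outcomes (a 2AFC orientation report), multichannel EEG
epochs aligned to movement onset, and force traces from which that onset is
detected.

The package implements, as tested reusable components:

* **Behavioural spectra** — is percent-correct rhythmic as a function of
  stimulus time relative to movement onset?  Two routes: a random-effects
  analysis fitting, per subject and frequency *f*, the logistic model
  `P(Y=1) = logit⁻¹(β₀ + β₁ sin(2πf t) + β₂ cos(2πf t))`, and a
  fixed-effects FFT of the binned, Hanning-tapered percent-correct series
  with a trial-level permutation test.
* **Phase estimation and extrapolation** — zero-phase Butterworth band-pass
  (default 3–5 Hz), Hilbert transform, down-sampling of the complex
  analytic signal to 200 Hz; the phase measured at time *t* is projected to
  the stimulus assuming constant frequency:
  `phase_at_stim(t) = phase(t) + 2πf (t_stim − t)`.
* **Phase → outcome inference** — per subject, channel and time, a
  maximum-likelihood logistic regression of the outcome on
  `sin(phase_at_stim)` and `cos(phase_at_stim)`; at the group level the
  per-subject coefficient pairs (β₁, β₂) are tested against zero with
  Hotelling's T² (exact F reference), summarized by the *predictive value*
  `PV = ‖(β̄₁, β̄₂)‖` with a leave-one-subject-out jackknife SE and the
  optimal phase `φ_opt = atan2(β̄₁, β̄₂)`, and corrected across channels ×
  times with Benjamini–Hochberg FDR.  Control variants: forward-only
  extrapolation, stimulus-locked phases, a joint early/late two-phase
  model, and a condition contrast by label permutation.
* **Phase locking** — mean resultant vectors `MRV_c(t) = mean_i H_ic(t)`
  (amplitude-normalized = inter-trial coherence), inter-individual
  consistency maps, and a split-half test that correlates the MRVs of two
  random halves of trials *across channels* with a complex correlation
  r(t), averaging Re r(t) over random partitions and testing it against 0
  across subjects.
* **Synthetic data** — a generator with known ground truth (movement-time
  distributions for short/long instructed intervals, uniform stimulus
  jitter, 1/f background EEG plus movement-locked ~4 Hz bursts, outcomes
  drawn from `P(correct) = logit⁻¹(β₀ + κ cos(φ − φ_opt))`), so every stage
  is testable end to end without any recordings.

## Worked example

Simulate 17 subjects whose outcomes are coupled (κ = 1) to the phase of a
late 4 Hz burst with optimal phase π/3, then run the full pipeline:

```python
import numpy as np
from phasebind import (SimConfig, BurstSpec, simulate_dataset,
                       bandpass_analytic, predict_timecourse)

cfg = SimConfig(n_subjects=17, n_trials=150, n_channels=3,
                noise_amplitude=3.0, kappa=1.0, phi_opt=np.pi / 3,
                bursts=[BurstSpec(center=-0.05, width=0.2, amplitude=2.0)])
subjects = simulate_dataset(cfg, seed=10000)
analytic = [bandpass_analytic(s["epochs"], window=(-1.9, 0.0))
            for s in subjects]
pm = predict_timecourse(analytic, [s["trials"] for s in subjects],
                        times=np.arange(-1.8, 1e-9, 0.1))
print("significant times:", np.round(pm.significant_times, 2))
c, t = np.unravel_index(np.nanargmax(pm.pv), pm.pv.shape)
print(f"peak PV {pm.pv[c, t]:.3f} at t = {pm.times[t]:+.2f} s, "
      f"phi_opt {pm.phi_opt[c, t]:.3f} rad")
```

Output:

```
significant times: [-0.6 -0.5 -0.4 -0.3 -0.2 -0.1  0. ]
peak PV 0.967 at t = +0.00 s, phi_opt 0.981 rad
```

The group predictive value is FDR-significant only in the burst epoch
(from −0.6 s onward; the burst sits at −0.05 s), and the recovered optimal
phase 0.98 rad matches the configured π/3 ≈ 1.05 rad: phases measured from
the synthetic EEG, extrapolated to each trial's stimulus time, recover the
latent phase that generated the outcomes.

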