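# chronnect

Chronnectomics of EEG dynamic functional connectivity: from a multichannel
resting-state recording to an **integrated dynamic functional connectivity
graph** (IDFCG) that stores, for every sensor pair in every sliding window,
both the coupling strength and the *dominant intrinsic coupling mode*
(DICM) — and from there to symbolic-dynamics features that predict a
subject's age.

The package is for researchers analyzing time-resolved EEG sensor networks
who want a single graph object that integrates within-frequency phase
coupling and cross-frequency phase-to-amplitude coupling, plus the
downstream machinery (topological filtering, microstate symbolization,
Markov/complexity features, cohort-level prediction) in one reproducible
pipeline.

## The method

1. **Preprocessing** — mains notch, optional PCA + ICA artifact removal
   (components are dropped when >30% of their windowed kurtosis or skewness
   z-scores fall outside ±2), and zero-phase 3rd-order Butterworth
   filtering into eight rhythms: δ 0.5–4, θ 4–8, α₁ 8–10, α₂ 10–13,
   β₁ 13–20, β₂ 20–30, γ₁ 30–48, γ₂ 52–70 Hz.  The Hilbert transform gives
   each band's instantaneous phase φ(t) and envelope A(t).

2. **Coupling (the IDFCG)** — in each sliding window, each sensor pair is
   scored on 36 candidate modes with the imaginary phase-locking value

       iPLV = | Im ⟨ e^{i(φ_a(t) − φ_b(t))} ⟩_t |,

   insensitive to zero-lag (volume-conducted) synchrony.  The 8
   within-band modes compare band phases; the 28 cross-frequency modes
   compare the slow band's phase against the phase of the slow-band
   component of the fast band's envelope (phase-to-amplitude coupling,
   both directions, max-statistic corrected).  Each candidate is tested
   against circular time-shift surrogates; the significant mode with the
   largest iPLV becomes the DICM (label 1–36, 0 = none).  Result: paired
   tensors `strength[T, N, N]` and `mode[T, N, N]`.

3. **Topological filtering** — orthogonal minimal spanning trees (OMST):
   successive edge-disjoint MSTs on distances 1/weight are aggregated
   until global efficiency minus wiring cost, J(m) = GE − Cost, is
   maximal.  Absolute/density/mean-degree thresholds are available for
   comparison.

4. **Network metric time series** — nodal global efficiency
   GE_i = (1/(N−1)) Σ_{j≠i} 1/d_ij on each filtered window graph, giving
   an N × T matrix, plus the per-window strength series.

5. **Microstates (NNMF-VQ)** — the window × sensor GE matrix is reduced by
   nonnegative matrix factorization, vector-quantized by the neural-gas
   algorithm into k prototype network microstates (smallest k with
   reconstruction error < 4%), seriated, and encoded as a symbolic
   sequence.

6. **Chronnectomic features** — transition rate TR, transition matrix TM,
   per-pair flexibility index FI (rate of DICM change), the 8 × 8 DICM
   comodulogram, complexity index CI (distinct words up to length 7)
   z-scored against 1,000 shuffles, the Ekroot–Cover entropy of Markov
   trajectories H = K − K′ + HΔ with K = (I − P + A)⁻¹(H* − HΔ), and the
   sample entropy of the strength series.  For k = 8 states and N = 64
   sensors the named feature vector has 4,263 entries.

7. **Prediction** — age regression via distance-correlation +
   dominant-set feature clustering, one representative per cluster, and a
   linear-kernel SVR under leave-one-out cross-validation; young vs.
   middle-aged classification via supervised Laplacian scores with a
   permutation threshold (mean + 2.5 SD) and an extreme learning machine.
   Feature selection is nested inside each fold by default.

## Worked example

A 4-channel, 40 s synthetic recording with a fully coupled α₁ pair
(phase lag π/2) at 10 dB SNR, pushed through the whole per-subject
pipeline:

```python
import numpy as np
from chronnect.synthgen import (CouplingSpecification, Epoch,
                                PlantedCoupling, gen_coupled_eeg)
from chronnect.pipeline import PipelineConfig, run_subject

spec = CouplingSpecification(
    epochs=(Epoch(40.0, (PlantedCoupling(pair=(0, 1), label=3, strength=1.0),)),),
    snr_db=10.0)
rec, _ = gen_coupled_eeg(spec, n_channels=4, fs=160.0, seed=1)

cfg = PipelineConfig(width_s=4.0, step_ms=250.0, n_surr=200, alpha=0.01,
                     k_min=2, k_max=6, master_seed=7)
res = run_subject(recording=rec, config=cfg)

frac = np.mean(res.idfcg.mode[:, 0, 1] == 3)
print(f"alpha1 dominant on the coupled pair in {100*frac:.0f}% of windows")
print(f"TR = {res.features['TR']:.3f}, Z(CI) = {res.features['CI_z']:.2f}, "
      f"SampEn = {res.features['SampEn']:.3f}")
```

prints

```
alpha1 dominant on the coupled pair in 96% of windows
TR = 0.547, Z(CI) = -7.03, SampEn = 1.496
```

The planted within-band mode (label 3 = α₁) dominates the coupled pair in
96% of the 129 windows; the microstate sequence jumps state roughly every
other window (TR ≈ 0.55) and is far less word-rich than its shuffles
(Z(CI) ≈ −7, as expected for a state sequence with temporal structure).
On noisy data the k-selection may not reach the 4% reconstruction target
within the allowed range; it then warns and keeps the largest k.

The same pipeline is scriptable from the shell:

```bash
chronnect simulate --out rec.edf --seed 1 --channels 8 --duration 30
chronnect run-all --edf rec.edf --out-dir out/
chronnect predict --manifest cohort.csv --task regression --nested
```

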