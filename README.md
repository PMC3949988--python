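# cohnet

Coherent-source analysis of concurrent EEG/MEG/EMG recordings during
rhythmic movement, with a synthetic ground-truth generator that makes the
whole chain testable end to end.

During self-paced finger tapping, the muscle and a distributed brain
network (primary sensorimotor cortex, premotor and supplementary motor
areas, posterior parietal cortex, thalamus, cerebellum) oscillate
coherently at the tapping rate (2-4 Hz).  `cohnet` implements the analysis
chain that localizes this network from sensor recordings and infers the
direction of interaction within it:

1. **DICS beamforming** — frequency-domain spatial filters
   `W = (L^T C~^-1 L)^+ L^T C~^-1` built from the band-limited sensor
   cross-spectral density `C(f)` and the lead field `L`, producing
   voxel-wise maps of magnitude-squared coherence with the rectified EMG.
   Sources are found sequentially: each local maximum above an
   epoch-permutation surrogate threshold (99th percentile of map maxima
   under 100 reference-epoch shuffles) is recorded and nulled, revealing
   weaker coherent sources.
2. **Source-signal reconstruction** — orientation-fixed unit-gain
   projections of the member voxels of each source, pooled into one time
   series per source.
3. **Renormalized partial directed coherence (RPDC)** — an MVAR model
   (least squares, AIC order selection) of the pooled source signals; for
   each edge j -> i the statistic
   `lambda_ij(f) = N X_ij(f)^T V_ij(f)^-1 X_ij(f)`,
   where `X_ij = [Re Abar_ij, Im Abar_ij]` is the frequency-transformed
   coefficient and `V_ij` its estimator covariance, is chi-square(2) under
   the null.  Edges are thresholded by a 100-fold segment-shuffle bootstrap
   (99th percentile) and screened with a time-reversal check against
   zero-lag mixing.

Forward modeling uses analytic spherical heads (closed-form MEG fields,
silent for radial dipoles; concentric-shell series EEG potentials with
average reference), so everything runs without MRI data.  The synthetic
study plants six lag-coupled narrow-band dipoles at the canonical
finger-tapping coordinates, drives an EMG with driver-locked bursts, and
projects to 96 EEG + 102 MEG channels with modality-specific noise — see
`docs/methods.md` for the model and its assumptions.

## Worked example

```python
import numpy as np
from cohnet import synthesis, PipelineConfig, run_pipeline

scen = synthesis.reference_study(seed=1)          # simulated study: 6 sources + EMG
cfg = PipelineConfig.reference_study("meg", seed=1)
res = run_pipeline(scen.task, scen.rest, scen.head, cfg)

for name, src in sorted(res.matched.items()):
    print(f"{name}: coherence {src.peak_coherence:.3f}, "
          f"{res.distances_mm[name]:.1f} mm from reference, "
          f"{src.orientation_class}")
print("scalp SNR  MEG", round(res.scalp_snr['meg'].mean, 2),
      " EEG", round(res.scalp_snr['eeg'].mean, 2))
```

prints

```
CER: coherence 0.007, 12.3 mm from reference, tangential
PMC: coherence 0.026, 12.0 mm from reference, radial
PPC: coherence 0.021, 10.0 mm from reference, tangential
PSMC: coherence 0.034, 8.9 mm from reference, tangential
SMA: coherence 0.020, 5.5 mm from reference, tangential
TH: coherence 0.022, 6.2 mm from reference, tangential
scalp SNR  MEG 2.67  EEG 1.2
```

All six planted sources are recovered from the MEG channels within about
one 10-mm grid step of their reference coordinates, and the MEG scalp SNR
exceeds the EEG one, as configured in the generator.  Rerunning with
`PipelineConfig.reference_study("eeg", ...)` localizes only cortical
sources on the full recording; adding `segment_selection=True` repeats the
analysis on the high-coherence segments of the recording.

The same chain is scriptable from the shell:

```
cohnet simulate --out dataset/ --seed 1
cohnet analyze --in dataset/ --out results/ --modality meg --seed 1
cohnet report --in results/
```

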