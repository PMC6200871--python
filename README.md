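# gcfd — generalized cross-frequency decomposition

Neuronal rhythms at different frequencies interact: a 10 Hz alpha
oscillation can be phase-synchronized with a 20 Hz beta rhythm (1:2), or
with a 30 Hz rhythm at 2:3, and so on.  In multichannel E/MEG recordings
such interactions are hidden by volume conduction — every sensor sees a
mixture of many sources — so coupling must be analysed between *components*
(spatially filtered source estimates), not between raw channels.

`gcfd` extracts pairs of components whose narrowband oscillations at
rationally related center frequencies f₁:f₂ = p:q are phase coupled, and
returns for each pair its time courses, spatial filters and spatial
patterns (scalp topographies).  It is aimed at EEG/MEG researchers studying
cross-frequency phase synchronization, and at anyone with multichannel
oscillatory data and a hypothesized integer frequency ratio.

## Method

For a real narrowband signal s(t), the analytic signal s̃(t) = s(t) + iH(s)(t)
(H the Hilbert transform) defines instantaneous amplitude A(t) = |s̃(t)| and
phase φ(t) = Arg s̃(t).  Two signals with ratio p:q are phase synchronized
when the generalized phase difference Δφ(t) = pφ₂(t) − qφ₁(t) is nearly
constant; the strength of coupling is the phase-locking value

    PLV(φ₁, φ₂) = (1/T) |Σₜ exp(i(pφ₂(t) − qφ₁(t)))| ∈ [0, 1].

The pipeline has four stages:

1. **Reference extraction (SSD).**  Spatio-spectral decomposition finds the
   spatial filters maximizing narrowband signal power against flanking-band
   noise power via the generalized eigenproblem C_signal w = λ C_flank w.
   The few strongest components of the reference band become candidate
   reference signals r(t).
2. **Dimensionality reduction.**  A secondary SSD of the fit band keeps 15
   "virtual sensors", shrinking the nonlinear problem below.
3. **Cross-frequency phase fitting (XPF).**  For each reference, find real
   weights w over the fit-band signals m̃ᵢ(t) minimizing

        Σₜ | (Σᵢ wᵢ m̃ᵢ(t))ᵖ − r̃^[q](t) |²,

   where r̃^[q] is the reference *frequency warped* by q (phase multiplied
   by q, amplitude preserved).  The component s = Σᵢ wᵢ mᵢ is then in p:q
   phase synchrony with r.  The problem is solved by multi-start
   trust-region least squares (closed form when p = 1); an optional scan of
   K constant phase offsets finds phase-*locked* (constant nonzero lag)
   components.
4. **Patterns and ranking.**  Each filter is converted to a spatial pattern
   via p = Mᵀs/(sᵀs) (equivalently the band covariance applied to the
   filter), virtual-sensor patterns are mapped back to channels through the
   SSD pattern matrix, and pairs are ranked by PLV.

A simulation generator reproduces the standard validation protocol
(frequency-warped 9–11 Hz Gaussian sources, 100 pink-noise dipoles, linear
mixing to 64 channels, variance-ratio SNR normalization), and the
evaluation module scores recovery with the pattern divergence
ϵ = 1 − |pᵀp̂|/(‖p‖‖p̂‖), greedy matching, and a segment-permutation
significance test.

## Worked example

```python
import numpy as np
from gcfd import GCFD, SimulationSpec, gen_dataset, greedy_match

# 3 coupled 20/30 Hz source pairs + 50 pink-noise dipoles on 64 channels
spec = SimulationSpec(n_pairs=3, n_noise=50, duration_s=60.0,
                      ratio=(2, 3), snr=0.5, seed=7)
X, truth = gen_dataset(spec)

model = GCFD(fs=200.0, f1=20.0, ratio=(2, 3), n_reference=3,
             random_state=0).fit(X)
for i, pair in enumerate(model.pairs_):
    print(f"pair {i}: PLV = {pair.plv:.3f}")

report = greedy_match(model.fit_patterns_(), truth.fit_patterns)
print("matched divergences:", np.round(report.divergences, 4))
```

Output:

```
pair 0: PLV = 0.442
pair 1: PLV = 0.331
pair 2: PLV = 0.239
matched divergences: [0.0043 0.0079 0.0231]
```

The three PLVs in the 0.2–0.45 range are the recovered 20↔30 Hz couplings
— far above the ≈0.01 chance level at this data length, though well below
1.0 because at SNR 0.5 the SSD reference components carry residual noise
whose phase error is tripled by the q = 3 warp.  The matched pattern
divergences ≲0.02 mean the recovered scalp topographies are close to
collinear with the true mixing columns (0 = identical up to scale and
sign, 1 = orthogonal).

The same workflow is available from the shell:

```bash
gcfd simulate --p 2 --q 3 --snr 0.5 --n-pairs 3 --n-noise 50 \
     --duration 60 --seed 7 --out scratch/sim
gcfd decompose --data scratch/sim_sensors --f1 20 --p 2 --q 3 \
     --n-ref 3 --seed 0 --out-dir scratch/out
```

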