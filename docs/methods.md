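# Methods

This note documents the models, numerical choices and validation design of
`gcfd`, and what its tests do and do not establish.

## Signal model and coupling measure

All analysis operates on narrowband real signals and their analytic
extensions s̃ = s + iH(s), factorized as A(t)e^{iφ(t)}.  Two narrowband
signals with center frequencies in ratio f₁:f₂ = p:q (p, q coprime — ratios
are reduced on construction) are considered phase coupled when the
generalized phase difference pφ₂ − qφ₁ (mod 2π) is non-uniformly
distributed; the phase-locking value PLV = |⟨e^{i(pφ₂−qφ₁)}⟩ₜ| quantifies
it.  All "mod 2π" arithmetic is done on unit phasors, never on raw angles,
avoiding branch-cut artifacts.

Frequency warping z ↦ |z|·e^{iq·Arg z} multiplies the instantaneous phase
(hence frequency, and bandwidth) by an integer while preserving the
amplitude envelope.  The amplitude-preserving warp, rather than the plain
complex power z^q, keeps the target of the optimization on the amplitude
scale of the reference (|z|^q would under- or overflow the residual for
large q).  The 0/0 case at z = 0 is defined as 0, the continuous limit.

## Filtering

All band filters are Butterworth, order 2 per direction, applied forward
and backward (`sosfiltfilt`), so the effective response has 4 poles and
exactly zero phase.  Neither the filter order nor the transition steepness
is a method constant; order 2 is standard EEG practice and stable for
2-Hz-wide bands at fs = 200 Hz, and is exposed as a parameter everywhere.
Band conventions default to pass ±1 Hz, band-stop ±2 Hz, flank ±3 Hz around
the center frequency.  For simulated data whose sources are warped copies
of a 9–11 Hz base rhythm, the harmonic of order n occupies n·(9–11) Hz, so
the simulation pipelines scale all three half-widths by the harmonic
number (`BandDefinition.scaled`).

Hilbert/filter edge transients corrupt phase estimates, so every PLV,
covariance and residual computation discards a configurable edge margin
(default 1 s per end; signals shorter than twice the margin fall back to
keeping the middle half).

## SSD

Spatio-spectral decomposition solves C_s w = λ C_f w, where C_s is the
covariance of the pass-band-filtered data and C_f that of the flanking
noise (band-pass into the ±3 Hz flank band, then band-stop of the ±2 Hz
band).  Both covariances receive a ridge of `shrinkage · trace/n` (default
1e-9) so that rank-deficient inputs (common after ICA cleaning) remain
solvable.  Eigenvalues are narrowband SNRs, sorted descending.  Patterns
are recovered from filters through the band covariance,
A = C_s W (WᵀC_s W)⁻¹, and each pattern's largest-magnitude entry is made
positive (eigenvectors are sign-ambiguous; a fixed convention makes runs
reproducible).  Defaults: 5 retained reference-band components, 15
fit-band virtual sensors.

## XPF

The phase fit minimizes Σₜ |(Σᵢ wᵢm̃ᵢ(t))ᵖ − r̃^{[q]}(t)|² over real w.  The
complex residual is stacked as real and imaginary parts (2T real
residuals) and solved with a trust-region-reflective least-squares solver
with an analytic Jacobian p·uᵖ⁻¹m̃ᵢ.  Implementation details:

* **p = 1** makes the problem linear; it is solved in closed form by
  `lstsq` (the global optimum, no restarts needed).
* **Multi-start.**  For p > 1 the objective is multimodal; the solver
  restarts from `n_restarts` (default 10) standard-normal weight vectors,
  each scaled so the initial component has unit mean power, and keeps the
  restart with the lowest final objective.  Ties below 1e-12 resolve to the
  lower restart index, making results deterministic under a fixed seed.
* **Conditioning.**  Fit channels and the warped reference are scaled to
  unit mean power before optimization; weights are rescaled to the original
  channel units afterwards.
* **Tolerances.**  ftol = xtol = gtol = 1e-10 and at most 500 residual
  evaluations per restart by default.  Clean fits converge in ~10
  iterations; the benchmark drivers cap at 1e-8/100 because only fits with
  no synchrony to find ever run longer.
* **Monitoring.**  The objective at every accepted iterate is recorded
  (`objective_history_`, non-increasing); `converged_` is False when the
  best restart hit the evaluation cap.
* **Phase-offset scan.**  For phase-locked (constant nonzero lag) coupling
  the fit is repeated against r̃^{[q,k]} = r̃^{[q]}·e^{2πik/K}, k = 0..K−1,
  and the run with the highest PLV wins (PLV, unlike the objective, is
  offset-invariant, so it selects the offset whose optimum actually locks).

### Reference sign and the offset scan

A subtlety absent from most descriptions of this family of methods: a
reference extracted by any linear decomposition is only defined up to
sign.  Negating the reference adds qπ to the warped target's phase, while
negating the weights multiplies the component's contribution by (−1)ᵖ.
When p is even and q odd, neither side can absorb the flip — the true
solution becomes infeasible for the strict-synchrony objective and the fit
collapses toward w = 0.  The end-to-end pipeline therefore defaults to
K = "auto": a two-point offset scan {0, π} when p is even, K = 1
otherwise.  Detached fits against an externally supplied reference keep
K = 1 by default since the reference sign is then physically meaningful.
This is the one place the package deviates from a plain K = 1 default; at
K ≈ 10 the scan searches arbitrary constant lags, as in cohort analyses.

## End-to-end pipeline

Preprocessing band-passes 0.5 Hz to 150% of the highest analysis frequency
(zero-phase).  Reference-band SSD yields up to `n_reference` candidate
references (clamped to the channel count with a warning); the fit band is
reduced to 15 virtual sensors by a secondary SSD whenever more than 20
channels are present ("auto"), since the nonlinear solve scales roughly
cubically with dimension.  Patterns found in virtual-sensor space are
mapped back to channels by p = S·p′ with S the retained SSD pattern
columns.  Every reference yields one (reference, fit) pair; all pairs are
returned sorted by descending PLV — selection of "the" coupled pair is
left to the caller.  Patterns are computed for both members of the pair by
the uncorrelated-sources regression p = Mᵀs/(sᵀs).  When the caller gives
an unordered frequency pair, the lower band should be the reference (lower
polynomial degree p converges faster and more accurately); the base
frequency can also be scanned over a grid, maximizing the top PLV.

## Simulation generator

The generator emulates the standard validation protocol for this method
family:

* **Coupled pairs.**  150 s of white noise at 200 Hz is band-passed to
  9–11 Hz (two-pass Butterworth), complexified, and frequency warped by p
  and by q, giving a source pair around 10p and 10q Hz whose generalized
  phase difference is *exactly* zero (both phases are integer multiples of
  the same base phase).  Defaults: 5 pairs per recording.
* **Background.**  100 mutually independent pink-noise dipoles.  Pink
  noise is made by 1/√f spectral shaping of white noise; content below
  0.5 Hz is zeroed, because the 1/f divergence at the lowest bins would
  otherwise concentrate nearly all variance in a few slow trends and make
  finite realizations of different dipoles spuriously correlated (real
  recordings are high-passed there anyway).
* **Mixing.**  Each source projects to 64 channels through a random
  unit-norm spatially smooth column (a sum of 2–4 signed Gaussian blobs
  evaluated on a deterministic sunflower layout of the unit disk).  A
  realistic boundary-element forward model is deliberately not included:
  the method's recovery guarantees rest only on instantaneous linear
  mixing, and any user leadfield (channels × nodes × 3) can be plugged in.
  Generated pattern matrices are redrawn until full rank; their median
  pairwise divergence (~0.6) is comparable to topographies of randomly
  placed cortical dipoles.
* **SNR.**  Each signal dipole is rescaled so that the mean across
  channels of its projected variance, divided by the mean across channels
  of the *cumulative* projected noise variance, equals the target SNR
  (0.1–2.0 in the studies).  Signal variance is measured on the narrowband
  source as generated, noise variance on the broadband sum.
* **Uncoupled control.**  The fit-band sources are warped from independent
  base rhythms, so within- and between-band sources are all mutually
  independent while all marginal spectra are unchanged.

What the generator does *not* emulate: realistic volume conduction and
electrode geometry, non-stationary coupling, amplitude–amplitude or
phase–amplitude interactions, artifacts, or line noise.  Passing the
simulation benchmarks therefore demonstrates correct recovery under
instantaneous linear mixing with 1/f background — not robustness to the
full phenomenology of empirical recordings.

## Scoring and inference

Recovery is scored by the pattern divergence ϵ = 1 − |pᵀp̂|/(‖p‖‖p̂‖)
(sign- and scale-blind; 0 collinear, 1 orthogonal).  Recovered and true
patterns are paired greedily — repeatedly take the globally smallest
remaining divergence and remove both patterns.  Greedy matching is not
globally optimal; an exact Hungarian assignment is available
(`method="hungarian"`) but greedy remains the default for comparability
with the original protocol.  With unequal counts, min(n, m) pairs are
formed.

Significance of an observed coupling is assessed by cutting the fit-band
data into segments (default 3 s, mirroring typical trial lengths),
shuffling segment order while keeping the reference intact, and re-running
the entire spatial-filter optimization per surrogate — so the null
distribution includes the optimizer's capacity to overfit.  The p-value
uses the add-one estimator (1 + #{null ≥ obs})/(1 + n_perm), which never
returns exactly zero; the default 1000 permutations are reduced in tests.

## Validation problem sizes

The published protocol uses 100 replicates of 150 s per condition.  The
package's own validation runs are scaled down to desk scale:

* detached-fit benchmark (`scripts/acceptance.py`, t1): 5 pairs, 100
  noise dipoles, 40 s, all ten ratios × SNR {1.0, 0.5, 0.1}; 6 replicates
  for p = 1 (cheap linear fits, and the conditions with the most sampling
  variance), 2 otherwise.
* full-pipeline benchmark (t2): 3 pairs, 50 dipoles, 60 s, same grid;
  8 replicates for p = 1, else 2.
* uncoupled control (t3): 5 pairs, 100 dipoles, 60 s, 10 replicates at
  2:3, SNR 0.5.

Both benchmarks fit in the 15-dimensional virtual-sensor space.  The test
suite uses further-reduced subsets of the same protocols.  Reported
summaries are the *worst-case* per-condition medians (t1, t2) and the
control mean (t3), so the single numbers bound every condition in the
grid.

## Known limitations

* The fit is asymmetric in the two bands; swapping reference and fit bands
  can give (slightly) different components.  No symmetrized variant is
  provided.
* Reference extraction quality bounds end-to-end accuracy: a reference
  that mixes two coupled sources yields a mixed fit component.  The
  detached mode (known reference) is markedly more accurate.
* Phase noise in the reference is amplified q-fold by the warp, so large q
  with noisy references lowers attainable PLV even when pattern recovery
  is good.
* PLV magnitudes, unlike pattern divergences, depend strongly on data
  length and SNR; compare them only within a fixed setup, or against the
  segment-permutation null.
* Inverse modeling (dipole fitting of recovered patterns) and artifact
  removal are out of scope; the pipeline expects pre-cleaned data.
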