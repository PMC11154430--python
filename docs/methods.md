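# Methods

This note documents the models, numerical choices and limitations behind
`gaitdmd`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## 1. Signal model

One step's vertical ground-reaction force, sampled at Δt = 0.02 s and
zero-padded to 100 frames, is modelled as a sum of K = 6 damped complex
conjugate sinusoid pairs,

    s_n = Σ_{k=1..K} 2 e^{α_k n Δt} Re( s0_k e^{2πi f_k n Δt} ),

with decay rate α_k < 0 (1/s), frequency f_k (Hz, below the 25 Hz
Nyquist limit) and complex initial condition s0_k (N). This is exactly
the class of signals a rank-2K linear recurrence generates, which is why
a Hankel (time-delay) embedding of rank 2K recovers the triplets
exactly from noiseless data: the estimator and the generator share one
parameterization, so recovery tests are parameter-recovery tests, not
model-mismatch tests. Robustness to model mismatch on real data is
*not* established by this suite (see §7).

## 2. Decomposition

`build_hankel` forms `D[i, j] = s_{i+j}` with a configurable row count;
`exact_dmd` computes the thin SVD of the unshifted block `X`, truncates,
forms the reduced propagator `Â = W* Y V S⁻¹`, eigendecomposes it and
lifts eigenvectors to exact dynamic modes `v = (1/μ) Y V S⁻¹ w`
(projected modes `W w` by option). Amplitudes solve `modes · b = D_0` by
least squares against the first snapshot column; a rank-deficient mode
matrix falls back to the minimum-norm solution with a warning. The fit
error is the spectral norm `‖Y − A X‖₂ = ‖Y (I − V_r V_r*)‖₂`, computed
in closed form from the SVD.

Truncation rules (`RankRule`):

* `error_threshold(ε)` — smallest r with `‖Y − A X‖₂ ≤ ε`; ε defaults to
  `1e-6 (rows + cols)` of the snapshot matrix. Monotone in ε.
* `variance_retained(q)` — smallest r whose cumulative squared singular
  values reach fraction q.
* `fixed(r)` — clamped to the numerical rank.

Singular values below `1e-12 σ_max` are always discarded first.

Row-count choice: the delay dimension has no canonical value. An aspect
requirement of very wide Hankel matrices conflicts numerically with a
100-frame padded window and ~45-frame stances, so the package instead
searches a small grid — the stance length, half of it, and 25 — and
keeps the embedding minimising the fit error, preferring those that meet
the ε threshold. The feature pipeline pins rows = 45 (just under half
the padded window, spanning one full stance) for cross-step
comparability.

The ε rule reaches its threshold only on (near-)noiseless signals; on
jittered, noisy steps it degenerates to full rank. The pipeline
therefore runs at the fixed operating point r = 12 (K = 6 pairs), which
the ε rule itself selects on noiseless steps.

## 3. Features

Eigenvalues convert to physical units through the principal logarithm:
α = Re ln μ / Δt, f = Im ln μ / (2πΔt); a real negative eigenvalue maps
to the Nyquist frequency. Real signals give conjugate-symmetric spectra;
modes are paired by `|μ_i − conj(μ_j)| ≤ tol` and each pair represented
once with f ≥ 0. The scalar clustered downstream is the modulus |s0| —
the conjugation-invariant choice; the complex value is retained for
reconstruction, and alternatives (real part, signed amplitude) would be
one-line changes.

A step's feature set is exactly K triplets sorted by ascending
frequency (ties: more negative α first, then larger |s0|). Pair
representatives are preferred over lone real eigenvalues, which only
fill a deficit: under noise a fixed-rank fit occasionally produces a
spurious real mode whose amplitude would displace a true pair and break
the frequency-rank correspondence across steps that centroid clustering
presupposes. `features_from_signal` escalates the truncation rank
(12 → 14 → 16) until K clean pairs appear and flags steps without them
as *ineligible*; baselines use eligible steps only. Cross-step mode
correspondence by frequency rank is itself a modelling choice: it is
reliable here because within- and between-person frequency variation
(≲ 0.05 Hz) is far smaller than the ≳ 1.1 Hz spacing between modes.

## 4. Baselines and identification

Per person, foot and speed: centroid = arithmetic mean of the triplets
at each mode rank; spread = inverse sample standard deviation per
component (floored at 1e6 when a component has zero variance, which
happens only in jitter-free synthetic cohorts). The identification cost
weights squared deviations by the *inverse standard deviation* — the
literal form of the method — although a textbook Mahalanobis distance
would use the inverse variance; `standardized=True` switches to the
latter. The literal form is dimensionally inhomogeneous (the |s0|
component, with the largest native scale, dominates the sum), and it is
sensitive to between-candidate differences in spread: a candidate with
looser spreads has uniformly smaller costs and attracts argmins. At the
default study conditions the recovered feature spread is jitter-dominated
and homogeneous across persons, so the effect is mild; at higher
measurement noise it degrades accuracy well before the features
themselves stop being informative. This is a property of the cost, kept
deliberately.

The Monte-Carlo protocol draws a person uniformly, 30% of their steps
without replacement, and scores the argmin over all enrolled baselines;
person and step draws use independent RNG substreams so extending the
repeat count never changes earlier draws. Three leakage regimes:

* `holdout=False` (default, the protocol used for headline accuracies):
  baselines include the probe steps — optimistic by construction.
* `holdout=True`: the probe person's baseline is recomputed without the
  drawn steps.
* `holdout="matched"`: additionally, every other candidate's baseline is
  rebuilt each repeat from an equal-size random subset. This removes the
  argmin advantage that a smaller, noisier baseline enjoys and makes all
  candidates statistically exchangeable — the correct protocol for
  chance-level null experiments. Null experiments additionally pool
  several independent zero-separation cohorts, because the conditional
  accuracy of any single finite cohort wanders a few points around 1/16
  (cohort-realization variance that a binomial interval on the repeat
  count does not cover).

## 5. Synthetic generator

**Base profile.** The frozen `BASE_MODES` table is a damped Fourier sine
series on the stance: frequencies are the odd harmonics k/(2T),
k = 1, 3, …, 11 of the stance duration T = 0.885 s, and every s0 is pure
imaginary, so each mode is a damped sine vanishing at first contact and,
jointly, at toe-off. Amplitudes were fitted once to a reference stance
profile (heel peak ~830 N, push-off bump, valley at ~2/3 of peak) and
frozen. Three structural properties motivated this family:

* *Progressive partial sums.* Fourier-like series reconstruct
  hierarchically: the two largest-|s0| pairs (the stance arch at
  0.57 Hz and the 2.8 Hz bump modulation) alone correlate 0.955 with
  the full signal and already show both force peaks. Generic 6-pair fits
  of the same shape fail this badly — they represent the late push-off
  bump through near-cancelling large amplitudes, and any 2-pair subset
  is then garbage.
* *Conditioning.* Odd harmonics keep the mode spacing (~1.13 Hz) above
  the spectral resolution of the stance window. With consecutive
  harmonics the 11th and 12th Hankel singular values fall to ~3e-3 N and
  the corresponding modes are unrecoverable under any measurement noise;
  an amplitude floor of 55 N serves the same purpose for the weakest
  modes.
* *Endpoint invariance under jitter.* The signal value at first contact
  is `2 Σ Re(s0_k)`; with pure-imaginary s0 it is exactly zero and stays
  zero under multiplicative amplitude jitter. After any perturbation the
  dominant mode's real part is additionally rebalanced so the
  first-contact value equals the profile's.

**Stance window.** A sum of damped exponentials is not compactly
supported: past toe-off the expansion keeps ringing at a few percent of
peak. The stance is therefore defined as the first run of frames with
positive force above 0.5% of peak (dips shorter than 5 frames bridged —
the same gap logic as pass segmentation), giving 38–51 frames across the
default cohort. Cropping, padding and rendering all use this window; the
raw expansion (with its ringing tail) is what the oracle and feature
paths consume, because hard truncation breaks the linear model the
estimator relies on.

**Cohorts and conditions.** Between-person spread scales α and |s0| by
`1 + separation·z` and shifts f by `separation · 0.3 Hz · z`;
`separation = 0` makes all walkers identical (the chance control).
Step-to-step jitter is multiplicative Gaussian on α and |s0| (1.5%) and
additive on f (5 mHz); measurement noise (0.05 N) acts only during
stance, since walkway sensors read exact zeros off contact. Fast walking
scales α and f by 1.15 and |s0| by 1.06 per person; feet differ by a
small fixed asymmetry. Defaults were calibrated once so that recovered
feature spread is jitter-dominated and the 16-walker accuracy falls in
the high-80s/low-90s band, and then frozen; they are study conditions,
not tuning knobs.

**Rendering.** Steps are placed along a 256 × 64 walkway (rows along the
walking direction; full instrument size 895 × 128 by config) as three
Gaussian pressure blobs — heel, metatarsal, toe — with smooth load
transfer over the stance phase. Each blob is normalized to unit sum
inside its footprint box, so the per-frame spatial integral equals the
step's (rectified) force signal exactly: integral fidelity is the
contract, anatomical fidelity a non-goal. Passes alternate direction
(odd passes stored flipped row- and column-wise, exactly undone by
direction normalization) and are separated by all-zero frame gaps; the
left foot occupies the higher columns in canonical orientation.
Rectification (clipping the signal at zero) is used in rendering because
pressures are non-negative; it is off by default in
`simulate_step_force` because it breaks the linear-model oracle.

## 6. Numerical and protocol choices

* Eigenvalue energy ordering `|v_k b_k|` inside the DMD layer; frequency
  ordering at the feature layer.
* The discrete-time reconstruction is `s_n = Σ μ_k^n v_k b_k`; feature
  scaling to physical units happens once, in the feature conversion.
* Cost ties resolve to the earliest enrolled candidate (logged).
* Pipeline runs are pure functions of config + seed; manifests record
  SHA-256 checksums of every artifact, and all JSON is written with
  sorted keys so reruns are byte-identical.
* Problem sizes: the default study uses 16 walkers × 30 steps per foot
  and speed, 1000 Monte-Carlo repeats per condition, and a pooled
  4 × 500-repeat null; the stability suite fits 208 padded steps. These
  sizes give ±2-point Monte-Carlo noise on accuracies and run in tens of
  seconds.

## 7. Limitations

* The generator and estimator share the damped-pair parameterization, so
  passing recovery tests demonstrate correctness of the implementation,
  not robustness of Hankel DMD to real plantar-pressure dynamics (model
  mismatch, sensor quantization, partial footprints, CoP shear are all
  absent).
* The synthetic lead-in and toe-off are smoother than real heel-strike
  transients; spatial blob shapes are schematic.
* The literal inverse-standard-deviation cost is scale-dominated by the
  |s0| component and degrades under heterogeneous estimation noise
  (§4); the standardized variant is more robust but is not the default.
* Identification accuracy is reported under the optimistic no-holdout
  protocol by default; holdout protocols are implemented and cost a few
  points of accuracy.
* Real eigenvalues at 0 or Nyquist frequency have no canonical place in
  a frequency-ranked pair list; they are excluded from feature sets
  unless needed to fill a deficit.
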