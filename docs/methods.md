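# Methods

## Problem and model

Optical myography infers intended finger movements from the deformation of
the forearm surface, observed as 6-DOF pose time series of fiducial markers
tracked by a camera. Each of `M = 10` markers contributes six channels
(x, y, z in meters; yaw, pitch, roll in radians), giving a feature matrix
`X` of width `P = 6M = 60`. The target is one activation column per
instructed movement (thumb rotation, thumb flexion, index flexion, combined
little/ring/middle flexion), each in [0, 1].

Two closed-form learners map features to activations, one model per degree
of freedom:

* **Ridge regression (RR):** `w = (X̃ᵀX̃ + λI)⁻¹ X̃ᵀy` on the
  bias-augmented `X̃ = [X, 1]`.
* **Random-Fourier-feature ridge (RR-RFF):** ridge on
  `φ(x) = √(2/D) cos(xΩ + β)` with `Ω_ij ~ N(0, σ²)`, `β_j ~ U(−π, π)`,
  `D = 500`. As `D → ∞` predictions converge to Gaussian-kernel ridge
  regression with kernel `exp(−σ²‖x − x′‖²/2)`; the bias column adds a
  constant `+1` to that kernel.

The intercept is a deliberate extension of the bare normal equations: the
band-passed features are zero-mean while the targets are not, so without a
bias the plateau at 1 would be unreachable. Penalizing the intercept with
the same λ keeps the closed form unchanged.

### Numerical solve

The SPD system is factorized by Cholesky (never inverted), with the dual
identity `w = X̃ᵀ(X̃X̃ᵀ + λI)⁻¹y` when features outnumber samples, and two
steps of iterative refinement. On well-conditioned systems the relative
normal-equation residual sits below 1e−8 (asserted in tests); the in-code
failure guard is 1e−4 because the verifiable residual floor grows with the
condition number — the λ = 1e−6 corner of the grid on RFF Gram matrices
legitimately reaches ~1e−6. `λ = 0` on a singular system is rejected with a
message advising λ > 0.

## Preprocessing

Undetected marker samples are replaced by the marker's last known pose
(leading gaps back-filled from the first detection; idempotent; a
never-detected marker is an error). Every channel is then band-pass
filtered with a second-order Butterworth (0.01–0.5 Hz), removing the static
pose offset and slow drift at the low end and tracking jitter at the high
end. Filtering is **zero-phase** (forward–backward, odd-reflection padding
of length `3·(order+1)`): the analysis is offline and the regression
targets an unshifted stimulus, so the phase lag of a causal pass would be
uncompensated; a `--causal` flag enables the single-pass variant for
comparison. The channel mean is subtracted before filtering (killing the DC
edge transient) and the residual column means are removed after, so feature
columns are exactly centered. Angle unwrapping across ±π is not performed
(synthetic angles stay small; a real-data concern, documented as a
limitation).

## Validation schemes

1. 10-fold CV, shuffled, all frames.
2. 10-fold CV, shuffled, plateau ("on–off") frames only — both 0- and
   1-valued plateaus count as on–off.
3. Train on all plateau frames, test on all intermediate (ramp) frames;
   grid search without cross-validation.
4. 5-fold CV on contiguous, unshuffled fifths (one repetition per fold
   under the default protocol; folds fall on repetition boundaries because
   the frame count divides evenly — otherwise equal fifths are used).
5. Contiguous fifths; train on plateau frames of four folds, test on all
   frames of the fifth.

Plateau masks are per-DOF (a frame can be on-plateau for a resting DOF
while another DOF is mid-ramp), with tolerance ε = 1e−6. Grids are
log-spaced: ten λ exponents in [−6, 0]; ten σ exponents in [−3, 3]
(100 (λ, σ) pairs). Hyperparameter selection and error reporting share the
same folds — the selected point's fold-mean NRMSE is what is reported, so
the estimate carries the usual optimistic selection bias (no nested CV).
Fit counts are exact: grid points × folds (e.g. 50 for linear 5-fold, 1000
for the kernel model at 10-fold). Within the RFF search, one (Ω, β) draw is
made per σ and reused across λ and folds, so λ comparisons are not
confounded by map resampling; the per-fold Gram matrix is shared across λ,
but each λ still performs a full factorize-and-solve fit.

NRMSE is RMSE divided by the target range; the range is taken from the full
stimulus column (1 for the standard protocol) so folds are comparable, with
a fallback of 1 for a constant target. Cross-subject aggregation reports
mean, SD (n−1 denominator) and SEM = SD/√n; significance uses the classical
pooled-variance two-tailed Student t-test (Welch and paired variants behind
flags).

## Synthetic generator

The generator reproduces the reference recording conditions: 4 movements
cued sequentially, 5 s activation + 3 s rest, 5 repetitions, 15 frames/s
(2400 frames, 160 s). Activations are raised-cosine-ramped trapezoids
("square–sinusoidal"): half-cosine ramp of `ramp_s = 1 s` up, hold at 1,
ramp down. Frames are stamped at exposure midpoints `t = (n + ½)/fps`,
which makes plateau frame counts match the closed-form
`round(fps · (flexion_s − 2·ramp_s))` (= 45) — with edge-of-frame sampling
every continuous profile samples both plateau boundaries and overcounts by
one.

Marker channels respond linearly:
`pose = baseline + G·activation + drift + noise`, with

* `G`: seeded sparse mixing, three dominant translation channels per DOF
  (~5 mm per unit activation, disjoint across DOFs) drawn on the six most
  proximal markers — finger-flexor bellies sit in the proximal forearm —
  plus ~10% cross-talk everywhere (0.5 mm translation, 2 mrad orientation);
* drift: per-channel sinusoid, 200 s period (safely below the 0.01 Hz
  high-pass edge), amplitude 2 mm / 5 mrad;
* noise: white Gaussian, SD 0.3 mm / 2 mrad — the order of fiducial-tag
  pose jitter at 720p;
* dropout: i.i.d. per (frame, marker) at rate 0.02, flagged undetected.

What the generator does **not** emulate: image formation (no rendering, no
detector), multi-DOF co-activation, biomechanical coupling or fatigue,
gross arm motion, angle wrap-around, and subject-specific anatomy beyond
the random mixing. Passing tests therefore demonstrate internal consistency
of the pipeline under a quasi-linear deformation model, not performance on
real video.

### A known floor of the noiseless configuration

The 1 s activation ramps carry spectral content above the 0.5 Hz low-pass
edge. That content survives in the raw target but is smoothed out of the
features, and in the noiseless generator every feature column is an exact
linear combination of the four filtered activation signals — so no linear
read-out can beat the projection of the target onto that span. This floor
is 0.039–0.081 NRMSE per DOF (the first DOF inflated by the filter's edge
transient at the record start), and the pipeline attains it to within 5e−3
(tested against the projection oracle). Noisy subjects score *better* under
shuffled 10-fold CV (~0.03): low-passed tracking noise is smooth in time
and acts as an implicit temporal basis that interpolates between
interleaved train and test frames — the same optimism that makes shuffled
CV the easiest scheme on real recordings. For the same reason the kernel
model appears much stronger than RR under scheme 3 on synthetic data; on
genuinely linear data without such structure the two methods are
statistically indistinguishable (p > 0.05), matching the expected
equivalence.

## Robustness procedures

* **Optical perturbations:** the affine pixel operator `f̃ = α·f + β`
  (scale, add, clip to [0, 255], round to the input's integer depth — the
  operator is exactly affine before clipping) and Gaussian blur with an
  odd k×k kernel, `σ_g = k/6` so the ±3σ support fills the kernel,
  normalized, reflected borders (mean-preserving within 1%), k up to 29.
  Applying them to camera frames requires a fiducial-detector adapter
  (frames in → trajectories out); the package ships the operators and the
  trajectory-level sweep, not a tag decoder.
* **Simulated amputee:** restrict features to the n most proximal markers
  (rows 0–2 of the 5×2 grid for n = 6, 36 feature columns) and re-run
  scheme 5. Because the default mixing places dominant deformation
  proximally, trimming changes NRMSE by < 0.01 on synthetic subjects.

## Problem sizes used in checks

Reported quantities are computed at the default session scale (10 subjects
× 2400 frames × 60 features) for the linear model; the kernel-model
comparisons use scheme 3 (single split) on six subjects, the
kernel-convergence study uses 120 training points with D ∈ {50, 500, 5000}
over 20 seeds, and the method-equivalence check uses eight 300×8 linear
datasets. Filter gains are measured on 1200 s sinusoids with 400 s edges
discarded so the 0.01 Hz transients decay below measurement precision.

## Limitations

* No real video or detector: absolute NRMSE values on camera data are out
  of reach by construction; only contracts, invariants and
  generator-controlled behaviour are validated.
* The shuffled schemes' optimism on temporally smooth signals is inherent;
  scheme 5 is the realistic figure of merit.
* Hyperparameter selection bias (shared folds) is reported as-is.
* The stimulus-synchronization contract requires exact frame-id equality
  between pose and stimulus files.
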