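# Methods

## Signal model and geometry

A 1-s, n-channel EEG window `X ∈ ℝ^{n×T}` (n = 10, T = 250 at 250 Hz) is
summarised by its spatial covariance `P = XXᵀ/(T−1)`. No mean subtraction
is applied by default — band-passed EEG is near zero-mean and the plain
cross-product is the protocol's definition — but `demean=True` gives the
textbook sample covariance. An optional shrinkage blends the estimate with
the trace-scaled identity, `(1−s)P + s·(tr P/n)I`.

Covariances are treated as points of the SPD manifold under the
affine-invariant metric. The geodesic distance is computed from the
eigenvalues of the symmetric form `P₁^{-1/2}P₂P₁^{-1/2}` (identical
spectrum to `P₁^{-1}P₂`, numerically stabler). All matrix functions (log,
exp, powers, square roots) go through a symmetric eigendecomposition with
an absolute eigenvalue floor of 1e-12 to absorb round-off.

The batch Fréchet mean uses tangent-space gradient descent with unit
step: project all matrices to the tangent space at the current estimate,
average the logs, exponentiate back; stop when the Frobenius norm of the
tangent gradient drops below `tol = 1e-9` (at most 100 iterations;
non-convergence raises and carries the last iterate). Streaming class
means take one geodesic step of length `1/α` toward each new matrix. For
feedback class means α is the running class count, which makes the stream
a uniform-weight approximation of the batch mean (verified to land within
5% of it on well-conditioned sets); the artifact-gate reference uses a
fixed α = 100 for slow adaptation. Both the per-run points and the class
means reset at run boundaries; the gate state persists across runs within
a session.

### Shrinkage default

The library function defaults to shrinkage 0, but the pipeline
configuration (engine, evaluation, band search) defaults to 0.01: a 4-Hz
band-limited 1-s window has a time–bandwidth product of ~8, below the 10
channels, so its covariance is effectively rank-deficient and the mean
iteration stalls without regularisation. 1% shrinkage is negligible for
broadband covariances and restores conditioning for narrow bands.

## Artifact gate

The Riemannian Potato keeps a reference covariance and running distance
statistics (μ, σ). It is initialised from the ten 1-s covariances of the
10-s resting baseline (1–30 Hz): reference = their Fréchet mean, μ/σ =
mean and standard deviation of their distances to it. A segment whose
1–30 Hz covariance lies further than `μ + zσ` (z = 2.5) from the
reference is rejected. Clean segments update the reference (geodesic step
1/100) and the statistics with rate w = 0.01 — μ first, then the variance
using the updated μ, then the square root (the update is a variance
recursion; taking the square root keeps the units consistent). The
baseline is filtered through the same causal path the online segments
see; mixing zero-phase baseline filtering with causal online filtering
would bias every online distance upward.

The gate always operates on the fixed 1–30 Hz band regardless of the
feedback band, so the engine maintains two parallel filter paths per
segment.

## Online loop and filtering

Online filters are causal 4th-order Butterworth band-passes with state
carried across the four contiguous MI segments of a trial and reset at
trial starts (the inter-trial signal is not streamed). Offline analyses
(evaluation, band selection) use the zero-phase forward–backward filter
instead. Each clean segment appends one row of geodesic distances to the
run's matrix (O(N) amortised via a capacity-doubling buffer), updates its
class's streaming mean, and triggers a re-embedding.

## Diffusion-map feedback

The kernel is `K_ij = exp(−δ²_ij/ε)` with ε = 20 (ε carries
squared-distance units; distances enter squared). Normalisation follows
the symmetric form `D^{-1/2}KD^{-1/2}` with D the diagonal of row sums,
whose eigenvectors are real and checkable against a dense symmetric
eigensolver; the stationary eigenpair (λ₀ = 1, eigenvector ∝ D^{1/2}·1)
is skipped and the 2-D coordinates are `λ_kφ_k`, k = 1, 2. Eigenvalues
are sorted descending; within numerically equal groups eigenvectors are
ordered by the index of their first significant component, and each
eigenvector's largest-magnitude component is made positive before
anchoring.

The two class means join the embedding as appended pseudo-points (their
distance rows are recomputed every frame because the means move), and
they participate in the kernel normalisation like any other point.
Because eigenvectors are sign-ambiguous, consecutive frames can mirror
about either axis; each new frame is aligned by flipping axes so that a
designated class-mean pseudo-point keeps its coordinate sign (sign 0
counts as +). Frames with fewer than three real points, or before both
class means exist, are emitted all-zero with a warm-up flag — with so few
points the projection is too variable to instruct.

## Learning metrics

- `ClassDis(A,B) = δ(P̄_A,P̄_B) / (½(σ_A+σ_B))` with Fréchet means and
  mean absolute deviations per class. The ratio is unbounded above; a
  vanishing denominator raises a degenerate-dispersion error rather than
  returning infinity.
- Fisher score `FS = |μ₁−μ₂|/(s₁²+s₂²)` exactly in this unnormalised
  form (sum of variances, numerator not squared); `classical=True`
  squares the numerator for comparison. Features are 2-Hz band powers of
  Laplacian-derived channels — each channel minus the mean of its
  montage neighbours (neighbour table shipped as editable JSON; boundary
  channels use the neighbours available) — computed by Hann-windowed
  periodograms in 1-s windows sliding every 62.5 ms. At 250 Hz that step
  is 15.625 samples; window starts are rounded per window so the printed
  window-count formula `floor((len−window)/step)+1` holds exactly. Note
  a Hann-windowed on-bin sinusoid leaks amplitude 0.5 into each adjacent
  1-Hz FFT bin, so its host 2-Hz bin holds at most 5/6 of total power —
  the tests assert that analytic value.
- MDM classification assigns a covariance to the class with the nearest
  Fréchet mean; exact ties break to the lexicographically first label.
  Accuracy is fivefold stratified cross-validation at the sample level
  (the protocol counts 160 1-s samples per run); a trial-level split is
  available to avoid within-trial leakage, which the sample split
  accepts by design.
- Learning trends are Pearson correlations of a per-run metric against
  the run index with the two-sided t-distribution p-value.

Metrics are recomputed offline in three band versions: `actual_online`
(broadband 8–30 Hz for sessions 1–2, the subject band after),
`broadband`, and `subject_specific`. Band selection scores all 19
overlapping 4-Hz bands (8–12 … 26–30 Hz, 1-Hz step) by run-averaged
ClassDis, excludes degenerate per-run scores as missing, breaks ties
toward the lower band, and flags the selection low-confidence when the
max–median gap is below 5%.

## Synthetic sessions

The generator emulates the physiology the protocol assumes, not any
particular recording. Each segment is spatially mixed 1/f background
noise (unit variance per source, mixing `I + 0.3G/√n` fixed per session)
plus a sinusoidal mu rhythm at 11 Hz with a random phase per segment and
10% log-normal amplitude jitter. The rhythm has a focal topography —
gain 1.0 at C3/C4, 0.6 at the surrounding electrodes — because a
spatially flat rhythm would be annihilated exactly by a Laplacian
derivation, which no real scalp rhythm is. Event-related
desynchronization multiplies the contralateral hemisphere's rhythm
amplitude by (1−g): left-hand imagery attenuates FC4/C2/C4/C6/CP4,
right-hand imagery FC3/C5/C3/C1/CP3, rest attenuates nothing. Artifacts
are Hann-enveloped broadband transients scaled to `gain ×` the clean
per-channel RMS (gain 10 inflates segment variance ~38-fold), flagged in
ground truth. Runs are balanced (20 left + 20 right cues, shuffled), and
one RNG seeded from the config drives everything, so sessions are
bit-reproducible.

The default rhythm amplitude is 0.8 against the unit background. That
ratio was fixed by a pilot run of the artifact gate: with a much stronger
rhythm the rest-to-imagery covariance shift dwarfs the baseline spread
and the gate rejects every clean segment, which no working protocol
shows; at 0.8 the gate operates realistically (sensitivity 1.0 on gain-10
artifacts, clean false-rejection ~5% over a full default session).

What the generator does not model: volume-conducted eye-blink or muscle
morphology, slow nonstationary drifts, inter-channel noise correlation
structure beyond the fixed mixing, beta-band activity, or
subject-specific rhythm frequencies. Passing tests therefore demonstrate
that the pipeline recovers the planted structure under clean SMR
phenomenology — not that it handles every pathology of real recordings.

## Problem sizes in the checks

The acceptance checks run at sizes chosen for stable estimates: the
artifact-gate operating point pools two full default sessions (800 MI
segments each, 10% artifact rate); the effect-size sweep uses one
20-trial run per seed with 20 seeds paired across g ∈ {0, 0.2, 0.4,
0.6}; the chance floor uses 50 seeds of one 20-trial run at g = 0 (80
samples per cross-validation, tightening the per-seed accuracy spread to
~0.07); band recovery uses 20 seeds of 12-trial runs at g = 0.4. Paired
seeds across effect sizes are a common-random-numbers design: the same
noise realisation underlies every g, so the sweep isolates the effect of
g itself.

## Known limitations

- The embedding recomputes a full eigendecomposition per frame; fine for
  N ≤ 162 (well under the 1-s update budget) but not for much longer
  runs.
- The streaming class mean with count-based α is order-dependent (a
  documented approximation to the batch mean).
- The sample-level CV split shares trials between train and test folds;
  use `split="trial"` when leakage matters.
- ClassDis is unbounded; comparisons across very different dispersion
  scales should prefer the per-run trend, not raw values.
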