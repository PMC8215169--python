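# riemannbci

Riemannian-geometry data-visualization feedback for motor-imagery BCI
training, as a tested, reusable streaming pipeline.

## The problem

Classifier-driven motor-imagery (MI) BCI training needs a calibration
recording before any feedback can be shown, and resets its display every
trial. An alternative is to show the subject the *geometry of their own
EEG*: each 1-s, 10-channel EEG window is summarised by its spatial
covariance matrix — a symmetric positive-definite (SPD) matrix, a point on
a curved manifold — and the accumulated pairwise geodesic distances
between all windows of a run are projected to a 2-D screen position. The
subject's task is to drive the points of the two imagery classes (left
hand / right hand) apart and to tighten each cluster. No classifier, no
calibration, and the feedback accumulates over the whole run.

This package implements that protocol end to end for simulation and
offline analysis:

- **SPD geometry** — covariance estimation `P = XXᵀ/(T−1)`, the
  affine-invariant geodesic distance
  `δ(P₁,P₂) = ‖log(P₁^{-1/2}P₂P₁^{-1/2})‖_F = (Σᵢ log²λᵢ)^{1/2}`,
  batch Fréchet means, and streaming geodesic mean updates
  `P̄ ← P̄^{1/2}[P̄^{-1/2}PP̄^{-1/2}]^{1/α}P̄^{1/2}`.
- **Riemannian Potato artifact gate** — a reference covariance (Fréchet
  mean of a 10-s resting baseline, 1–30 Hz) with adaptive distance
  statistics; a segment is rejected when its distance exceeds
  `μ + 2.5σ`, and clean segments mildly adapt the reference (α = 100) and
  the statistics (rate w = 0.01).
- **Diffusion-map feedback** — Gaussian kernel `K_ij = exp(−δ²_ij/ε)`
  (ε = 20), symmetric normalisation `K^norm = D^{-1/2}KD^{-1/2}`, and 2-D
  coordinates `Yᵢ = (λ₁φ₁ᵢ, λ₂φ₂ᵢ)` from the dominant non-trivial
  eigenpairs, with the two class means embedded as pseudo-points and axis
  signs anchored to one of them to stop frame-to-frame mirror flips.
- **Learning metrics** — the classifier-independent separability
  `ClassDis = δ(P̄_A, P̄_B) / (½(σ_A + σ_B))`, spatio-spectral Fisher
  scores `FS = |μ₁−μ₂|/(s₁²+s₂²)` of Laplacian-derived band powers, and
  fivefold cross-validated accuracy of the minimum-distance-to-mean (MDM)
  classifier, each per run and per band version, with Pearson learning
  trends across runs.
- **Band selection** — the 19 overlapping 4-Hz bands from 8–12 to
  26–30 Hz scored by run-averaged ClassDis; the winner becomes the
  subject-specific feedback band for later sessions.
- **Synthetic SMR sessions** — 10-channel 250-Hz EEG with a focal 11-Hz
  mu rhythm over 1/f background, class-lateralised event-related
  desynchronization of controllable effect size g, protocol timing
  (10-s baseline, 40-trial runs, 4 × 1-s MI segments per trial), and
  injected high-amplitude artifacts with ground-truth flags.

## A worked example

```sh
python examples/03_feedback_session.py
```

```
presented segments: 80
retained (clean):   64
rejected (gate):    16
mean:left   at (-0.0083, +0.0000)
mean:right  at (+0.0095, -0.0001)
class-mean separation on screen: 0.0178
warm-up frames before a stable projection: 2
```

A 20-trial run with a solid ERD effect (g = 0.5) and 5% injected
artifacts: the gate discards the artifacts (plus the early clean windows
it is still strict about), every retained window re-embeds the display,
and by the end of the run the two class-mean "rectangles" sit on opposite
sides of the screen — the separation the subject is trained to maximise.
The other examples walk through the geometry primitives
(`01_spd_geometry.py`), the artifact gate (`02_artifact_gate.py`), the
learning metrics and trends (`04_learning_metrics.py`) and band selection
(`05_band_selection.py`).

The same pipeline is scriptable from the shell:

```sh
riemannbci simulate --seed 7 --out session.h5
riemannbci replay --input session.h5 --out-dir replay/
riemannbci evaluate --session session.h5 --band-version broadband --out metrics.csv
riemannbci select-band --input session.h5 --out band.yaml
```

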