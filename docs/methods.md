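# Methods

## Model

The focus of attention is treated as a unitary point mass at position
`a(t)` on the retina plane. Pre-attentive feature activations act as a mass
distribution μ(x) that attracts the focus through the two-dimensional
Coulomb (inverse-distance) field

    E(a) = (2π)⁻¹ Σ_x (x − a) / (‖x − a‖² + ε) · μ(x),

and the focus obeys the damped Newtonian equation

    ä + λ ȧ − E(a) = 0.

Eight features are extracted from the stimulus: the spatial gradients of
brightness, of the three color channels (raw RGB by default; an
opponent-color transform is available as a configuration hook), and of four
oriented edge-energy maps at 0°/45°/90°/135°. Orientation maps come from an
even-symmetric (cosine-phase) Gabor bank, wavelength 8 px, envelope σ = 4 px,
with the DC component removed (a uniform image gives exactly zero response)
and a 1/(2πσ²) gain so orientation responses sit on the same scale as the
raw gradients. Each feature's mass is `μ_i = α_i ‖f_i‖` (pointwise Euclidean
norm of the gradient 2-vector); all `α_i` default to 1 — equal feature
weighting.

Inhibition of return (IOR) is a leaky memory field relaxing toward a
unit-peak Gaussian bump at the current focus,

    ∂I/∂t + βI = β g(x − a(t)),  g(u) = exp(−‖u‖²/2σ²),

and discounts the masses as μ(1 − I). Because g peaks at 1, I stays in
[0, 1] and the discounted mass can never go negative.

The winner-take-all (WTA) baseline combines the eight feature magnitude
maps with equal weight, repeatedly selects the global maximum (row-major
tie-break) and inhibits a disk of 2° of visual angle around each selection.
Its output is discrete: n fixations with uniform durations, n = 3
fixations/s × exposure. The historical proximity/similarity preference
rules are deliberately not implemented.

## Numerical integration

The equation of motion is integrated with fixed-step classical RK4 and
operator splitting: the inhibition field is frozen during the (a, v) update
and then advanced with its exact exponential solution
`I ← g + (I − g)·e^{−β dt}` about the new focus. Fixed stepping makes
trajectories bit-reproducible; the exponential IOR update is
unconditionally stable and exact in the stationary case. The focus is
clamped to the frame with the outward velocity component zeroed, which
prevents escape when masses hug the border. Divergence (non-finite state)
raises an error naming the step.

The singularity of the kernel at x = a is regularized with ε = 0.25 px²
inside the squared norm. The associated potential, used only as a test
instrument, is `U(a) = (4π)⁻¹ Σ_x μ(x) ln(‖a − x‖² + ε)`, chosen so that
−∇U = E exactly; with static mass and no IOR, `½‖ȧ‖² + U` is a Lyapunov
function (dE/dt = −λ‖ȧ‖²).

## Units, time scale and field strength

The dynamics run in dimensionless model-time units with `time_scale = 40`
units per second of viewing and `dt = 0.01` units (the evaluation protocols
use 0.02; halving dt moves a 3-second endpoint by ≪ 0.1 px). β = 0.1 per
model-time unit. With these choices a dwell lasts a few hundred
milliseconds and saccades take tens of milliseconds, matching free-viewing
statistics at a few fixations per second.

The total mass is normalized to a fixed mean density of 3.5 per pixel
before integration (`mass_density`, switchable off). The normalization
fixes the gravitational time scale independently of image contrast and
resolution; without it the same λ produces either a crawl or an
oscillation depending on how much contrast an image happens to have. Equal
feature weighting is preserved — normalization rescales the total, not the
balance between features.

Angular quantities convert to pixels through one `pixels_per_degree` scale.
The working resolution for natural images is 224×224, treated as ≈17.5° of
visual field (12.8 px/°), in the range of typical desktop eye-tracking
setups; synthetic 64×64 frames use the same 17.5° convention (≈3.66 px/°).
The IOR bump width defaults to σ = 2° — the same angular scale as the WTA
inhibition radius.

## Fixation detection

The continuous trajectory is segmented with a velocity-threshold detector
(I-VT): speeds by central differences, maximal sub-threshold runs, runs
shorter than 80 ms discarded, fixation at the run centroid. Because the
model's dwell drift scales with the time compression, protocols use an
escalating threshold ladder (60/100/150 px/s) rather than one absolute
threshold, taking the first segmentation that yields at least the window
length needed by the metrics.

## Scanpath metrics

* SED: the frame is split into m×m cells (m = 5), fixations are replaced by
  cell labels (row-major, half-open cells except the last) and the
  Levenshtein distance with unit costs is returned, unnormalized.
* TDE: every length-k window (k = 3) of the reference sequence is compared
  with all windows of the simulated one as concatenated 2k-vectors; the
  Euclidean distance is divided by k (per-fixation average, comparable
  across k) and the minimum over simulated windows is averaged over
  reference windows.
* STDE: TDE on coordinates normalized per axis by the frame size, mapped
  through exp(−d) into a similarity in (0, 1]. The exponential map is the
  standard distance→similarity transform and keeps reported values in the
  range conventionally printed for this score.
* NSS: the saliency map is z-scored over pixels and sampled at the nearest
  pixel to each fixation; the mean sampled value is returned.

Multi-observer evaluation averages each metric over observers, skipping
pairs that fail a metric's preconditions (with a warning); aggregation over
images is a plain mean with the standard deviation reported alongside.

## Parameter tuning

`grid_search_tune` simulates the model at every lattice point of a
parameter grid on held-out images, accumulates a Gaussian of 1° at each
detected model fixation into an empirical saliency map, scores it with NSS
against the pooled human fixations, and returns the argmax (ties break
first-in-grid). The estimator facade `GravityScanpathModel.fit` wraps this
procedure; β is kept at 0.1 — varying it has little effect — and the search
is primarily over the damping λ.

## Synthetic data

The generator produces gray frames with Gaussian blobs (smooth or
noise-textured), uniform squares and i.i.d. noise patches, all
reproducible bit-for-bit from a seed, and synthetic observers that visit a
given attractor sequence with Gaussian positional jitter and lognormal
durations (30 ms saccade gaps, cumulative onsets). The observer model is
deliberately minimal: no saccadic main sequence, no center bias, no
fixational tremor. Passing the synthetic benchmarks therefore shows that
the model ranks above the baseline under controlled attractor geometry; it
does not certify performance on natural images or real eye-tracking data.

### Behavioral regimes and the benchmark design

The 1/r kernel is long-ranged: on a scene of several equal, well-separated
mass concentrations the aggregate far field dominates local structure.
Underdamped (λ ≈ 1 at the default field strength), the focus oscillates
about the scene's global center of mass and IOR only jiggles it; strongly
overdamped, it creeps to an equilibrium where the inhibition bump exactly
cancels the local pull — a true fixed point of the IOR dynamics — and
freezes. In both regimes fixations land between objects, an intrinsic
property of the model on symmetric multi-object scenes (on natural images
mass is spread broadly, so the far field largely cancels). With a single
dominant concentration the model parks within a fraction of a pixel of its
centroid.

The model-comparison benchmark therefore uses paired-object scenes: two
equally strong, compact, lightly textured objects (σ = 3.8 px, amplitude
0.6, texture sd 0.5, 24–30 px apart) plus two weak distractors. Attention
alternates between the two centroids under IOR — several well-centered
fixations per exposure — while the baseline, whose 2° inhibition disk
covers a compact object whole, is forced from the objects' contrast maxima
onto distractors and background after its first selections. Synthetic
observers alternate between the two object centroids with 2.5 px jitter,
the natural free-viewing pattern on a two-object display. Texture matters
twice: it fills the object interior with gradient mass (a smooth blob's
gradient lives on an annulus, which by the 2-D shell theorem exerts no
inward pull from inside), and it keeps the contrast maximum the baseline
selects slightly off-center.

The three-blob exploration protocol uses a wider IOR bump (3°) than the
package default: with three equal smooth blobs the bump must suppress a
whole annulus of mass to release the focus, and the 2° bump makes
within-pair cycling too sticky at that geometry.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| λ | 1.0 | damping; calibrated by NSS grid search in `fit` |
| β | 0.1 | IOR relaxation rate per model-time unit |
| σ_ior | 2° | IOR bump width (3° in the exploration protocol) |
| ε | 0.25 px² | kernel regularizer |
| α_i | 1 | equal feature weighting |
| mass_density | 3.5 | mean mass per pixel after normalization |
| dt | 0.01 | integrator step, model-time units |
| time_scale | 40 /s | model-time units per second of viewing |
| duration | 3 s | exposure (5 s for longer-exposure datasets) |
| speed threshold | 50 px/s | I-VT default (ladder 60/100/150 in protocols) |
| min fixation | 80 ms | I-VT minimum duration |
| grid_m, embed_k | 5, 3 | SED cells per side, TDE window length |

## Known limitations

* Fixation offsets of a few pixels from object centroids are intrinsic on
  multi-object scenes (partially inhibited objects are pulled toward their
  neighbors); the reported benchmarks measure the model against the
  baseline under the same conditions rather than against an absolute
  centering criterion.
* Static images only; the per-step loop would accept a time-varying mass
  but no video input path is provided.
* The velocity-threshold detector is the simplest standard choice;
  dispersion- or HMM-based detectors may segment the model's slow drift
  differently.
* Absolute values of SED/TDE/STDE depend on unreported metric
  hyper-parameters (m, k, the similarity transform); comparisons in this
  package are therefore directional, between models under identical
  settings.
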