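# Methods

`igrtqa` re-solves a planar patient-setup registration independently of the
clinical treatment-machine software, so that the clinically applied couch
correction can be double-checked by an algorithm with a *different* metric
and optimizer. This note records the model, the numerical choices, and what
the synthetic phantoms do and do not establish.

## Registration model

A registration aligns a moving kV radiograph onto a fixed reference DRR by
minimizing an intensity cost over an in-plane rigid transform
`T = (tx, ty, θ)` acting in physical millimetres about a configurable
centre (default: the fixed image's physical centre). Sample points that a
candidate transform maps outside the moving image are excluded through an
overlap mask rather than zero-filled; a parameter point whose valid overlap
drops below 25 % of the reference is treated as infinitely bad (a sentinel
cost of `inf`), which bounds the search without raising mid-optimization.
Resampling is bilinear: for noisy kV data the robustness of a low-order
interpolant is preferred over the smoothness of cubic schemes, and the
interpolator is isolated in one function should that trade-off be revisited.

Two orthogonal planar solutions (AP and lateral) are fused into a 5-DOF
couch correction under a fixed view convention: AP x → lateral shift,
AP y and LAT x → longitudinal (averaged, with their disagreement reported
as a consistency diagnostic), LAT y → vertical, AP rotation → couch yaw,
LAT rotation → couch pitch. The convention is configurable in the sense
that any flips belong to the image reader, not the fusion rule.

## Cost functions

All metrics share the convention *lower is better* and are averaged over
the valid mask so values are comparable across overlap sizes (a summed
variant would reward transforms that shrink the overlap).

* **NCC** — negated Pearson correlation of the masked pixel pairs. Exactly
  −1 under any positive linear intensity relation; undefined (sentinel) on
  constant regions.
* **Gradient difference** — mean over interior masked pixels of the squared
  difference of central-difference gradients (row and column, per mm).
  Implemented literally as a mean of squared gradient differences; the
  variance-normalized reciprocal variant found elsewhere in the
  registration literature is available behind `normalized_graddiff=True`.
* **Mean reciprocal squared difference (MRSD)** — `−mean(1 / (1 + d²/λ²))`
  with `d` the intensity difference and λ the capture radius (default 0.1
  in normalized intensity). Each pixel's contribution saturates for
  differences beyond a few λ, which sharpens sensitivity near the optimum
  and flattens the far field; the printed source for this metric's exact
  reciprocal form is ambiguous, and the standard Lorentzian form above is
  the one implemented.

## Preprocessing

A DRR and a kV radiograph are related by an unknown monotone intensity map
(detector response, technique factors). Before any metric is evaluated the
moving kV image is histogram-matched onto the fixed DRR: quantile
landmarks (default 7, estimated from a 1024-bin histogram CDF) of the
foreground — pixels above the image mean, excluding the dark background —
are mapped piecewise-linearly onto the reference's landmarks. The low end
of the map is anchored at the full-image minima so the excluded background
maps into the reference's background range instead of being extrapolated
off-scale. Both images are then linearly normalized to [0, 1] (this fixes
the scale that MRSD's λ refers to). The remap is monotone non-decreasing
by construction, so it can in principle invert the monotone degradation;
matching is applied once per registration and cached, not per evaluation.
Matching direction is kV → DRR because the DRR is the planning-derived
standard.

## Optimizers

Both optimizers search in a *scaled* parameter space: raw parameters are
multiplied by per-parameter scales (default 1 per mm, 0.5 per degree — one
scaled unit of rotation is roughly the border displacement a degree of
rotation induces ~30 mm off-centre), so a single step-length schedule
covers mixed units.

* **Regular-step gradient descent** (deterministic): unit-gradient steps
  (central finite differences, probe `min_step/10`), step length starting
  at 2 scaled units, multiplied by 0.9 whenever the gradient direction
  reverses, stopping at 200 iterations, a step below 0.01, or a scaled
  gradient magnitude below 1e−5 (the inter-iteration change of the
  magnitude is also recorded in the trace for diagnosis). A step landing
  on a sentinel cost is rejected and the step halved.
* **One-plus-one evolutionary strategy** (stochastic, elitist): a single
  parent perturbed by an isotropic Gaussian of radius r (initial 1 scaled
  unit); on improvement the child becomes parent and r grows by 2, capped
  at 30 scaled units (the landscape extent, preventing divergence on flat
  regions); on failure r shrinks by 2^(−1/4) (the conventional quarter-
  power companion of a growth factor of 2). Stops when r < 1.5e−6 or at
  2000 iterations. One explicit seeded generator per run; traces are
  bit-reproducible.

Every run records a per-iteration trace (cost, parameters, step/radius,
acceptance) and a stop reason; the best-so-far cost sequence is
non-increasing by construction for the evolutionary strategy and tracked
explicitly for gradient descent, which returns the best point evaluated.

## Landscape diagnostics

`map_search_space` evaluates a metric exhaustively on a translation grid
(default ±30 mm at 1 mm, rotation held at zero — rotation maps are out of
scope). Two summaries quantify what a practitioner reads off such a map:

* `count_local_minima`: interior nodes strictly below all 8 neighbours by
  more than a depth tolerance, default 1 % of the map's cost range. The
  tolerance screens sub-prominence ripples; a sweep over tolerances is
  reported by `minima_tolerance_sweep` because no canonical value exists.
  Note that with this screen a *broad* basin's minimum does not count as a
  "spot": the diagnostic counts prominent, trap-like minima.
* `basin_width`: extent of the connected region around the global minimum
  within a fraction (default 10 %) of the cost range, i.e. how sharply the
  optimum is defined.

## Synthetic phantoms

Phantoms are rendered analytically from ellipse/rectangle primitives with
4× supersampling, so the planted transform is exact and landscapes are
smooth at sub-millimetre scale. The kV counterpart is produced by
re-rendering the scene under the planted transform, then applying a
monotone degradation `v → contrast · clip(v,0)^γ + offset` plus additive
Gaussian noise (optionally Poisson-like shot noise), emulating the
nonlinear detector response, reduced contrast and quantum noise of a
flat-panel radiograph against a computed DRR.

Two anatomy presets model two distinct clinical situations:

* `head_shoulders` (default) — an aperiodic head-and-shoulders scene with
  a single well-conditioned similarity basin. Default degradation
  γ = 1.8, contrast 0.6, offset 0.05, noise σ = 0.02 (moderate technique
  mismatch). Used for convergence, recovery, optimizer-agreement and
  capture-range studies.
* `cspine` — a cervical-spine scene with a periodic vertebral column
  (16 mm pitch) and low-contrast airway/lung features, degraded with
  γ = 3.5, contrast 0.5, offset 0.05, σ = 0.002 (severe soft-tissue
  compression at low noise). Shifting by one vertebral pitch re-aligns
  most of the *visible* bone in the raw kV image, producing secondary
  NCC basins whose relative prominence exceeds the 1 % screen; histogram
  matching restores the aperiodic soft-tissue context, deepening the true
  basin until those alias minima fall below the screen. Used for the
  landscape and preprocessing-necessity studies.

The presets are deliberately separate: a periodic column genuinely
destroys the multi-centimetre capture range (both optimizers can lock onto
a one-pitch alias), so the conditions that exhibit landscape multimodality
and the conditions that exhibit a 2 cm capture range cannot be one and the
same scene — clinically they are different patients.

An articulated variant moves skull-group and body-group primitives by
different transforms (e.g. a flexed neck), in which case no single rigid
truth exists; both component truths are returned so optimizer disagreement
can be studied as a signal rather than an error.

What the phantoms do **not** model: scatter, beam hardening, detector
vignetting or lag, collimation borders, overlay burn-ins, and genuinely
deformable anatomy. Passing tests therefore establish correctness of the
algorithmic pipeline under a monotone-intensity, rigid (or piecewise-rigid)
image model — not clinical performance on real radiographs.

## Batch simulation and QA thresholds

`make_case_batch` draws planted transforms uniformly (defaults ±15 mm,
±3°), simulates the "clinical" correction as truth plus Gaussian jitter
(defaults σ = 0.3 mm / 0.1°, roughly the registration reproducibility of
a well-behaved case), and can plant outlier discrepancies and articulated
cases. QA thresholds default to warn at 2 mm / 1° and error at 3 mm / 1.5°,
magnitudes at which planar-registration disagreement is clinically
investigated; they are configuration, never hard-coded. Batch statistics
(means, exceedance fractions at 3 mm / 1°, maxima) are computed exactly
over the supplied reports. Report files carry an OK/WARNING/ERROR status
and the process exits 0/1/2 accordingly so schedulers can dispatch
notifications; notification transport itself is out of scope.

## Problem sizes used in the shipped studies

The reference pair is 256×256 at 1 mm spacing — large enough for ±30 mm
searches to retain the required 25 % overlap. The test suite runs most
registrations on 128×128 phantoms and the landscape studies on coarse or
reduced-range grids; the acceptance script uses the full 256 mm scale with
a 20-case batch and 10-start multistarts. These sizes were chosen so the
whole verification runs in minutes on one CPU while keeping every
qualitative regime (multi-centimetre captures, sub-millimetre agreement)
intact.

## Known limitations

* 2D/2D orthogonal-pair workflow only; 3D/2D registration, DRR ray-casting
  and Mattes mutual information are explicit non-goals.
* Landscape maps cover translations only; rotation is held at zero.
* The gradient-difference metric is sensitive to noise amplified by
  histogram matching in severely compressed regions; it is provided for
  comparison, while NCC is the recommended default.
* The fusion rule assumes ideal orthogonal view geometry; real imager
  flips/rotations must be normalized upstream.
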