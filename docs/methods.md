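# Methods

## Count-distribution nulls

The window of area S = a² is partitioned into N = m² sections of area
D = S/N.  Three nested models predict the distribution of the number of
cells x found in one section when n cells occupy the window.

**Hypergeometric (excluded-area seat model).**  Discretize the window
into M = S/A seats of one cell area A, K = D/A per section; n cells
occupy n distinct seats.  Then

    P(x) = C(K, x) C(M−K, n−x) / C(M, n)
    mean = nK/M,   var = (nK/M)(1 − K/M)(M − n)/(M − 1)
    VMR  = (1 − 1/N)(M − n)/(M − 1)

The ratio to the binomial VMR is exactly (M − n)/(M − 1).  Evaluation
goes through `scipy.stats.hypergeom` (log-gamma arithmetic), stable to
M ~ 1e8; the test suite carries an exact big-integer oracle
(`math.comb` + `Fraction`) for small M.

The seat picture needs a map from the physical cell to the seat area A.
The package defaults to the circumscribing-circle area A = π(d/2)²; a
square footprint A = d² is available (`seat_model_params(...,
footprint="square")`).  M = S/A and K = D/A are generally non-integer
for physical parameters; they are rounded to the nearest integer and the
residuals are reported in the returned metadata.  At the reference
density (n = 185, a = 1150 µm, d = 10 µm) the circle footprint gives
M ≈ 16 839 and a hypergeometric/binomial VMR ratio of 98.9%.

**Binomial** is the A → 0 (M → ∞) limit at fixed p = K/M = 1/N:
mean np, variance np(1 − p), VMR = 1 − 1/N.  **Poisson** is the further
n → ∞, p → 0 limit at λ = np: VMR = 1.  `hypergeometric_to_binomial_limit_check`
quantifies the first convergence as a sup-norm pmf distance along an
increasing M sequence.

## Excluded-volume placement simulator

Each frame places n cell centers uniformly in [0, a)² subject to the
hard-core constraint ‖xᵢ − xⱼ‖ ≥ d (closed inequality; a separation of
exactly d is legal).  Placement is sequential random adsorption: each
cell redraws uniform proposals until one clears every already-placed
cell.  Pinned stationary-cell coordinates are inserted first and are
bit-identical in every frame.  Numerical guards:

- proposal budget 10⁴ per cell; exhaustion raises `PlacementError`
  (a frame that cannot be completed is aborted, not restarted);
- a fail-fast feasibility guard at packing fraction 0.3, far above the
  φ ≈ 0.01 regime of interest and safely below the RSA jamming coverage
  (≈ 0.55 for disks);
- one `numpy` Generator per run, seeded once; frames draw from the
  continued stream, so a single integer reproduces the whole run.

With d = 0 the procedure reduces to plain uniform sampling; the pooled
quadrat VMR then matches 1 − 1/N and the KL divergence from the binomial
pmf is small.  Note the plug-in KL estimator has positive bias of order
(number of occupied bins)/(2 · samples) ≈ 9 × 10⁻⁴ at 900 frames and
m = 4, which sets the scale of the values observed.

## Quadrat statistics

Sections are half-open [low, high) boxes: the index of a point is
⌊x m / a⌋, so a center exactly on an internal boundary is counted in the
right/upper compartment; a center exactly at x = a or y = a is clamped
into the last row/column (the window edge case is not covered by the
boundary rule and must be fixed somehow; the clamp keeps the count).
Pooled statistics use the sample variance (denominator n_samples − 1);
with ≥ 3600 section-frame samples the choice is numerically immaterial
but it is fixed for exact tests.

The Kullback–Leibler divergence is computed in the direction
D(empirical ‖ model) = Σ q(x) ln(q(x)/p(x)) over occupied bins, natural
log; a model zero under empirical mass yields +∞ with a warning rather
than an exception.

Area fraction is n̄ π(d/2)²/a²; volume fraction n̄ (4/3)π(d/2)³/(a²t)
for chamber thickness t.  (At the reference numbers n̄ = 185.18,
d = 10 µm, t = 10 µm the literal volume-fraction formula gives ≈ 0.73%;
reports of 0.76% for equivalent settings are not reproducible from the
printed inputs and the package implements the literal formula.)

**Radial distribution function.**  g(r) is estimated from ordered pair
displacements binned in annuli of width Δr, with the translational edge
correction: a pair with displacement (dx, dy) in the a × a window gets
weight a²/((a − |dx|)(a − |dy|)), the inverse of the fraction of window
translations keeping both members visible.  Normalization uses the
unbiased pair intensity n(n − 1)/a⁴ summed over frames, so a homogeneous
Poisson pattern yields g → 1 without further calibration.  Frames with
fewer than two points are skipped with a warning.  The estimator
requires r_max < a/2.

## Trajectory preprocessing

**Thinning.**  `thin_frames(traj, stride)` keeps frames whose raw index
is a multiple of the stride and renumbers them by integer division, so
fps divides by the stride and consecutive analyzed frames differ by one
index; thinning with strides s₁ then s₂ equals thinning once with s₁s₂.

**Steady-state trimming.**  After loading a chamber, cells flow in and
out of the field of view until the in-window count plateaus.  The
detector averages the per-frame counts over consecutive non-overlapping
windows (default 120 s) and returns the earliest window from which every
subsequent window-to-window relative change stays below `rel_tol`
(default 0.05).  The default tolerance is set by the noise floor of the
emulated data: per-frame counts are autocorrelated (window residence
~10 s), so 120 s window means at n̄ ~ 100 fluctuate by 3–4%; a 1%
tolerance would never latch.  When no plateau exists the configured
fallback trim (default 20 min, a conservative bound for this kind of
recording) is returned with a warning, which `trim_transient` propagates
into the run summary.

**Stationary-cell detection.**  Speed between consecutive analyzed
frames is displacement × fps.  A particle is stationary if it has a run
of consecutive frames — gaps break runs, conservatively treating missed
detections as distinct adhesion events — with every speed strictly
below 18 µm/s and dwell strictly exceeding 30 s.  The dwell of a run
with k detections is k/fps, so at 1 fps a run needs ≥ 31 low-speed
positions.  Each qualifying particle contributes exactly one pinned
point (adhered cells have one location): the mean position over its
longest qualifying run.

## Synthetic trajectory generator

The generator emulates the recording geometry end to end: a circular
chamber (default diameter 2 mm) with a central square observation window
(default 1150 µm), cells of 10 µm diameter, recorded at 30 fps.  Only
positions inside the window are emitted, so tracks are interrupted when
cells exit — the tracker sees a finite field of view — and per-frame
counts fluctuate through influx/outflux.

- **Movers** follow a persistent random walk: per-cell speed drawn once
  from N(100, 10) µm/s (clipped at 0), heading diffusing with
  rotational diffusivity 0.5 rad²/s, step length v/fps.  The
  persistent-random-walk choice (over run-and-tumble) is deliberate:
  only the speed scale and density matter for the downstream spatial
  statistics, and heading diffusion is the simplest dynamics with a
  tunable persistence.
- **Walls** reflect: a step crossing the chamber boundary is folded back
  radially and the heading flipped.  No wall adhesion is modeled.
- **Excluded volume** during motion is enforced by step rejection: cells
  of a pair that would end closer than d stay in place for that frame
  and redraw their heading.  At φ ≈ 0.01 rejections are rare; no force
  resolution is attempted.
- **Stationary cells** (ids 0..k−1) are pinned inside the window for the
  whole recording at mutually feasible positions.
- **Transient**: `transient_extra` adds that fraction of extra cells,
  initially inside the window, which leave with exponential lifetime
  `transient_tau_s` (default 300 s).  The in-window count then decays
  toward the steady value; because the extras also redistribute across
  the chamber during their first ~20 s, `fit_transient_decay` excludes
  the initial mixing period before fitting A e^{−t/τ} + B by nonlinear
  least squares.

The ground-truth record carries the planted stationary ids/positions and
per-frame true window counts, and the emitted file reproduces those
counts exactly (round-trip integrity is tested).

### What the generator does and does not emulate

It reproduces the density, speed scale, hard-core exclusion, open-window
count fluctuation, pinned-cell inhomogeneity and loading transient of a
real recording.  It does **not** model phototaxis, bioconvection,
hydrodynamic swimmer–swimmer coupling, cell-size heterogeneity, tracking
errors (broken/merged tracks, localization noise) or illumination
inhomogeneity.  Passing tests therefore demonstrate that the *analysis
pipeline* is correct under the stated statistical structure, not that
real recordings are free of those effects.

## Study conditions and problem sizes

Simulation-based checks use the reference conditions throughout: a
1150 µm window, d = 10 µm, 185 cells per frame (area fraction 1.1%),
900 frames, partitions m = 2..10, and 20 replicates where replicate
means are compared (excluded-volume depression, stationary-cell
elevation).  The stationary-cell arm pins 20 clustered cells inside a
single 115 µm corner patch so the cluster lies in one section at every
partition m ≤ 10.  Cross-module consistency between the swimmer
generator and the placement simulator is evaluated at matched *per-frame*
counts: the open observation window makes the per-frame total fluctuate,
and that fluctuation (variance ≈ var(n_t)/N per section) is shared by
both arms under count matching, isolating the spatial structure under
comparison.

## Known limitations

- The hypergeometric seat model ignores that continuous random packing
  cannot reach 100% occupancy; at φ ≳ 0.1 it diverges noticeably from
  the placement simulator (which is the reason the simulator, not the
  closed form, is the reference for the excluded-volume effect).
- The RSA placement is sequential, not an equilibrium hard-disk
  ensemble; at φ ≈ 0.01 the difference is negligible but grows with
  density.
- The KL divergence of an empirical histogram is biased upward by
  finite sampling; values at the 1e−3 scale for 900-frame runs are
  dominated by that bias, not by model mismatch.
- `detect_steady_state` assumes the plateau is approached from one side
  within the recording; oscillatory counts (e.g. bioconvection) would
  need a different criterion.
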