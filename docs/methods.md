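# Model and methods

## The model

`thetasweeps` implements a mechanistic model of how hippocampal place cells
could acquire behavior-dependent theta sweeps from *internally generated*
sequences. The place-cell layer is a 1-D continuous-attractor rate network
of N = 250 units. Unit activation r follows

    tau_r dr/dt = -r + i_theta + W_rec((1 - d) ⊙ f ⊙ sigma_r(r)) + i_init + i_ext

with tau_r = 5 ms and logistic output sigma_r(x) = 1/(1 + e^{-alpha_r(x - x_r)}),
alpha_r = 6, x_r = 0.5.

* **Theta drive.** i_theta = -(i_max - i_min) e^{kappa cos(theta)}/e^{kappa} + i_max
  with kappa = 12, i_max = 1.6, i_min = -1, theta the phase of a free-running
  8 Hz oscillation. The drive is strongly excitatory over most of the cycle
  and collapses to a narrow inhibition trough around theta = 0 that silences
  the network between cycles.
* **Recurrent weights.** W_ij = (w_max - w_min) e^{-(i - j - delta)^2 / 2 sigma^2} + w_min,
  delta = 0.6, sigma = 5, w_max = 0.5, w_min = -2.8: a translation-invariant
  Gaussian profile on the unit index with a uniform inhibitory floor and a
  small forward asymmetry. The asymmetry makes the activity bump propagate
  up the index at roughly delta/tau_r ≈ 120 units/s while the drive is on.
* **Short-term plasticity.** Presynaptic facilitation f (tau_f = 0.32 s,
  baseline f0 = 0.14) and depression d (tau_d = 0.06 s) follow
  tau_f df/dt = -f + (1 - f) sigma_r + f0 and tau_d dd/dt = -d + sigma_r
  (fixed points f* = (s + f0)/(1 + s), d* = s for constant drive s). When
  the trough releases the network, the new bump forms at the units whose
  outgoing synapses are most facilitated and least depressed — slightly
  ahead of where the previous cycle's bump *started* — so successive sweeps
  advance: theta sequences are generated without any spatial input.
* **Spatial input and anchoring.** 128 frozen, weakly spatially tuned
  features s(x) (smoothed noise in [-1, 1] on 1 cm bins) reach the network
  through plastic weights W_s: i_ext = beta_max · beta_theta · sigma_s(W_s s),
  beta_max = 0.4, dendritic logistic with alpha_s = 12, x_s = 0.7, and gate
  beta_theta = e^{kappa_s sin(theta)}/e^{kappa_s} (kappa_s = 2) peaking at
  theta = pi/2, early in the cycle. W_s starts at 0 and learns with the
  normalized Hebbian rule tau_w dW_s/dt = beta_theta (sigma_r(r) - i_ext) ⊗ s,
  tau_w = 20 s. Because the internal sequence advances at a fixed pace in
  unit space while the animal covers ground at v̄(x), units become anchored
  to positions spaced proportionally to the local typical speed — the
  *elastic map*.
* **Behavior.** The virtual rat runs 30 laps (1 ms Euler steps) on a 200 cm
  track with a triangular target speed profile (15 cm/s at the ends,
  80 cm/s mid-track) multiplied by smooth noise (white noise convolved with
  a 2 s Gaussian kernel, affinely scaled to [0.5, 1.5] over the session).
  At each lap start the rat teleports to x = 0, r and d reset to 0, f to
  f0, and the first five units receive a beta_theta-shaped kick for one
  theta cycle of lap-elapsed time; theta itself is never reset.

## Analyses

All analyses operate on sigma_r(r) (and on i_ext for the "true" fields),
recorded every millisecond, with the first 80 s discarded as the learning
transient.

* **Activation maps**: mean activation per unit per 2 cm bin, smoothed with
  a normalized 3 cm Gaussian (reflective boundaries); empty bins are
  flagged and linearly interpolated before smoothing.
* **Place fields**: one field per unit with map peak ≥ 0.2 whose profile
  drops below 50 % of the peak on both sides before the track ends; field
  size is the extent above 10 % of the peak (interpolated crossings; if one
  side never crosses, size = twice the peak-to-crossing distance and the
  field is marked incomplete — incomplete fields are excluded downstream).
* **True fields** use the identical pipeline on the spatial drive. One
  normalization is required: i_ext carries the multiplicative theta gate,
  so its raw time average is bounded by beta_max⟨beta_theta⟩ ≈ 0.12 and an
  absolute 0.2 threshold would retain nothing. Each bin's mean i_ext is
  therefore divided by that bin's mean beta_theta, recovering the spatial
  envelope beta_max·sigma_s(W_s s(x)) on a 0–0.4 scale where the same
  threshold is meaningful. Peak positions are essentially unaffected.
* **Field shift / onset look-ahead**: backward shift = true peak − measured
  peak; onset look-ahead = true peak − measured field start; both are
  converted to time by dividing by the occupancy-weighted mean of v̄(x)
  over the measured field's extent.
* **Phase precession**: mean activation per (2 cm × 20°) position-phase
  bin; the slope is fitted with scipy's orthogonal distance regression on
  the in-field bins with activation ≥ 10 % of the in-field maximum,
  weighted by activation. Phase is periodic, so the fit is repeated for
  every 360° branch cut at a phase-bin boundary and the branch with the
  lowest weighted orthogonal residual wins. ODR (total least squares) is
  essential for the near-vertical clouds at the slow track ends, which
  ordinary least squares flattens.
* **Instantaneous-speed ratios**: in a 45-lap session, field sizes and
  precession slopes are recomputed twice using only the steps in the top or
  bottom 20 % of instantaneous speeds *within each spatial bin*; the
  top/bottom ratio per unit quantifies (in)variance to instantaneous speed.
* **Field density**: place-field peaks (one per unit with peak ≥ 0.2;
  edge-cut fields keep their peak) counted in 10 cm windows with 2 cm
  stride, against the window-mean v̄. The edge-cutoff filter is *not*
  applied here: it would deplete exactly the slow end-of-track windows and
  distort the density-speed relation, and a peak is well defined for a
  cut-off field.
* **Decoding**: represented position per step is the 2 cm bin whose
  template (the unit's smoothed measured map column) has the highest
  Pearson correlation with the instantaneous population vector; ties go to
  the lowest bin, steps with all activations ≤ 0.1 or zero variance are
  invalid (this removes the inhibition troughs). Theta cycles are segmented
  at theta = 0; each is split into ten 36° windows anchored at the cycle
  start. Look-behind = mean real − mean decoded position in the first
  window with valid steps; look-ahead = mean decoded − mean real in the
  last; length = decoded(last) − decoded(first). Cycles are excluded when
  the first or last track bin wins anywhere in the cycle (boundary
  artifact) or when the cycle contains a lap teleport (the mean real
  position is then meaningless).

## Numerical choices

Forward Euler at dt = 1 ms throughout (the behavioral step size); a
step-halving test keeps the one-cycle integration error of r under 1 %.
Within a step: drives are computed from the current theta and x; r is
updated with the pre-update f, d, sigma_r; f and d with the pre-update
sigma_r; W_s with the post-update sigma_r — any consistent explicit order
is O(dt)-equivalent. The integration core is a numba-compiled loop; a plain
numpy stepper with identical semantics is kept as the reference
implementation and the two are cross-checked in the tests. Unit indices and
positions are 0-based; all spatial bins are half-open [lo, hi). Randomness
flows from one master seed through `numpy.random.SeedSequence` into
independent behavior and feature streams per run; every run of an
experiment re-draws both (each run is a fresh track). Non-finite state
aborts a run with a diagnostic.

## What the synthetic behavior does and does not emulate

The generator produces smooth lap-to-lap speed variability around a fixed
position-dependent mean, which is what the anchoring rule must average
over. It does not model pauses, reversals, reward consumption, 2-D
movement, or speed-dependent theta frequency; passing tests therefore speak
to the model's internal consistency under idealized running, not to fits of
any experimental dataset.

## Design choices where the design was open

* The spec's command-line surface is provided as a thin two-verb wrapper
  (`run`, `report`) over the library; finer verbs (simulate/analyze/decode
  separately) would require persisting multi-hundred-MB state traces that
  the library pipelines through memory instead.
* Field shifts are stored backward-positive (true − measured), matching the
  direction in which the quantity is discussed and plotted.
* The optional speed-modulated propagation extension is exposed as
  `NetworkParams.delta_speed_gain` (the recurrent asymmetry delta scaled by
  1 + gain·(v/v̄ − 1) per step), default off.
* Theta is free-running across lap teleports; the lap-start kick window is
  measured in lap-elapsed time (125 ms), not phase-aligned.

## Known limitations

* With the stated parameters the internal sequence advances ~2.6 units per
  theta cycle before anchoring (u0 ≈ 26 units/s), so a 30-lap session uses
  roughly 150 of the 250 units. All *temporal* shift statistics scale with
  1/u0; the package reports what the equations produce (pooled backward
  shift ≈ 330 ms, onset look-ahead ≈ 950 ms under default conditions)
  rather than calibrating the emergent propagation speed.
* Anchoring acts as slow negative-feedback error correction: the
  cycle-start bump position tracks the learned unit-position map with ~2
  units of jitter, but the per-cycle advance is not instantaneously
  proportional to v/v̄. Field properties are consequently only
  approximately invariant to instantaneous speed: the top/bottom-20 %
  ratio distributions are centered near 1, with the size-ratio mean
  slightly above 1 (fields stretch a little when running faster than
  usual). For the same reason the backward field shift is about twice the
  decoded look-behind, so the binned look-behind-vs-shift relation falls
  below the identity line.
* The input weights do not converge to a fixed point within a session: the
  Hebbian rule keeps strengthening saturated inputs slowly, so the
  spatial-input fields are broader than the region a unit is currently
  anchored to, and field positions creep backward by ~1 cm per lap late in
  the session. Analyses average over the post-80 s window.
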