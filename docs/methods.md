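# Methods

## Problem and scope

`vsom` implements and compares three vestibular-only spatial-orientation
models for motion perception and motion-sickness prediction: the subjective
vertical model (SVM), a multi-sensory observer model (MSOM) and a particle
filter model (PFM).  All three take head-frame specific force
`f_h = a - g` (otoliths) and head angular velocity `omega_h` (semicircular
canals) and emit estimates of gravity, acceleration, velocity, angular
velocity and orientation.  The difference between sensed afferents and the
internal model's prediction of those afferents — the sensory conflict — is
the assumed driver of motion sickness, accumulated as

    MS(t) = \int_0^t W . |c(t')| dt'

with one fitted non-zero weight per model (gravity conflict for the SVM,
otolith magnitude conflict for the MSOM, angular-velocity conflict for the
PFM).  A Hill-saturation + second-order-filter head (the classic motion
sickness incidence model, `P/(mu s + 1)^2` on `(c/b)^n/(1+(c/b)^n)`) is
provided as a configurable alternative; no published values for
`(b, n, P, mu)` ship with the package.

Everything is simulated in darkness; visual channels, posture dependence,
habituation/sensitization and amplitude thresholds are out of scope.

## Stimuli

Motion paradigms are produced by a three-joint serial kinematic chain
(revolute/prismatic joints with arbitrary axes, trajectories and link
offsets).  Forward kinematics give head orientation and position; angular
velocity is assembled analytically from the joint axis rates, and inertial
acceleration comes from second-order central finite differences of position
(the grid is padded by two samples on each side so no one-sided stencil
touches the returned window; centripetal magnitudes are accurate to <0.1%
at `dt = 0.01 s`).  Head frame: x forward (naso-occipital), y left, z up;
gravity `(0,0,-9.81)` in the earth frame, so an upright stationary head
senses `+9.81` on head z.

Defaults per paradigm (all configurable):

| paradigm | defaults | notes |
|---|---|---|
| EVAR | 30 deg/s yaw | earth-vertical, upright |
| OVAR | 15 deg tilt, 30 deg/s | spin about the tilted long body axis |
| CENTRIFUGE | 250 deg/s, r = 0.54 m | upright, radius along head y |
| CCCP | 138 deg/s yaw; 45 deg roll steps, 2 s move, 10 s dwell | rolls toggle 0 <-> 45 deg about head x |
| PRP | +-15 deg roll at 0.2 Hz | |
| LTA / VTA | 0.89 m/s^2 peak at 0.2 Hz | translation only, no head rotation |

All constant-rate rotations ramp up with a 1 s raised-cosine velocity
profile; onset profiles are not standardized in the source literature and
an impulsive start would put unphysical energy into the canal models.  The
CCCP yaw rate is likewise not standardized; 138 deg/s (23 rpm) sits inside
the 10–30 rpm range of classic cross-coupled Coriolis studies and is the
single largest lever on the cross-paradigm ratios (see Limitations).
Sessions default to 200 s.

## SVM

Sensing stage: first-order canal high-pass `s tau_ssc/(1 + s tau_ssc)`
(`tau_ssc = 5.7 s` in all presets) and the Mayne equation

    d g_hs/dt = (f_h - g_hs)/tau_lp - omega_hs x g_hs

with `a_hs = f_h - g_hs`.  Conflicts `c_g`, `c_a`, `c_w` feed integral
gains `K_gc/s`, `K_ac/s` (building the internally estimated specific force)
and the proportional velocity-storage gain `K_wc`
(`omega_hat = omega_hs + K_wc c_w`, which yields unit initial percept gain,
the closed-form EVAR decay `tau_ssc (1 + K_wc)`, and the raw canal response
in the `K_wc = 0` limit).  An internal copy of the sensing stage tracks the
estimated quantities.  Axis-split parameters (xy vs z) apply
component-wise in the head frame.  For translational inputs the conflicts
obey

    c_g/f = s / (tau_lp s^2 + (1 + K_ac tau_lp) s + K_gc)
    c_a/f = tau_lp s^2 / (same denominator)

and the simulated small-signal responses match these to better than 1%.

## MSOM

Otoliths are unity transfer functions, canals first-order high-pass (the
original second-order canal dynamics are simplified to first order).  The
estimated gravity has fixed magnitude 9.81 and is updated by rotation only:

    a_hat  = K_a c_o            (algebraic)
    c_o    = (f - g_hat)/(1 - K_a)
    c_oa   = (f_hat x f)/(|f||f_hat|)       (sine of the otolith angle error)
    omega_hat = (K_w (omega_hs + z_int) + K_fw c_oa)/(1 + K_w)
    d g_hat/dt = (K_f c_oa - K_1 omega_hat) x g_hat

with `K_1 = (K_wf K_w + 1)/K_w`.  With the tabulated `K_wf = 1` this makes
the gravity-rotation path track a sustained real rotation with exactly unit
gain in every preset — the property that lets the observer discriminate a
roll from an acceleration (near-zero pure-roll conflict) while the EVAR
percept still decays with `tau_ssc (1 + K_w)`.  Signs were fixed against
the lateral/vertical linearizations (`c_o/f = s/(s(1-K_a)+K_f)`,
`c_oa = -c_o/|g|`, vertical gain `1/(1-K_a)`), which the simulator
reproduces to 5 digits; note the algebraic consequence that a positive
sustained lateral push yields a negative-signed `a_hat` (the published gain
`K_a` is negative) — conflict norms, which is what sickness uses, are
unaffected.  `|g_hat| = 9.81` is exact at every sample (the cross-product
update is norm-preserving; residual RK4 drift is projected out each step).

## PFM

Per Euler step each of 800 particles: (1) draws a canal-state hypothesis
around the sensed canal afferent of the previous step
(`C_i = V_{t-1} + N(0, sigma_c)`, per axis); (2) inverts the discrete canal
equation for the angular velocity consistent with it
(`Omega_t = Omega_{t-1} + (C_t - C_{t-1}) + dt C_{t-1}/T_c`, the exact
inverse of the forward model — round trip is machine precision); (3)
rotates its orientation quaternion; (4) computes the earth-frame
acceleration implied by fixed-magnitude gravity; (5) is weighted by
zero-mean Gaussian stationarity priors on acceleration and angular velocity
(`sigma_a`, `sigma_w`, independent per axis); (6) is resampled
(systematic by default; multinomial behind a flag).  Posterior weighted
means before resampling form the percept; the conflict is
`c_w = SSC(omega_h) - SSC(omega_hat)` with SSC the canal high-pass.  Total
weight collapse falls back to uniform resampling.

Emergent behaviour with the published presets: EVAR percept gain ~0.88
(canal noise), decay ~27 s; centrifugation somatogravic roll saturation
~35 s (20 seeds, per-seed sd 0.3 s); no conflict for vertical motion
beyond the Monte-Carlo noise floor (`sigma_c/sqrt(N)`ish).  The posterior
scatter shrinks with particle count and per-seed fitted constants vary by
~3% at 800 particles.

## Analyses

* **Exponential fits** — `A e^{-bt}` / `A(1 - e^{-bt})` by nonlinear least
  squares; EVAR fits use a window from 2 s after rotation onset (skipping
  the spin-up ramp) to 150 s.  Fits whose residual RMS exceeds half the
  signal amplitude are rejected as non-decaying.
* **Frequency responses** — per frequency a sinusoidal translational probe
  (default 0.1 m/s^2) is simulated for a 20 s transient plus at least five
  steady cycles; gain is the least-squares sinusoid amplitude over the
  input amplitude, with a drift flag if the last two cycles disagree by
  >5%.  Break frequency: the -3 dB point relative to the low-frequency
  plateau, log-interpolated on a 30-point log grid over 0.01–2 Hz.
* **Sickness sensitivity** — post-transient time-averaged weighted conflict
  magnitude at fixed peak acceleration, self-normalized to its grid
  maximum; the reported peak is a grid point.  The rectified conflict
  carries >=50% of its power in the DC bin, which is why integrating |c|
  barely distorts these curves.
* **Feedback-gain sweep** — time-averaged `|c_g|` for PRP and LTA across
  `K_wc`; LTA is flat (no rotation/translation coupling in the SVM), PRP
  decreases monotonically toward an asymptote.
* **SMAE** — `mean(2|p - r|/(|p| + |r| + 1e-9))`, range [0, 2].  The
  original fit metric is not defined in print; this symmetric-MAPE form is
  adopted, and absolute published error tables (which would also require
  unpublished experimental series) are not reproduced.

## Tuning

Bisection anchors the angular-velocity feedback gain to a target EVAR decay
(18.7 s gives `K_wc = 2.28`).  Global search: 10 simulated-annealing runs
of 100 iterations from the literature values; proposal sd 10% of each bound
width, geometric cooling 0.95 per iteration, initial temperature equal to
the starting objective magnitude (schedule details are the package's
choice).  All evaluations in the lowest 10th percentile (across all runs)
become candidates, capped at 30; k-means (z-scored, k = 3) clusters them
and a bounded quasi-Newton refinement runs from each centroid (standing in
for an interior-point step; for these smooth low-dimensional objectives the
two are interchangeable), with the guarantee that the final answer is never
worse than the best raw candidate.  Because the original experimental
perception series are unpublished, tuning is validated by synthetic
parameter recovery: percept reports generated from known parameters plus 5%
Gaussian observation noise are recovered within 15% (typically a few
percent).

## What the synthetic data do and do not show

The synthetic reports emulate the *shapes* of classic perception data
(exponential EVAR decay, saturating centrifugation roll, sinusoidal OVAR
percepts) with white Gaussian observation noise.  Real report series have
correlated noise, drift, quantized response devices and between-subject
variability; passing recovery tests therefore demonstrates that the tuning
machinery is correct and identifiable under honest noise, not that the
published parameter values are the unique optimum for the real data.

## Numerical choices

RK4 at `dt = 0.01 s` for SVM/MSOM (inputs linearly interpolated at half
steps), Euler for the PFM at the same step; quaternions renormalized each
step.  The inner loops are numba-compiled; the particle filter uses its
own vectorized quaternion kernels.  PFM statistics default to 20 seeds.
Non-finite states abort with the failure time; a vanishing specific-force
magnitude makes the MSOM angle conflict undefined and is rejected.

## Known limitations

* The PFM's cross-paradigm sickness ratios (CCCP vs OVAR/PRP) come out
  near 5 where the original comparison reports 27 and 170: the rebuilt
  filter tracks smooth rotations with ~0.9 gain, leaving ~10% of the canal
  signal as conflict, whereas the published ratios imply residuals below
  the 800-particle Monte-Carlo floor.  The printed propagation step admits
  several readings (where the canal noise enters, resampling cadence) and
  none we tried reaches that regime while preserving the EVAR behaviour.
* The PFM centrifugation time constant is ~35 s against the published
  ~27 s, and the published trace's time-step-induced under-damped
  oscillations are not reproduced.
* The SVM OVAR/CCCP conflict ratio depends almost linearly on the
  unprinted CCCP yaw rate and roll amplitude; at the defaults above it is
  ~1.1 against the published 2.6.
* Sickness-tuned MSOM roll discrimination is weaker than perception-tuned
  (its otolith steering gain `K_f` is nearly zero).
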