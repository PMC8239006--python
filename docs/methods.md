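# Methods

`dendroclust` simulates how synaptic inputs on developing dendrites organize
into local clusters (and, with a somatic feedback signal, global maps)
through an activity-dependent, neurotrophin-based plasticity rule driven by
retinal-wave-like spontaneous activity.

## The plasticity models

All simulation time is in milliseconds; model variables are unitless and
interpreted relative to each other.

**Full neurotrophin model.** Per excitatory synapse *k* on a dendrite, five
coupled variables evolve under explicit Euler integration:

    tau_M dM_k/dt = -M_k + phi * x_dur * x_k(t)                     (MMP9)
    tau_Y dY_k/dt = -Y_k + sum_l s_kl W_l x_l(t) [+ s_k B_amp B(t)] (calcium)
    tau_P dP_k/dt = -P_k + (1-eta) Y_k - M_k P_k                    (proBDNF)
    tau_B dB_k/dt = -B_k + eta Y_k + M_k P_k                        (BDNF)
    tau_W dW_k/dt = alpha B_k - beta P_k,  W_k clipped to [0, 1]

`x_k(t)` is the binary event train (50-ms bursts), `s_kl =
exp(-d_kl^2/(2 sigma_c^2))` the Gaussian calcium-spread proximity over path
distance, and `eta = 0.45` the constitutive BDNF fraction.  Activity-gated
MMP9 converts proBDNF to BDNF; because `eta < 1/2`, calcium without local
presynaptic activity releases more proBDNF than BDNF and depresses, while
coincident pre- and postsynaptic activity potentiates.  The balance point is
`M* = 1 - 2 eta = 0.1`.

*Drive normalization.* We write the presynaptic drive as `phi * x_dur` per
unit of event indicator.  Taking the efficiency constant `phi = 3/50 per ms`
literally as the indicator coefficient would cap the accumulator at ~0.005,
below the heterosynaptic offset `|rho| = 1/11`, making potentiation
impossible for any input; the event-duration scaling is the unique reading
under which both the steady-state constant `kappa = 0.32` and
stimulation-induced potentiation hold.  Equivalently: time is measured in
units of the 50-ms event duration wherever `phi` appears.

**Generalized model.** A quasi-steady-state substitution for P and B
(`tau_P = tau_B -> 0`) followed by linearization around `M = 0` gives the
reduced, analytically tractable rule

    tau_v dv_k/dt = -v_k + phi * x_dur * x_k(t)
    tau_u du_k/dt = -u_k + g(sum_l s_kl w_l x_l(t)) [+ s_k B_amp B(t)]
    tau_w dw_k/dt = F(u_k (v_k + rho)),  w clipped to [0, 1]

with `rho = ((alpha+beta) eta - beta)/((alpha+beta)(1-eta))` (= -1/11
nominally) and `tau_w = tau_W /((alpha+beta)(1-eta))`.  `g` is an optional
sigmoidal dendritic nonlinearity (`gamma c1/(1+exp(-c2(I-c3))) +
(1-gamma) I`), `F` an optional cooperativity gate that zeroes the update
unless more than three neighbours within a spacing threshold were active
within a timing threshold.  The two models' weight trajectories correlate
above 0.99 on matched event trains (tested).

**Integration.** Explicit Euler, dt = 5 ms for branch/tree development runs
and dt = 1 ms for the stiff two-synapse protocols (tau_P = tau_B = 5 ms;
with dt equal to the stiffest tau the Euler decay factor is zero, i.e. a
quasi-steady-state update).  Halving dt changes one-minute trajectories by
< 1% (tested).  Long runs use numba kernels chunked at 10 simulated
minutes; the kernels are verified step-for-step against pure-python
reference steppers.  Structural turnover (replacement of any synapse whose
efficacy falls below W_thr = 0.02 by a fresh synapse at a random position
with a random receptive field and efficacy 0.5) is applied between chunks;
10 minutes is 0.05% of a 15-day run.

## Steady-state analysis

Averaging the generalized dynamics under stationary input gives the drift

    tau_w <dw_k/dt> = phi sum_l s_kl w_l (int gamma_kl(t) Gamma(t) dt
                       + mu_k mu_l) + rho sum_l s_kl w_l mu_l,

with `Gamma(t) = exp(-|t|/tau_u)/(tau_u + tau_v)` and all quantities in
event-normalized units (phi -> 3, a 15/min rate -> mu = 0.0125,
tau_u + tau_v -> 18).  For boxcar events sharing exact times (the
multiple-interaction construction) the lagged covariance is a unit triangle
scaled by the shared-event rate; the kernel integral is evaluated by
adaptive quadrature.  The homogeneous-correlation competition boundary is
`c* = (kappa S - 1)/(S - 1)` with `S = sqrt(2 pi) sigma_c nu` and
`kappa = (-rho/phi - mu)(tau_u + tau_v) ~ 0.32`; the sign predictor
`1 + (S-1) c - S kappa` is used for the phase diagram (it handles S < 1 and
negative c* uniformly).  At the nominal density nu = 0.2 per um, S ~ 3.0
sits almost exactly at the zero of c*: competition is *marginal* and driven
by local density fluctuations, which is what makes structural turnover
selective rather than destructive.

The two-synapse constants K1-K3 of the stimulated/silent drift forms are
not available in closed form; they are fit once by least squares of the
quadrature drift against the stated functional shapes.

## Stimulus stage

**LN-Poisson cascade.** Each synapse owns a Gabor receptive field: two
opposite-sign Gaussian lobes of identical shape (semi-minor axis half the
semi-major), displaced by diameter/2 along the orientation axis, each lobe
normalized to unit absolute integral.  The instantaneous rate is
`a exp(b <H, s(t)>)` with a = 0.2 Hz, b = 9.4; events are Bernoulli draws
per 50-ms bin (`P = 1 - exp(-rate * 50 ms)`), so overlapping draws merge
into contiguous binary runs.  Receptive-field centres are drawn from a
symmetric Gaussian of std sigma_p (ferret 5.3 deg, mouse 26 deg, macaque
2 deg), rejection-sampled into a 50-deg circle; orientations are uniform on
[0, 360).

**Surrogate retinal waves.** Real retinal-wave simulations are out of
scope; the surrogate must deliver the property the plasticity consumes:
correlated input whose structure follows receptive-field geometry.  A wave
is a *travelling shower of Gaussian blobs* — blob std 10 deg, positions on
a jittered lateral grid, amplitudes windowed by a Gaussian domain of std
15 deg, all moving at constant speed in a random direction, at random
lateral offsets; fronts are therefore locally irregular, like real waves at
receptive-field scale.  The blob-to-lobe projection is a closed-form
Gaussian-product integral, evaluated in a numba kernel, so multi-day drives
cost seconds and a rasterized-movie route (`generate_wave_movie` +
`ln_encode`) exists for validation; the two agree to < 1% of the drive
scale (tested).

Three consequences of this geometry, matching the intended regimes:
a front aligned with a Gabor's axis sweeps one lobe then the other and
drives it strongly (orientation selectivity -> ferret orientation
clustering); blob-scale irregularity breaks orientation coherence beyond
the domain size, so mouse-scale centre spreads decorrelate same-orientation
pairs; off-centre blob passes drive filters of any orientation, so
*overlapping* receptive fields correlate irrespective of orientation
(mouse overlap clustering).

**Calibration (fixed once).** The study's stated operating point is ~15
events/min of individual 50-ms Poisson bursts per synapse.  The baseline
`a` contributes 12/min; wave rate supplies the rest: 60 waves/min for
ferret-size filters, 55/min for mouse.  Wave speed is 100 deg/s (ferret)
and 200 deg/s (mouse): a wave passage must be shorter than the event
duration or events merge into long bursts, inflating the indicator duty
cycle and autocovariance and abolishing the marginal competition; the
mouse's 20-deg filter needs the faster sweep.  A 6-h wave sample is looped
over multi-day runs (loop length is a parameter).

**White-noise control.** Temporally i.i.d. Gaussian pixels smoothed with a
2-deg Gaussian.  Because frames are i.i.d., the filter-drive vector is
exactly multivariate normal with covariance computed from the smoothed
rasterized filters; long control runs sample that law directly.  The
pixel variance of the control is not a physical quantity (it depends on
raster resolution), so the drive scale is normalized to give the same
~15 events/min mean rate as the wave condition — the control then differs
only in spatiotemporal structure.

## Soma and backpropagating action potentials

The somatic accumulator `A(t) = sum_k w_k u_k` excludes the bAP-fed
component of u (tracked as a shadow accumulator with the same tau_u), so
there is no positive feedback loop.  On each upward crossing of `A_th` a
somatic burst fires with probability 0.25; a 200-ms refractory period
prevents dt-dependent multi-draws (a draw-per-step-while-above variant is
a config option).  A successful draw emits a 1-s burst of ten 50-ms bAP
pulses — the same somatic-burst convention used by the paired-burst
plasticity protocol — each pulse delivering calcium `B_amp s_k` with
`s_k = exp(-d_k^2/(2 sigma_bAP^2))` over path distance to the soma
(attenuation factors 25/75/125 um).

`A_th = 25` in the nominal table is tied to the full ~300-synapse
reconstructed-tree configuration and was chosen so the soma's bAP-event
rate matches the synaptic event rate (~15/min).  That *rate calibration*
is the invariant we preserve: tree runs record the somatic drive over a
20-minute lead-in with bursts disabled and set the threshold whose
crossing rate, thinned by the firing probability and the ten events per
burst, meets the target.  A selective (tail) threshold matters more than
the exact rate: if threshold crossings are driven by baseline fluctuations
rather than wave peaks, bursts carry no orientation information and the
heterosynaptic offset turns them into indiscriminate proximal depression.
The calibrated threshold is stored in checkpoints.

Tree protocols default to slow waves (30 deg/s; rates recalibrated to the
same ~15 events/min).  The coincidence term that potentiates soma-aligned
proximal synapses requires the presynaptic accumulator (tau 600 ms) to
remain elevated through the 1-s somatic burst; with the branch protocols'
fast sweeps a wave passes in 0.2-0.5 s and bursts land mostly on decayed
accumulators, net-depressing the whole proximal tree.  Real retinal waves
dwell over a receptive field for seconds, so the slow regime is the
realistic one for somatic coincidence; the faster branch default instead
protects the 50-ms Poisson event statistics that the local competition
balance requires.  A single stimulus satisfying both constraints would
need within-wave temporal structure (flicker) that the closed-form
surrogate does not model — this is the surrogate's main limitation, and
the reason the scaled tree-organization checks are statistically fragile
at desk scale (see below).

## Morphology

Linear branches (periodic for the two-synapse and branch-clustering
protocols; default L = 150 um, nu = 0.2/um -> 30 synapses) or rooted trees
of ~10-um segments.  SWC files are parsed and resampled into uniform
segments; a synthetic binary-branching generator (default ~1500 um cable,
scaled runs use 600 um) stands in for a database reconstruction — only the
path-distance structure matters downstream.  Path distances between
on-segment positions use a cached node-distance matrix.  Proximity values
are zeroed beyond 5 sigma (error < 4e-6).  The density-ramp schedule adds a
synapse every 64 min while scaling sigma_c and the per-event calcium
increment by sqrt(nu_0/nu(t)) so the neighbourhood calcium
(sigma_c * increment * nu) is conserved.

## Organization statistics

Orientation differences are axial: `min(|t1'-t2'|, 180-|t1'-t2'|)` with
angles mod 180 (range [0, 90] deg; chance level 45 deg).  The somatic
preference is the plain circular average `arg(mean exp(i theta))` over the
full circle — deliberately not the doubled-angle axial mean, matching the
convention the dispersion statistics are defined with.  Pairwise activity
correlations apply a 3-s boxcar before Pearson; undefined statistics
(zero-variance trains, balanced angle sets) propagate as missing values or
raise, never as silent zeros.  Cluster size lambda comes from a Gaussian
fit to the baseline-subtracted correlation-versus-distance curve (2-um
bins, baseline = mean correlation beyond 50 um).  Receptive-field overlap
is the pixel-wise Pearson correlation of rasterized filters; the
receptive-field offset is the distance of a synapse's centre from the mean
centre.  The correlation-versus-orientation-difference summaries use three
30-deg bins over [0, 90]; a monotone decrease over a 0-180 direction
difference is *not* a property of the model (a Gabor rotated by 180 deg is
the negated filter, and under the 3-s boxcar its response is
indistinguishable from the original's).

## Inhibitory scenarios

GABAergic synapses (default density 0.05/um) receive the same LN input and
turnover rule; their efficacies follow the proximity-weighted `B - P` of
the excitatory population.  Scenario A subtracts their drive from calcium
throughout (with calcium floored at zero); scenario B adds it until day 4
and subtracts afterwards.

## Scaled problem sizes

Published-scale spans (15-day branches, 5-day trees, 50-80 repetitions) are
plain arguments; the test suite and worked examples use the package's
desk-scale defaults: 2-5 simulated days and 3-5 seeds for branch runs,
600-um trees for 1 simulated day with 1-2 seeds per attenuation factor,
10 repetitions per phase-diagram cell.  Branch survival flattens within
~2 days, so the 4-day stable fraction approximates the 15-day one; the
acceptance script runs the full 15 days.

## Known limitations

* The surrogate waves reproduce the input property the model consumes, not
  retinal biophysics; absolute correlation magnitudes (~0.05-0.2 after the
  3-s boxcar) and therefore exact turnover counts depend on the surrogate's
  geometry.  Results about *which* organization emerges are robust to this;
  single-seed organization metrics on 30-synapse branches are noisy, so
  tests pool across seeds.
* Global tree organization (dispersion and offset gradients along the
  tree, and their ordering across bAP attenuation factors) appears in
  individual scaled runs but is not statistically stable over the few
  seeds and single scaled day that the default test suite affords; the
  published-scale protocol (full-length trees, five simulated days, tens
  of repetitions) is exposed through the same functions.
* The burst-pairing curve's depression onset is asymmetric here
  (~ -1.3 s / +2.1 s): the presynaptic accumulator built up by a 1-s burst
  (tau 600 ms) is still above the conversion balance point 0.5-1.5 s later.
  A symmetric window at +/-1 s would require a several-fold smaller
  presynaptic accumulation, which is incompatible with kappa = 0.32 and
  with stimulation-induced potentiation under the same constants.
* No cable-equation electrophysiology, no receptor kinetics, no apical/
  basal distinction; GABA density and the E/I cluster statistics are
  exploratory rather than calibrated.
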