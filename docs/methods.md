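# Methods

`cxheading` models angular-velocity integration in the heading circuit of
the desert locust central complex. This note records the model equations,
the parameter choices that matter, the optimisation and evaluation
procedures, and the design decisions taken where the biology leaves the
implementation open.

## Neuron and synapse model

Neurons are single-compartment, steady-state firing-rate units: membrane
potentials equilibrate instantaneously relative to the synapses
(`tau_m = 1.5 ms << tau_s`), so rates are algebraic functions of the
synaptic state and only synaptic variables are integrated.

The steady-state potential of neuron *i* (mV above rest) follows the
shunting conductance law

    U_inf = sum_j( g_tot_ij * P_s_j * E_s ) / (1 + sum_j( g_tot_ij * P_s_j ))

where `P_s_j` is the open probability of the channels driven by
presynaptic neuron *j* and `E_s` a synaptic reversal potential. The total
relative conductance of each synapse is

    g_tot_ij = g_s_ij + P_rel_cw * g_mod_cw_ij + P_rel_ccw * g_mod_ccw_ij

i.e. an unmodulated weight plus contributions from the two
angular-velocity (AV) neurons, scaled by their presynaptic release
probabilities. Rates come from a logistic function fitted to a noisy
integrate-and-fire neuron:

    r(U) = 99.6 Hz / (1 + exp(-0.19 mV^-1 * (U - 17.8 mV)))

Synaptic open probabilities follow first-order kinetics driven by a
Poisson presynaptic spike train with rate `r`:

    dP_s/dt = P_s_max * r - (r + 1/tau_s) * P_s ,  P_s_max = 1

with fixed point `r / (r + 1/tau_s)`. The release probability of each AV
neuron relaxes toward its normalised rate,

    dP_rel/dt = (r_AV / r_AV_max - P_rel) / tau_s_mod ,

which is proportional to the rate at the fixed point and confined to
[0, 1]. Internally time is in ms and rates in spikes/ms; interfaces use
Hz, mV and degrees (wrapped to [0, 360)).

**Sign convention.** A single reversal potential `E_ex = +60 mV` above
rest is used for every synapse and the *sign of the weight* decides
excitation versus inhibition. Negative conductances are an abstraction
(biologically they would be separate inhibitory pathways); the
denominator of the potential equation is guarded at `1e-3` and a
violation raises a degeneracy error. An `E_in` constant is kept in the
configuration for paired-pathway variants but unused by default.

**Time constants.** `tau_s = 20 ms`, `tau_s_mod = 40 ms` by default
(both configurable). The constraints are: `tau_s >= 10 * tau_m` (the
steady-state-rate assumption), `tau_s_mod > tau_s` (modulation acts
through slower cascades), and — decisive for function — both synapse
types must approach equilibrium within the 160 ms velocity phase of the
training trials. If `tau_s_mod` is comparable to or longer than that
phase, training calibrates the integration gain on a transient-release
regime and the circuit over-rotates roughly threefold once `P_rel`
reaches equilibrium during long evaluations; with the 20/40 ms defaults
the trained gain transfers to sustained rotations.

## Circuit

34 neurons: 16 CL1a (heading-encoding columnar neurons, one per
protocerebral-bridge column L8..R8, preferred headings `k * 22.5`
degrees), 16 CL2 (columnar neurons inheriting heading and carrying turn
sensitivity), 2 AV neurons, plus a bias neuron at a constant 100 Hz that
sets the operating point. The AV neurons fire linearly with the speed of
their preferred turning direction, up to 30 Hz at 150 deg/s, and act
only by modulating synapses; they make no conventional connections.

The connectivity mask allows synapses only where axonal arborisations
overlap with the right polarity:

1. CL1a_k -> CL2_k within a PB column;
2. CL2_k -> the CL1a pair sharing its CBL column: CL1a_k (ipsilateral)
   and CL1a_(k+8) (contralateral). Along the CBL the two hemispheres'
   projections interleave (column map `c(k) = 2*(k mod 8) + (k div 8)`,
   two intercalated 180-degree maps), so the neuron in the same CBL
   column from the other hemisphere is the antipodal one. The exact
   near-midline pairing cannot be pinned down from projection schemes
   alone; the builder exposes an override (`cl2_to_cl1a_pairs`) for
   alternative conventions.
3. CL1a <-> CL1a wherever their CBL arbors overlap (central column plus
   up to two flanking columns on each side): same-hemisphere neighbours
   `k +- 1`, cross-hemisphere partners `(a, a+8)` and `(a, a+7)`, and
   self-connections.
4. CL2 <-> CL2 all-to-all within a lower-nodulus hemisphere group
   (columns 0..7 and 8..15), including self.
5. bias -> every columnar neuron.

This yields 282 permitted feed-forward synapses. Both AV neurons may
modulate every synapse among the columnar neurons (not the bias
synapses): 250 positions each, hence 782 free parameters in total.
Variants restrict modulation to synapses onto CL1a only or CL2 only.

Initial states encode a heading `phi` as identical CL1a and CL2 bumps
`r_k = 5 Hz * cos(phi_pref_k - phi) + 25 Hz`, with every synapse at the
fixed point of its presynaptic rate and `P_rel = 0` (zero-velocity
stationary state). Headings are decoded by least-squares fitting
`alpha * cos + beta * sin + gamma` to the 16 CL1a rates and taking
`atan2(beta, alpha)`; the fitted amplitude is exposed so degenerate
(bumpless) profiles raise an explicit error.

## Integration

A classical fixed-step RK4 integrator advances `P_s` (33 values — one
per presynaptic neuron, since the kinetics depend only on the
presynaptic rate) and `P_rel` (2 values). Probabilities are clamped to
[0, 1] after each step (inactive in practice for non-negative rates).
Angular-velocity input is held constant within a step (zero-order
hold). Steps of 1–8 ms give indistinguishable trajectories (decoded
headings at 1 vs 4 ms agree to well under a degree over 200 ms);
training uses 4 ms, all reported simulations 1 ms.

## Weight optimisation

Free parameters: all masked `g_s`, `g_mod_cw`, `g_mod_ccw`. The batch
mixes 64 *maintenance* trials (random heading, zero velocity throughout)
and 64 *shift* trials (random heading, one constant velocity drawn
uniformly from [-150, 150] deg/s for the first 4/5 of a 200 ms horizon,
zero for the final 1/5), integrated at 4 ms. With states indexed
`R[j]` = rates after `j` steps (`j = 0..49`), the objective is

    L = MSE(R_CL1a[::10], maintenance target) + same for CL2
      + MSE(R_CL1a[-10:], shift target)      + same for CL2
      + 0.1 * sum over quadrant diagonals of Var(weights on diagonal)

where targets are the sinusoidal encodings of the true heading
(maintenance: the initial heading; shift: initial + v * 0.16 s). The
regulariser runs over the wrapped diagonals of the four 16 x 16
quadrants of the columnar weight matrix, separately for each weight
class, and pushes repeated anatomical motifs toward equal strength
(rotation-equivariance); bias weights are unregularised.

Gradients are computed by reverse-mode (adjoint) differentiation through
the RK4 steps, written directly against the vectorised drift: the
release-probability trajectory carries no weight dependence, so only the
33-dimensional `P_s` adjoint is propagated, and each stage contributes
outer-product weight gradients. The analytic gradient matches central
finite differences to better than 1e-4 relative error (tested).
Optimisation uses L-BFGS-B (history 50, projected-gradient tolerance
1e-7) from a uniform(-0.01, 0.01) seeded initialisation. Weight
configurations that drive the shunting denominator into degeneracy
return a large penalty so the line search backtracks. The default
iteration cap is 3000: the joint network has ~2.6x more parameters than
the restricted variants and needs roughly that many iterations to reach
the loss plateau; comparing variants at equal but insufficient budgets
confounds the comparison with optimisation error. One fit takes a few
minutes on one CPU core.

Solutions are a family, not a point: different seeds give different
weight matrices with closely matching behaviour (evaluation errors
within a few percent). The fitted recurrent blocks are functional but
not transpose-symmetric (relative asymmetry 0.4–0.7); the
diagonal-variance regulariser promotes rotation-equivariance, not
symmetry, and nothing in the objective selects symmetric members.
Clockwise and counterclockwise modulatory weights come out largely
complementary in sign (agreement fraction ~0.8 among significant
entries).

## Evaluation protocols

**Angular-velocity input generator.** Low-pass-filtered Gaussian noise —
an Ornstein–Uhlenbeck process sampled at 1 ms with correlation time
500 ms and stationary SD 50 deg/s, clipped to +-150 deg/s — emulating the
meandering rotation of a walking locust. It reproduces zero mean,
boundedness and an autocorrelation time equal to the filter constant; it
does not attempt to reproduce the saccadic micro-structure or
speed-coupled turning statistics of real locust walking, so passing
tests speak to integration of smooth, bounded rotation histories only.

**Integration accuracy.** Trials of 4 s at 1 ms steps from random
headings; the error is `|((phi_true - phi_decoded + 180) mod 360) - 180|`
at the endpoint. Noise models: (a) zero-mean Gaussian membrane noise
(SD 0–1 mV) added to every columnar `U_inf` each millisecond, before the
rate nonlinearity; (b) open-probability noise — each millisecond the
`P_s` entering the conductances is resampled from a Beta distribution
with mean equal to the noise-free value and pseudocount nu (shapes
`nu*mu`, `nu*(1-mu)`), leaving the state itself untouched; (c) weight
noise — every weight multiplied once per trial by an independent
uniform factor in [1-rho, 1+rho]. The noise-free mean error at these
study conditions is ~8–10 degrees over 4 s (n = 200–400); error grows
monotonically with membrane noise and is far more sensitive to weight
noise than to either state noise, since weight noise deforms the
attractor itself.

**Attractor stability.** 100 ms trials; Gaussian noise with SD
`sigma_rel * 5 Hz` is added to the initial presynaptic columnar rates
(which also seed the synaptic fixed points). Stability is the residual
RMS of the best-fitting cosine to the final CL1a activity, divided by
the RMS of the mean-removed fit (0 = perfect sinusoid, 1 = residual as
large as the signal). Strong initial perturbations (relative residual
~0.6) are absorbed to ~0.04 within 100 ms; +-5% weight noise leaves a
~10x larger final residual than the noise-free circuit.

**Closed-loop agent.** The CL1a rates are squashed by a logistic sigmoid
(midpoint 25 Hz, slope 2.5 Hz) into a rounded square wave and mapped
onto 8 TB1 units by a non-negative 8 x 16 matrix fitted by
ridge-regularised NNLS (ridge 0.1, 128 phases) to reproduce TB1 bumps
shifted by -5 degrees (compensating the discrete-time interface bias;
the fit prunes to two adjacent CL1a inputs per TB1 unit). Steering
compares a hard-coded CPU4 goal bump against the TB1 bump shifted one
column left or right, rectifies, sums, and scales the difference
(motor gain 150 deg/s per unit, saturating at 150 deg/s); the command is
an odd function of heading error. Agents walk 200 steps of 0.1 s at one
step-length per step (no side-stepping or turning on the spot), the
compass is integrated in 1 ms increments under the realised angular
velocity (command plus wind rotation), and wind gusts (500–1500 ms)
either displace the agent one step-length laterally or rotate it by a
uniform(-90, 90)-degree total spread smoothly over the gust; the
compass sees wind-induced rotation. Typical behaviour: alignment from a
random initial heading within ~2 s, then goal holding with median final
deviation ~15–20 degrees after 20 s; deviations are left/right
symmetric, and the mean deviation falls steeply from its
initialisation level while slow cue-free compass drift accumulates
afterwards — an expected property of a compass with no external
reference.

## Numerical choices and degenerate inputs

- float64 throughout; the logistic uses `expit` (no overflow).
- Decoding raises an explicit undefined-phase error below amplitude
  1e-8 Hz rather than returning an arbitrary angle.
- The steady-state denominator guard (1e-3) turns pathological weight
  configurations into a catchable error (simulation) or a penalty
  (training line search).
- Beta-noise means are clipped to [1e-9, 1 - 1e-9] so the shape
  parameters stay positive at the interval ends.
- All randomness flows from explicit integer seeds; one master seed
  expands into per-stage seeds by `SeedSequence` spawning, and repeated
  runs are bit-identical (weight files round-trip exactly).

## Known limitations

- The anatomical mask near the PB midline is a convention (documented
  above and overridable); alternative pairings train to comparable
  integrators but differ cell-for-cell.
- A 16-column discrete ring is only approximately a continuous
  attractor: without input the bump settles toward one of a finite set
  of stable states, giving a mean zero-velocity drift of ~4 degrees
  over 4 s (worst case ~8 degrees between stable states).
- The absolute integration-error level depends on constants the biology
  does not pin down (synaptic time constants, the spectrum of the
  angular-velocity input); under the defaults documented here the
  residual ~9-degree error over 4 s is set mainly by attractor
  discreteness and by extrapolating the trained gain to sustained
  rotations, so comparisons against published error levels should be
  read as bounds rather than point estimates.
- No spiking, no multi-compartment neurons, no TB1/TB2 recurrence
  inside the compass, no sky-compass cue fusion: heading information
  enters once, at initialisation.
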