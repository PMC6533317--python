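# Methods

`comdyn` simulates a distributed neural circuit in which perceptual
decisions, decision uncertainty, and changes-of-mind arise from the
interaction of three modules, and provides the dynamical-systems analysis
that explains the change-of-mind mechanism.

## The circuit

**Sensorimotor module.** Two competing excitatory populations, each
selective for one choice, are described by the reduced two-variable
mean-field model of decision making: the state variables are the
population-averaged NMDA synaptic gating variables S1, S2 with

    dS_i/dt = -S_i / tau_s + (1 - S_i) * gamma * H(x_i),

where H is the single-cell input-output function fitted to a leaky
integrate-and-fire neuron,

    H(x) = (a x - b) / (1 - exp(-d (a x - b))),

and the input current combines recurrent excitation, cross-inhibition,
background drive, the stimulus, uncertainty feedback and noise:

    x_i = J_N_self S_i - J_N_cross S_j + I0 + I_i + J_mc0 y_U + I_noise,i
    I_i = J_A_ext * mu0 * (1 +/- eps / 100).

Evidence quality eps (equivalent to motion coherence, in %) biases the two
stimulus currents in opposite directions. Noise currents are
Ornstein-Uhlenbeck processes with amplitude `sigma_noise` and correlation
time `tau_noise`, integrated by the Euler-Maruyama scheme together with the
deterministic equations (default step 0.5 ms; results are insensitive to
refining the step, which the suite checks).

**Uncertainty-monitoring module.** A cortical-column-like pair: an
inhibitory population integrating the summed sensorimotor rates and an
excitatory uncertainty-encoding population receiving a tonic bias
`mu_tonic` minus that inhibition, both threshold-linear:

    tau_mc dy_inh/dt = [J_V_inh (H1 + H2) - g]_+  - y_inh
    tau_mc dy_U/dt   = [mu - J_N_inh y_inh - g]_+ - y_U.

`y_U` is fed back equally to both sensorimotor populations through
`J_mc0`. A large top-down inhibition `g` clamps the module from trial
start; it is removed 400 ms (inhibitory) and 500 ms (uncertainty-encoding)
after stimulus onset and reinstated at a larger amplitude the moment a
decision is detected. This produces the phasic uncertainty transient
peaking around response initiation.

**Motor module.** Two threshold-linear integrators with mutual inhibition
equal to their leak, so the rate difference integrates the sensorimotor
rate difference (a line attractor):

    tau_h dy_L/dt = [J H1 - J_N_LR y_R - g]_+ - y_L   (mirror for y_R).

The read-out position is x = q (y_L - y_R) with q = |T_pos| / M_th, so
|x| = T_pos exactly when the leading rate reaches the motor target
threshold M_th with the other silent. The motor module is clamped by `g`
until the sensorimotor decision.

**Trial schedule and read-outs.** A trial starts 900 ms before stimulus
onset, and times out 4 s after it. The *initial response time* is the
first time a sensorimotor rate reaches `decision_threshold` (35.5 Hz); the
*final choice* is whichever motor rate first reaches M_th (17.4 Hz). A
trial in which no motor target is reached by timeout is an *indecision*
and is excluded from behavioural analyses. A *change-of-mind* is a sign
reversal of x(t) after movement initiation with a target still reached.
Because both motor rates are near zero at movement onset, the sign of x is
only registered once |x| exceeds 5% of |T_pos| (configurable); without a
minimum-excursion rule, numerical wobble around x = 0 would be counted as
reversals, which is also why experimental change-of-mind classification
uses a minimum-deviation criterion.

Decision uncertainty is read out per trial as the peak of y_U (real-time
measure) and the trapezoidal area under y_U over the recorded window
(post-hoc measure, in nA*ms on the internal time grid). Across coupled
trial pairs, the first trial's area X sets the second trial's tonic bias:
mu -> mu + C with C = alpha X + beta (alpha = 0.008 nA, beta = 0.5 nA),
reset to the default after each pair.

## Mechanism of change-of-mind

With the stimulus on and weak feedback, the (S1, S2) subsystem is in the
winner-take-all regime: two choice attractors separated by a saddle. The
uncertainty transient adds a common excitatory current to both
populations; above a critical value (~0.031 nA in the default profile)
the choice attractors vanish and a single *choice-neutral* stable state
near the diagonal appears. A trial caught by this state is pulled back
toward symmetry; when the transient decays the winner-take-all landscape
returns and noise can re-resolve the competition toward the other choice
— a change-of-mind, read out as a motor-position reversal. Because the
transient is strongest on slow, uncertain trials, reversals concentrate at
low evidence quality and predominantly correct an impending error.

The `phaseplane` module reproduces this analysis numerically: nullclines
by sign-change bracketing plus bounded root polishing, fixed points by
dense multi-start Newton search (residuals verified below 1e-10, Jacobian
eigenvalues for stability, cross-checked in the tests against a brute-force
residual-sign grid), and the bifurcation diagram and critical current by
bisection on the number of choice attractors (1e-4 nA resolution).

## Parameters

Defaults live in `profiles/default.yaml`; every value can be overridden.
Times are ms, currents nA, rates Hz.

* Input-output and gating constants (a = 270 Hz/nA, b = 108 Hz,
  d = 0.154 s, gamma = 0.641, tau_s = 100 ms) and the stimulus coupling
  (J_A_ext = 5.2e-4 nA/Hz, mu0 = 30 Hz) are the published constants of the
  reduced two-variable model this module derives from.
* Recurrent couplings J_N_self = 0.266 nA, J_N_cross = 0.065 nA and
  I0 = 0.325 nA were calibrated once, jointly, under three structural
  constraints: the resting state must be stable for the 900 ms
  pre-stimulus period; the choice-attractor firing rate must lie a few Hz
  *below* the 35.5 Hz read-out threshold (so that threshold crossing is
  normally triggered by the uncertainty transient, the regime in which the
  read-out thresholds 35.5 ~ 2 x 17.4 Hz are mutually consistent); and the
  critical feedback current must match the reported ~0.03 nA.
* Uncertainty-module couplings (J_mc0 = 0.042 nA, tau_mc = 160 ms,
  J_V_inh = 0.021 nA/Hz, J_N_inh = 2.0, mu_tonic = 2.4 nA) and the noise
  parameters (sigma_noise = 0.011 nA, tau_noise = 14 ms) were calibrated
  once against the behavioural suite (psychometric threshold and slope,
  RT-uncertainty correlation, change-of-mind structure) and then frozen.
  Noise amplitude controls threshold-crossing jitter while the product
  sigma^2 tau controls the low-frequency power that drives choice errors;
  the pair was chosen to set both regimes.
* Gating amplitudes (1000 / 3000 nA), release delays (400 / 500 ms),
  stimulus onset (900 ms), timeout (4 s), thresholds (35.5 / 17.4 Hz),
  motor coupling (J = 1 nA/Hz), target position (750) and the coupled-trial
  constants (0.008 nA, 0.5 nA) are the printed protocol values.

## What the simulations do and do not show

The generator emulates a two-alternative reaction-time task with a fixed
evidence-quality grid and counterbalanced correct side. It does not model
sensory transduction, trial-history effects beyond the explicit coupled
pairs, non-stationary attention or motor kinematics beyond the linear
position read-out; passing tests therefore certify the circuit mechanism,
not agreement with any particular experimental dataset.

Under the frozen profile the desk-scale protocol (2000 trials per
condition) reproduces the psychometric fit (threshold ~7.3-7.6%, slope
~1.25-1.31), the trial-level RT-uncertainty correlation (~0.93), the
condition-level regression (R^2 ~0.98), the declining-correct /
high-error uncertainty geometry, the change-of-mind probability structure
(decreasing in evidence quality, corrections dominating, correct-reversal
peak at eps = 3.2), and the bifurcation at ~0.031 nA. Two known fidelity
limits, both documented in the tests: the indecision rate is ~0.1% rather
than the reported 2.2% (in this profile the uncertainty transient almost
always triggers a decision before timeout), and the rising error branch
of the uncertainty pattern is weak because error response times lengthen
only mildly with evidence quality.

## Numerical choices

* Forward Euler-Maruyama at dt = 0.5 ms; threshold crossings are detected
  on grid points without sub-step interpolation.
* Exact sensorimotor threshold ties resolve to population 1 with a warning
  (measure-zero with noise).
* Initial conditions: S1 = S2 = 0.1, all threshold-linear variables and
  noise currents 0; the network relaxes to its resting state during the
  pre-stimulus 900 ms, so the exact value is uncritical.
* Per-trial RNG streams are spawned from the master seed
  (`numpy.random.SeedSequence`), making blocks bitwise reproducible and
  independent of batch size.
* The transfer function's removable singularity at a x = b is filled with
  its series expansion (relative error < 1e-9 against the analytic
  expansion).
* Feature scaling (min-max) is applied per trial set and per measure;
  it fails loudly on degenerate (constant) inputs.
* The choice-neutral label uses |S1 - S2| < 0.05 (configurable constant in
  `phaseplane`).

## Known limitations

* The calibrated profile is one point in a degenerate parameter family;
  quantities not pinned by the suite (e.g. absolute RT scale, indecision
  tail) should not be over-interpreted.
* Uncertainty-module variables are rate-like quantities on an nA scale
  (gain 1); only normalized uncertainty values are meaningful across
  profiles.
* The bifurcation analysis freezes the uncertainty module; it describes
  the sensorimotor subsystem under a constant feedback current, not the
  full 8-dimensional flow.
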