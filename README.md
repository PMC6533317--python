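# comdyn

Simulation and analysis of a distributed neural circuit in which decision
uncertainty is computed on-line and fed back to the decision circuit,
occasionally producing changes-of-mind.

`comdyn` is for computational neuroscientists studying perceptual decision
making. It couples three modules: a **sensorimotor module** (the reduced
two-variable attractor model of two competing populations, state variables
S1, S2 = NMDA synaptic gating, firing rates `H(x) = (ax-b)/(1-e^{-d(ax-b)})`),
an **uncertainty-monitoring microcircuit** (an inhibitory population
integrating the summed sensorimotor rates, inhibiting an uncertainty-encoding
population whose phasic activity `y_U` is fed back as excitation
`J_mc0 * y_U` to both decision populations), and a **motor module** (two
threshold-linear integrators with mutual inhibition forming a line attractor,
read out as screen position `x = q(y_L - y_R)`).

A trial runs under a reaction-time protocol: stimulus at 900 ms, top-down
gating released 400/500 ms later, initial choice when a sensorimotor rate
crosses 35.5 Hz, final choice when a motor rate crosses 17.4 Hz, 4 s timeout.
A **change-of-mind** is a reversal of the sign of x(t) with a target still
reached; **decision uncertainty** is the peak or the trapezoidal area of the
y_U transient. Phase-plane analysis shows why reversals happen: sufficiently
strong uncertainty feedback (≈ 0.03 nA) transiently destroys the two choice
attractors, leaving a single choice-neutral stable state that lets the losing
population recover. See `docs/methods.md` for the full model description.

## Worked example

```python
from comdyn import ModelParameters, analysis
from comdyn.simulate import run_block
from comdyn.phaseplane import critical_current

params = ModelParameters()                    # frozen default profile
trials = run_block(400, params=params, master_seed=7)
df = trials.to_frame()

fit = analysis.fit_weibull(df[~df.indecision])
print(f"psychometric threshold alpha = {fit.alpha:.2f}%, slope beta = {fit.beta:.2f}")

reg = analysis.rt_uncertainty_regression(df[~df.indecision], level="trial")
print(f"RT-uncertainty Pearson r = {reg['pearson_r']:.2f}")

curve = analysis.com_probability_curve(df)
print("P(change-of-mind):", dict(zip(curve.epsilon, curve.p_any.round(3))))

print(f"critical feedback current = {critical_current(0.0, params):.4f} nA")
```

Output (seed 7, 400 trials/condition, ~30 s):

```
psychometric threshold alpha = 6.74%, slope beta = 1.22
RT-uncertainty Pearson r = 0.94
P(change-of-mind): {0.0: 0.072, 3.2: 0.07, 6.4: 0.068, 12.8: 0.032, 25.6: 0.0, 51.2: 0.0}
critical feedback current = 0.0306 nA
```

The threshold is the evidence quality (% coherence) at which accuracy
reaches 1 - 0.5/e ≈ 0.82 under the Weibull fit; the correlation says slower
trials carry higher uncertainty read-outs; change-of-mind probability falls
with evidence quality; the critical current is where the winner-take-all
regime gives way to the choice-neutral attractor.

The same operations are available from a shell:

```bash
comdyn simulate --n-trials 400 --seed 7 --out trials.csv
comdyn analyze --summary trials.csv --out-dir results/ --plots
comdyn phaseplane --epsilon 0 --i-fb 0:0.05:40 --out bifurcation.csv
comdyn coupled --n-pairs 500 --seed 7 --out pairs.csv
```

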