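# syndrive

Synaptic-drive firing-rate modelling of excitatory/inhibitory neuronal
networks, built to study how anesthetic agents suppress excitatory brain
activity.

The *synaptic drive* of a neuron is the convolution of its firing rate with
the postsynaptic-potential kernel, `S_i(t) = ∫ α_i(t−τ) f_i(v_i(τ)) dτ`.
With an exponential kernel `α(t) = B e^{−t/λ}` the drives of a network obey

    dS_i/dt = −S_i/λ_i + B_i f_i( Σ_j A_ij S_j + v_th,i ),

and with the Erlang kernel `α(t) = B t e^{−t/λ}` (delayed peak, as in real
postsynaptic potentials) the corresponding second-order equations.  The
weights `A_ij` are nonnegative from excitatory and nonpositive from
inhibitory neurons; the activation `f` is half-wave, logistic, or
saturating-linear.  Anesthetics act by prolonging the inhibitory time
constants `λ^I`, and the package implements the three levels of analysis of
that mechanism:

* **Network simulation** — first- and second-order models, with an
  independent convolution oracle, nonnegativity/invariance guarantees, and
  diagnostics for partial synchronization and the biphasic (overshoot, then
  suppression) response.
* **Two-class mean field** — the planar mean excitatory/inhibitory model
  `dS̄E/dt = f(a S̄E − b S̄I + vthE) − S̄E/λE` (and its inhibitory twin):
  nullclines, equilibria and their Jacobian trace/determinant
  classification, conditions for uniqueness, Hopf-candidate scans in any
  parameter (awake state → limit cycle → suppressed state as `λ^I` grows),
  and limit-cycle detection.
* **Partial-synchronization certificates** — for networks containing
  inhibitory neurons that receive no inhibitory input: Lyapunov/LMI
  feasibility and verification (`[[Q,−P],[−P,R]] ⪰ 0`,
  `Ω = PL + LP − Q − ÃᵀRÃ ≻ 0`), and explicit inhibitory-time-constant
  inequalities under which every excitatory drive is driven to zero.

A catalog of reference networks and parameter sets (6-, 12-, and 8-neuron
systems, mean-field bifurcation studies, published certificate matrices), a
seeded random-network generator, JSON/CSV I/O, and a `syndrive` CLI
(`simulate`, `scan`, `lmi`, `condition`, `fixture`, `generate`) round out
the package.  The Hill dose-response utility `P = C^γ/(C50^γ + C^γ)` links
the dynamics to concentration-response curves.

## Worked example

Six neurons (E1–E3, I1–I3) in which I2 and I3 receive no inhibitory input,
with fast excitatory decay (λ^E = 0.05 s) and a prolonged inhibitory
decay (λ^I = 0.5 s):

```python
import numpy as np
from syndrive import (paper_fixture, partition_inhibitory, lmi_feasibility,
                      threshold_premise, simulate_first_order, sync_diagnostics)

fx = paper_fixture("fig11")
net = fx["network"]
part = partition_inhibitory(net)
print("uninhibited subset:", part.no_input_set)

cert = lmi_feasibility(part)
print(f"LMI feasible: {cert.feasible}  (min eig Omega = {cert.lambda_min_Omega:.3f})")
print("threshold premise holds:", threshold_premise(net, part, fx["S0I"]).holds)

traj = simulate_first_order(net, np.r_[fx["S0E"], fx["S0I"]], (0.0, 5.0))
d = sync_diagnostics(traj)
print("suppressed states:", [traj.labels[i] for i in d.zero_set])
print("persistent states:", {traj.labels[i]: round(float(traj.S[-1, i]), 3)
                             for i in d.constant_set})
```

which prints

```
uninhibited subset: [1 2]
LMI feasible: True  (min eig Omega = 10.619)
threshold premise holds: True
suppressed states: ['E1', 'E2', 'E3', 'I1']
persistent states: {'I2': 0.15, 'I3': 0.25}
```

The certificate (solved from scratch) plus the threshold premise prove
exponential partial synchronization, and the simulation confirms it: every
coupled drive (all excitatory neurons and I1) is suppressed, while the
uninhibited I2, I3 settle at their own nonzero levels — the model's picture
of anesthetic unconsciousness as selective silencing of coupled excitatory
activity.

At the mean-field level, scanning the inhibitory time constant for the
reference aggregates:

```python
from syndrive import MeanFieldParams, find_equilibria, hopf_scan

p = MeanFieldParams(a=10, b=9, c=6, d=1, vthE=-0.5, vthI=-2.5)
eq = find_equilibria(p)[0]
print(f"equilibrium ({eq.point[0]:.4f}, {eq.point[1]:.4f}): {eq.classification}")
print("oscillation window in lam_I:",
      [round(c, 3) for c in hopf_scan(p, "lamI", 0.5, 3.0).crossings])
```

```
equilibrium (0.5000, 0.5000): unstable
oscillation window in lam_I: [0.884, 1.852]
```

Below the window the awake equilibrium is stable; inside it the state
oscillates (a stable limit cycle born at a Hopf bifurcation — the regime
where response to stimulus depends on the phase at which it arrives); above
it the system settles into the suppressed state.

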