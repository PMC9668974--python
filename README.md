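# pulselock

Event-driven simulation and frequency-locking theory for pulse-coupled
class I neurons with spike-timing-dependent plasticity (STDP).

## The problem

When two neurons are coupled by plastic excitatory synapses, the timing
of their spikes rewrites the synapses, and the synapses rewrite the
timing.  For class I neurons — those that cross into firing through a
SNIC bifurcation and therefore advance (never delay) their phase in
response to excitation — this feedback settles into one of three
asymptotic states: a unidirectional link from the *slower* to the
faster neuron that locks the pair at a winding number n/1 (the fast
neuron fires n ≥ 2 spikes per slow cycle, so the slow neuron becomes
the pacemaker), the reverse fast-to-slow link locking at 1/1, or full
disconnection.  In heterogeneous networks the first state lets slow
neurons enslave whole groups of faster ones and generate low-frequency
collective rhythms.

`pulselock` provides, for anyone studying synchronization in plastic
spiking networks:

* an exact event-driven simulator for quadratic integrate-and-fire
  (QIF) phase networks with additive nearest-neighbor pair-based STDP,
  and for arbitrary class I neurons via tabulated phase response
  curves (PRCs);
* the complete closed-form Arnold-tongue theory: with frozen weights
  `g1 = ω₁·cot[(π/2)(T₂/T₁ − n + 1)]`, `g2 = ω₂·cot[(π/2)·T₁/T₂]`, and
  under STDP the boundaries obtained from the per-cycle weight budgets
  and their stability thresholds Q₁, Q₂;
* near-resonance boundaries for any class I PRC from a parabolic fit
  `Z(φ) ≈ Z_max − α(φ − φ_max)²` of its peak;
* Wang–Buzsáki and Morris–Lecar conductance-based models with period
  measurement, SNIC-current localization, and numerical PRC
  extraction;
* post-hoc analysis of converged networks: thresholded connectivity
  graphs, synchronized clusters, and pacemaker identification.

## Worked example

Two QIF neurons, the second 1.85× slower, coupling g = 0.7, STDP with
p = d = 0.001, τ_p = π/3, τ_d = π, started with a strong slow→fast and
weak fast→slow synapse:

```python
import math, numpy as np
from pulselock import NetworkConfig, NeuronSpec, run, classify_mode, winding_number
from pulselock.experiments import DEFAULT_STDP

T1 = 2 * math.pi
cfg = NetworkConfig(
    neurons=[NeuronSpec(T=T1), NeuronSpec(T=1.85 * T1)],
    g=0.7, t_max=4e4, stdp=DEFAULT_STDP,
    W0=np.array([[0.0, 0.9], [0.1, 0.0]]),
)
log = run(cfg)
print("final weights:", np.round(log.final_W, 4).tolist())
print("mode:", classify_mode(log), " winding:", winding_number(log, fast=0, slow=1))
```

prints

```
final weights: [[0.0, 0.9998], [0.0, 0.0]]
mode: i  winding: 2
```

— the slow→fast synapse saturated (W₁₂ ≈ 1), the reverse one died, and
the fast neuron fires exactly 2 spikes per period of the slow one: the
slow neuron has become the pacemaker (mode i).  The analytic STDP
tongue boundary for these periods,

```python
from pulselock import g1_stdp
g1_stdp(T1, 1.85 * T1, DEFAULT_STDP)   # 0.4031...
```

confirms g = 0.7 lies inside the locked region.

A command-line interface wraps the main drivers:

```bash
pulselock two-neuron --case slow-pacemaker --outdir out/
pulselock snic                       # Wang–Buzsáki SNIC current
pulselock prc --model ml             # Morris–Lecar PRC + parabolic fit
pulselock tongue-scan --mode i --frozen
```

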