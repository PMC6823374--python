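# fracfhr

Simulation and analysis of the **fractional-order FitzHugh-Rinzel (FH-R)
bursting neuron**, for computational neuroscientists studying how
memory-dependent (power-law) membrane dynamics reshape spiking, bursting and
synchronization.

## The model

The FH-R neuron is a three-variable fast-slow excitable system — membrane
voltage `v`, recovery variable `w`, and a slow current modulation `y`:

```
D^α v = v − v³/3 − w + y + I
D^α w = δ (a + v − b w)
D^α y = μ (c − v − d y)
```

where `D^α` is the Caputo fractional derivative of commensurate order
0 < α ≤ 1 and `I` is a constant stimulus current. At α = 1 the model is the
classical FH-R elliptic burster; for α < 1 every variable carries a
power-law memory of its own past, which lowers firing rates, introduces
first-spike latency, and converts bursting into mixed-mode oscillations or
quiescence.

The package provides:

* **`fracfhr.solver`** — the explicit L1 discretization of the Caputo
  derivative for arbitrary finite-dimensional vector fields, with the update
  split into its history-free *Markov term* and the *memory trace*
  (the weighted sum of all past increments, identically zero at α = 1).
* **`fracfhr.stability`** — analytic machinery: the equilibrium cubic
  `F(v*) = v*³ − 3pv* = q`, the characteristic polynomial, the critical
  exponent `α* = (2/π)|arg λ|` at which a fractional Hopf bifurcation
  occurs, the chaos necessary condition for saddle-foci of index 2, the
  α-independent stability window in `I`, and classical Hopf currents by
  trace-zero inversion or eigenvalue continuation.
* **`fracfhr.coupling`** — two FH-R neurons electrically (bidirectionally)
  coupled through voltage, with the similarity function
  `S²(γ) = ⟨(v₁(t) − v₂(t−γ))²⟩ / (⟨v₁²⟩⟨v₂²⟩)^{1/2}` used to diagnose
  complete synchronization (S(0) → 0).
* **`fracfhr.spikes`** — spike detection, first-spike latency, firing rate
  and qualitative regime labels (quiescent / tonic / bursting / mixed-mode).
* **`fracfhr.cli`** — a `fracfhr` command with `simulate`, `analyze`,
  `hopf-curve`, `couple`, `sweep`, `spikes` and `fixtures` subcommands; all
  runs write a manifest for bit-for-bit reproducibility.

Five canonical parameter sets `"I"`–`"V"` are bundled (`fracfhr.preset`),
all sharing a = 0.7, b = 0.8, d = 1, δ = 0.08: the elliptic burster
(set I, I = 0.3125), tonic spiking (set II, I = 0.4), a fast slow-variable
regime (set III, μ = 0.18, I = 3), a saddle regime (set IV, c = 1.3) and
sparse high-amplitude spiking (set V, c = −0.908, μ = 0.002).

## Worked example

```python
import fracfhr as f

p = f.preset("I")                       # elliptic burster
rep = f.stability_report(p)
print(rep.equilibrium.v_star)           # -0.8850976854773176
print(rep.spectrum.complex_pair)        # (0.07634925727513363+0.24581088522827046j)
print(rep.critical_alpha)               # 0.8082791271286841
print(rep.hopf_continuation)            # (0.13871543154579621, 3.161284568454204)

cfg = f.SolverConfig(alpha=0.98, n_steps=20000, dt=0.1, seed=5)
traj = f.simulate(p, cfg)               # L1 Caputo integration, 2000 ms
train = f.detect_spikes(traj)
print(len(train))                       # 53
print(f.firing_rate(train, (0.0, 2000.0)))  # 26.5  (spikes/s)
```

The equilibrium is the unique real root of the cubic (unique because
b·d < b + d makes F strictly increasing). Its Jacobian has one small
negative real eigenvalue and an unstable complex pair — a saddle-focus of
index 2 — so the fixed point is asymptotically stable exactly for
α < α\* ≈ 0.80828: below that order the neuron is quiescent, above it the
memory trace sustains oscillations, and the same threshold is the necessary
condition for chaotic dynamics. The two Hopf currents bracket the stimulus
window (≈ 0.1389, 3.1611) outside which stability is independent of α.

The same analysis from the shell:

```sh
fracfhr analyze --preset I          # JSON report with all of the above
fracfhr simulate --preset I --alpha 0.98 --steps 20000 --seed 5 --out run.csv
fracfhr spikes run.csv --out-prefix run_spikes
fracfhr sweep --preset III --alpha 0.99 --ge-min 0 --ge-max 0.6 --ge-steps 25
```

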