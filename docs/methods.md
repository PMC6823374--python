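# Methods

## Model

The FitzHugh-Rinzel neuron couples a FitzHugh-Nagumo fast subsystem (v, w)
to a slow current modulation y:

    D^α v = v − v³/3 − w + y + I      = f₁
    D^α w = δ (a + v − b w)           = f₂
    D^α y = μ (c − v − d y)           = f₃

with a commensurate Caputo derivative of order 0 < α ≤ 1 on every equation.
All constants are dimensionless; v is on a mV-like scale and t on a ms-like
scale, but no unit system is enforced. δ (default 0.08) sets the recovery
time scale and μ the (much slower) modulation time scale — μ = 0.0001 in the
bursting sets, which means the burst cycle lives on a ~10⁴ ms horizon, a
fact that matters repeatedly below.

Throughout we assume **(A)** b·d < b + d. The equilibrium voltage solves
the cubic F(v*) = v*³ − 3pv* = q with p = 1 − 1/b − 1/d and
q = 3I − 3a/b + 3c/d; under (A), p < 0, F is strictly increasing, and the
equilibrium E(v*, (v*+a)/b, (c−v*)/d) is unique. (A) is checked at
`ParameterSet` construction and violating it only warns — simulation is
well-defined without it — but every analysis routine refuses to run
(`AssumptionAError`), since uniqueness and the root-localization arguments
all rest on it.

## L1 scheme and memory accounting

The Caputo derivative is discretized by the L1 scheme: with β = 1 − α and
increments Δx_k = x(t_{k+1}) − x(t_k),

    x(t_N) ≈ dt^α Γ(2−α) f(x(t_{N−1})) + x(t_{N−1})
             − Σ_{k=0}^{N−2} Δx_k [(N−k)^β − (N−1−k)^β].

The first two terms are the Markov term, the sum is the memory trace;
`memory_decomposition` reproduces any stored state as their difference
exactly. The weights telescope (Σ = N^β − 1), which the tests use as an
independent oracle.

Numerical choices:

* **Explicit evaluation.** The field is evaluated at the previous step's
  state. This makes the α = 1 limit *exactly* forward Euler (every memory
  weight is identically zero, Γ(1) = 1), which the test suite asserts to
  1e−10 on all presets; the α = 1 path also skips the O(N²) history sum
  since it would only add exact zeros.
* **Full history by default.** The memory sum is O(N²) over a run. An
  optional `memory_window` truncates it to the most recent increments; this
  is an approximation beyond the plain L1 scheme, off by default, and the
  tests confirm a window covering the whole history is bit-identical to the
  exact sum.
* **Γ(2−α)** via `scipy.special.gamma`.
* **Defaults** dt = 0.1 ms and 20 000 steps (2000 ms), the grid used by the
  regime studies here.
* **Divergence guard**: any non-finite component or |x| > 10³ aborts with
  the step index. The model's attractors live within |v| ≲ 2.5, so the
  bound only triggers on genuine blow-up.
* **Initial conditions** are the equilibrium plus `perturbation_scale`
  times a U(0,1)³ draw from a seeded `numpy` generator. The default scale
  is 1.0 — a literal reading of "small random perturbations ... uniformly
  distributed in (0, 1)" — and runs are bit-reproducible given (seed,
  config).

## Stability and bifurcation analysis

The equilibrium cubic is solved through the companion matrix (`numpy.roots`)
rather than Cardano's formula, which degrades near p → 0; the unique real
root is selected. Eigenvalues at the equilibrium are computed twice — as
roots of the analytically expanded characteristic polynomial (trace, sum of
principal minors, determinant) and as `eigvals` of the Jacobian — and the
two routes must agree to 1e−8 or the analysis refuses to report. Note the
sum of principal 2×2 minors is δbμd + μ(1 − d + d v*²) + δ(1 − b + b v*²);
expanding the printed Jacobian is the authority here.

A commensurate-order fixed point is asymptotically stable iff every
eigenvalue satisfies |arg λ| > απ/2 (principal value in (−π, π]; a negative
real eigenvalue has |arg| = π and never destabilizes). det J < 0 under (A)
forces one negative real eigenvalue λ₁, so everything hinges on the other
two:

* **All real:** stability is α-independent; `critical_alpha` returns None.
* **Complex pair λ:** α* = (2/π)|arg λ|. When λ₁ < 0 this equals the
  arccos form in (trace − λ₁)√(−λ₁) / (2√(−det J)), and the implementation
  cross-checks the two to 1e−6 at runtime. A stable pair gives a formal
  value above 1, reported as None (stable on all of (0, 1]).
* **Saddle-focus of index 2** (λ₁ < 0, Re λ > 0): the same threshold,
  written (2/π)·atan(|Im λ|/Re λ), is the *necessary* condition for chaos;
  `chaos_alpha` reports it only in that configuration and the package makes
  no claim that chaos actually occurs above it.

Trace zero at v_H = ±√(1 − δb − μd) (= γ₁, γ₂) brackets the stimulus
window (I_low, I_high) = (0.1389, 3.1611 at the base constants) inside
which stability can depend on α. Two caveats are deliberate features of
the implementation:

* The window is a *sufficient* condition for α-independent stability whose
  root-localization step assumes μ < bδ (with d = 1). For set III
  (μ = 0.18 > bδ = 0.064) the window test wrongly suggests independence
  while the complex pair is unstable (α* = 0.95665); the report therefore
  carries both `outside_window` (the window test) and
  `stable_for_all_alpha` (a direct Hurwitz check on the eigenvalues), and
  they are allowed to disagree.
* The classical Hopf currents come in two variants that differ in the
  fourth decimal: trace-zero inversion of F (0.1389 / 3.1611) and the true
  Re(λ) = 0 crossing found by scanning and Brent root-finding
  (0.138715 / 3.161285). Both are exposed with a method tag rather than
  reconciled — the gap *is* the trace-zero approximation error, because the
  real eigenvalue is small but nonzero. The continuation scan starts
  slightly outside the trace-zero window, since the true crossing sits
  just below I_low.

`hopf_curve` evaluates α*(I) on a stimulus grid and masks (NaN) the
all-real region — the cubic discriminant is positive for I roughly in
[0.7, 2.6] at base constants — where no fractional Hopf point exists.
`n_index` exposes n_i = απ/2 − |arg λ_i|, the fractional analogue of an
eigenvalue real part.

## Coupled pair and synchronization

Two identical neurons are coupled bidirectionally through voltage only
(g_e ≥ 0); the stacked six-dimensional system is integrated by the same L1
code, so the synchronization manifold v₁ = v₂, w₁ = w₂, y₁ = y₂ is exactly
invariant in the discrete dynamics (asserted to 1e−10) and swapping the two
seeds swaps the trajectories exactly. Complete synchronization is declared
when the similarity function at zero lag, computed over the post-transient
half of the run, falls below 0.01 (no printed criterion exists beyond
"converges to zero"; the lag-γ form is implemented for completeness but CS
uses γ = 0). S(γ) is invariant under common rescaling of both signals and
equals 2 for exactly antiphase signals.

Conditions chosen here, once, for the coupled studies: perturbation scale
0.1 per neuron, horizon 2000 ms, transient fraction 0.5, sweep grid
g_e ∈ [0, 0.6] with 25 points. The scale matters: the coupling acts on v
only, so the difference in the slow variable decays at rate ~μ no matter
how strong g_e is, and with full U(0,1) offsets the bursting pair (set I,
μ = 10⁻⁴) needs horizons of order 10⁴ ms to lock — at scale 0.1 and 2000 ms
the pair at α = 0.99, g_e = 0.55 reaches S(0) ≈ 0.01. Whether a 0.01-point
drop in α (0.99 → 0.98) destroys CS is sensitive to initial conditions and
horizon at these settings and is not asserted anywhere.

## Spike metrics

A spike is an upward crossing of v through a threshold (default 0.5),
merged within a 2 ms refractory minimum; the model has ~2-amplitude spikes
over a baseline near −1, and counts are insensitive to thresholds across
[0.3, 0.7], which is tested. First-spike latency is the first crossing time
from t = 0; firing rate is a window count per second. Regime labels are
qualitative diagnostics only: *quiescent* (no post-transient spikes and
tail peak-to-peak amplitude < 0.1), *bursting* (some inter-spike gap
exceeds 5× the median interval), *mixed-mode* (spikes interleaved with
prominent sub-threshold maxima, `scipy.signal.find_peaks` with prominence
0.1), else *tonic*. Mixed-mode has no crisp operational definition in the
literature on this model; the label is heuristic and no quantitative claim
rests on it.

## Problem sizes and what the tests show

The dichotomy checks (quiescent at α* − 0.05, oscillatory at α* + 0.05,
sets I, II, III, V) run 2000 ms at dt = 0.1 from perturbations of scale
0.01: local asymptotic stability is a small-perturbation statement, and
with μ = 10⁻⁴ a full-size perturbation keeps the voltage bursting for far
longer than any reasonable test horizon even below α*. The bursting-
structure checks use the classical order (α = 1), where the Euler fast path
allows a 20 000 ms horizon covering several burst cycles. Firing-rate
ordering (set II: rate at α = 0.92 below α = 1) and the set-IV latency
ordering (α = 0.80 later than α = 0.85) use single seeded runs; in the
saddle regime some seeds never spike within the horizon, so the test pins a
seed that does — these are property checks of orderings, not estimates of
rates.

Synthetic inputs in the tests (flat traces, sines with known crossing
counts, shifted/scaled series) exercise the metric definitions with
closed-form expectations; they emulate idealized voltage traces, not
physiological recordings. Passing tests demonstrate internal consistency of
scheme and analysis and reproduction of the model's analytic structure —
they say nothing about fit to biological neurons.

## Known limitations

* The L1 scheme is first-order and explicit; no predictor-corrector or
  adaptive stepping. Convergence is checked empirically by step-halving,
  not proven.
* Full-memory cost is O(N²); very long fractional runs are expensive
  (truncation exists but changes the dynamics).
* No continuation of limit cycles or Floquet analysis; the bifurcation
  toolbox covers equilibria only.
* Networks are limited to the symmetric two-neuron electrical pair; no
  heterogeneous pairs, no chemical synapses, no lag/phase synchronization
  measures beyond S(γ).
* Near the critical order (within ~0.01 of α*) transients decay so slowly
  that finite-horizon simulations cannot cleanly classify the regime;
  analytic α* is the authority there.
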