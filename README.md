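# gjgate

Continuous-time Markov chain (CTMC) models of **gap-junction channel
voltage gating**, built compositionally with Kronecker (stochastic
automata network, SAN) algebra and solved with structure-exploiting
steady-state methods.

## The problem

Gap-junction (GJ) channels couple the cytoplasms of adjacent cells —
cardiac myocytes, neurons and glia, lens fibers. Each channel is two
hemichannels in series, each hemichannel a hexamer of connexins, and
each connexin contributes a voltage-sensitive *subgate* switching
between open (o), closed (c), and optionally deep-closed (d) states.
Junctional conductance g_j measured at steady state decays symmetrically
with transjunctional voltage V_j of either polarity.

Fitting such models to recordings needs steady-state probabilities at
~10³ voltages per candidate parameter set, over ~10³–10⁴ optimizer
iterations — so both *building* the transition-rate matrix and *solving*
πQ = 0, Σπ = 1 must be fast. `gjgate` targets exactly that: cheap
generator assembly via Kronecker sums, and solvers that exploit the
resulting block-tridiagonal/banded structure.

## What's inside

* **Model variants** — 12 two-state subgates lumped to a 49-state chain
  (7 blocks of 7, bandwidth 15); 6 three-state subgates (28 states,
  blocks 7..1); 12 three-state subgates (28² = 784 states, 28 blocks of
  28 in a five-layer pattern).
* **Biophysics** — Boltzmann transition probabilities
  `p_oc = K·k/(1+k)`, `p_co = K/(1+k)` with `k = exp(A·P·(V − V0))`,
  converted to rates by `λ = p/τ`; rectified subgate conductances
  `g_o = 2·exp(P·V/Ro)`, `g_c = 0.25·exp(P·V/Rc)`; an iterative series
  voltage division (all rates are *functional*: they depend on the
  global state through that division); junctional conductance
  `g_j = Σ_i π_i·g_left,i·g_right,i/(g_left,i + g_right,i)`.
* **Solvers** — dense Gaussian elimination, banded elimination, a block
  recursive (Thomas-style) direct method for equal-block partitions, and
  block Gauss-Seidel with warm starts for repetitive solves over a
  voltage sweep.
* **Complexity ledger** — exact integer operation counts per method and
  the crossover iteration thresholds between them.
* **Sweep pipeline** — g_j–V_j curves with cold- vs warm-started
  iterative solves, CSV/JSON export, and a seeded synthetic parameter
  generator.

## Worked example

```sh
python examples/03_steady_state_solvers.py
```

```
model: two_state_12, n = 49, bandwidth (k1, k2, m) = (7, 7, 15)
dense_ge             outer_iterations=  0 residual=3.77e-18 max|pi - pi_dense|=0.00e+00
banded_ge            outer_iterations=  0 residual=1.44e-18 max|pi - pi_dense|=6.94e-17
block_recursive      outer_iterations=  0 residual=1.78e-18 max|pi - pi_dense|=1.11e-16
block_gauss_seidel   outer_iterations= 22 residual=6.58e-09 max|pi - pi_dense|=6.80e-07
```

The three direct methods agree to machine precision; block Gauss-Seidel
stops when consecutive iterates differ by less than 1e-6 everywhere,
leaving an error of the same order. `examples/05_voltage_sweep.py`
sweeps V_j from 0 to 100 mV in 0.5 mV steps: the normalized conductance
decays from 1.0 at 0 mV to 0.72 at 100 mV for the shipped synthetic
parameters, and warm-starting each solve from the previous voltage's
solution cuts total outer iterations from 4197 to 2380 (a 43 % saving)
without changing the curve.

Other examples cover Kronecker composition and the product-form steady
state (`01`), gating rates and the voltage division (`02`), and the
operation-count ledger (`04`). A thin CLI wraps the pipeline:

```sh
gjgate sweep --model two12 --v-start 0 --v-end 100 --v-step 0.1 \
    --method bgs --epsilon 1e-6 --warm-start --out sweep.csv
gjgate complexity --model two12
```

## Layout

```
src/gjgate/
  tensor_core.py   Kronecker primitives, functional-rate SAN assembly, bandwidth
  gating.py        Boltzmann rates, rectified conductances, voltage division, g_j
  models.py        state spaces, generator assembly, exact lumping checks
  solvers.py       dense / banded / block-recursive / block Gauss-Seidel, Q#
  complexity.py    exact operation counts and thresholds
  sweep.py         voltage sweeps, warm starts, synthetic parameters, export
  cli.py           `gjgate` command
docs/methods.md    model, assumptions, numerical choices, limitations
examples/          one narrative script per capability
```
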