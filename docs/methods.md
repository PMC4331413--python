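# Methods

## Model

A gap-junction channel is modeled as two hemichannels in series, each a
parallel array of six connexin subgates. A subgate is a small Markov
automaton: open <-> closed, optionally extended by a deep-closed state
reached from the closed state. Because the subgates of a hemichannel are
exchangeable, the hemichannel is lumped to the counts of subgates per
state: a 7-state closed-count automaton for two-state subgates, a
28-state (n_open, n_closed) automaton (n_open + n_closed <= 6) for
three-state subgates. Three channel variants are composed from these:

| kind           | automata             | states | block partition  |
|----------------|----------------------|--------|------------------|
| `two_state_12` | two 7-state          | 49     | 7 blocks of 7    |
| `three_state_6`| one 28-state (left only gates; the right hemichannel is held fully open) | 28 | blocks 7,6,...,1 |
| `three_state_12`| two 28-state        | 784    | 28 blocks of 28  |

The global infinitesimal generator is assembled by a generalized
Kronecker composition: each listed local transition moves one automaton
and contributes its rate *evaluated at the current global state*;
diagonals are negated row sums. With state-independent rates this
reduces exactly to the Kronecker sum of the local generators, and the
steady state of independent automata factorizes into the Kronecker
product of the local steady states — both reductions are exercised by
the test suite, as is exact lumpability: aggregating the steady state of
the full 2^12-state subgate chain by closed counts reproduces the
49-state model to ~1e-14 in the constant-rate regime.

Generators are materialized as explicit dense matrices with block
metadata. At <= 784 states, materialization is cheap and lets the
structured solvers index blocks directly; descriptor-only
(shuffle-product) solves are deliberately out of scope.

## Transition rates and conductances

Per subgate, the open->closed and closed->open transition probabilities
follow a Boltzmann law, `k = exp(A*P*(V - V0))`, `p_oc = K*k/(1+k)`,
`p_co = K/(1+k)`, converted to CTMC rates by `lambda = p/tau`. Units and
defaults:

* `A` (1/mV) — voltage sensitivity; >= 0, with `A = 0` the degenerate
  voltage-insensitive regime used by the closed-form tests.
* `P` (+1/-1) — gating polarity.
* `K` (dimensionless) and `tau` (time) — kinetics only; both cancel in
  the equilibrium ratio `p_oc/p_co = k`, so the steady state is
  invariant to them (tested through the full solver stack).
* `V0` (mV) — half-activation voltage.
* `Ro`, `Rc` (mV) — rectification constants of the open/closed subgate
  conductances `g_o = 2*exp(P*V/Ro)`, `g_c = 0.25*exp(P*V/Rc)`;
  infinity disables rectification. Exponentials saturate at |x| = 700
  rather than overflow.

The closed <-> deep-closed step has no printed rate law in the source
model family; this package reuses the same Boltzmann form with an
independent parameter set `{A_d, P_d, K_d, V0_d}` (deep closure treated
as a second, slower two-state gate nested on the closed state). The
deep state's conductance defaults to the closed-state conductance
(`g_deep_policy="closed"`) and can be set to a constant residual value.
These are package design choices, not literature-asserted laws.

Hemichannel conductance is the parallel sum over subgates; the
transjunctional voltage divides across the two series hemichannels at
the fixed point of `V_left = Vj * g_right/(g_left + g_right)` with both
conductances evaluated at the voltages being solved for. The fixed
point is found by damped iteration (damping 0.5, cap 100) and stops
when a full undamped step would change both voltages by less than 0.1 %
relative — at that point series current balance holds to the same
order, which the tests verify against an independent bisection root.
Each hemichannel's rates are evaluated at that hemichannel's voltage —
the per-hemichannel voltage is applied uniformly to its six subgates.

Docked hemichannels face each other, so by default the right
hemichannel senses the voltage across it with opposite sign
(`antiparallel=True`, configurable). This convention makes the g_j-V_j
curve of a homotypic channel an exact even function of V_j and makes
left/right parameter swap plus voltage reversal a pure state
relabeling; both symmetries are tested.

## Steady-state solution

`pi Q = 0` with `sum(pi) = 1` is solved four ways:

* **dense_ge** — the last balance equation of the transposed system is
  replaced by the normalization row; LAPACK dense solve.
* **banded_ge** — one probability is pinned and the remaining banded
  subsystem is solved by the banded LU driver; deleting the pinned
  state's row/column never widens the band. Pinning a state whose
  probability is ~20 orders of magnitude below the peak is numerically
  hostile, so the pin is chosen adaptively (start at the last state,
  re-pin at the largest-magnitude entry of a rejected attempt; accept
  on residual <= 1e-10 x scale and entries >= -1e-12).
* **block_recursive** — forward elimination `pi_i = pi_{i+1} S_i` over
  an equal-size block-tridiagonal partition with `S_i = -L_i (D_i +
  S_{i-1} U_{i-1})^{-1}`, a singular terminal block solve, and back
  substitution. Only defined for equal blocks (the 49-state model and
  toys); the varying-block 28-state model raises an explicit error.
  Despite the known rounding sensitivity of such recursions, the small
  generator entries (1e-4..1e-1) keep it within ~1e-12 of the dense
  solution, which the acceptance suite asserts.
* **block_gauss_seidel** — sweeps blocks in index order, solving
  `pi_i Q_ii = -sum_{j != i} pi_j Q_ji` against the diagonal block via
  the banded (Thomas, for tridiagonal blocks) driver, renormalizing
  after each sweep. Iteration stops when consecutive iterates differ by
  less than `epsilon` in every entry (default 1e-6), from a uniform
  1/n start unless a warm-start vector is supplied.

Numerical notes, chosen once and fixed:

* Stopping on consecutive-iterate differences leaves a final error of
  order `epsilon * rho/(1 - rho)` for contraction factor rho; measured
  against the dense oracle this is ~0.7*epsilon at the shipped defaults
  (rho ~ 0.43, ~2.7 iterations per decade) and up to ~12*epsilon for
  the steepest seeded parameter sets. Tests therefore assert iterative
  agreement at multiples of epsilon, and tighten epsilon when tight
  agreement is required.
* The residual `max|pi Q|` decreases monotonically over sweeps for the
  49- and 28-state models; the 784-state model can raise it once on the
  very first sweep (transient of the uniform start) and is monotone
  thereafter.
* Solutions are invariant to global rate rescaling `Q -> cQ` and to the
  DTMC/CTMC transformation `P = I + tau*Q` (both tested).

The group inverse `Q# = (Q + 1 pi)^{-1} - 1 pi` supports the
steady-state perturbation bound `||dpi||_1/||pi||_1 <= ||Q#||_inf
||dQ||_inf`, which justifies warm starts: a 0.1 mV voltage step
perturbs generator entries by ~1e-4..1e-3, so consecutive steady states
are close. Over a 0-100 mV sweep in 0.1 mV steps at epsilon = 1e-6,
warm starts cut total outer iterations by roughly half (55 % for the
shipped defaults) without changing the curve; the previous solution is
reused only for steps <= 1 mV, larger jumps fall back to the uniform
start.

## Complexity ledger

Abstract exact integer operation counts (never timings): standard
Gaussian elimination `(4n^3 + 9n^2 - 13n)/6`; banded elimination
`n(m+1)^2/4`; the block recursive procedure tallied from its six
operation kinds at block size 7 (total 3514); one block Gauss-Seidel
sweep at 122n = 854 (49-state) and 365n = 10220 (784-state). The
28-state model's per-sweep cost is carried as the constant 196 because
its varying block sizes do not fit the equal-block row scheme. Derived
thresholds: block Gauss-Seidel beats standard elimination below 96
(49-state) and 80 (28-state) outer iterations, beats the recursion at 4
or fewer, and the recursion is a 23.3-fold saving over standard
elimination.

## Synthetic parameters and what the tests do not show

No experimental parameter values ship with the package; the defaults
and the seeded fixture generator are labeled synthetic. The fixture
generator draws homotypic sets with `A in [0.01, 0.1]` /mV, `V0 in
[10, 60]` mV, `K in [0.005, 0.02]`, mild rectification (`Ro in
[100, 500]`, `Rc in [50, 300]` mV) and `tau = 1`, which puts
seed-averaged generator entries in the 1e-4..1e-1 band. Bandwidths are
measured, not assumed: the 49-state generator always has m = 15; the
28-state and 784-state generators measure m = 13 and m = 337 under the
block orderings used here.

Passing tests therefore demonstrate internal consistency — solver
equivalence, closed-form reductions, symmetry and invariance properties
— under realistic rate magnitudes, not fidelity to any particular
connexin isoform's recordings. Iteration counts of the iterative
solver, `||Q#||`, and the precise shape of the g_j-V_j curve all depend
on the gating parameters and will differ for fitted values.

Problem sizes used by the test and acceptance suites: all three model
variants at up to 10 seeded parameter sets x 6 voltages; full
0-100 mV / 0.1 mV warm-vs-cold sweeps on the 49-state model; one
4096-state lumping solve per suite.

## Known limitations

* No synchronizing events, descriptor-vector (shuffle) products, or
  projection methods (Arnoldi/GMRES/BiCGSTAB) — out of scope.
* No parameter fitting to recordings, dwell-time statistics, kinetic
  (time-course) simulation, or plaque-level multi-channel models.
* Heterotypic channels are expressible only as two different
  `GatingParams` sets; different isoform stoichiometries are not.
* The block recursive solver requires equal block sizes by
  construction.
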