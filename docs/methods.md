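# Methods

## Model

A network consists of M pools and N lanes. Lane *i* has `n_i` sites with
densities `x^i_j ∈ [0,1]`, rates `λ^i_0..λ^i_{n_i} > 0` (units 1/time;
densities and pool levels are dimensionless occupancies), a source pool
and a sink pool. The entry flux is `λ^i_0 G_i(z_src)(1 − x^i_1)`; the
input function `G_i` is continuous, strictly increasing and vanishes at
zero, so an empty pool admits no entries and a fuller pool admits more.
Site-to-site flux is `λ^i_j x^i_j (1 − x^i_{j+1})` (simple exclusion in
mean field), the exit flux `λ^i_{n_i} x^i_{n_i}` feeds the sink pool, and
each pool's level `z_j ≥ 0` evolves by its flux balance. The component
sum of the vector field is identically zero, so the total occupancy
`Q = Σ z + ΣΣ x` is a first integral.

Structural facts the implementation relies on (and the test suite checks
numerically rather than takes on faith): the state space
`[0,1]^{Σn_i} × [0,∞)^M` is invariant; trajectories separate uniformly
from its boundary (persistence); the Jacobian is Metzler, so the flow is
cooperative; every level set `{Q = r}` contains exactly one steady state
`e_r`, which attracts the whole level set; and `e_{r1} ≪ e_{r2}`
componentwise for `r1 < r2`.

The shipped input-function registry holds `identity`, `tanh` and
`scaled_identity` (c·z). Custom callables are accepted but vetted at
construction on a 65-point grid over [0, 10] for `G(0) = 0`, strict
monotonicity and non-negativity. Self-loop lanes (source = sink) are
accepted with a warning: they conserve particles trivially but fall
outside the bipartite two-pool theory.

## Steady states: two routes

**ODE relaxation + Newton.** `find_steady_state` integrates the dynamics
in growing chunks (LSODA, analytic Jacobian) until `‖f‖∞ < 1e-6`, then
runs Newton on the algebraic system in which one redundant pool equation
(the rows of f sum to zero) is replaced by the conservation constraint
`Q − r = 0`; the Jacobian row is replaced by ones accordingly. Newton is
run to a residual of 1e-12. Pure relaxation converges only linearly and
cannot certify 4-decimal agreement cheaply; the Newton step does.

**Spectral.** For a lane with effective entry rate `λ_0 G(e_z)`, the
steady-state densities are ratios of consecutive entries of the Perron
eigenvector of the `(n+2)×(n+2)` symmetric tridiagonal Jacobi matrix
with off-diagonals `λ_k^{−1/2}`, and the lane's flux is `1/σ²` with σ
the Perron eigenvalue (computed with the dedicated symmetric-tridiagonal
eigensolver, eigenvector sign fixed positive). A zero effective entry
returns the all-zero profile instead of building a singular matrix.
When the eigenvector underflows — long lanes with extreme rate ratios
localize it on a few entries — the densities are recovered from the
constant flux by recursion instead: backward
(`e_n = R/λ_n`, `e_j = R/(λ_j(1−e_{j+1}))`) for entry-limited lanes,
forward (`e_1 = 1 − R/λ_0^eff`, `e_{j+1} = 1 − R/(λ_j e_j)`) for
congested ones; each recursion is stable precisely in the regime it is
used for, and the result is validated to lie in (0, 1).

The pool levels solve conservation plus per-pool flux balance (one
balance is redundant). For a bipartite two-pool network this is a nested
bracketing bisection — outer on `z_1 ∈ (0, r)`, where total occupancy is
strictly increasing because every density and the balancing `z_2` rise
with `z_1`; inner on `z_2`, where the return lanes' aggregate output is
strictly increasing — with guaranteed convergence and tolerance 1e-12,
no Newton fragility. For M ≥ 3 pools the M−1 balances + conservation are
solved by a hybrid root solve in log pool levels (kept positive, clipped
to the physical bound `z ≤ 2r`) from a few multi-start initializations.
The two routes agree to better than 1e-6 on random network ensembles
(tested), which is the package's main internal cross-validation.

## Integration and conservation

Defaults `rtol = 1e-10`, `atol = 1e-12`: tight enough to hold the first
integral to `1e-8·max(1, Q)` over the horizons used and to reproduce
4-decimal steady-state values. Conservation is *monitored, not enforced*
— a projection step could silently mask an inconsistently assembled
field, so excessive drift raises instead. During relaxation (whose
endpoint is refined by Newton anyway) looser tolerances (1e-9/1e-11)
are used for speed.

## Periodic rates and entrainment

Time-varying rates are closures of t attached to specific (lane, site)
slots with a declared common period T; T-periodicity, continuity (by
sampling) and strict positivity are verified on a 64-point grid, not
assumed. The forced network entrains: trajectories converge to a unique
T-periodic orbit per level set. `estimate_period` discards the first 50%
of a uniformly sampled trajectory as transient, flags a component
constant when its peak-to-trough amplitude is below 1e-8, and otherwise
locates the dominant period as the global maximum of the biased
autocorrelation past the zero-lag lobe, refined by parabolic
interpolation. The biased (1/N) normalization tapers repeat peaks at
2T, 3T, … so the global maximum sits at the fundamental period; the
harmonic at T/2 carries less correlation unless the signal genuinely has
that period. On the sinusoidally forced benchmark this recovers the
period to ~0.2%, well within the ±1% acceptance band.

## Perturbation classification

For a rate increase `λ_k → λ̄_k` in one lane, the density at site k falls
and all downstream densities of that lane rise (always; checked as the
"local inequalities"). In a bipartite two-pool network, the rest of the
network follows one of five patterns determined by the two pool levels:
both rise (i); source falls, sink rises (ii); both fall (iii); source
unchanged, sink rises (iv); source falls, sink unchanged (v). Source
rising while the sink falls cannot occur. The classifier compares pool
levels with a relative tolerance (default 1e-6) for the equality cases —
which are measure-zero numerically and therefore rare — preferring
strict cases when the difference resolves, verifies that every
non-perturbed lane moves with the pool feeding it, ignores the
(unconstrained) sites upstream of the perturbed rate, and returns
`other` with diagnostics only when no pattern matches, which signals
numerical trouble since the case list is exhaustive. Decreased rates are
classified as the reversed increase. Sweeps classify consecutive grid
points (each step is a small increase), so monotone trends accumulate
across the grid.

## Exclusion-process Monte Carlo

The stochastic counterpart keeps integer particles: at most one per
site, integer pool counts, and exponential waiting times — hops at
`λ_j` where allowed, exits at `λ_n`, entries at `λ_0 G(z)` with z the
integer source-pool count. Since all clocks are exponential, the
Gillespie direct method (recompute propensities, sample one event) is
statistically exact and identical to per-transition clocks redrawn
whenever an enabling condition or pool level changes (memorylessness).
Propensities are fully recomputed after every event: the networks are
small (≲ 100 transitions) and a full refresh is cheap and immune to
incremental bookkeeping drift. Effective entry rates are pre-tabulated
for every integer pool level 0..Q, so custom input functions cost
nothing in the inner loop, which is numba-compiled (a pure-Python
fallback with the same semantics and random stream exists). Runs start
with empty lanes and all particles in the pools; occupancies are
time-weighted averages (occupied duration over retained duration) after
a burn-in of 10⁴ events by default. Fixed seeds give identical results.

Validation compares MC site means with the mean-field steady state by
pooled Pearson correlation over ensembles of random networks. The
scaled-down suite runs 10 networks × 10⁶ events (the desk-scale choice;
the correlation is insensitive to ensemble size well before that) on a
three-pool ring of 20/30/40-site lanes at 6 particles with hop rates
`base + U(0,1)`. The generator's ensembles emulate the variability of
heterogeneous transition rates; they do not emulate finite-size TASEP
correlations, so agreement here shows mean-field adequacy at low
density, not in the maximal-current regime, where boundary-layer
deviations of order 0.02–0.03 are real and expected (the single-chain
convergence test therefore probes the entry-limited regime).

## Numerical edge cases and limitations

- `r = 0` short-circuits to the all-zero steady state (the origin is the
  unique equilibrium of the empty network).
- Input functions are evaluated at `max(z, 0)` inside the vector field so
  that integrators may probe marginally negative pool levels without
  leaving the domain of G.
- The M ≥ 3 pool solve is a root find, not a bracketing method; it is
  verified against the ODE route but can in principle need better
  starting points for extreme topologies. The two-pool path never does.
- Equality cases (iv)/(v) of the classifier depend on the chosen
  tolerance; exact equalities do not occur in floating point.
- The Monte Carlo model interprets "steps" as events and uses integer
  pool counts; a fractional requested occupancy is rounded to the
  nearest integer with a warning.
- No inter-lane coupling other than through pools; no discrete-time
  parallel-update TASEP variant; no continued-fraction chain solver.
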