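"""Stochastic exclusion-process simulator with pool-dependent entry rates.

Cross-validates the mean-field ODE network: particles hop along each chain
under simple exclusion (a site holds at most one particle and a hop needs
an empty target), exiting into the chain's sink pool; a particle enters a
chain's first site from its source pool at rate l0 * G(z), where z is the
*integer* number of particles currently in the pool.  All waiting times
are exponential, so the process is simulated exactly with the Gillespie
direct method: after every event all transition propensities are
recomputed (by memorylessness this is statistically identical to keeping
per-transition exponential clocks and redrawing those whose enabling
condition or pool level changed).  Site occupancies are averaged with
time weighting (occupied duration / retained duration) after a burn-in.

The event loop is compiled with numba when available; a pure-Python
fallback with identical semantics and random stream is used otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import SteadyStateResult
from .network_model import PoolNetwork

__all__ = ["MCConfig", "MCResult", "simulate_exclusion", "compare_to_ode"]


@dataclass
class MCConfig:
    """Monte Carlo run configuration.

    ``total_particles`` is the integer first integral of the stochastic
    system; all particles start in the pools.  ``n_steps`` counts events
    and ``burn_in`` events are discarded before averaging.
    """

    total_particles: int
    n_steps: int = 10_000_000
    burn_in: int = 10_000
    seed: int = 0
    initial_pools: dict[str, int] | None = None

    def __post_init__(self):
        if self.total_particles != int(self.total_particles):
            warnings.warn(
                f"total_particles rounded from {self.total_particles} to "
                f"{round(self.total_particles)}: the stochastic system holds "
                f"an integer number of particles"
            )
            self.total_particles = int(round(self.total_particles))
        self.total_particles = int(self.total_particles)
        if self.total_particles < 0:
            raise ValueError("total_particles must be >= 0")
        if not 0 <= self.burn_in < max(self.n_steps, 1):
            raise ValueError("burn_in must be < n_steps")


@dataclass
class MCResult:
    """Time-averaged site occupancies and pool levels."""

    site_means: dict[str, np.ndarray]
    pool_means: dict[str, float]
    n_events: int
    elapsed_model_time: float
    config: MCConfig = field(repr=False, default=None)

    def flat_site_means(self, network: PoolNetwork) -> np.ndarray:
        return np.concatenate([self.site_means[c.chain_id] for c in network.chains])


def _event_loop(
    n_steps, burn_in, occ, pools, site_off, rate_flat, rate_off,
    src, dst, g_table, site_acc, pool_acc, seed,
):  # pragma: no cover - exercised through the njit/python dispatch
    np.random.seed(seed)
    C = len(site_off) - 1
    S = len(occ)
    M = len(pools)
    K = S + C  # one entry + (n-1) hops + one exit per chain
    a = np.zeros(K)
    t_retained = 0.0
    for step in range(n_steps):
        # recompute all propensities (chains are small; full refresh is
        # cheap and immune to bookkeeping drift)
        total = 0.0
        for c in range(C):
            lo = site_off[c]
            hi = site_off[c + 1]
            n = hi - lo
            ro = rate_off[c]
            to = lo + c
            # entry into site 1
            p = g_table[c, pools[src[c]]] if occ[lo] == 0 else 0.0
            a[to] = p
            total += p
            # hops j -> j+1 (j = 1..n-1)
            for j in range(1, n):
                if occ[lo + j - 1] == 1 and occ[lo + j] == 0:
                    p = rate_flat[ro + j]
                else:
                    p = 0.0
                a[to + j] = p
                total += p
            # exit from site n
            p = rate_flat[ro + n] if occ[hi - 1] == 1 else 0.0
            a[to + n] = p
            total += p
        if total <= 0.0:
            break
        dt = np.random.exponential(1.0) / total
        if step >= burn_in:
            t_retained += dt
            for i in range(S):
                if occ[i] == 1:
                    site_acc[i] += dt
            for j in range(M):
                pool_acc[j] += pools[j] * dt
        u = np.random.random() * total
        acc = 0.0
        k = K - 1
        for i in range(K):
            acc += a[i]
            if u < acc:
                k = i
                break
        # decode transition k
        c = 0
        for cc in range(C):
            if k < site_off[cc + 1] + cc + 1:
                c = cc
                break
        lo = site_off[c]
        hi = site_off[c + 1]
        n = hi - lo
        j = k - (lo + c)
        if j == 0:
            occ[lo] = 1
            pools[src[c]] -= 1
            if pools[src[c]] < 0:
                raise AssertionError("pool went negative")
        elif j < n:
            occ[lo + j - 1] = 0
            occ[lo + j] = 1
        else:
            occ[hi - 1] = 0
            pools[dst[c]] += 1
    return t_retained


try:  # compile the loop when numba is present
    import numba

    _event_loop_jit = numba.njit(_event_loop, cache=False)
except ImportError:  # pragma: no cover
    _event_loop_jit = _event_loop


def simulate_exclusion(network: PoolNetwork, cfg: MCConfig) -> MCResult:
    """Run the exclusion process and return time-averaged occupancies.

    Starts with empty chains and all particles in the pools (split as
    evenly as possible unless ``cfg.initial_pools`` says otherwise).  The
    integer particle count is conserved at every event and no site ever
    holds more than one particle.  Identical seeds give identical results.
    """
    Q = int(cfg.total_particles)
    C = network.n_chains
    M = network.n_pools
    site_off = np.zeros(C + 1, dtype=np.int64)
    rate_off = np.zeros(C + 1, dtype=np.int64)
    for i, c in enumerate(network.chains):
        site_off[i + 1] = site_off[i] + c.n_sites
        rate_off[i + 1] = rate_off[i] + c.n_sites + 1
    rate_flat = np.concatenate([np.asarray(c.rates) for c in network.chains])
    src = np.array([network.pools.index(c.source_pool) for c in network.chains],
                   dtype=np.int64)
    dst = np.array([network.pools.index(c.sink_pool) for c in network.chains],
                   dtype=np.int64)
    # tabulate the effective entry rate for every possible integer pool level
    g_table = np.zeros((C, Q + 1))
    for i, c in enumerate(network.chains):
        for z in range(Q + 1):
            g_table[i, z] = c.rates[0] * c.input_function._fn(float(z))
    if cfg.initial_pools is not None:
        pools = np.array([int(cfg.initial_pools.get(p, 0)) for p in network.pools],
                         dtype=np.int64)
        if pools.sum() != Q:
            raise ValueError("initial_pools must sum to total_particles")
    else:
        pools = np.full(M, Q // M, dtype=np.int64)
        pools[: Q % M] += 1
    occ = np.zeros(site_off[-1], dtype=np.int8)
    site_acc = np.zeros(site_off[-1])
    pool_acc = np.zeros(M)
    if Q == 0:
        t_ret = 0.0
        n_events = 0
    else:
        t_ret = _event_loop_jit(
            cfg.n_steps, cfg.burn_in, occ, pools, site_off, rate_flat,
            rate_off, src, dst, g_table, site_acc, pool_acc, int(cfg.seed),
        )
        n_events = cfg.n_steps
    if t_ret > 0:
        site_means_flat = site_acc / t_ret
        pool_means = pool_acc / t_ret
    else:
        site_means_flat = site_acc
        pool_means = pool_acc.astype(float)
        if Q == 0:
            pool_means = pools.astype(float)
    site_means = {
        c.chain_id: site_means_flat[site_off[i]:site_off[i + 1]].copy()
        for i, c in enumerate(network.chains)
    }
    total = sum(m.sum() for m in site_means.values()) + pool_means.sum()
    if Q > 0 and abs(total - Q) > 1e-6 * max(1, Q):
        warnings.warn(
            f"time-averaged occupancy {total:.6f} deviates from the particle "
            f"count {Q}; increase n_steps"
        )
    return MCResult(
        site_means=site_means,
        pool_means={p: float(pool_means[j]) for j, p in enumerate(network.pools)},
        n_events=n_events,
        elapsed_model_time=float(t_ret),
        config=cfg,
    )


def compare_to_ode(
    mc: MCResult, ss: SteadyStateResult, network: PoolNetwork | None = None
) -> tuple[float, float]:
    """Pearson correlation (r, p-value) between MC site means and the
    mean-field steady-state site densities, flattened over all chains."""
    network = network or ss.network
    a = mc.flat_site_means(network)
    b = np.concatenate([ss.chain_densities(c.chain_id) for c in network.chains])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance input to the correlation")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
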