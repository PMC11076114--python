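"""Reference networks used throughout the tests and documentation.

These are small, fully specified pool networks with known steady-state
behaviour, plus random-network generators for property testing and Monte
Carlo validation.  The deterministic ones are also shipped as YAML config
files under ``poolflow/benchmarks/`` for the command-line interface.
"""

from __future__ import annotations

import numpy as np

from .dynamics import TimeVaryingRates
from .network_model import ChainSpec, InputFunction, PoolNetwork, build_network

__all__ = [
    "two_pool_small",
    "two_pool_periodic",
    "single_bottleneck_free",
    "downstream_bottleneck",
    "two_competing_lanes",
    "three_pool_ring",
    "mc_validation_network",
    "random_two_pool_network",
    "three_pool_ring_random",
]


def two_pool_small() -> PoolNetwork:
    """One forward and one return lane of two sites each across two pools.

    With total occupancy r = 2 the steady state is
    [0.3589 0.2302 0.1909 0.2763 0.6023 0.3414] (4-decimal benchmark).
    """
    return build_network(
        pools=["I", "II"],
        chains=[
            ChainSpec("X1", 2, (0.8, 1.0, 1.2), "I", "II", InputFunction.tanh()),
            ChainSpec("Y1", 2, (1.0, 2.0, 1.0), "II", "I", InputFunction.identity()),
        ],
    )


def two_pool_periodic() -> tuple[PoolNetwork, TimeVaryingRates, np.ndarray]:
    """A two-pool network with sinusoidally varying rates of period 1.

    Returns (network, rates, initial state).  Every trajectory entrains to
    a period-1 orbit.  The constant-rate columns of the network definition
    hold the time averages of the varying rates.
    """
    net = build_network(
        pools=["I", "II"],
        chains=[
            ChainSpec("X1", 3, (0.8, 3.0, 3.0, 3.0), "I", "II", InputFunction.identity()),
            ChainSpec("Y1", 2, (1.2, 4.0, 1.0), "II", "I", InputFunction.identity()),
        ],
    )
    rates = TimeVaryingRates(
        functions={
            ("X1", 2): lambda t: 3.0 + 2.0 * np.sin(2 * np.pi * t),
            ("X1", 3): lambda t: 3.0 - 2.0 * np.sin(2 * np.pi * t),
            ("Y1", 1): lambda t: 4.0 - 2.0 * np.sin(2 * np.pi * t),
        },
        period=1.0,
    )
    v0 = np.zeros(net.state_size)
    v0[net.pool_index("II")] = 1.0
    return net, rates, v0


def single_bottleneck_free() -> PoolNetwork:
    """One 10-site forward lane, two 5-site return lanes, all rates 1.

    Raising any rate of the forward lane raises both pool levels (no
    internal bottleneck: extra throughput benefits the whole network).
    Reference total occupancy r = 0.4.
    """
    ident = InputFunction.identity()
    return build_network(
        pools=["I", "II"],
        chains=[
            ChainSpec("X1", 10, (1.0,) * 11, "I", "II", ident),
            ChainSpec("Y1", 5, (1.0,) * 6, "II", "I", ident),
            ChainSpec("Y2", 5, (1.0,) * 6, "II", "I", ident),
        ],
    )


def downstream_bottleneck() -> PoolNetwork:
    """A 20-site forward lane with a slow site-7 rate (0.1), 10-site return.

    Raising an upstream rate of the forward lane piles particles against
    the bottleneck: the source pool drains while the sink pool still
    gains.  Reference total occupancy r = 8.
    """
    ident = InputFunction.identity()
    lam = [1.0] * 21
    lam[7] = 0.1
    return build_network(
        pools=["I", "II"],
        chains=[
            ChainSpec("X1", 20, tuple(lam), "I", "II", ident),
            ChainSpec("Y1", 10, (1.0,) * 11, "II", "I", ident),
        ],
    )


def two_competing_lanes() -> PoolNetwork:
    """Two forward lanes (10 and 5 sites, the first with a slow site-7
    rate of 0.1) and two 5-site return lanes.

    Raising a mid-lane rate of the first forward lane depresses both pool
    levels: particles pile against the first lane's bottleneck while the
    lanes compete for the same source pool.  Reference total occupancy
    r = 8.
    """
    ident = InputFunction.identity()
    lam = [1.0] * 11
    lam[7] = 0.1
    return build_network(
        pools=["I", "II"],
        chains=[
            ChainSpec("X1", 10, tuple(lam), "I", "II", ident),
            ChainSpec("X2", 5, (1.0,) * 6, "I", "II", ident),
            ChainSpec("Y1", 5, (1.0,) * 6, "II", "I", ident),
            ChainSpec("Y2", 5, (1.0,) * 6, "II", "I", ident),
        ],
    )


def three_pool_ring() -> PoolNetwork:
    """Three 2-site lanes around a ring of three pools.

    With total occupancy r = 4 the steady state is
    [0.09514 0.04541 0.8249 0.9082 0.1998 0.0908 0.12613 0.5745 1.1350].
    """
    return build_network(
        pools=["P1", "P2", "P3"],
        chains=[
            ChainSpec("R1", 2, (0.8, 1.0, 2.0), "P1", "P2", InputFunction.tanh()),
            ChainSpec("R2", 2, (1.0, 1.2, 0.1), "P2", "P3", InputFunction.tanh()),
            ChainSpec("R3", 2, (0.1, 0.5, 1.0), "P3", "P1", InputFunction.identity()),
        ],
    )


def mc_validation_network(seed: int = 0) -> PoolNetwork:
    """Two forward lanes (10, 15 sites) and one 15-site return lane with
    jittered rates, for exclusion-process validation at 7 particles.

    Rates: entry 1 everywhere; lane 1 hops 1 + U(0,1), lane 2 hops
    2 + U(0,1), return lane hops 5 + U(0,1).
    """
    rng = np.random.default_rng(seed)
    ident = InputFunction.identity()

    def jitter(base, n):
        return (1.0,) + tuple(base + rng.uniform(0.0, 1.0) for _ in range(n))

    return build_network(
        pools=["I", "II"],
        chains=[
            ChainSpec("X1", 10, jitter(1.0, 10), "I", "II", ident),
            ChainSpec("X2", 15, jitter(2.0, 15), "I", "II", ident),
            ChainSpec("Y1", 15, jitter(5.0, 15), "II", "I", ident),
        ],
    )


def random_two_pool_network(
    rng: np.random.Generator,
    *,
    n_forward: int | None = None,
    n_return: int | None = None,
    site_range: tuple[int, int] = (2, 10),
    rate_range: tuple[float, float] = (0.1, 5.0),
) -> PoolNetwork:
    """A random bipartite two-pool network for property tests.

    Chain lengths are uniform over ``site_range``, rates uniform over
    ``rate_range`` and input functions drawn from {identity, tanh}.
    """
    n_forward = n_forward or int(rng.integers(1, 4))
    n_return = n_return or int(rng.integers(1, 4))
    funcs = [InputFunction.identity(), InputFunction.tanh()]

    def make(cid, src, dst):
        n = int(rng.integers(site_range[0], site_range[1] + 1))
        rates = tuple(rng.uniform(*rate_range, size=n + 1))
        return ChainSpec(cid, n, rates, src, dst, funcs[int(rng.integers(2))])

    chains = [make(f"X{i + 1}", "I", "II") for i in range(n_forward)]
    chains += [make(f"Y{i + 1}", "II", "I") for i in range(n_return)]
    return build_network(["I", "II"], chains)


def three_pool_ring_random(rng: np.random.Generator) -> PoolNetwork:
    """The 20/30/40-site three-pool ring with jittered rates used for the
    Monte Carlo validation ensemble (entry rates 1, hop rates base +
    U(0,1) with bases 0.5, 2 and 1; identity input functions; intended
    total occupancy 6)."""
    ident = InputFunction.identity()
    dims = (20, 30, 40)
    bases = (0.5, 2.0, 1.0)
    pools = ["P1", "P2", "P3"]
    chains = []
    for i, (n, b) in enumerate(zip(dims, bases)):
        rates = (1.0,) + tuple(b + rng.uniform(0.0, 1.0) for _ in range(n))
        chains.append(
            ChainSpec(f"R{i + 1}", n, rates, pools[i], pools[(i + 1) % 3], ident)
        )
    return build_network(pools, chains)
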