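"""Domain types for pool-coupled ribosome flow model (RFM) networks.

A network consists of M particle *pools* and N unidirectional transport
*chains* (RFM lanes).  Each chain draws particles from its source pool at an
effective entry rate ``lambda_0 * G(z)`` -- where ``z`` is the source pool's
occupancy and ``G`` a strictly increasing *input function* with ``G(0) = 0``
-- and deposits the particles leaving its last site into its sink pool.  The
closed system conserves the total occupancy

    Q = sum(pool levels) + sum(all site densities),

which is the network's first integral.

The state-vector layout is fixed by declaration order: all sites of chain 1,
then chain 2, ..., then the pool levels in pool declaration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "InputFunction",
    "ChainSpec",
    "PoolNetwork",
    "NetworkState",
    "build_network",
    "total_occupancy",
    "evaluate_input_function",
    "register_input_function",
]


# ---------------------------------------------------------------------------
# Input functions (pool outflow functions G / H)
# ---------------------------------------------------------------------------

#: grid used to vet monotonicity / non-negativity of input functions
_CHECK_GRID = np.linspace(0.0, 10.0, 65)


def _check_input_function(fn: Callable[[float], float], name: str) -> None:
    """Verify fn(0)=0, strict increase and non-negativity on a grid."""
    vals = np.array([float(fn(z)) for z in _CHECK_GRID])
    if abs(vals[0]) > 1e-12:
        raise ValueError(f"input function {name!r} must satisfy G(0)=0, got {vals[0]!r}")
    if np.any(vals < -1e-12):
        raise ValueError(f"input function {name!r} returns negative values")
    if np.any(np.diff(vals) <= 0):
        raise ValueError(f"input function {name!r} is not strictly increasing on [0, 10]")


_REGISTRY: dict[str, Callable[..., tuple[Callable, Callable]]] = {}


def register_input_function(name: str, factory: Callable[..., tuple[Callable, Callable]]) -> None:
    """Register a named input-function family.

    ``factory(**params)`` must return a pair ``(fn, dfn)`` of callables
    (the function and its derivative).  The function is vetted for the
    G(0)=0 / strict-monotonicity contract at :class:`InputFunction`
    construction time.
    """
    _REGISTRY[name] = factory


register_input_function("identity", lambda: (lambda z: z, lambda z: 1.0))
register_input_function("tanh", lambda: (np.tanh, lambda z: 1.0 / np.cosh(z) ** 2))
register_input_function(
    "scaled_identity", lambda c=1.0: (lambda z: c * z, lambda z: c)
)


@dataclass(frozen=True)
class InputFunction:
    """A pool outflow function G: [0, inf) -> [0, inf).

    Must vanish at zero and be continuous and strictly increasing; these
    properties make the entry flux shut off exactly when the feeding pool
    is empty and guarantee the cooperative structure of the network flow.
    """

    name: str
    params: dict = field(default_factory=dict)
    _fn: Callable[[float], float] = field(default=None, repr=False, compare=False)
    _dfn: Callable[[float], float] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._fn is None:
            if self.name not in _REGISTRY:
                raise ValueError(
                    f"unknown input function {self.name!r}; known: {sorted(_REGISTRY)}"
                )
            fn, dfn = _REGISTRY[self.name](**self.params)
            object.__setattr__(self, "_fn", fn)
            object.__setattr__(self, "_dfn", dfn)
        _check_input_function(self._fn, self.name)

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "InputFunction":
        return cls("identity")

    @classmethod
    def tanh(cls) -> "InputFunction":
        return cls("tanh")

    @classmethod
    def scaled_identity(cls, c: float) -> "InputFunction":
        return cls("scaled_identity", {"c": float(c)})

    @classmethod
    def custom(cls, fn, dfn=None, name: str = "custom") -> "InputFunction":
        """Wrap a user callable; it is vetted on a grid at construction."""
        return cls(name="custom", params={"label": name}, _fn=fn, _dfn=dfn)

    # -- evaluation ---------------------------------------------------------
    def __call__(self, z: float) -> float:
        if np.any(np.asarray(z) < 0):
            raise ValueError("input functions are defined on [0, inf)")
        return self._fn(z)

    def derivative(self, z: float) -> float:
        if self._dfn is None:
            raise ValueError(
                f"input function {self.name!r} has no registered derivative"
            )
        return self._dfn(z)

    def to_dict(self) -> dict:
        if self.name == "custom":
            raise ValueError("custom input functions cannot be serialized")
        return {"name": self.name, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "InputFunction":
        return cls(d["name"], dict(d.get("params", {}) or {}))


def evaluate_input_function(spec: InputFunction, z: float) -> float:
    """Evaluate an input function at pool occupancy ``z >= 0``."""
    return spec(z)


# ---------------------------------------------------------------------------
# Chains and networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSpec:
    """One RFM lane: ``n_sites`` sites and ``n_sites + 1`` hop rates.

    ``rates[0]`` is the bare entry rate (multiplied by G(source pool level)
    to give the effective entry rate), ``rates[j]`` the hop rate from site
    j to j+1 and ``rates[-1]`` the exit rate into the sink pool.  Rates
    have units of 1/time; site densities are dimensionless in [0, 1].
    """

    chain_id: str
    n_sites: int
    rates: tuple[float, ...]
    source_pool: str
    sink_pool: str
    input_function: InputFunction

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError(f"chain {self.chain_id!r}: n_sites must be >= 1")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.rates) != self.n_sites + 1:
            raise ValueError(
                f"chain {self.chain_id!r}: expected {self.n_sites + 1} rates "
                f"(entry, hops, exit), got {len(self.rates)}"
            )
        if any(r <= 0 for r in self.rates):
            raise ValueError(f"chain {self.chain_id!r}: all rates must be > 0")

    def with_rate(self, site_index: int, new_rate: float) -> "ChainSpec":
        """Copy with rate at ``site_index`` (0 = entry, n = exit) replaced."""
        if not 0 <= site_index <= self.n_sites:
            raise IndexError(
                f"chain {self.chain_id!r}: site_index {site_index} outside "
                f"0..{self.n_sites}"
            )
        if new_rate <= 0:
            raise ValueError("rates must be > 0")
        rates = list(self.rates)
        rates[site_index] = float(new_rate)
        return ChainSpec(
            self.chain_id, self.n_sites, tuple(rates),
            self.source_pool, self.sink_pool, self.input_function,
        )

    def to_dict(self) -> dict:
        return {
            "id": self.chain_id,
            "n_sites": self.n_sites,
            "rates": list(self.rates),
            "source_pool": self.source_pool,
            "sink_pool": self.sink_pool,
            "input_function": self.input_function.to_dict(),
        }


@dataclass(frozen=True)
class PoolNetwork:
    """The directed multigraph of pools (nodes) and chains (edges).

    Declaration order of ``chains`` then ``pools`` defines the state-vector
    layout used by every numerical routine in the package.
    """

    pools: tuple[str, ...]
    chains: tuple[ChainSpec, ...]

    # -- layout -------------------------------------------------------------
    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_sites_total(self) -> int:
        return sum(c.n_sites for c in self.chains)

    @property
    def state_size(self) -> int:
        """Total state dimension s = sum of site counts + number of pools."""
        return self.n_sites_total + self.n_pools

    def chain_slice(self, chain_id: str) -> slice:
        """Index range of a chain's site densities in the state vector."""
        off = 0
        for c in self.chains:
            if c.chain_id == chain_id:
                return slice(off, off + c.n_sites)
            off += c.n_sites
        raise KeyError(f"unknown chain {chain_id!r}")

    def pool_index(self, pool_id: str) -> int:
        """Index of a pool level in the state vector."""
        try:
            return self.n_sites_total + self.pools.index(pool_id)
        except ValueError:
            raise KeyError(f"unknown pool {pool_id!r}") from None

    def get_chain(self, chain_id: str) -> ChainSpec:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"unknown chain {chain_id!r}")

    def state_labels(self) -> list[str]:
        labels = [
            f"{c.chain_id}.x{j + 1}" for c in self.chains for j in range(c.n_sites)
        ]
        labels += [f"pool.{p}" for p in self.pools]
        return labels

    def chains_from_pool(self, pool_id: str) -> list[ChainSpec]:
        return [c for c in self.chains if c.source_pool == pool_id]

    def chains_into_pool(self, pool_id: str) -> list[ChainSpec]:
        return [c for c in self.chains if c.sink_pool == pool_id]

    # -- editing ------------------------------------------------------------
    def with_rate(self, chain_id: str, site_index: int, new_rate: float) -> "PoolNetwork":
        chains = tuple(
            c.with_rate(site_index, new_rate) if c.chain_id == chain_id else c
            for c in self.chains
        )
        if all(c is o for c, o in zip(chains, self.chains)):
            raise KeyError(f"unknown chain {chain_id!r}")
        return PoolNetwork(self.pools, chains)

    # -- interoperability ---------------------------------------------------
    def to_multigraph(self) -> nx.MultiDiGraph:
        """Export the pool multigraph (nodes = pools, edges = chains)."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.pools)
        for c in self.chains:
            g.add_edge(
                c.source_pool,
                c.sink_pool,
                key=c.chain_id,
                chain_id=c.chain_id,
                n_sites=c.n_sites,
                rates=",".join(repr(r) for r in c.rates),
                input_function=c.input_function.name,
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_multigraph(), path)

    def to_dict(self) -> dict:
        return {
            "pools": list(self.pools),
            "chains": [c.to_dict() for c in self.chains],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoolNetwork":
        chains = [
            ChainSpec(
                chain_id=str(cd["id"]),
                n_sites=int(cd["n_sites"]),
                rates=tuple(cd["rates"]),
                source_pool=str(cd["source_pool"]),
                sink_pool=str(cd["sink_pool"]),
                input_function=InputFunction.from_dict(cd["input_function"]),
            )
            for cd in d["chains"]
        ]
        return build_network([str(p) for p in d["pools"]], chains)


def build_network(
    pools: Sequence[str],
    chains: Sequence[ChainSpec],
    *,
    warn_self_loops: bool = True,
) -> PoolNetwork:
    """Validate and assemble a :class:`PoolNetwork`.

    Every pool must have at least one inbound and at least one outbound
    chain (otherwise the pool is a pure source or sink and the system is
    not a closed particle-conserving network).  Self-loop chains (source
    pool == sink pool) are accepted but flagged with a warning.
    """
    pools = tuple(str(p) for p in pools)
    if len(set(pools)) != len(pools):
        raise ValueError("pool identifiers must be unique")
    ids = [c.chain_id for c in chains]
    if len(set(ids)) != len(ids):
        raise ValueError("chain identifiers must be unique")
    if not pools or not chains:
        raise ValueError("a network needs at least one pool and one chain")
    pool_set = set(pools)
    inbound: dict[str, int] = {p: 0 for p in pools}
    outbound: dict[str, int] = {p: 0 for p in pools}
    for c in chains:
        for role, pid in (("source_pool", c.source_pool), ("sink_pool", c.sink_pool)):
            if pid not in pool_set:
                raise ValueError(
                    f"chain {c.chain_id!r}: {role} {pid!r} is not a declared pool"
                )
        outbound[c.source_pool] += 1
        inbound[c.sink_pool] += 1
        if c.source_pool == c.sink_pool and warn_self_loops:
            warnings.warn(
                f"chain {c.chain_id!r} feeds back into its own source pool "
                f"{c.source_pool!r}",
                stacklevel=2,
            )
    for p in pools:
        if outbound[p] == 0:
            raise ValueError(f"pool {p!r} has no outbound chain")
        if inbound[p] == 0:
            raise ValueError(f"pool {p!r} has no inbound chain")
    return PoolNetwork(pools, tuple(chains))


# ---------------------------------------------------------------------------
# States and the first integral
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Site densities per chain plus pool levels at one time point."""

    site_densities: dict[str, np.ndarray]
    pool_levels: dict[str, float]

    def to_vector(self, network: PoolNetwork) -> np.ndarray:
        v = np.empty(network.state_size)
        for c in network.chains:
            x = np.asarray(self.site_densities[c.chain_id], dtype=float)
            if x.shape != (c.n_sites,):
                raise ValueError(
                    f"chain {c.chain_id!r}: expected {c.n_sites} site densities"
                )
            v[network.chain_slice(c.chain_id)] = x
        for p in network.pools:
            v[network.pool_index(p)] = float(self.pool_levels[p])
        return v

    @classmethod
    def from_vector(cls, network: PoolNetwork, v: np.ndarray) -> "NetworkState":
        v = np.asarray(v, dtype=float)
        if v.shape != (network.state_size,):
            raise ValueError(
                f"state vector must have length {network.state_size}, got {v.shape}"
            )
        return cls(
            site_densities={
                c.chain_id: v[network.chain_slice(c.chain_id)].copy()
                for c in network.chains
            },
            pool_levels={p: float(v[network.pool_index(p)]) for p in network.pools},
        )

    @classmethod
    def pools_only(cls, network: PoolNetwork, levels: dict[str, float] | float) -> "NetworkState":
        """Empty chains with the given pool levels (a number splits evenly)."""
        if not isinstance(levels, dict):
            levels = {p: float(levels) / network.n_pools for p in network.pools}
        return cls(
            site_densities={c.chain_id: np.zeros(c.n_sites) for c in network.chains},
            pool_levels={p: float(levels.get(p, 0.0)) for p in network.pools},
        )


def check_in_state_space(v: np.ndarray, network: PoolNetwork, tol: float = 1e-9) -> None:
    """Raise if a state vector leaves [0,1]^sites x [0,inf)^pools by > tol."""
    ns = network.n_sites_total
    x = v[:ns]
    z = v[ns:]
    if np.any(x < -tol) or np.any(x > 1 + tol) or np.any(z < -tol):
        raise ValueError("state outside the invariant state space")


def total_occupancy(state, network: PoolNetwork | None = None) -> float:
    """First integral Q: all pool levels plus all site densities.

    Accepts a :class:`NetworkState` (with ``network``) or a plain state
    vector.  Q is conserved along every trajectory of the closed network.
    """
    if isinstance(state, NetworkState):
        if network is None:
            return float(
                sum(np.sum(x) for x in state.site_densities.values())
                + sum(state.pool_levels.values())
            )
        state = state.to_vector(network)
    return float(np.sum(np.asarray(state, dtype=float)))
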