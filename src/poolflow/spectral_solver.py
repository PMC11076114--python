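"""Simulation-free steady states via Perron eigenpairs of Jacobi matrices.

For an isolated RFM chain with rates (l0, ..., ln), the steady-state site
densities are encoded in the Perron (maximal) eigenpair of the symmetric,
non-negative, irreducible (n+2)x(n+2) tridiagonal matrix whose off-diagonal
entries are l_k^(-1/2):

    e_j  = zeta_{j+2} / (sqrt(l_j) * sigma * zeta_{j+1}),    j = 1..n,
    R    = 1 / sigma**2                    (steady-state output flux).

For a chain inside a pool network the entry rate is replaced by the
*effective* entry rate l0 * G(e_z) with e_z the steady-state level of the
source pool.  The pool levels themselves solve a small nonlinear system:
the conservation constraint (total occupancy = r) together with one flux
balance (inbound = outbound) per pool, of which one is redundant.  Since a
chain's output flux and every site density increase strictly with its
effective entry rate, the two-pool system can be solved by nested
bracketing bisection with guaranteed convergence; networks with three or
more pools use a damped root solve in log pool levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal
from scipy.optimize import brentq, root

from .dynamics import SteadyStateResult
from .network_model import ChainSpec, PoolNetwork

__all__ = [
    "JacobiSpectrum",
    "PoolBalanceSolution",
    "jacobi_matrix",
    "perron_eigenpair",
    "chain_steady_state",
    "steady_state_output_rate",
    "solve_pool_balance",
]


@dataclass
class JacobiSpectrum:
    """Perron eigenvalue sigma > 0 and all-positive eigenvector zeta."""

    sigma: float
    zeta: np.ndarray


@dataclass
class PoolBalanceSolution:
    """Steady-state pool levels and per-chain densities at occupancy r."""

    pool_levels: dict[str, float]
    chain_densities: dict[str, np.ndarray]
    chain_sigmas: dict[str, float]
    r: float
    residual: float

    def to_result(self, network: PoolNetwork) -> SteadyStateResult:
        v = np.empty(network.state_size)
        for c in network.chains:
            v[network.chain_slice(c.chain_id)] = self.chain_densities[c.chain_id]
        for p in network.pools:
            v[network.pool_index(p)] = self.pool_levels[p]
        from .dynamics import vector_field  # local import avoids cycle at import time

        res = float(np.max(np.abs(vector_field(network, v))))
        return SteadyStateResult(
            e=v, r=self.r, residual=res, method="spectral",
            diagnostics={"pool_residual": self.residual,
                         "sigma": dict(self.chain_sigmas)},
            network=network,
        )


# ---------------------------------------------------------------------------
# Single-chain spectral machinery
# ---------------------------------------------------------------------------

def jacobi_matrix(rates) -> np.ndarray:
    """Symmetric tridiagonal (n+2)x(n+2) matrix with zero diagonal and
    off-diagonal entries rates[k]**(-1/2).

    ``rates[0]`` should already be the effective entry rate (l0 * G(e_z)
    for a pooled chain).
    """
    lam = np.asarray(rates, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("all rates must be > 0")
    off = lam ** -0.5
    n2 = len(lam) + 1
    A = np.zeros((n2, n2))
    idx = np.arange(len(lam))
    A[idx, idx + 1] = off
    A[idx + 1, idx] = off
    return A


def perron_eigenpair(rates_or_matrix) -> JacobiSpectrum:
    """Maximal eigenpair of a Jacobi matrix, eigenvector sign-fixed positive.

    Accepts either the rate list or the assembled matrix.  Uses the
    dedicated symmetric-tridiagonal eigensolver restricted to the top
    eigenvalue.
    """
    A = np.asarray(rates_or_matrix, dtype=float)
    if A.ndim == 1:
        A = jacobi_matrix(A)
    d = np.ascontiguousarray(np.diag(A))
    e = np.ascontiguousarray(np.diag(A, 1))
    m = A.shape[0]
    w, vec = eigh_tridiagonal(d, e, select="i", select_range=(m - 1, m - 1))
    zeta = vec[:, 0]
    if zeta[0] < 0:
        zeta = -zeta
    if np.any(zeta <= 0):
        raise RuntimeError("Perron eigenvector is not strictly positive")
    return JacobiSpectrum(sigma=float(w[0]), zeta=zeta)


def _densities_from_eigenvector(lam: np.ndarray, spec: JacobiSpectrum) -> np.ndarray:
    n = len(lam) - 1
    j = np.arange(1, n + 1)
    return spec.zeta[j + 1] / (np.sqrt(lam[j]) * spec.sigma * spec.zeta[j])


def _densities_from_flux(lam: np.ndarray, sigma: float) -> np.ndarray:
    """Recover densities from the constant chain flux R = 1/sigma**2.

    The backward recursion e_n = R/l_n, e_j = R/(l_j (1 - e_{j+1})) is
    stable for entry-limited (low-density) chains; the forward recursion
    e_1 = 1 - R/l0_eff, e_{j+1} = 1 - R/(l_j e_j) is stable for congested
    ones.  Try the one matching the regime first, then the other.
    """
    R = 1.0 / sigma ** 2
    n = len(lam) - 1

    def backward():
        e = np.empty(n)
        e[n - 1] = R / lam[n]
        for i in range(n - 2, -1, -1):
            e[i] = R / (lam[i + 1] * (1.0 - e[i + 1]))
        return e

    def forward():
        e = np.empty(n)
        e[0] = 1.0 - R / lam[0]
        for i in range(1, n):
            e[i] = 1.0 - R / (lam[i] * e[i - 1])
        return e

    order = (backward, forward) if lam[0] <= np.min(lam[1:]) else (forward, backward)
    for rec in order:
        with np.errstate(all="ignore"):
            e = rec()
        if np.all(np.isfinite(e)) and np.all(e > 0) and np.all(e < 1):
            return e
    raise RuntimeError("flux recursions produced densities outside (0, 1)")


def chain_steady_state(rates, effective_entry_rate: float | None = None) -> np.ndarray:
    """Steady-state site densities of one chain from its Perron eigenpair.

    ``rates`` are the chain's (n+1) rates; if ``effective_entry_rate`` is
    given it replaces ``rates[0]``.  A zero effective entry (empty source
    pool) yields the all-zero profile rather than a singular matrix.  When
    the eigenvector underflows (long chains with extreme rate ratios
    localize it on a few entries), the densities are recovered instead
    from the constant steady-state flux 1/sigma**2, which only needs the
    eigenvalue.
    """
    lam = np.array(rates, dtype=float)
    if effective_entry_rate is not None:
        lam[0] = effective_entry_rate
    n = len(lam) - 1
    if lam[0] == 0.0:
        return np.zeros(n)
    sigma = _perron_eigenvalue(lam)
    try:
        e = _densities_from_eigenvector(lam, perron_eigenpair(lam))
        if np.all(np.isfinite(e)) and np.all(e > 0) and np.all(e < 1):
            return e
    except RuntimeError:
        pass
    return _densities_from_flux(lam, sigma)


def steady_state_output_rate(spectrum_or_sigma) -> float:
    """Steady-state output flux R = 1 / sigma**2."""
    sigma = getattr(spectrum_or_sigma, "sigma", spectrum_or_sigma)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return 1.0 / float(sigma) ** 2


def _perron_eigenvalue(lam: np.ndarray) -> float:
    d = np.zeros(len(lam) + 1)
    e = np.ascontiguousarray(lam ** -0.5)
    m = len(lam) + 1
    w = eigh_tridiagonal(d, e, select="i", select_range=(m - 1, m - 1),
                         eigvals_only=True)
    return float(w[0])


def _chain_profile(chain: ChainSpec, z_source: float) -> tuple[np.ndarray, float, float]:
    """(densities, output flux, sigma) of a chain fed by a pool at level z."""
    eff = chain.rates[0] * chain.input_function._fn(max(z_source, 0.0))
    if eff <= 0.0:
        return np.zeros(chain.n_sites), 0.0, np.inf
    lam = np.array(chain.rates, dtype=float)
    lam[0] = eff
    sigma = _perron_eigenvalue(lam)
    dens = chain_steady_state(chain.rates, eff)
    return dens, 1.0 / sigma ** 2, sigma


def _chain_output(chain: ChainSpec, z_source: float) -> float:
    lam = np.array(chain.rates, dtype=float)
    lam[0] = chain.rates[0] * chain.input_function._fn(max(z_source, 0.0))
    if lam[0] <= 0.0:
        return 0.0
    return 1.0 / _perron_eigenvalue(lam) ** 2


# ---------------------------------------------------------------------------
# Pool balance
# ---------------------------------------------------------------------------

def _is_two_pool_bipartite(network: PoolNetwork) -> bool:
    if network.n_pools != 2:
        return False
    return all(c.source_pool != c.sink_pool for c in network.chains)


def _solve_two_pool(network: PoolNetwork, r: float, tol: float) -> PoolBalanceSolution:
    """Nested bisection for the bipartite two-pool network.

    Outer bracket on the first pool level z1: total occupancy S(z1) is
    strictly increasing (raising z1 raises every chain's effective entry
    rate, hence every density, and forces the balancing z2 up as well).
    Inner bracket on z2: the aggregate output of the chains fed by pool 2
    is strictly increasing in z2 and must equal the aggregate output of
    the chains fed by pool 1.
    """
    p1, p2 = network.pools
    out1 = network.chains_from_pool(p1)  # fed by pool 1 (output -> pool 2)
    out2 = network.chains_from_pool(p2)

    def z2_for(z1: float) -> float | None:
        """Level of pool 2 whose chains' total output matches pool 1's."""
        target = sum(_chain_output(c, z1) for c in out1)
        if target <= 0.0:
            return 0.0

        def h(z2):
            return sum(_chain_output(c, z2) for c in out2) - target

        lo, hi = 0.0, max(r, 1.0)
        f_hi = h(hi)
        while f_hi < 0.0:
            hi *= 4.0
            if hi > 1e12:
                return None  # pool 1's output exceeds what pool 2 can pass
            f_hi = h(hi)
        return brentq(h, lo, hi, xtol=1e-14, rtol=8.9e-16)

    def occupancy_excess(z1: float) -> float:
        z2 = z2_for(z1)
        if z2 is None:
            return np.inf
        sites = sum(_chain_profile(c, z1)[0].sum() for c in out1)
        sites += sum(_chain_profile(c, z2)[0].sum() for c in out2)
        return z1 + z2 + sites - r

    lo, hi = 0.0, r
    # occupancy_excess(0) = -r < 0 and occupancy_excess(r) >= 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if occupancy_excess(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < max(tol, 1e-15 * r):
            break
    z1 = 0.5 * (lo + hi)
    z2 = z2_for(z1)
    if z2 is None:
        raise RuntimeError(
            f"pool-balance bisection failed: no feasible level for pool {p2!r} "
            f"at z1 = {z1!r} (bracket [{lo}, {hi}])"
        )
    levels = {p1: z1, p2: z2}
    return _assemble_solution(network, levels, r)


def _assemble_solution(network, levels: dict[str, float], r: float) -> PoolBalanceSolution:
    dens, sig = {}, {}
    for c in network.chains:
        d, _, s = _chain_profile(c, levels[c.source_pool])
        dens[c.chain_id] = d
        sig[c.chain_id] = s
    total = sum(levels.values()) + sum(d.sum() for d in dens.values())
    resid = abs(total - r)
    for p in network.pools:
        inflow = sum(
            c.rates[-1] * dens[c.chain_id][-1] for c in network.chains_into_pool(p)
        )
        outflow = sum(
            _chain_profile(c, levels[p])[1] for c in network.chains_from_pool(p)
        )
        resid = max(resid, abs(inflow - outflow))
    return PoolBalanceSolution(
        pool_levels=levels, chain_densities=dens, chain_sigmas=sig,
        r=r, residual=resid,
    )


def _solve_m_pool(network: PoolNetwork, r: float, tol: float) -> PoolBalanceSolution:
    """General M-pool solve: M-1 per-pool flux balances + conservation,
    in log pool levels (keeps levels positive)."""
    M = network.n_pools

    w_max = np.log(2.0 * r)  # pool levels are bounded by the first integral

    def residuals(w: np.ndarray) -> np.ndarray:
        z = np.exp(np.clip(w, -700, w_max))
        levels = dict(zip(network.pools, z))
        profiles = {c.chain_id: _chain_profile(c, levels[c.source_pool]) for c in network.chains}
        res = np.empty(M)
        for j, p in enumerate(network.pools[:-1]):
            inflow = sum(
                profiles[c.chain_id][1] for c in network.chains_into_pool(p)
            )
            outflow = sum(
                profiles[c.chain_id][1] for c in network.chains_from_pool(p)
            )
            res[j] = inflow - outflow
        total = z.sum() + sum(pr[0].sum() for pr in profiles.values())
        res[-1] = total - r
        return res

    best = None
    for frac in (0.5, 0.2, 0.8):
        w0 = np.full(M, np.log(frac * r / M))
        sol = root(residuals, w0, method="hybr", options={"xtol": 1e-13})
        nrm = np.max(np.abs(residuals(sol.x)))
        if best is None or nrm < best[1]:
            best = (sol.x, nrm)
        if nrm < tol:
            break
    w, nrm = best
    if nrm > max(tol, 1e-9):
        raise RuntimeError(
            f"pool-balance root solve did not converge (residual {nrm:.2e})"
        )
    levels = dict(zip(network.pools, np.exp(np.clip(w, -700, w_max))))
    return _assemble_solution(network, levels, r)


def solve_pool_balance(
    network: PoolNetwork, r: float, tol: float = 1e-12
) -> PoolBalanceSolution:
    """Steady-state pool levels and chain densities at total occupancy r.

    Solves the conservation + flux-balance system in the pool levels only;
    chain densities follow from the spectral chain solve at effective
    entry rate l0 * G(e_z).  Agrees with the ODE-relaxation route (this is
    checked extensively in the test suite).
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    if r == 0.0:
        return PoolBalanceSolution(
            pool_levels={p: 0.0 for p in network.pools},
            chain_densities={c.chain_id: np.zeros(c.n_sites) for c in network.chains},
            chain_sigmas={c.chain_id: np.inf for c in network.chains},
            r=0.0, residual=0.0,
        )
    if _is_two_pool_bipartite(network):
        return _solve_two_pool(network, r, tol)
    return _solve_m_pool(network, r, tol)
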