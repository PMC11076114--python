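"""ODE dynamics of pool-coupled RFM networks.

The network is a closed, cooperative (Metzler-Jacobian) dynamical system
with the total occupancy Q as a first integral: every level set {Q = r}
contains exactly one steady state, which attracts every trajectory that
starts inside it.  This module assembles the vector field and its analytic
Jacobian, integrates trajectories (with conservation monitoring), finds
steady states by relaxation + Newton refinement on the conservation-
constrained algebraic system, and estimates the asymptotic period of
trajectories driven by periodically varying rates (entrainment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network_model import (
    NetworkState,
    PoolNetwork,
    total_occupancy,
)

__all__ = [
    "TimeVaryingRates",
    "Trajectory",
    "SteadyStateResult",
    "PeriodEstimate",
    "vector_field",
    "jacobian",
    "integrate",
    "find_steady_state",
    "simulate_periodic",
    "estimate_period",
]


# ---------------------------------------------------------------------------
# Time-varying rates
# ---------------------------------------------------------------------------

@dataclass
class TimeVaryingRates:
    """Periodic time-dependent overrides for selected transition rates.

    ``functions`` maps ``(chain_id, site_index)`` -> callable of time; any
    rate without an override keeps its constant value from the network
    definition.  All overrides must share the common period ``period``;
    periodicity and strict positivity are verified numerically on a
    64-point grid over one period (they are not assumed).
    """

    functions: dict[tuple[str, int], Callable[[float], float]]
    period: float

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be > 0")

    def validate(self, network: PoolNetwork, n_grid: int = 64) -> None:
        grid = np.linspace(0.0, self.period, n_grid, endpoint=False)
        for (cid, k), fn in self.functions.items():
            chain = network.get_chain(cid)
            if not 0 <= k <= chain.n_sites:
                raise ValueError(f"rate override ({cid!r}, {k}) out of range")
            vals = np.array([float(fn(t)) for t in grid])
            shifted = np.array([float(fn(t + self.period)) for t in grid])
            if np.any(vals <= 0):
                raise ValueError(f"rate override ({cid!r}, {k}) is not strictly positive")
            err = np.max(np.abs(vals - shifted))
            if err > 1e-9 * max(1.0, np.max(np.abs(vals))):
                raise ValueError(
                    f"rate override ({cid!r}, {k}) is not {self.period}-periodic "
                    f"(max deviation {err:.2e})"
                )

    def chain_rates(self, chain, t: float) -> np.ndarray:
        rates = np.array(chain.rates, dtype=float)
        for k in range(chain.n_sites + 1):
            fn = self.functions.get((chain.chain_id, k))
            if fn is not None:
                rates[k] = fn(t)
        return rates


def _chain_rate_arrays(network: PoolNetwork, rates, t: float) -> list[np.ndarray]:
    if rates is None:
        return [np.asarray(c.rates) for c in network.chains]
    return [rates.chain_rates(c, t) for c in network.chains]


# ---------------------------------------------------------------------------
# Vector field and Jacobian
# ---------------------------------------------------------------------------

def _as_vector(state, network: PoolNetwork) -> np.ndarray:
    if isinstance(state, NetworkState):
        return state.to_vector(network)
    return np.asarray(state, dtype=float)


def vector_field(network: PoolNetwork, state, t: float = 0.0, rates=None) -> np.ndarray:
    """Right-hand side of the network ODEs.

    For a chain fed by pool j with rates (l0, ..., ln) and input function G:

        dx1 = l0*G(zj)*(1-x1) - l1*x1*(1-x2)
        dxm = l(m-1)*x(m-1)*(1-xm) - lm*xm*(1-x(m+1))    (interior)
        dxn = l(n-1)*x(n-1)*(1-xn) - ln*xn               (exit)

    and each pool balances its inbound chain outputs against the effective
    entry fluxes of its outbound chains.  The components sum to zero
    identically (particle conservation).
    """
    v = _as_vector(state, network)
    ns = network.n_sites_total
    dv = np.zeros_like(v)
    z = v[ns:]
    rate_arrays = _chain_rate_arrays(network, rates, t)
    off = 0
    for chain, lam in zip(network.chains, rate_arrays):
        n = chain.n_sites
        x = v[off:off + n]
        src = network.pools.index(chain.source_pool)
        dst = network.pools.index(chain.sink_pool)
        zsrc = max(z[src], 0.0)
        entry = lam[0] * chain.input_function._fn(zsrc) * (1.0 - x[0])
        # flux[j] = flow out of site j (flux[0] == entry flux into site 1)
        flux = np.empty(n + 1)
        flux[0] = entry
        flux[1:n] = lam[1:n] * x[:-1] * (1.0 - x[1:])
        flux[n] = lam[n] * x[n - 1]
        dv[off:off + n] = flux[:-1] - flux[1:]
        dv[ns + src] -= entry
        dv[ns + dst] += flux[n]
        off += n
    return dv


def jacobian(network: PoolNetwork, state, t: float = 0.0, rates=None) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field`.

    Block structure: a tridiagonal block per chain, a column coupling each
    chain's first site to its source pool level (through G'), and rows
    coupling each pool to the first/last sites of its outbound/inbound
    chains.  Off-diagonal entries are >= 0 on the state space (Metzler),
    and every column sums to zero (the differential of conservation).
    """
    v = _as_vector(state, network)
    ns = network.n_sites_total
    s = network.state_size
    J = np.zeros((s, s))
    z = v[ns:]
    rate_arrays = _chain_rate_arrays(network, rates, t)
    off = 0
    for chain, lam in zip(network.chains, rate_arrays):
        n = chain.n_sites
        x = v[off:off + n]
        src = network.pools.index(chain.source_pool)
        dst = network.pools.index(chain.sink_pool)
        zsrc = max(z[src], 0.0)
        g = chain.input_function._fn(zsrc)
        gp = chain.input_function.derivative(zsrc)
        # d flux[j] / d x  (flux[j] leaves site j; flux[0] is the entry flux)
        for j in range(n):
            row = off + j
            # site j+1 (0-based j) gains flux[j], loses flux[j+1]
            if j == 0:
                J[row, off] -= lam[0] * g                     # d entry/dx1
                J[row, ns + src] += lam[0] * gp * (1.0 - x[0])
            else:
                J[row, off + j - 1] += lam[j] * (1.0 - x[j])
                J[row, off + j] += -lam[j] * x[j - 1]
            if j < n - 1:
                J[row, off + j] -= lam[j + 1] * (1.0 - x[j + 1])
                J[row, off + j + 1] += lam[j + 1] * x[j]
            else:
                J[row, off + n - 1] -= lam[n]
        # pool rows
        J[ns + src, off] += lam[0] * g                        # -d entry/dx1 * (-1)
        J[ns + src, ns + src] -= lam[0] * gp * (1.0 - x[0])
        J[ns + dst, off + n - 1] += lam[n]
        off += n
    return J


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Integrated states sampled at increasing times."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), state_size)
    network: PoolNetwork

    @property
    def conservation_drift(self) -> float:
        """max_t |Q(t) - Q(0)| along the sampled trajectory."""
        q = self.states.sum(axis=1)
        return float(np.max(np.abs(q - q[0])))

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.network.state_labels())
        df.insert(0, "time", self.times)
        return df


def integrate(
    network: PoolNetwork,
    initial,
    t_final: float,
    rates: TimeVaryingRates | None = None,
    *,
    t0: float = 0.0,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
    drift_tol: float | None = 1e-8,
) -> Trajectory:
    """Integrate the network ODEs from ``initial`` over [t0, t_final].

    Conservation of Q is monitored, not enforced: a drift exceeding
    ``drift_tol * max(1, Q(0))`` raises, since silent projection could
    mask an inconsistently assembled field.
    """
    v0 = _as_vector(initial, network)
    if rates is not None:
        rates.validate(network)
    sol = solve_ivp(
        lambda t, y: vector_field(network, y, t, rates),
        (t0, t_final),
        v0,
        method=method,
        jac=lambda t, y: jacobian(network, y, t, rates),
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    traj = Trajectory(times=sol.t, states=sol.y.T.copy(), network=network)
    if drift_tol is not None:
        q0 = total_occupancy(v0)
        if traj.conservation_drift > drift_tol * max(1.0, abs(q0)):
            raise RuntimeError(
                f"first-integral drift {traj.conservation_drift:.2e} exceeds "
                f"tolerance; the vector field may be mis-assembled"
            )
    return traj


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateResult:
    """A steady state e on the level set {Q = r}."""

    e: np.ndarray
    r: float
    residual: float
    method: str
    diagnostics: dict = field(default_factory=dict)
    network: PoolNetwork | None = None

    def as_state(self, network: PoolNetwork | None = None) -> NetworkState:
        return NetworkState.from_vector(network or self.network, self.e)

    def pool_level(self, pool_id: str) -> float:
        return float(self.e[self.network.pool_index(pool_id)])

    def chain_densities(self, chain_id: str) -> np.ndarray:
        return self.e[self.network.chain_slice(chain_id)].copy()

    def output_rate(self, chain_id: str) -> float:
        """Steady-state exit flux lambda_n * e_n of one chain."""
        chain = self.network.get_chain(chain_id)
        dens = self.chain_densities(chain_id)
        return float(chain.rates[-1] * dens[-1])


def _newton_refine(
    network: PoolNetwork,
    v: np.ndarray,
    r: float,
    tol: float,
    max_iter: int = 50,
) -> tuple[np.ndarray, int]:
    """Newton on {vector_field = 0} with one redundant pool equation
    replaced by the conservation constraint Q - r = 0."""
    s = network.state_size
    v = v.copy()
    for it in range(max_iter):
        F = vector_field(network, v)
        F[-1] = v.sum() - r
        nrm = np.max(np.abs(F))
        if nrm < tol:
            return v, it
        J = jacobian(network, v)
        J[-1, :] = 1.0
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"Newton refinement failed: {exc}") from exc
        v -= step
    return v, max_iter


def find_steady_state(
    network: PoolNetwork,
    r: float | None = None,
    initial=None,
    *,
    tol: float = 1e-12,
    switch_tol: float = 1e-6,
    max_time: float = 2e5,
) -> SteadyStateResult:
    """Steady state on the level set Q = r (or of Q(initial)).

    Strategy: relax towards equilibrium by integrating the dynamics until
    the field's max-norm drops below ``switch_tol``, then polish with
    Newton on the conservation-constrained algebraic system.  Relaxation
    alone converges only linearly; the Newton step certifies the residual.
    """
    if initial is None:
        if r is None:
            raise ValueError("provide r or an initial state")
        v = NetworkState.pools_only(network, float(r)).to_vector(network)
    else:
        v = _as_vector(initial, network)
        if r is not None and abs(v.sum() - r) > 1e-8 * max(1.0, abs(r)):
            raise ValueError(
                f"initial state has Q = {v.sum():.6g}, not on the level set r = {r}"
            )
        r = float(v.sum())
    r = float(r)
    if r < 0:
        raise ValueError("r must be >= 0")
    if r == 0.0:
        return SteadyStateResult(
            e=np.zeros(network.state_size), r=0.0, residual=0.0,
            method="ode_relaxation", diagnostics={"note": "origin equilibrium"},
            network=network,
        )
    t_done, chunk = 0.0, 25.0
    n_chunks = 0
    while True:
        f = vector_field(network, v)
        if np.max(np.abs(f)) < switch_tol:
            break
        if t_done >= max_time:
            raise RuntimeError(
                f"relaxation did not reach ||f|| < {switch_tol} within t = {max_time}"
            )
        traj = integrate(
            network, v, chunk, rtol=1e-9, atol=1e-11, drift_tol=None,
        )
        v = traj.final_state()
        t_done += chunk
        chunk = min(2 * chunk, 1e4)
        n_chunks += 1
    v, n_newton = _newton_refine(network, v, r, tol)
    residual = float(np.max(np.abs(vector_field(network, v))))
    return SteadyStateResult(
        e=v, r=r, residual=residual, method="ode_relaxation",
        diagnostics={
            "relaxation_time": t_done,
            "relaxation_chunks": n_chunks,
            "newton_iterations": n_newton,
        },
        network=network,
    )


# ---------------------------------------------------------------------------
# Periodic forcing and entrainment
# ---------------------------------------------------------------------------

def simulate_periodic(
    network: PoolNetwork,
    rates: TimeVaryingRates,
    initial,
    n_periods: int,
    *,
    samples_per_period: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate under T-periodic rates over ``n_periods`` periods.

    Trajectories of the periodically forced network entrain: they converge
    to a unique T-periodic orbit on their level set.  States are sampled
    uniformly so the result can feed :func:`estimate_period` directly.
    """
    rates.validate(network)
    T = rates.period
    t_final = n_periods * T
    t_eval = np.linspace(0.0, t_final, n_periods * samples_per_period + 1)
    return integrate(
        network, initial, t_final, rates,
        t_eval=t_eval, rtol=rtol, atol=atol,
    )


@dataclass
class PeriodEstimate:
    period: float | None
    flag: str  # "periodic" | "constant" | "undetermined"
    component_periods: np.ndarray  # NaN for components flagged constant
    amplitudes: np.ndarray


def _autocorr_period(y: np.ndarray, dt: float) -> float | None:
    """Dominant period of a uniformly sampled signal via the biased
    autocorrelation (global maximum past the zero-lag lobe, refined by
    parabolic interpolation)."""
    n = len(y)
    y = y - y.mean()
    f = np.fft.rfft(y, 2 * n)
    c = np.fft.irfft(f * np.conj(f))[:n]
    if c[0] <= 0:
        return None
    c = c / c[0]
    # skip the zero-lag main lobe: advance to the first local minimum
    i0 = 1
    while i0 < n - 1 and c[i0 + 1] < c[i0]:
        i0 += 1
    hi = n // 2
    if i0 >= hi - 1:
        return None
    k = i0 + int(np.argmax(c[i0:hi]))
    if k <= 0 or k >= n - 1:
        return None
    denom = c[k - 1] - 2.0 * c[k] + c[k + 1]
    delta = 0.0 if denom == 0 else 0.5 * (c[k - 1] - c[k + 1]) / denom
    return (k + delta) * dt


def estimate_period(
    traj: Trajectory,
    discard_fraction: float = 0.5,
    *,
    constant_amplitude: float = 1e-8,
) -> PeriodEstimate:
    """Estimate the asymptotic period of each state component.

    The first ``discard_fraction`` of the samples is discarded as
    transient.  A component whose retained peak-to-trough amplitude is
    below ``constant_amplitude`` is flagged constant.  The trajectory must
    be uniformly sampled.
    """
    t = traj.times
    if len(t) < 16:
        raise ValueError("too few samples for period estimation")
    dts = np.diff(t)
    if np.max(np.abs(dts - dts[0])) > 1e-9 * dts[0]:
        raise ValueError("period estimation requires uniform sampling")
    dt = float(dts[0])
    start = int(len(t) * discard_fraction)
    seg = traj.states[start:]
    ncomp = seg.shape[1]
    periods = np.full(ncomp, np.nan)
    amps = seg.max(axis=0) - seg.min(axis=0)
    for i in range(ncomp):
        if amps[i] < constant_amplitude:
            continue
        p = _autocorr_period(seg[:, i], dt)
        if p is not None:
            periods[i] = p
    if np.all(np.isnan(periods)):
        return PeriodEstimate(None, "constant", periods, amps)
    est = float(np.nanmedian(periods))
    ok = np.isnan(periods) | (np.abs(periods - est) < 0.05 * est)
    flag = "periodic" if np.all(ok) else "undetermined"
    return PeriodEstimate(est, flag, periods, amps)
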