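"""Network-wide effect of changing a single transition rate.

Raising one rate l_k of a chain always lowers the steady-state density at
site k and raises the densities at every downstream site of that chain
(the local inequalities).  The rest of the two-pool network responds in
one of exactly five ways, determined by how the two pool levels move:

    i    both pool levels rise,
    ii   the perturbed chain's source pool falls, its sink pool rises,
    iii  both pool levels fall,
    iv   source pool unchanged, sink pool rises,
    v    source pool falls, sink pool unchanged,

with all chains fed by a pool moving together with that pool's level.
A rise of the source pool together with a fall of the sink pool cannot
occur.  The exact-equality cases (iv)/(v) are measure-zero numerically,
so equality is declared below a relative tolerance and strict cases are
preferred whenever the difference resolves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SteadyStateResult, find_steady_state
from .network_model import PoolNetwork
from .spectral_solver import solve_pool_balance

__all__ = [
    "PerturbationReport",
    "perturb_rate",
    "classify_effect",
    "sweep_rate",
    "perturbation_report",
]


def perturb_rate(
    network: PoolNetwork, chain_id: str, site_index: int, new_rate: float
) -> PoolNetwork:
    """Copy of the network with one rate replaced; the original is untouched.

    ``site_index`` runs over 0 (entry) .. n (exit) of the chain.
    """
    return network.with_rate(chain_id, site_index, new_rate)


def _signed(delta: float, scale: float, tol: float) -> int:
    """-1 / 0 / +1 with |delta| <= tol * max(1, scale) counted as zero."""
    if abs(delta) <= tol * max(1.0, abs(scale)):
        return 0
    return 1 if delta > 0 else -1


def classify_effect(
    e_before: SteadyStateResult,
    e_after: SteadyStateResult,
    network: PoolNetwork,
    perturbed_chain_id: str,
    tol: float = 1e-6,
) -> tuple[str, dict]:
    """Label the steady-state response to an increased rate as one of the
    five cases (or ``"other"`` with diagnostics, which signals numerical
    trouble since the case list is exhaustive for two-pool networks).

    Pool I is the perturbed chain's source pool, Pool II its sink pool.
    Consistency of the non-perturbed chains is verified: chains fed by a
    pool must move in the same direction as that pool's level.  Sites
    upstream of the perturbed rate carry no guaranteed ordering and are
    ignored.
    """
    if e_before.e.shape != e_after.e.shape:
        raise ValueError("steady states come from differently shaped networks")
    chain = network.get_chain(perturbed_chain_id)
    p1, p2 = chain.source_pool, chain.sink_pool
    dz1 = e_after.e[network.pool_index(p1)] - e_before.e[network.pool_index(p1)]
    dz2 = e_after.e[network.pool_index(p2)] - e_before.e[network.pool_index(p2)]
    s1 = _signed(dz1, e_before.e[network.pool_index(p1)], tol)
    s2 = _signed(dz2, e_before.e[network.pool_index(p2)], tol)
    label = {
        (1, 1): "i",
        (-1, 1): "ii",
        (-1, -1): "iii",
        (0, 1): "iv",
        (-1, 0): "v",
    }.get((s1, s2), "other")
    diag = {"dz_source": float(dz1), "dz_sink": float(dz2),
            "sign_source": s1, "sign_sink": s2}
    if label == "other":
        return label, diag
    # every non-perturbed chain moves with the pool feeding it
    for c in network.chains:
        if c.chain_id == perturbed_chain_id:
            continue
        expected = s1 if c.source_pool == p1 else s2 if c.source_pool == p2 else None
        if expected is None:
            continue
        sl = network.chain_slice(c.chain_id)
        dd = e_after.e[sl] - e_before.e[sl]
        signs = {_signed(d, b, tol) for d, b in zip(dd, e_before.e[sl])}
        # individual sites may sit below tol, but none may oppose the pool
        allowed = {0} if expected == 0 else {0, expected}
        if signs - allowed:
            diag["inconsistent_chain"] = c.chain_id
            return "other", diag
    return label, diag


def local_inequalities(
    e_before: SteadyStateResult,
    e_after: SteadyStateResult,
    network: PoolNetwork,
    chain_id: str,
    site_index: int,
) -> dict:
    """Check the guaranteed local response of the perturbed chain to a rate
    increase: density at the perturbed site falls, all downstream
    densities rise."""
    sl = network.chain_slice(chain_id)
    before = e_before.e[sl]
    after = e_after.e[sl]
    n = len(before)
    checks = {}
    if 1 <= site_index <= n:
        checks["site_k_decreases"] = bool(after[site_index - 1] < before[site_index - 1])
    downstream = slice(site_index, n)
    checks["downstream_increase"] = bool(np.all(after[downstream] > before[downstream]))
    return checks


@dataclass
class PerturbationReport:
    chain_id: str
    site_index: int
    old_rate: float
    new_rate: float
    e_before: SteadyStateResult
    e_after: SteadyStateResult
    case_label: str
    local_checks: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _steady(network: PoolNetwork, r: float, method: str) -> SteadyStateResult:
    if method == "spectral":
        return solve_pool_balance(network, r).to_result(network)
    return find_steady_state(network, r=r)


def perturbation_report(
    network: PoolNetwork,
    chain_id: str,
    site_index: int,
    new_rate: float,
    r: float,
    *,
    method: str = "spectral",
    tol: float = 1e-6,
) -> PerturbationReport:
    """Solve both networks at the same r and classify the effect."""
    old_rate = network.get_chain(chain_id).rates[site_index]
    perturbed = perturb_rate(network, chain_id, site_index, new_rate)
    before = _steady(network, r, method)
    after = _steady(perturbed, r, method)
    if new_rate >= old_rate:
        label, diag = classify_effect(before, after, network, chain_id, tol)
        checks = local_inequalities(before, after, network, chain_id, site_index)
    else:
        # the theory is stated for increases; classify the reversed pair
        label, diag = classify_effect(after, before, network, chain_id, tol)
        checks = local_inequalities(after, before, network, chain_id, site_index)
        diag["direction"] = "decrease (classified as the reverse increase)"
    return PerturbationReport(
        chain_id=chain_id, site_index=site_index,
        old_rate=float(old_rate), new_rate=float(new_rate),
        e_before=before, e_after=after,
        case_label=label, local_checks=checks, diagnostics=diag,
    )


def sweep_rate(
    network: PoolNetwork,
    chain_id: str,
    site_index: int,
    values,
    r: float,
    *,
    method: str = "spectral",
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Steady states over an ascending grid of values of one rate.

    Returns one row per grid value with the pool levels, each chain's
    output rate, the case label relative to the previous grid point
    (``case_vs_prev``) and whether the local inequalities held between
    consecutive points.
    """
    values = list(values)
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("grid values must be strictly ascending")
    rows = []
    prev = None
    for val in values:
        net_v = perturb_rate(network, chain_id, site_index, val)
        ss = _steady(net_v, r, method)
        row = {"value": float(val)}
        for p in network.pools:
            row[f"pool.{p}"] = ss.pool_level(p)
        for c in network.chains:
            row[f"output.{c.chain_id}"] = ss.output_rate(c.chain_id)
        if prev is None:
            row["case_vs_prev"] = ""
            row["local_ok"] = True
        else:
            label, _ = classify_effect(prev, ss, network, chain_id, tol)
            checks = local_inequalities(prev, ss, network, chain_id, site_index)
            row["case_vs_prev"] = label
            row["local_ok"] = all(checks.values())
        rows.append(row)
        prev = ss
    return pd.DataFrame(rows)
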