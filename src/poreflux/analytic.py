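"""Exact stationary solutions of the channel master equation.

Two levels of exactness are provided:

* :func:`one_site_steady_state` — the closed-form stationary solution of the
  three-state single-site channel (empty / holds an n particle / holds an m
  particle), the Michaelis–Menten-like limit in which competition cannot
  change relative efficiencies.
* :func:`exact_steady_state` — brute-force stationary distribution over the
  full enumerated occupancy state space of an arbitrary (small) channel.
  This generalizes the same method to N sites and any per-site capacity and
  serves as the independent oracle for the kinetic Monte Carlo engine.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .channel import ChannelSpec

__all__ = [
    "OneSiteSolution",
    "SpeciesSteadyState",
    "SteadyStateSolution",
    "one_site_steady_state",
    "one_site_efficiency_ratio",
    "enumerate_states",
    "exact_steady_state",
]

#: Dense linear solve below this many states, sparse direct solve above.
DENSE_CUTOFF = 5_000
#: Default cap on the enumerated state-space size.
MAX_STATES = 200_000


# ---------------------------------------------------------------------------
# One-site channel: closed form
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneSiteSolution:
    """Stationary solution of the three-state one-site channel.

    ``P_empty + P_n + P_m = 1``; ``efficiency_s = flux_right_s / J_s`` and
    ``prob_s = r_s_fwd / (r_s_fwd + r_s_back)`` is the probability that a
    particle which entered leaves on the far side.
    """

    P_empty: float
    P_n: float
    P_m: float
    flux_right_n: float
    flux_right_m: float
    efficiency_n: float
    efficiency_m: float
    prob_n: float
    prob_m: float


def _one_site_species(J: float, r_fwd: float, r_back: float) -> tuple[float, float]:
    """(J/R, prob) for one species, with the absorbing-channel error check."""
    if min(J, r_fwd, r_back) < 0:
        raise ValueError("one-site rates and fluxes must be >= 0")
    R = r_fwd + r_back
    if J > 0 and R == 0:
        raise ValueError(
            "species with positive flux has zero total exit rate: "
            "the channel would absorb particles forever and no stationary flux exists"
        )
    load = J / R if R > 0 else 0.0
    prob = r_fwd / R if R > 0 else math.nan
    return load, prob


def one_site_steady_state(
    J_n: float,
    J_m: float,
    r_n_fwd: float,
    r_n_back: float,
    r_m_fwd: float = 0.0,
    r_m_back: float = 0.0,
) -> OneSiteSolution:
    """Solve the three-state master equation of the one-site channel.

    The stationary balance J_s·P_empty = (r_s_fwd + r_s_back)·P_s gives
    P_s = (J_s/R_s)·P_empty with P_empty fixed by normalization.  The
    transport efficiency (transmitted over impinging flux) reduces to
    ``(r_fwd/R)·P_empty``, which is also its well-defined J → 0 limit.
    """
    load_n, prob_n = _one_site_species(J_n, r_n_fwd, r_n_back)
    load_m, prob_m = _one_site_species(J_m, r_m_fwd, r_m_back)
    P_empty = 1.0 / (1.0 + load_n + load_m)
    P_n = load_n * P_empty
    P_m = load_m * P_empty
    R_n = r_n_fwd + r_n_back
    R_m = r_m_fwd + r_m_back
    eff_n = (r_n_fwd / R_n) * P_empty if R_n > 0 else math.nan
    eff_m = (r_m_fwd / R_m) * P_empty if R_m > 0 else math.nan
    return OneSiteSolution(
        P_empty=P_empty,
        P_n=P_n,
        P_m=P_m,
        flux_right_n=r_n_fwd * P_n,
        flux_right_m=r_m_fwd * P_m,
        efficiency_n=eff_n,
        efficiency_m=eff_m,
        prob_n=prob_n,
        prob_m=prob_m,
    )


def one_site_efficiency_ratio(
    J_n: float,
    J_m: float,
    r_n_fwd: float,
    r_n_back: float,
    r_m_fwd: float,
    r_m_back: float,
) -> float:
    """Ratio efficiency_m / efficiency_n of the one-site channel.

    The common occupancy factor P_empty cancels, so the ratio equals
    ``(r_m_fwd/R_m) / (r_n_fwd/R_n)`` and is independent of both impinging
    fluxes: in a one-site channel the relative transport of the two species
    is not influenced by competition.
    """
    sol = one_site_steady_state(J_n, J_m, r_n_fwd, r_n_back, r_m_fwd, r_m_back)
    if not (sol.efficiency_n > 0):
        raise ValueError("efficiency of the n species is zero; the ratio is undefined")
    return sol.efficiency_m / sol.efficiency_n


# ---------------------------------------------------------------------------
# N-site channel: enumerated state space
# ---------------------------------------------------------------------------

def _site_occupancies(n_species: int, capacity: int) -> list[tuple[int, ...]]:
    """All per-site occupancy vectors with total <= capacity, lexicographic."""
    return sorted(
        c
        for c in itertools.product(range(capacity + 1), repeat=n_species)
        if sum(c) <= capacity
    )


def enumerate_states(spec: ChannelSpec, max_states: int = MAX_STATES) -> np.ndarray:
    """Enumerate every occupancy state of the channel.

    Returns an array of shape ``(K, N, S)`` of particle counts (species s at
    site i), in deterministic lexicographic order.  The per-site capacity
    constraint is the only coupling, so the state space is the product of
    per-site occupancy vectors.
    """
    N, S = spec.n_sites, len(spec.species)
    per_site = _site_occupancies(S, spec.capacity)
    n_states = len(per_site) ** N
    if n_states > max_states:
        raise ValueError(
            f"state space has {n_states} states, above the cap of {max_states}; "
            "use the kinetic Monte Carlo engine for channels this large"
        )
    states = np.empty((n_states, N, S), dtype=np.int16)
    for k, combo in enumerate(itertools.product(per_site, repeat=N)):
        states[k] = combo
    return states


@dataclass(frozen=True)
class SpeciesSteadyState:
    """Stationary per-species fluxes and occupancies."""

    entry_flux: float
    exit_flux_left: float
    exit_flux_right: float
    mean_density: np.ndarray  # shape (N,)
    efficiency: float
    translocation_probability: float
    entry_probability: float


@dataclass(frozen=True)
class SteadyStateSolution:
    """Exact stationary distribution plus derived transport metrics."""

    spec: ChannelSpec
    states: np.ndarray  # (K, N, S)
    pi: np.ndarray  # (K,)
    per_species: dict[str, SpeciesSteadyState]
    residual: float

    def summary_dict(self) -> dict:
        """JSON-ready per-species summary."""
        return {
            "n_states": int(self.states.shape[0]),
            "residual": self.residual,
            "species": {
                label: {
                    "entry_flux": s.entry_flux,
                    "exit_flux_left": s.exit_flux_left,
                    "exit_flux_right": s.exit_flux_right,
                    "efficiency": s.efficiency,
                    "translocation_probability": s.translocation_probability,
                    "entry_probability": s.entry_probability,
                    "mean_density": list(map(float, s.mean_density)),
                }
                for label, s in self.per_species.items()
            },
        }

    def state_table(self):
        """Per-state stationary probabilities as a tidy DataFrame.

        States are encoded as flat occupancy strings, sites separated by
        ``|`` and species counts within a site by ``,``.
        """
        import pandas as pd

        encoded = [
            "|".join(",".join(str(c) for c in site) for site in state)
            for state in self.states
        ]
        return pd.DataFrame({"state": encoded, "probability": self.pi})


def _stationary_distribution(Q: sp.csr_matrix) -> tuple[np.ndarray, float]:
    """Solve pi @ Q = 0, sum(pi) = 1; returns (pi, residual)."""
    K = Q.shape[0]
    A = Q.T.tocsr()
    if K <= DENSE_CUTOFF:
        M = A.toarray()
        M[-1, :] = 1.0
        b = np.zeros(K)
        b[-1] = 1.0
        try:
            pi = np.linalg.solve(M, b)
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError(
                f"stationary system is singular (K={K}); "
                "check that every fed species can reach a bath"
            ) from exc
    else:
        rows = A.tolil()
        rows[-1, :] = 1.0
        b = np.zeros(K)
        b[-1] = 1.0
        pi = spla.spsolve(rows.tocsr(), b)
    residual = float(np.abs(A @ pi).max())
    if not np.isfinite(pi).all() or residual > 1e-8:
        raise ArithmeticError(
            f"stationary solve ill-conditioned: residual {residual:.3e} "
            f"(K={K}, min pi {pi.min():.3e})"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return pi, residual


def exact_steady_state(spec: ChannelSpec, max_states: int = MAX_STATES) -> SteadyStateSolution:
    """Exact stationary solution over the enumerated occupancy states.

    The transition-rate generator contains three event families: Poisson
    arrivals that add a particle at the entrance site whenever its total
    occupancy is below capacity (blocked arrivals simply do not appear as
    transitions — the blocked flux is ``J · P(entrance full)``); hops that
    move one particle along an internal edge whose target site has room; and
    exits that remove a particle from a boundary site.  With ``c`` identical
    particles at a site each single-particle rate is multiplied by ``c``.
    """
    from .channel import validate_channel

    problems = validate_channel(spec)
    if problems:
        raise ValueError("invalid channel spec:\n" + "\n".join(f"- {p}" for p in problems))

    N, S = spec.n_sites, len(spec.species)
    n_max = spec.capacity
    M = spec.entrance_site - 1
    states = enumerate_states(spec, max_states=max_states)
    K = states.shape[0]
    index = {states[k].tobytes(): k for k in range(K)}
    site_sums = states.sum(axis=2)  # (K, N)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(k: int, state: np.ndarray, i: int, s: int, di: int, rate: float) -> None:
        """Transition: one s-particle leaves site i; di=+1/-1 hop, 0 exit."""
        new = state.copy()
        new[i, s] -= 1
        if di:
            new[i + di, s] += 1
        k2 = index[new.tobytes()]
        rows.append(k)
        cols.append(k2)
        vals.append(rate)

    for k in range(K):
        state = states[k]
        ssum = site_sums[k]
        for s, sp_ in enumerate(spec.species):
            # arrival
            if sp_.flux_J > 0 and ssum[M] < n_max:
                new = state.copy()
                new[M, s] += 1
                rows.append(k)
                cols.append(index[new.tobytes()])
                vals.append(sp_.flux_J)
            for i in range(N):
                c = int(state[i, s])
                if c == 0:
                    continue
                if i == 0:
                    if sp_.exit_left > 0:
                        add(k, state, i, s, 0, c * sp_.exit_left)
                elif ssum[i - 1] < n_max:
                    r = sp_.hop_rate[(i + 1, i)]
                    if r > 0:
                        add(k, state, i, s, -1, c * r)
                if i == N - 1:
                    if sp_.exit_right > 0:
                        add(k, state, i, s, 0, c * sp_.exit_right)
                elif ssum[i + 1] < n_max:
                    r = sp_.hop_rate[(i + 1, i + 2)]
                    if r > 0:
                        add(k, state, i, s, +1, c * r)

    Q = sp.coo_matrix((vals, (rows, cols)), shape=(K, K)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    pi, residual = _stationary_distribution(Q.tocsr())

    per_species: dict[str, SpeciesSteadyState] = {}
    for s, sp_ in enumerate(spec.species):
        p_free = float(pi[site_sums[:, M] < n_max].sum())
        entry_flux = sp_.flux_J * p_free
        left = float((pi * states[:, 0, s]).sum()) * sp_.exit_left
        right = float((pi * states[:, N - 1, s]).sum()) * sp_.exit_right
        density = (pi[:, None] * states[:, :, s]).sum(axis=0)
        eff = right / sp_.flux_J if sp_.flux_J > 0 else math.nan
        transloc = right / entry_flux if entry_flux > 0 else math.nan
        per_species[sp_.label] = SpeciesSteadyState(
            entry_flux=entry_flux,
            exit_flux_left=left,
            exit_flux_right=right,
            mean_density=density,
            efficiency=eff,
            translocation_probability=transloc,
            entry_probability=p_free,
        )
    return SteadyStateSolution(
        spec=spec, states=states, pi=pi, per_species=per_species, residual=residual
    )
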