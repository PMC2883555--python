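"""Scripted in-silico experiments: trapping, titration, width, length, addition.

All drivers share one default kinetic profile: a 6-site single-file channel
(capacity 1) entered at site 2, carrying a strongly trapped "specific"
species ``n`` (square well, trapping strength r/r_o = 100, i.e. exit rate
0.01·r) and a weakly trapped "non-specific" species ``m`` whose trapping
strength is swept from 1 (no trapping) up to that of the specific species.
The free hop rate r of the non-trapped species is the time unit; the default
total impinging flux is J_tot = 0.01·r.

Each driver returns a tidy :class:`pandas.DataFrame`; stochastic runs carry
batch-means standard errors.  The ``engine`` field of the plan selects the
kinetic Monte Carlo simulator (default) or the exact master-equation solver
for channels small enough to enumerate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analytic import exact_steady_state
from .channel import ChannelSpec, make_square_well_species
from .kmc import KmcSettings, SimulationTally, mean_density, simulate
from .observables import (
    MetricValue,
    TransportMetrics,
    _divide,
    find_jamming_point,
    metrics,
    relative_metrics,
    selectivity_ratio,
)

__all__ = [
    "SweepPlan",
    "WEAK",
    "STRONG",
    "default_plan",
    "build_channel",
    "single_species_sweep",
    "titration_sweep",
    "capacity_sweep",
    "length_sweep",
    "addition_sweep",
]

WEAK = "m"  # weakly trapped / non-specific species
STRONG = "n"  # strongly trapped / specific species


def _log_grid(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(np.logspace(math.log10(lo), math.log10(hi), n))


@dataclass(frozen=True)
class SweepPlan:
    """Base profile plus sweep definitions shared by all experiment drivers."""

    n_sites: int = 6
    capacity: int = 1
    entrance_site: int = 2
    strong_strength: float = 100.0
    total_flux: float = 0.01
    #: weak-species trapping strengths r/r_o^m swept along the x axis
    grid: tuple[float, ...] = field(default_factory=lambda: _log_grid(1.0, 100.0, 15))
    #: weak-species share of the total flux: 0.5 is a 1:1 mixture, 0.9 a 9:1
    #: excess of the weakly trapped species
    fractions: tuple[float, ...] = (0.5, 0.9)
    settings: KmcSettings = field(default_factory=lambda: KmcSettings(sample_time=1e6))
    baseline_mode: str = "per-species-flux"
    base_seed: int = 0
    engine: str = "kmc"  # "kmc" | "exact"
    rate_law: str = "metropolis"
    # width sweep
    capacities: tuple[int, ...] = (1, 2, 3)
    # length sweep
    lengths: tuple[int, ...] = tuple(range(2, 11))
    #: weak-species strength held fixed in the width/length sweeps
    weak_strength_fixed: float = 1.0
    # addition sweep: specific-species flux is held fixed while the
    # non-specific flux is *added* on top at these multiples
    strong_flux: float = 0.001
    addition_ratios: tuple[float, ...] = (1.0, 10.0)
    #: trapping strengths of the *added* species.  The addition experiment
    #: probes non-specific additions, so the added species stays weakly to
    #: moderately trapped (well below the specific species' strength 100);
    #: additions at comparable trapping belong to the titration sweep.
    addition_grid: tuple[float, ...] = field(default_factory=lambda: _log_grid(1.0, 30.0, 9))

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")
        if any(g <= 0 for g in self.grid):
            raise ValueError("trapping strengths must be positive")
        if list(self.grid) != sorted(self.grid):
            raise ValueError("sweep grid must be sorted ascending")
        if any(not (0 <= f <= 1) for f in self.fractions):
            raise ValueError("mixture fractions must lie in [0, 1]")


def default_plan(**overrides) -> SweepPlan:
    """The default experiment profile, with keyword overrides."""
    return SweepPlan(**overrides)


def build_channel(
    plan: SweepPlan,
    weak_strength: float,
    weak_flux: float,
    strong_flux: float,
    n_sites: int | None = None,
    capacity: int | None = None,
) -> ChannelSpec:
    """Two-species channel of the plan's profile at the given mixture point.

    A species with zero flux is dropped entirely, so single-species baselines
    are the same channel with only the fed species present.
    """
    N = n_sites if n_sites is not None else plan.n_sites
    species = []
    if weak_flux > 0:
        species.append(
            make_square_well_species(WEAK, weak_flux, weak_strength, N, rate_law=plan.rate_law)
        )
    if strong_flux > 0:
        species.append(
            make_square_well_species(
                STRONG, strong_flux, plan.strong_strength, N, rate_law=plan.rate_law
            )
        )
    return ChannelSpec(
        n_sites=N,
        capacity=capacity if capacity is not None else plan.capacity,
        entrance_site=plan.entrance_site,
        species=tuple(species),
    )


class _Runner:
    """Run channels under the plan's engine, handing out sequential seeds."""

    def __init__(self, plan: SweepPlan):
        self.plan = plan
        self.next_seed = plan.base_seed
        self.seeds_used: list[int] = []

    def run(self, spec: ChannelSpec) -> tuple[TransportMetrics, np.ndarray, int]:
        seed = self.next_seed
        self.next_seed += 1
        self.seeds_used.append(seed)
        if self.plan.engine == "exact":
            sol = exact_steady_state(spec)
            density = np.stack(
                [sol.per_species[lbl].mean_density for lbl in spec.labels], axis=1
            )
            return metrics(sol), density, seed
        if self.plan.engine != "kmc":
            raise ValueError(f"unknown engine {self.plan.engine!r}; expected 'kmc' or 'exact'")
        tally = simulate(spec, replace(self.plan.settings, seed=seed))
        return metrics(tally), mean_density(tally), seed


def _mv_cols(prefix: str, mv: MetricValue) -> dict[str, float | None]:
    return {prefix: mv.value, f"{prefix}_se": mv.se}


# ---------------------------------------------------------------------------
# Single-species experiment: efficiency vs trapping strength (jamming)
# ---------------------------------------------------------------------------

def single_species_sweep(plan: SweepPlan) -> pd.DataFrame:
    """Efficiency and translocation probability of one species vs trapping.

    The returned frame carries the jamming point (trapping strength of
    maximal efficiency) in ``df.attrs["jamming"]``.
    """
    runner = _Runner(plan)
    rows = []
    for strength in plan.grid:
        spec = build_channel(plan, weak_strength=1.0, weak_flux=0.0, strong_flux=plan.total_flux)
        # sweep the single species' own trapping strength
        spec = replace(
            spec,
            species=(
                make_square_well_species(
                    STRONG, plan.total_flux, strength, spec.n_sites, rate_law=plan.rate_law
                ),
            ),
        )
        m, _, seed = runner.run(spec)
        sm = m[STRONG]
        rows.append(
            {
                "trapping_strength": strength,
                **_mv_cols("efficiency", sm.efficiency),
                **_mv_cols("translocation_probability", sm.translocation_probability),
                **_mv_cols("entry_probability", sm.entry_probability),
                "seed": seed,
            }
        )
    df = pd.DataFrame(rows)
    jam = find_jamming_point(list(zip(df["trapping_strength"], df["efficiency"])))
    df["is_jamming_point"] = df["trapping_strength"] == jam.trapping_strength
    df.attrs["jamming"] = jam
    return df


# ---------------------------------------------------------------------------
# Titration experiment: two-species mixture at fixed total flux
# ---------------------------------------------------------------------------

def _baseline_fluxes(plan: SweepPlan, J_weak: float, J_strong: float) -> tuple[float, float]:
    if plan.baseline_mode == "per-species-flux":
        return J_weak, J_strong
    if plan.baseline_mode == "total-flux":
        tot = J_weak + J_strong
        return tot, tot
    raise ValueError(f"unknown baseline_mode {plan.baseline_mode!r}")


def _mixture_point(
    runner: _Runner,
    plan: SweepPlan,
    strength: float,
    J_weak: float,
    J_strong: float,
    n_sites: int | None = None,
    capacity: int | None = None,
):
    """Run one mixture point plus its two single-species baselines."""
    mix_spec = build_channel(plan, strength, J_weak, J_strong, n_sites, capacity)
    mix, density, seed = runner.run(mix_spec)
    bw, bs = _baseline_fluxes(plan, J_weak, J_strong)
    base_w, _, _ = runner.run(build_channel(plan, strength, bw, 0.0, n_sites, capacity))
    base_s, _, _ = runner.run(build_channel(plan, strength, 0.0, bs, n_sites, capacity))
    baselines = {WEAK: base_w, STRONG: base_s}
    return mix, baselines, density, seed


def titration_sweep(plan: SweepPlan) -> pd.DataFrame:
    """Relative transport of both species in a titrated mixture.

    The total flux is held fixed; ``fraction_weak`` of it impinges as the
    weakly trapped species.  Each row holds one (strength, fraction, species)
    combination with the three relative metrics against the single-species
    baseline dictated by ``plan.baseline_mode``.
    """
    runner = _Runner(plan)
    rows = []
    for fraction in plan.fractions:
        J_weak = fraction * plan.total_flux
        J_strong = (1.0 - fraction) * plan.total_flux
        if J_weak == 0 or J_strong == 0:
            raise ValueError("titration fractions must keep both species present")
        for strength in plan.grid:
            mix, baselines, _, seed = _mixture_point(runner, plan, strength, J_weak, J_strong)
            rel = relative_metrics(mix, baselines, plan.baseline_mode)
            sel = selectivity_ratio(mix, WEAK, STRONG, baselines)
            for label in (WEAK, STRONG):
                r = rel[label]
                mm = mix[label]
                rows.append(
                    {
                        "weak_trapping_strength": strength,
                        "fraction_weak": fraction,
                        "species": label,
                        **_mv_cols("efficiency_ratio", r["efficiency_ratio"]),
                        **_mv_cols("probability_ratio", r["probability_ratio"]),
                        **_mv_cols("entry_ratio", r["entry_ratio"]),
                        **_mv_cols("efficiency", mm.efficiency),
                        **_mv_cols("selectivity_ratio", sel),
                        "baseline_mode": plan.baseline_mode,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Width experiment: per-site capacity
# ---------------------------------------------------------------------------

def capacity_sweep(plan: SweepPlan) -> pd.DataFrame:
    """Selectivity ratio vs weak trapping strength for each channel width."""
    if any(c < 1 for c in plan.capacities):
        raise ValueError("per-site capacities must be >= 1")
    runner = _Runner(plan)
    J_weak = 0.5 * plan.total_flux
    J_strong = 0.5 * plan.total_flux
    rows = []
    for n_max in plan.capacities:
        for strength in plan.grid:
            mix, baselines, _, seed = _mixture_point(
                runner, plan, strength, J_weak, J_strong, capacity=n_max
            )
            sel = selectivity_ratio(mix, WEAK, STRONG, baselines)
            rows.append(
                {
                    "capacity": n_max,
                    "weak_trapping_strength": strength,
                    **_mv_cols("selectivity_ratio", sel),
                    "baseline_mode": plan.baseline_mode,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Length experiment: number of channel sites
# ---------------------------------------------------------------------------

def length_sweep(plan: SweepPlan) -> pd.DataFrame:
    """Selectivity ratio vs channel length at fixed per-site kinetics."""
    if any(n < 2 for n in plan.lengths):
        raise ValueError(
            "channel lengths must be >= 2 (the one-site channel is the "
            "no-competition negative control)"
        )
    runner = _Runner(plan)
    J_weak = 0.5 * plan.total_flux
    J_strong = 0.5 * plan.total_flux
    rows = []
    for n_sites in plan.lengths:
        mix, baselines, _, seed = _mixture_point(
            runner, plan, plan.weak_strength_fixed, J_weak, J_strong, n_sites=n_sites
        )
        sel = selectivity_ratio(mix, WEAK, STRONG, baselines)
        rows.append(
            {
                "n_sites": n_sites,
                "weak_trapping_strength": plan.weak_strength_fixed,
                **_mv_cols("selectivity_ratio", sel),
                "baseline_mode": plan.baseline_mode,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Addition experiment: non-specific flux on top of the specific flux
# ---------------------------------------------------------------------------

def addition_sweep(plan: SweepPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect of *adding* the weakly trapped species on the specific flux.

    The specific species' flux is held at ``plan.strong_flux`` while the
    non-specific species is added on top at ``plan.addition_ratios`` times
    that flux; its trapping strength is swept.  Returns the relative
    efficiency table and a tidy density-profile table sampled at the weak
    (first), intermediate (middle) and strong (last) grid points.
    """
    runner = _Runner(plan)
    J_strong = plan.strong_flux
    grid = plan.addition_grid
    regimes = {
        grid[0]: "weak",
        grid[len(grid) // 2]: "intermediate",
        grid[-1]: "strong",
    }
    rows = []
    density_rows = []
    for ratio in plan.addition_ratios:
        J_weak = ratio * J_strong
        # baseline: specific species alone, flux unchanged by the addition
        base_s, _, _ = runner.run(build_channel(plan, 1.0, 0.0, J_strong))
        for strength in grid:
            mix_spec = build_channel(plan, strength, J_weak, J_strong)
            mix, density, seed = runner.run(mix_spec)
            rel = _divide(mix[STRONG].efficiency, base_s[STRONG].efficiency)
            rows.append(
                {
                    "addition_ratio": ratio,
                    "weak_trapping_strength": strength,
                    **_mv_cols("relative_efficiency", rel),
                    "seed": seed,
                }
            )
            if strength in regimes:
                for i in range(mix_spec.n_sites):
                    for s, label in enumerate(mix_spec.labels):
                        density_rows.append(
                            {
                                "addition_ratio": ratio,
                                "regime": regimes[strength],
                                "weak_trapping_strength": strength,
                                "site": i + 1,
                                "species": label,
                                "mean_occupancy": float(density[i, s]),
                            }
                        )
    return pd.DataFrame(rows), pd.DataFrame(density_rows)
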