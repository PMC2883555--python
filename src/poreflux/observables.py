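"""Transport metrics derived from tallies and exact solutions.

The three headline quantities, per species:

* efficiency — transmitted (right-exiting) flux over impinging flux,
* entry probability — fraction of arrivals that found room and entered,
* translocation probability — fraction of entered particles that left on the
  far side rather than returning,

with the exact decomposition ``efficiency = entry_probability ×
translocation_probability``.  Mixture runs are compared against matched
single-species baselines through :func:`relative_metrics` and
:func:`selectivity_ratio`; sweeps over trapping strength are reduced to a
jamming point by :func:`find_jamming_point`.

Metrics that cannot be formed (a species that never arrived, a zero
baseline) are carried as explicit ``None`` values rather than silently
coerced to 0, since sweeps routinely cross regimes where a species never
enters the channel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .analytic import OneSiteSolution, SteadyStateSolution
from .kmc import SimulationTally, standard_errors

__all__ = [
    "MetricValue",
    "SpeciesMetrics",
    "TransportMetrics",
    "RelativeMetrics",
    "JammingPoint",
    "metrics",
    "relative_metrics",
    "selectivity_ratio",
    "find_jamming_point",
]

BASELINE_MODES = ("per-species-flux", "total-flux")


class MetricValue(NamedTuple):
    """A point estimate with an optional Monte Carlo standard error.

    ``value`` is ``None`` when the metric is undefined (0/0); ``se`` is
    ``None`` for exact (deterministic) results.
    """

    value: float | None
    se: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class SpeciesMetrics:
    efficiency: MetricValue
    translocation_probability: MetricValue
    entry_probability: MetricValue
    flux_right: MetricValue
    flux_left: MetricValue


@dataclass(frozen=True)
class TransportMetrics:
    """Per-species transport metrics from one run or one exact solution."""

    per_species: dict[str, SpeciesMetrics]
    source: str  # "kmc" | "exact" | "one_site"

    def __getitem__(self, label: str) -> SpeciesMetrics:
        return self.per_species[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.per_species)


@dataclass(frozen=True)
class RelativeMetrics:
    """Mixture metrics divided by matched single-species baselines."""

    per_species: dict[str, dict[str, MetricValue]]
    baseline_mode: str

    def __getitem__(self, label: str) -> dict[str, MetricValue]:
        return self.per_species[label]


def _ratio_metric(num: int, den: int, se: tuple[float, float] | None) -> MetricValue:
    if den == 0:
        return MetricValue(None, None)
    return MetricValue(num / den, se[1] if se else None)


def _metrics_from_tally(tally: SimulationTally) -> TransportMetrics:
    try:
        ses = standard_errors(tally)
    except ValueError:
        ses = {label: {} for label in tally.labels}
    per_species = {}
    for s, label in enumerate(tally.labels):
        att = int(tally.attempts[s])
        ent = int(tally.entries[s])
        exr = int(tally.exits_right[s])
        exl = int(tally.exits_left[s])
        se = ses.get(label, {})
        T = tally.elapsed_sample_time
        per_species[label] = SpeciesMetrics(
            efficiency=_ratio_metric(exr, att, se.get("efficiency")),
            translocation_probability=_ratio_metric(
                exr, ent, se.get("translocation_probability")
            ),
            entry_probability=_ratio_metric(ent, att, se.get("entry_probability")),
            flux_right=MetricValue(exr / T),
            flux_left=MetricValue(exl / T),
        )
    return TransportMetrics(per_species=per_species, source="kmc")


def _metrics_from_exact(sol: SteadyStateSolution) -> TransportMetrics:
    per_species = {}
    for label, s in sol.per_species.items():
        def mv(x: float) -> MetricValue:
            return MetricValue(None) if math.isnan(x) else MetricValue(x)

        per_species[label] = SpeciesMetrics(
            efficiency=mv(s.efficiency),
            translocation_probability=mv(s.translocation_probability),
            entry_probability=mv(s.entry_probability),
            flux_right=MetricValue(s.exit_flux_right),
            flux_left=MetricValue(s.exit_flux_left),
        )
    return TransportMetrics(per_species=per_species, source="exact")


def _metrics_from_one_site(sol: OneSiteSolution) -> TransportMetrics:
    def mv(x: float) -> MetricValue:
        return MetricValue(None) if math.isnan(x) else MetricValue(x)

    def flux_left(flux_right: float, prob: float) -> MetricValue:
        # r_back·P = flux_right·(1-p)/p; unrecoverable when p = 0
        if math.isnan(prob) or prob == 0:
            return MetricValue(None)
        return MetricValue(flux_right * (1.0 - prob) / prob)

    per_species = {
        "n": SpeciesMetrics(
            efficiency=mv(sol.efficiency_n),
            translocation_probability=mv(sol.prob_n),
            entry_probability=mv(sol.P_empty),
            flux_right=MetricValue(sol.flux_right_n),
            flux_left=flux_left(sol.flux_right_n, sol.prob_n),
        ),
        "m": SpeciesMetrics(
            efficiency=mv(sol.efficiency_m),
            translocation_probability=mv(sol.prob_m),
            entry_probability=mv(sol.P_empty),
            flux_right=MetricValue(sol.flux_right_m),
            flux_left=flux_left(sol.flux_right_m, sol.prob_m),
        ),
    }
    return TransportMetrics(per_species=per_species, source="one_site")


def metrics(tally_or_solution) -> TransportMetrics:
    """Compute per-species transport metrics from a tally or exact solution."""
    if isinstance(tally_or_solution, SimulationTally):
        return _metrics_from_tally(tally_or_solution)
    if isinstance(tally_or_solution, SteadyStateSolution):
        return _metrics_from_exact(tally_or_solution)
    if isinstance(tally_or_solution, OneSiteSolution):
        return _metrics_from_one_site(tally_or_solution)
    raise TypeError(f"cannot derive metrics from {type(tally_or_solution).__name__}")


def _divide(num: MetricValue, den: MetricValue) -> MetricValue:
    """Delta-method ratio of two metric values; undefined propagates."""
    if not num.defined or not den.defined or den.value == 0:
        return MetricValue(None, None)
    value = num.value / den.value
    terms = []
    if num.se is not None and num.value != 0:
        terms.append((num.se / num.value) ** 2)
    if den.se is not None:
        terms.append((den.se / den.value) ** 2)
    se = abs(value) * math.sqrt(sum(terms)) if terms else None
    return MetricValue(value, se)


def relative_metrics(
    mixture: TransportMetrics,
    baselines: dict[str, TransportMetrics],
    baseline_mode: str = "per-species-flux",
) -> RelativeMetrics:
    """Mixture metrics normalized by matched single-species baselines.

    ``baselines[label]`` must come from a run of the same channel with only
    that species present — at the species' own mixture flux in
    ``per-species-flux`` mode, or at the full mixture flux in ``total-flux``
    mode.  Standard errors are propagated by the delta method.
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}; expected {BASELINE_MODES}")
    per_species: dict[str, dict[str, MetricValue]] = {}
    for label, mix in mixture.per_species.items():
        if label not in baselines:
            raise ValueError(f"no baseline supplied for species {label!r}")
        base = baselines[label][label]
        per_species[label] = {
            "efficiency_ratio": _divide(mix.efficiency, base.efficiency),
            "probability_ratio": _divide(
                mix.translocation_probability, base.translocation_probability
            ),
            "entry_ratio": _divide(mix.entry_probability, base.entry_probability),
        }
    return RelativeMetrics(per_species=per_species, baseline_mode=baseline_mode)


def selectivity_ratio(
    mixture: TransportMetrics,
    weak_label: str,
    strong_label: str,
    baselines: dict[str, TransportMetrics],
) -> MetricValue:
    """Mixture weak/strong efficiency ratio over the single-species ratio.

    Values below 1 mean competition enhanced the channel's selectivity
    against the weakly trapped species beyond what the trapping-time
    difference alone provides.
    """
    mix = _divide(
        mixture[weak_label].efficiency, mixture[strong_label].efficiency
    )
    alone = _divide(
        baselines[weak_label][weak_label].efficiency,
        baselines[strong_label][strong_label].efficiency,
    )
    return _divide(mix, alone)


class JammingPoint(NamedTuple):
    trapping_strength: float
    efficiency: float
    boundary: bool


def find_jamming_point(sweep: list[tuple[float, float]]) -> JammingPoint:
    """Locate the jamming transition in a (trapping_strength, efficiency) sweep.

    The jamming point is the trapping strength at which transport efficiency
    peaks before decreasing; ties break toward the weaker trapping.  The
    result is flagged ``boundary`` when the maximum sits at either end of the
    grid, in which case the sweep did not bracket the transition.
    """
    if len(sweep) < 3:
        raise ValueError(f"need at least 3 sweep points (got {len(sweep)})")
    strengths = [s for s, _ in sweep]
    if any(b <= a for a, b in zip(strengths, strengths[1:])):
        raise ValueError("sweep must be sorted by strictly increasing trapping strength")
    best = max(range(len(sweep)), key=lambda i: (sweep[i][1], -i))
    return JammingPoint(
        trapping_strength=sweep[best][0],
        efficiency=sweep[best][1],
        boundary=best in (0, len(sweep) - 1),
    )
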