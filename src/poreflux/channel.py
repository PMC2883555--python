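"""Channel geometry and species kinetics.

A channel is a one-dimensional chain of ``n_sites`` sites (1-based indexing;
the "left" bath adjoins site 1 and the "right" bath adjoins site N).  Each
site holds at most ``capacity`` particles, summed over all species.  Particles
of each species impinge on the entrance site ``entrance_site`` with a Poisson
flux ``flux_J``, hop between neighbouring sites with directed rates, and leave
the channel from the boundary sites with exit ("off") rates.

Rates for a species can be given explicitly, built uniform (a species that
interacts only sterically with the channel), or derived from a per-site
binding-energy landscape via a detailed-balance rate law.  The free hop rate
of the non-trapped species is the canonical time unit (r = 1), so fluxes and
rates are naturally quoted in units of r.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "Edge",
    "RATE_LAWS",
    "SpeciesSpec",
    "ChannelSpec",
    "EnergyProfile",
    "internal_edges",
    "make_uniform_species",
    "make_trapped_species",
    "make_square_well_species",
    "validate_channel",
    "channel_to_config",
    "channel_from_config",
]

#: A directed internal edge (i, j) with |i - j| = 1, sites 1-based.
Edge = tuple[int, int]

RATE_LAWS = ("metropolis", "symmetric")


def internal_edges(n_sites: int) -> Iterator[Edge]:
    """Yield every directed internal edge of an ``n_sites`` chain."""
    for i in range(1, n_sites):
        yield (i, i + 1)
        yield (i + 1, i)


@dataclass(frozen=True)
class SpeciesSpec:
    """Kinetics of one particle species.

    Parameters
    ----------
    label
        Short unique identifier (conventionally "m" for the weakly trapped /
        non-specific species and "n" for the strongly trapped / specific
        one, but any label works).
    flux_J
        Impinging flux: rate of arrival events at the entrance site, whether
        or not the arriving particle finds room to enter.
    hop_rate
        Directed internal hop rates, one entry per directed edge
        ``(i, i±1)``.  A missing edge is a validation error, not an implicit
        zero.
    exit_left, exit_right
        Exit rates from site 1 into the left bath and from site N into the
        right bath.
    """

    label: str
    flux_J: float
    hop_rate: Mapping[Edge, float]
    exit_left: float
    exit_right: float

    def validate(self, n_sites: int) -> list[str]:
        """Return the list of invariant violations for a channel of length N."""
        problems: list[str] = []
        if not self.label:
            problems.append(f"species label must be non-empty (got {self.label!r})")
        if not (self.flux_J >= 0):
            problems.append(f"species {self.label!r}: flux_J must be >= 0 (got {self.flux_J})")
        for name in ("exit_left", "exit_right"):
            v = getattr(self, name)
            if not (v >= 0):
                problems.append(f"species {self.label!r}: {name} must be >= 0 (got {v})")
        required = set(internal_edges(n_sites))
        given = set(self.hop_rate)
        for edge in sorted(required - given):
            problems.append(f"species {self.label!r}: missing hop_rate for edge {edge}")
        for edge in sorted(given - required):
            problems.append(f"species {self.label!r}: hop_rate for non-edge {edge}")
        for edge in sorted(required & given):
            if not (self.hop_rate[edge] >= 0):
                problems.append(
                    f"species {self.label!r}: hop_rate{edge} must be >= 0 "
                    f"(got {self.hop_rate[edge]})"
                )
        return problems


@dataclass(frozen=True)
class ChannelSpec:
    """Channel geometry plus the species that compete for its sites."""

    n_sites: int
    capacity: int
    entrance_site: int
    species: tuple[SpeciesSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.species)

    def species_by_label(self, label: str) -> SpeciesSpec:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(f"no species labelled {label!r}")


@dataclass(frozen=True)
class EnergyProfile:
    """Per-site binding energies (units of kT) and the free hop rate.

    ``site_energy[i]`` is the dimensionless energy of a particle at site
    ``i + 1``; the baths on both sides sit at energy 0.  Negative energies are
    wells (traps), positive energies are barriers.
    """

    site_energy: tuple[float, ...]
    baseline_rate: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_energy", tuple(float(e) for e in self.site_energy))
        if not (self.baseline_rate > 0):
            raise ValueError(f"baseline_rate must be > 0 (got {self.baseline_rate})")
        if not all(math.isfinite(e) for e in self.site_energy):
            raise ValueError("site energies must be finite")

    def __len__(self) -> int:
        return len(self.site_energy)


def _law_rate(law: str, r: float, e_from: float, e_to: float) -> float:
    """Directed rate for a move from energy ``e_from`` to ``e_to``."""
    if law == "metropolis":
        return r * math.exp(-max(0.0, e_to - e_from))
    if law == "symmetric":
        return r * math.exp(-(e_to - e_from) / 2.0)
    raise ValueError(f"unknown rate_law {law!r}; expected one of {RATE_LAWS}")


def make_uniform_species(label: str, flux_J: float, r: float, n_sites: int) -> SpeciesSpec:
    """A species that interacts only sterically with the channel.

    All internal hops and both exits proceed at the free rate ``r``.
    """
    if not (r > 0):
        raise ValueError(f"free hop rate r must be > 0 (got {r})")
    if not (flux_J >= 0):
        raise ValueError(f"flux_J must be >= 0 (got {flux_J})")
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1 (got {n_sites})")
    hops = {edge: r for edge in internal_edges(n_sites)}
    return SpeciesSpec(label=label, flux_J=flux_J, hop_rate=hops, exit_left=r, exit_right=r)


def make_trapped_species(
    label: str,
    flux_J: float,
    profile: EnergyProfile,
    rate_law: str = "metropolis",
) -> SpeciesSpec:
    """Derive a species' rates from a binding-energy landscape.

    Both rate laws satisfy single-particle detailed balance on every internal
    edge, ``rate(i→j)·exp(−E_i) = rate(j→i)·exp(−E_j)``, so the stationary
    single-particle occupancy of site i is proportional to ``exp(−E_i)``.
    Exits use the bath energy fixed at 0: a boundary site sitting in a well of
    depth ε exits at ``r·exp(−ε)`` under the metropolis law, which is how the
    trapping strength r/r_o is realised.
    """
    if rate_law not in RATE_LAWS:
        raise ValueError(f"unknown rate_law {rate_law!r}; expected one of {RATE_LAWS}")
    if not (flux_J >= 0):
        raise ValueError(f"flux_J must be >= 0 (got {flux_J})")
    n = len(profile)
    if n < 1:
        raise ValueError("energy profile must cover at least one site")
    r = profile.baseline_rate
    e = profile.site_energy
    hops: dict[Edge, float] = {}
    for (i, j) in internal_edges(n):
        hops[(i, j)] = _law_rate(rate_law, r, e[i - 1], e[j - 1])
    return SpeciesSpec(
        label=label,
        flux_J=flux_J,
        hop_rate=hops,
        exit_left=_law_rate(rate_law, r, e[0], 0.0),
        exit_right=_law_rate(rate_law, r, e[n - 1], 0.0),
    )


def make_square_well_species(
    label: str,
    flux_J: float,
    trapping_strength: float,
    n_sites: int,
    r: float = 1.0,
    rate_law: str = "metropolis",
) -> SpeciesSpec:
    """Species uniformly trapped over the whole channel.

    ``trapping_strength = r / r_o`` is the ratio of the free hop rate to the
    exit ("off") rate; the corresponding square well has depth
    ``ln(trapping_strength)`` at every site, so internal hops stay at ``r``
    while both exits drop to ``r_o`` (metropolis law).  Strength 1 reduces to
    :func:`make_uniform_species`; strengths below 1 describe a repelled
    species that leaves faster than it hops.
    """
    if not (trapping_strength > 0):
        raise ValueError(f"trapping_strength must be > 0 (got {trapping_strength})")
    profile = EnergyProfile((-math.log(trapping_strength),) * n_sites, baseline_rate=r)
    return make_trapped_species(label, flux_J, profile, rate_law=rate_law)


def validate_channel(spec: ChannelSpec) -> list[str]:
    """Collect every invariant violation of a channel spec (empty list = valid)."""
    problems: list[str] = []
    if not (isinstance(spec.n_sites, int) and spec.n_sites >= 1):
        problems.append(f"n_sites must be an integer >= 1 (got {spec.n_sites})")
    if not (isinstance(spec.capacity, int) and spec.capacity >= 1):
        problems.append(f"capacity must be an integer >= 1 (got {spec.capacity})")
    if not (
        isinstance(spec.entrance_site, int) and 1 <= spec.entrance_site <= max(spec.n_sites, 1)
    ):
        problems.append(
            f"entrance_site must satisfy 1 <= M <= n_sites (got {spec.entrance_site})"
        )
    labels = [s.label for s in spec.species]
    if len(set(labels)) != len(labels):
        problems.append(f"species labels must be unique (got {labels})")
    if not spec.species:
        problems.append("species list must not be empty")
    if isinstance(spec.n_sites, int) and spec.n_sites >= 1:
        for s in spec.species:
            problems.extend(s.validate(spec.n_sites))
    return problems


# ---------------------------------------------------------------------------
# Config (de)serialization.  One JSON-compatible dialect; hop rates are always
# written explicitly so a write→read round trip is exact field-for-field.
# ---------------------------------------------------------------------------

def channel_to_config(spec: ChannelSpec) -> dict:
    """Serialize a channel spec to the JSON-compatible config mapping."""
    return {
        "channel": {
            "n_sites": spec.n_sites,
            "capacity": spec.capacity,
            "entrance_site": spec.entrance_site,
        },
        "species": [
            {
                "label": s.label,
                "flux": s.flux_J,
                "rate_spec": {
                    "kind": "explicit",
                    "hop_rates": [[i, j, s.hop_rate[(i, j)]] for (i, j) in sorted(s.hop_rate)],
                    "exit_left": s.exit_left,
                    "exit_right": s.exit_right,
                },
            }
            for s in spec.species
        ],
    }


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ValueError(f"unknown key(s) {unknown} in {where}; allowed: {sorted(allowed)}")


def _species_from_config(entry: dict, n_sites: int) -> SpeciesSpec:
    _check_keys(entry, {"label", "flux", "rate_spec"}, "species entry")
    label = entry["label"]
    flux = float(entry["flux"])
    rs = entry["rate_spec"]
    kind = rs.get("kind")
    if kind == "uniform":
        _check_keys(rs, {"kind", "r"}, f"rate_spec of species {label!r}")
        return make_uniform_species(label, flux, float(rs["r"]), n_sites)
    if kind == "energy_profile":
        _check_keys(rs, {"kind", "r", "energies", "rate_law"}, f"rate_spec of species {label!r}")
        profile = EnergyProfile(tuple(rs["energies"]), baseline_rate=float(rs["r"]))
        if len(profile) != n_sites:
            raise ValueError(
                f"species {label!r}: energy profile has {len(profile)} entries "
                f"for a {n_sites}-site channel"
            )
        return make_trapped_species(label, flux, profile, rate_law=rs.get("rate_law", "metropolis"))
    if kind == "explicit":
        _check_keys(
            rs, {"kind", "hop_rates", "exit_left", "exit_right"}, f"rate_spec of species {label!r}"
        )
        hops = {(int(i), int(j)): float(rate) for i, j, rate in rs["hop_rates"]}
        return SpeciesSpec(
            label=label,
            flux_J=flux,
            hop_rate=hops,
            exit_left=float(rs["exit_left"]),
            exit_right=float(rs["exit_right"]),
        )
    raise ValueError(
        f"species {label!r}: unknown rate_spec kind {kind!r}; "
        "expected uniform | energy_profile | explicit"
    )


def channel_from_config(config: dict) -> ChannelSpec:
    """Parse and fully validate a channel spec from the config mapping."""
    _check_keys(config, {"channel", "species", "kmc"}, "config")
    chan = config["channel"]
    _check_keys(chan, {"n_sites", "capacity", "entrance_site"}, "channel section")
    n_sites = int(chan["n_sites"])
    spec = ChannelSpec(
        n_sites=n_sites,
        capacity=int(chan["capacity"]),
        entrance_site=int(chan["entrance_site"]),
        species=tuple(_species_from_config(e, n_sites) for e in config["species"]),
    )
    problems = validate_channel(spec)
    if problems:
        raise ValueError("invalid channel config:\n" + "\n".join(f"- {p}" for p in problems))
    return spec
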