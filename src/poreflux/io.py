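"""Config files, result serialization, named test fixtures.

One JSON-compatible config dialect is used everywhere so write-then-read
round trips are exact.  A config file holds a ``channel`` section, a
``species`` list and an optional ``kmc`` section (see
:func:`poreflux.channel.channel_from_config` for the schema).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

from .analytic import SteadyStateSolution
from .channel import (
    ChannelSpec,
    channel_from_config,
    channel_to_config,
    make_square_well_species,
    make_uniform_species,
)
from .kmc import KmcSettings, SimulationTally, mean_density, standard_errors

__all__ = [
    "load_config",
    "save_config",
    "make_fixture",
    "FIXTURE_NAMES",
    "tally_to_dict",
    "solution_to_dict",
    "density_table",
]

_KMC_KEYS = {"sample_time", "n_batches", "seed", "burn_in_time", "stationarity_check"}


def load_config(path: str | Path) -> tuple[ChannelSpec, KmcSettings | None]:
    """Read and fully validate a channel config; unknown keys are rejected."""
    with open(path) as fh:
        config = json.load(fh)
    spec = channel_from_config(config)
    settings = None
    if "kmc" in config:
        kmc = config["kmc"]
        unknown = sorted(set(kmc) - _KMC_KEYS)
        if unknown:
            raise ValueError(f"unknown key(s) {unknown} in kmc section; allowed: {sorted(_KMC_KEYS)}")
        settings = KmcSettings(**kmc)
    return spec, settings


def save_config(spec: ChannelSpec, path: str | Path, settings: KmcSettings | None = None) -> None:
    config = channel_to_config(spec)
    if settings is not None:
        config["kmc"] = asdict(settings)
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("one_site", "two_site", "default_profile", "dilute_uniform")


def make_fixture(name: str) -> ChannelSpec:
    """Return one of the named, fully specified test channels.

    * ``one_site`` — single-site two-species channel with the closed-form
      reference rates (n: exits 0.5/0.5; m: exits 3.0 back / 1.0 forward).
    * ``two_site`` — two-site single-file channel with 9 occupancy states:
      a weakly and a strongly trapped species competing for two sites.
    * ``default_profile`` — the default experiment profile: 6 sites, capacity 1,
      entrance at site 2, specific species trapped at strength 100 and the
      non-specific species untrapped, 1:1 mixture at total flux 0.01.
    * ``dilute_uniform`` — 4-site single-species channel at J = 0.001 entered
      at site 1: the splitting-probability (gambler's-ruin) testbed.
    """
    if name == "one_site":
        from .channel import SpeciesSpec

        n = SpeciesSpec(label="n", flux_J=0.01, hop_rate={}, exit_left=0.5, exit_right=0.5)
        m = SpeciesSpec(label="m", flux_J=0.01, hop_rate={}, exit_left=3.0, exit_right=1.0)
        return ChannelSpec(n_sites=1, capacity=1, entrance_site=1, species=(n, m))
    if name == "two_site":
        weak = make_square_well_species("m", 0.005, 1.0, 2)
        strong = make_square_well_species("n", 0.005, 100.0, 2)
        return ChannelSpec(n_sites=2, capacity=1, entrance_site=1, species=(weak, strong))
    if name == "default_profile":
        weak = make_square_well_species("m", 0.005, 1.0, 6)
        strong = make_square_well_species("n", 0.005, 100.0, 6)
        return ChannelSpec(n_sites=6, capacity=1, entrance_site=2, species=(weak, strong))
    if name == "dilute_uniform":
        sp = make_uniform_species("u", 0.001, 1.0, 4)
        return ChannelSpec(n_sites=4, capacity=1, entrance_site=1, species=(sp,))
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def _clean(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def tally_to_dict(tally: SimulationTally) -> dict:
    """JSON-ready summary of a KMC run: counts, metrics, SEs, densities."""
    try:
        ses = standard_errors(tally)
    except ValueError:
        ses = {}
    density = mean_density(tally)
    out = {
        "elapsed_sample_time": tally.elapsed_sample_time,
        "rng_seed": tally.rng_seed,
        "zero_rate_termination": tally.zero_rate_termination,
        "warnings": list(tally.warnings),
        "species": {},
    }
    for s, label in enumerate(tally.labels):
        att = int(tally.attempts[s])
        ent = int(tally.entries[s])
        exr = int(tally.exits_right[s])
        out["species"][label] = {
            "attempts": att,
            "blocked": int(tally.blocked[s]),
            "entries": ent,
            "exits_left": int(tally.exits_left[s]),
            "exits_right": exr,
            "in_channel_final": int(tally.in_channel_final[s]),
            "efficiency": exr / att if att else None,
            "entry_probability": ent / att if att else None,
            "translocation_probability": exr / ent if ent else None,
            "standard_errors": {k: v[1] for k, v in ses.get(label, {}).items()},
            "mean_density": [float(d) for d in density[:, s]],
        }
    return out


def solution_to_dict(sol: SteadyStateSolution) -> dict:
    summary = sol.summary_dict()
    for sp in summary["species"].values():
        for key, val in sp.items():
            sp[key] = _clean(val)
    return summary


def density_table(tally: SimulationTally):
    """Tidy per-site density profile (site, species, mean_occupancy)."""
    import pandas as pd

    density = mean_density(tally)
    rows = [
        {"site": i + 1, "species": label, "mean_occupancy": float(density[i, s])}
        for s, label in enumerate(tally.labels)
        for i in range(density.shape[0])
    ]
    return pd.DataFrame(rows)
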