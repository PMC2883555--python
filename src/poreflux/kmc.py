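"""Continuous-time kinetic Monte Carlo engine.

Rejection-free Gillespie-style simulation of the multi-species
exclusion-with-trapping hopping process.  At every step the full set of
active event channels is enumerated — one arrival channel per species plus
one hop/exit channel per (species, site, direction) with at least one
particle present and a non-blocked target — the waiting time is exponential
in the total rate, and the event is selected proportionally to its rate.
Arrivals fire at the impinging flux J regardless of occupancy; an arrival
that finds the entrance site full is counted as blocked, which is what makes
``efficiency = transmitted/impinging`` and ``entry probability =
entries/attempts`` directly measurable.

Counting starts after a burn-in period.  Exits are only credited to
particles that themselves entered after burn-in (particles present at the
end of burn-in are marked "untagged" and the mover within a site/species is
drawn uniformly), so the tally identities

* ``attempts = blocked + entries``
* ``entries = exits_left + exits_right + in_channel_final``

hold as exact integer identities for every run.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .channel import ChannelSpec, validate_channel

__all__ = ["KmcSettings", "SimulationTally", "simulate", "mean_density", "standard_errors"]


@dataclass(frozen=True)
class KmcSettings:
    """Run-length and bookkeeping settings for one KMC run.

    ``burn_in_time=None`` selects the default 10 / (smallest positive exit
    rate), the slowest single-particle release timescale in the channel.
    """

    sample_time: float
    n_batches: int = 16
    seed: int = 0
    burn_in_time: float | None = None
    stationarity_check: bool = False

    def __post_init__(self) -> None:
        if not (self.sample_time > 0):
            raise ValueError(f"sample_time must be > 0 (got {self.sample_time})")
        if self.n_batches < 2:
            raise ValueError(f"n_batches must be >= 2 (got {self.n_batches})")
        if self.burn_in_time is not None and self.burn_in_time < 0:
            raise ValueError(f"burn_in_time must be >= 0 (got {self.burn_in_time})")


@dataclass
class SimulationTally:
    """Event counts and time-integrated occupancies from one KMC run.

    Count arrays are indexed by species (order of ``labels``); batch arrays
    carry the per-batch breakdown used for batch-means standard errors.
    """

    labels: tuple[str, ...]
    attempts: np.ndarray  # (S,)
    blocked: np.ndarray
    entries: np.ndarray
    exits_left: np.ndarray
    exits_right: np.ndarray
    in_channel_final: np.ndarray
    elapsed_sample_time: float
    time_integrated_occupancy: np.ndarray  # (N, S)
    batch_attempts: np.ndarray  # (B, S)
    batch_blocked: np.ndarray
    batch_entries: np.ndarray
    batch_exits_left: np.ndarray
    batch_exits_right: np.ndarray
    batch_occupancy: np.ndarray  # (B, N, S), time-integrated per batch
    rng_seed: int
    zero_rate_termination: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def n_batches(self) -> int:
        return self.batch_attempts.shape[0]

    def species_index(self, label: str) -> int:
        return self.labels.index(label)


@njit(cache=True)
def _core(J, hf, hb, exl, exr, n_max, M, burn_in, sample_time, n_batches, seed):
    S = J.shape[0]
    N = hf.shape[1]
    occ = np.zeros((N, S), np.int64)
    unt = np.zeros((N, S), np.int64)  # particles present at end of burn-in
    sitesum = np.zeros(N, np.int64)
    att = np.zeros((n_batches, S), np.int64)
    blk = np.zeros((n_batches, S), np.int64)
    ent = np.zeros((n_batches, S), np.int64)
    exlc = np.zeros((n_batches, S), np.int64)
    exrc = np.zeros((n_batches, S), np.int64)
    occ_int = np.zeros((n_batches, N, S), np.float64)
    n_slots = S + 2 * N * S
    rates = np.zeros(n_slots, np.float64)

    np.random.seed(seed)
    t = 0.0
    t_end = burn_in + sample_time
    batch_dt = sample_time / n_batches
    tagged = False
    zero_rate = False

    while True:
        # Rebuild the event-rate vector.  Slot layout (documented RNG order):
        # [0..S): arrivals; then per species s and site i two slots,
        # leftward (exit_left at i=0, hop i->i-1 otherwise) and rightward
        # (exit_right at i=N-1, hop i->i+1 otherwise).
        total = 0.0
        for s in range(S):
            rates[s] = J[s]
            total += J[s]
        for s in range(S):
            base = S + 2 * N * s
            for i in range(N):
                c = occ[i, s]
                rl = 0.0
                rr = 0.0
                if c > 0:
                    if i == 0:
                        rl = c * exl[s]
                    elif sitesum[i - 1] < n_max:
                        rl = c * hb[s, i]
                    if i == N - 1:
                        rr = c * exr[s]
                    elif sitesum[i + 1] < n_max:
                        rr = c * hf[s, i]
                rates[base + 2 * i] = rl
                rates[base + 2 * i + 1] = rr
                total += rl + rr

        if total <= 0.0:
            t_new = t_end
            zero_rate = True
        else:
            t_new = t + np.random.exponential(1.0 / total)

        # accumulate occupancy-time over [t, t_new) clipped to the sample window
        a = t if t > burn_in else burn_in
        b = t_new if t_new < t_end else t_end
        while a < b:
            bi = int((a - burn_in) / batch_dt)
            if bi >= n_batches:
                bi = n_batches - 1
            seg = burn_in + (bi + 1) * batch_dt
            if seg > b:
                seg = b
            w = seg - a
            if w > 0.0:
                for i in range(N):
                    for s in range(S):
                        if occ[i, s] > 0:
                            occ_int[bi, i, s] += occ[i, s] * w
            if seg <= a:
                break
            a = seg

        if t_new >= t_end:
            break
        if (not tagged) and t_new >= burn_in:
            for i in range(N):
                for s in range(S):
                    unt[i, s] = occ[i, s]
            tagged = True
        t = t_new

        counting = t_new >= burn_in
        bi_ev = 0
        if counting:
            bi_ev = int((t_new - burn_in) / batch_dt)
            if bi_ev >= n_batches:
                bi_ev = n_batches - 1

        x = np.random.random() * total
        chosen = -1
        acc = 0.0
        for k in range(n_slots):
            acc += rates[k]
            if x < acc:
                chosen = k
                break
        if chosen < 0:  # float round-off: fall back to the last active slot
            for k in range(n_slots - 1, -1, -1):
                if rates[k] > 0.0:
                    chosen = k
                    break

        if chosen < S:
            s = chosen
            if counting:
                att[bi_ev, s] += 1
            if sitesum[M] < n_max:
                occ[M, s] += 1
                sitesum[M] += 1
                if counting:
                    ent[bi_ev, s] += 1
            else:
                if counting:
                    blk[bi_ev, s] += 1
        else:
            k = chosen - S
            s = k // (2 * N)
            rem = k % (2 * N)
            i = rem // 2
            rightward = rem % 2 == 1
            c = occ[i, s]
            moves_untagged = np.random.random() * c < unt[i, s]
            occ[i, s] -= 1
            sitesum[i] -= 1
            if moves_untagged:
                unt[i, s] -= 1
            if rightward:
                if i == N - 1:
                    if counting and not moves_untagged:
                        exrc[bi_ev, s] += 1
                else:
                    occ[i + 1, s] += 1
                    sitesum[i + 1] += 1
                    if moves_untagged:
                        unt[i + 1, s] += 1
            else:
                if i == 0:
                    if counting and not moves_untagged:
                        exlc[bi_ev, s] += 1
                else:
                    occ[i - 1, s] += 1
                    sitesum[i - 1] += 1
                    if moves_untagged:
                        unt[i - 1, s] += 1

    if not tagged:  # no event ever fired inside the sample window
        for i in range(N):
            for s in range(S):
                unt[i, s] = occ[i, s]
    return att, blk, ent, exlc, exrc, occ_int, occ, unt, zero_rate


def _rate_arrays(spec: ChannelSpec):
    N, S = spec.n_sites, len(spec.species)
    J = np.zeros(S)
    hf = np.zeros((S, N))
    hb = np.zeros((S, N))
    exl = np.zeros(S)
    exr = np.zeros(S)
    for s, sp_ in enumerate(spec.species):
        J[s] = sp_.flux_J
        exl[s] = sp_.exit_left
        exr[s] = sp_.exit_right
        for i in range(N - 1):
            hf[s, i] = sp_.hop_rate[(i + 1, i + 2)]
            hb[s, i + 1] = sp_.hop_rate[(i + 2, i + 1)]
    return J, hf, hb, exl, exr


def _default_burn_in(spec: ChannelSpec) -> float:
    exit_rates = [
        r for sp_ in spec.species for r in (sp_.exit_left, sp_.exit_right) if r > 0
    ]
    return 10.0 / min(exit_rates) if exit_rates else 0.0


def simulate(spec: ChannelSpec, settings: KmcSettings) -> SimulationTally:
    """Run one KMC realization of the channel and return its tally."""
    problems = validate_channel(spec)
    if problems:
        raise ValueError("invalid channel spec:\n" + "\n".join(f"- {p}" for p in problems))
    burn_in = settings.burn_in_time
    if burn_in is None:
        burn_in = _default_burn_in(spec)
    J, hf, hb, exl, exr = _rate_arrays(spec)
    att, blk, ent, exlc, exrc, occ_int, occ, unt, zero_rate = _core(
        J,
        hf,
        hb,
        exl,
        exr,
        spec.capacity,
        spec.entrance_site - 1,
        float(burn_in),
        float(settings.sample_time),
        int(settings.n_batches),
        int(settings.seed),
    )
    tally = SimulationTally(
        labels=spec.labels,
        attempts=att.sum(axis=0),
        blocked=blk.sum(axis=0),
        entries=ent.sum(axis=0),
        exits_left=exlc.sum(axis=0),
        exits_right=exrc.sum(axis=0),
        in_channel_final=(occ - unt).sum(axis=0),
        elapsed_sample_time=float(settings.sample_time),
        time_integrated_occupancy=occ_int.sum(axis=0),
        batch_attempts=att,
        batch_blocked=blk,
        batch_entries=ent,
        batch_exits_left=exlc,
        batch_exits_right=exrc,
        batch_occupancy=occ_int,
        rng_seed=int(settings.seed),
        zero_rate_termination=bool(zero_rate),
    )
    unresolved = tally.in_channel_final.sum()
    total_entries = tally.entries.sum()
    if total_entries > 0 and unresolved / total_entries > 0.01:
        tally.warnings.append(
            f"{unresolved} of {total_entries} entries were still in the channel at the "
            "end of the run (> 1%); translocation probabilities may be biased — "
            "increase sample_time"
        )
    if settings.stationarity_check:
        _stationarity_check(tally)
    return tally


def _stationarity_check(tally: SimulationTally) -> None:
    """Flag drift between first- and second-half efficiencies (> 5 SE)."""
    B = tally.n_batches
    half = B // 2
    for s, label in enumerate(tally.labels):
        halves = []
        for sl in (slice(0, half), slice(half, B)):
            att = tally.batch_attempts[sl, s].astype(float)
            ok = att > 0
            if ok.sum() < 2:
                halves = []
                break
            eff = tally.batch_exits_right[sl, s][ok] / att[ok]
            halves.append((eff.mean(), eff.std(ddof=1) / math.sqrt(ok.sum())))
        if halves:
            (m1, se1), (m2, se2) = halves
            se = math.hypot(se1, se2)
            if se > 0 and abs(m1 - m2) > 5 * se:
                tally.warnings.append(
                    f"species {label!r}: first/second-half efficiencies differ by "
                    f"{abs(m1 - m2):.4g} (> 5 SE = {5 * se:.4g}); burn-in may be too short"
                )


def mean_density(tally: SimulationTally) -> np.ndarray:
    """Time-averaged occupancy per site and species, shape (N, S)."""
    if not (tally.elapsed_sample_time > 0):
        raise ValueError("tally has zero elapsed sample time; no density is defined")
    return tally.time_integrated_occupancy / tally.elapsed_sample_time


def standard_errors(tally: SimulationTally) -> dict[str, dict[str, tuple[float, float]]]:
    """Batch-means (mean, SE) of efficiency, translocation and entry probability.

    Batch values are ratios of within-batch counts; batches whose denominator
    is zero are dropped.  Raises if fewer than two batches carry data for
    every metric of every fed species.
    """
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for s, label in enumerate(tally.labels):
        att = tally.batch_attempts[:, s].astype(float)
        ent = tally.batch_entries[:, s].astype(float)
        per_metric: dict[str, tuple[float, float]] = {}
        for name, num, den in (
            ("efficiency", tally.batch_exits_right[:, s], att),
            ("entry_probability", tally.batch_entries[:, s], att),
            ("translocation_probability", tally.batch_exits_right[:, s], ent),
        ):
            ok = den > 0
            if ok.sum() < 2:
                if tally.attempts[s] == 0:
                    continue  # species never fed: metric undefined, not an error
                raise ValueError(
                    f"species {label!r}: fewer than 2 batches with data for {name}; "
                    "increase sample_time or reduce n_batches"
                )
            vals = num[ok] / den[ok]
            per_metric[name] = (
                float(vals.mean()),
                float(vals.std(ddof=1) / math.sqrt(ok.sum())),
            )
        out[label] = per_metric
    return out
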