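# Methods

## The model

`poreflux` implements a kinetic (master-equation) model of transport through
a narrow channel, of the kind used to describe nuclear-pore-complex-like
transporters and their artificial nanopore mimics. The channel is a chain of
`N` sites. Particles of one or more species arrive at an entrance site `M`
as a Poisson stream with impinging flux `J` (per species), enter when the
entrance site's total occupancy is below the per-site capacity `n_max`, hop
between neighbouring sites with directed rates, and leave the channel from
site 1 (back into the entrance-side bath) or site `N` (transported) with
exit ("off") rates. Capacity is the only interaction: a hop or entry into a
full site is impossible. `n_max = 1` is single-file transport; larger
`n_max` emulates a wider channel.

Three observables summarize transport, per species:

* **efficiency** `eff = transmitted flux / impinging flux`,
* **entry probability** `P_in = entered / arrived`,
* **translocation probability** `P_tr = transmitted / entered`,

with the exact decomposition `eff = P_in · P_tr`. Selectivity between a
weakly trapped ("non-specific", label `m`) and a strongly trapped
("specific", label `n`) species is quantified by ratios of these quantities
against matched single-species baselines, and by the **selectivity ratio**
`(eff_m/eff_n) / (eff_m,alone/eff_n,alone)`.

### Rates from binding energies

When hop/exit rates derive from a per-site binding energy `E_i` (in kT,
baths at 0), two detailed-balance rate laws are available:

* `metropolis` (default): `rate = r·exp(−max(0, ΔE))` — downhill moves at
  the free rate `r`, uphill moves Boltzmann-suppressed;
* `symmetric`: `rate = r·exp(−ΔE/2)`.

Both satisfy `rate(i→j)·e^{−E_i} = rate(j→i)·e^{−E_j}` on every edge, so the
single-particle stationary occupancy is `∝ e^{−E_i}`; the choice only
rescales the trapping-strength axis. No cap is applied to uphill symmetric
rates: any one-sided cap would break detailed balance, which the test suite
asserts to machine precision.

A species trapped "in the channel" is modelled as a square well of depth `ε`
over all `N` sites: internal hops stay at `r`, while both exits drop to
`r_o = r·e^{−ε}`. The **trapping strength** is `r/r_o = e^ε`. A site-resolved
well (e.g., a trap at one position only) is equally expressible through
`EnergyProfile`, but changes only the dwell time at that site, not the exit
rates, and therefore not the translocation probability of a single particle;
the square well is what realizes the off-rate knob that the trapping
phenomenology (facilitated transport followed by jamming) requires.

## Exact stationary solutions

For the one-site channel the three-state master equation (empty / holds `n` /
holds `m`) has the closed form

    P_s = (J_s/R_s)·P_0,  P_0 = 1/(1 + J_n/R_n + J_m/R_m),  R_s = r_s,fwd + r_s,back,

giving `eff_s = (r_s,fwd/R_s)·P_0` and `P_tr,s = r_s,fwd/R_s`. Because `P_0`
is common to both species, the cross-species efficiency ratio
`(r_m,fwd/R_m)/(r_n,fwd/R_n)` is independent of both fluxes: a channel that
holds at most one particle cannot change relative selectivity through
competition. This is the model's negative control.

For general (small) channels, `exact_steady_state` enumerates every
occupancy state (site-wise product of per-site occupancy vectors,
lexicographic, deterministic), assembles the transition-rate generator
(arrivals gated by entrance capacity, hops gated by target capacity, exits;
`c` identical particles at a site multiply the single-particle rate by `c`),
and solves `πQ = 0` with the normalization row replacing one equation —
dense below 5,000 states, sparse direct above. The solver refuses state
spaces above a configurable cap (default 2·10⁵) and reports the residual;
solves with residual above 1e-8 raise. In practice sparse direct
factorization becomes uneconomical around ~10⁴–10⁵ states for these
generators (fill-in), which is why the width experiments run on the
simulator instead.

Blocked arrivals are not transitions; the blocked flux is `J·P(entrance
full)`, which is what makes `P_in = 1 − P(entrance full)` available from the
stationary distribution.

## Kinetic Monte Carlo engine

The simulator is a rejection-free continuous-time (Gillespie/BKL-family)
algorithm. Each step rebuilds the full event-rate vector — one arrival
channel per species (always active at rate `J`; a blocked arrival is a
counted no-op) plus one channel per (species, site, direction) — draws an
exponential waiting time at the total rate, and picks an event
proportionally to its rate. With at most `2 + 2·N·S ≈ 40` channels for every
geometry studied here, a full rebuild inside a numba-compiled loop is both
simpler and faster than incremental bookkeeping. The RNG is numba's
per-thread NumPy-compatible generator seeded once per run; the event order
is fixed (arrivals first, then per-species site-major left/right), so
identical (spec, settings, seed) reproduce tallies bit-for-bit.

Counting starts after a burn-in (default `10 / min positive exit rate`, the
slowest single-particle release timescale). Particles already in the channel
when counting starts are marked untagged; hop and exit events draw the moved
particle uniformly within its (site, species) pool, and untagged exits are
not credited. This makes

    attempts = blocked + entries
    entries  = exits_left + exits_right + in_channel_final

exact integer identities for every run, at the price of one extra uniform
per hop/exit event. Statistically the exclusion of pre-existing particles is
a transient-suppression of order (channel dwell time / sample time).

Uncertainties are batch-means standard errors: the sample window is split
into `n_batches` (default 16–20) equal time slices, each metric is formed
per batch, and the SE is `std/√B` over batches with a nonzero denominator.
An optional stationarity check compares first- and second-half efficiencies
and warns at 5 SE. A warning is also attached when more than 1 % of entries
are still in the channel at the end of a run, since translocation
probabilities are then biased downward.

## Experiment drivers and their defaults

All sweeps share one default profile, chosen once: `N = 6`, `n_max = 1`,
entrance `M = 2`, free hop rate `r = 1` (the time unit), total flux
`J_tot = 0.01·r`, specific species at trapping strength 100 (`r_o = 0.01`),
non-specific species swept over strengths 1–100 (15 log-spaced points).
The single-species (jamming) sweep spans strengths 1–10⁴ to bracket the
transition; its efficiency maximum sits near strength 10–30, between
facilitated transport (translocation rises from 2/7 toward 1/2) and
entrance blocking.

Two baseline conventions are implemented and always recorded:
`per-species-flux` (the species alone at its mixture flux) and `total-flux`
(the species alone at the full mixture flux). The weak species' inhibition
is reported against per-species baselines; the strong species' enhancement
is a statement about equal *total* concentration and is only visible against
the total-flux baseline — in per-species normalization it hovers at 1.00–1.04
at the default profile. Both numbers are computed; outputs carry the mode.

The inhibition of the weak species is translocation-driven (its probability
ratio falls below its entry ratio) on the interior of the contrast axis,
roughly strengths 2–30 at the default profile; at the untrapped extreme the
two contributions are comparable. Tests therefore probe the claim at a 10×
trapping contrast.

The addition experiment holds the specific flux at `J_n = 0.001` (a tenth of
the titration total, so the specific species alone leaves the channel far
from jamming) and adds the non-specific species at 1× or 10× that flux. Its
trapping-strength grid spans 1–30: the *added* species is by construction
the weakly-to-moderately trapped one, and additions at near-specific
trapping (where entry blocking collapses the specific flux) are the
titration experiment's regime. On this grid the 10× curve is non-monotonic —
within 0.5 % of 1 at both ends, peaking near +4 % at strength ≈ 13 — while
the 1× peak is only ≈ +0.6 %, which is why quantitative assertions use the
10× curve. The enhancement mechanism is visible in the density profiles the
driver records: the added species accumulates in the entrance half,
hampering backward escape of the specific species.

Sweep runs derive their seeds sequentially from the plan's `base_seed` and
record them in the output tables.

## What the synthetic conditions do and do not show

All inputs are synthetic: the package's claims are about the kinetic model
itself, not about any particular channel's measured rate constants. The
model ignores everything the mapping to real channels would add — flexible
polymer (FG-nup) dynamics, position-dependent capacity, particle size
mixtures, concentration gradients and return flux from the trans side, and
any coupling between binding and geometry. Agreement of the simulator with
the enumerated exact solution shows the sampler is correct; the sweep
phenomenology (jamming, competition-induced inhibition/enhancement,
width/length trends, addition non-monotonicity) shows the mechanism operates
in the model, with magnitudes that depend on the unprinted profile choices
above.

## Numerical choices

* Stochastic acceptance comparisons use 3 batch-means SE plus an absolute
  floor (5e-3 on probabilities/efficiencies, 1e-2 on occupancies): near-empty
  tallies have degenerate SE estimates, and with hundreds of simultaneous
  3-SE comparisons a bare band would produce order-one false alarms.
* Undefined metrics (0/0) are explicit `None`s and propagate; they are never
  coerced to 0.
* Jamming-point ties break toward weaker trapping; endpoint maxima are
  flagged `boundary`.
* Run lengths in the test suite are sized from exact-solution effect sizes
  and binomial SE estimates so that each asserted ordering is a ≳3σ event
  under the model; the largest runs (width sweep) use sample time 8e7.

## Known limitations

* The exact solver is limited by sparse-LU fill-in well before the state cap
  for multi-species, higher-capacity channels.
* Batch-means SEs assume batches longer than the slowest relaxation time;
  for extreme trapping (strength ≫ 10³) the default batching undercovers,
  which the stationarity check can flag but not repair.
* Translocation statistics for species that almost never enter are reported
  with few effective samples; the per-batch dropout rule can leave them
  undefined at short sample times.
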