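# Methods

## The system and the model

`metacoop` simulates a metapopulation of budding-yeast wells growing on
sucrose through daily dilution–migration–growth cycles. Two strains share
each well: *producers* secrete invertase whose hydrolysis products act as a
public good, and *non-producers* consume the good without paying the
production cost. Within a cycle the densities `Np`, `Nnp` (cells/µL) follow

    dNnp/dt = r · Nnp · (1 − (Np+Nnp)/K) · Np / (Np + k_M)
    dNp/dt  = r(1−c) · Np · (1 − (Np+Nnp)/K) · (Np + ε) / (Np + ε + k_M)

Both strains grow logistically toward a common carrying capacity `K`, with
growth modulated by a Monod factor in the available public good, taken
proportional to the producer density. Producers pay a fractional cost `c`
and enjoy a private benefit `ε` — the share of the good captured before it
diffuses away, expressed in equivalent producer cells/µL.

This structure produces the three phenomena the package is organised
around:

* **Negative frequency-dependent selection.** Rare producers grow at
  `r(1−c)·ε/(ε+k_M)` while non-producers cannot grow at all; common
  producers pay `c` against free-riders growing at nearly `r`. A well-mixed
  population therefore settles at an intermediate producer fraction.
* **Density-dependent selection.** The same producer fraction in a denser
  well means more absolute producers and a more saturated Monod factor,
  shifting the balance toward free-riders; sparser wells equilibrate at
  higher producer fractions. Equivalently, the equilibrium fraction is
  non-decreasing in the dilution factor below the collapse point.
* **An Allee effect.** Below a critical producer density the community
  cannot regrow `D`-fold within one cycle, so raising `D` past a tipping
  point `D*` causes sudden collapse, not gradual decline.

On the placement of `ε`: the private benefit is modelled as an additive
contribution to the good concentration a producer experiences, so it enters
both numerator and denominator of the producer Monod factor and a rare
producer grows at a *bounded* fraction `ε/(ε+k_M)` ≈ 0.35 of maximum. The
alternative of adding `ε` only to the numerator was evaluated and rejected:
it weakens the Allee effect so much that no collapse occurs below `D = 2000`
and it more than doubles the equilibrium producer fraction, inconsistent
with the behaviour the parameters were fitted to reproduce.

## The daily cycle

One cycle applies, in order: division of every density by `D` (dilution into
fresh medium), multiplication by the dispersal matrix `M` (migration), and
numerical integration of the growth ODE for `t_grow` hours. Dilution and
migration are both linear maps, so their relative order cannot change the
resulting state; it only decides which operation a one-cycle perturbation is
book-kept against. The implementation fixes dilute-then-migrate and does not
branch.

After growth, any strain density below the extinction cutoff (default
0.005 cells/µL ≈ one cell in a 200 µL well) is set to exactly zero. The
continuous model otherwise never reaches zero, so some cutoff is required
for extinction to be a well-defined event; the chosen value is the smallest
physically meaningful density for the experimental well volume. The cutoff
does not move the collapse boundary — below the Allee threshold the decline
to zero is deterministic — it only fixes when the event is recorded.

Measurements (trajectory records) are taken at the end of growth, matching
daily plate-reader/cytometry sampling.

## Migration

Every node exports the same fraction `m` of its cells per cycle, split
evenly among its neighbours, independent of how many neighbours it has. The
dispersal matrix is column-stochastic with `M[j][j] = 1−m` (1 for isolated
nodes) and `M[i][j] = m/deg(j)` on edges: cell numbers are conserved
exactly, and on heterogeneous graphs net flow runs from low- to high-degree
nodes (in a star, sides send `m` to the centre, the centre returns `m/n_side`
to each side). Migration is simultaneous, computed from the pre-migration
state. For any degree-regular graph with identical node states the operator
is the identity, which is why fully connected networks and isolated wells
behave identically from uniform starts.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| `r` | maximum per-capita growth rate | h⁻¹ | 0.5 |
| `c` | public-good production cost | — | 0.07 |
| `K` | carrying capacity | cells/µL | 90 000 |
| `ε` | producer private benefit | cells/µL | 14 |
| `k_M` | half-saturation producer density | cells/µL | 26 |
| `t_grow` | growth time per cycle | h | 22 |
| `D` | daily dilution factor | — | 650 |
| `m` | migrant fraction per cycle | — | 0.6 |

The defaults are the fitted values for the yeast sucrose system: `r` and `K`
measured directly; `c`, `ε` and the growth duration fitted manually inside
the biological constraint box `c < 0.1`, `ε ≈ k_M`, lag phase 1–4 h (the
22 h effective growth time encodes a 1 h lag in a 23 h incubation). The
`calibrate` operation reconstructs that manual fit as a coarse grid search
over `c ∈ {0.03…0.09}`, `ε/k_M ∈ [0.25, 1]`, `t_grow ∈ [19, 22]` h scored by
squared relative error against supplied summary targets; it is a
convenience, not an inference method.

At `D = 650` a cycle spans `log₂ 650 ≈ 9.3` generations, so `m = 0.6` per
cycle corresponds to roughly 6% migrants per generation.

## Numerical choices

* Growth integration: adaptive Runge–Kutta (RK45) at `rtol = 1e-8`,
  `atol = 1e-10` cells/µL, all nodes integrated as one vectorised system.
  Post-integration densities below `atol` are clipped to zero, and a strain
  that starts a cycle at exactly zero is pinned at zero (the subspace is
  absorbing; pinning removes solver round-off).
* Steady state: the cycle map is iterated until the maximum relative change
  of any node density over one cycle is below `1e-6` (default), up to 2000
  cycles. Periodic orbits up to period 32 are recognised by recurrence
  within the same tolerance on two consecutive cycles; the minimum-density
  phase of the orbit — the least resilient point — is returned and used as
  the reference state for perturbation protocols. Extinction and
  non-convergence are reported as distinct outcomes.
* Survival classification (`survives`): early exit on all-node extinction
  (absorbing) or on convergence at relative change `< 1e-10` — a converged
  nonzero state trivially survives the remaining cycles. Near-boundary
  transients pass the neighbourhood of the saddle far above that tolerance,
  so the shortcut does not affect classification at the bisection
  resolutions used.
* Bisections: the critical dilution `D*` is bracketed by a surviving and a
  collapsing endpoint and bisected to relative tolerance `1e-3` (coarser in
  some tests); shock magnitudes are bisected geometrically for `ΔD` (the
  scale spans decades) and arithmetically for `Δr`. Monotone classification
  inside the bracket is assumed and verified at the endpoints; a shock
  bracket whose upper endpoint still recovers is reported `capped` rather
  than extrapolated.
* Resilience protocol: equilibrate, shock for one cycle (`D′ = D·ΔD` or
  `r′ = r − Δr`), then relax for up to 500 cycles. Recovery means the
  all-node total density returns within 5% of the pre-shock steady-state
  total. The basin (recovery-threshold) search scales the whole equilibrium
  state by `s ∈ (0, 1]` and bisects the same recovery criterion, reporting
  both `s` and `s ×` mean per-node equilibrium density.

## Initial conditions

Because of the Allee effect the model has a genuine survival basin: a dilute
inoculum (e.g. 10⁴ cells/µL total at 10% producers) lies *outside* the basin
of an isolated well at `D = 650` and collapses, while the same fractions at
saturated-culture density survive. Runs therefore default to a
saturated-culture-like start of 8×10⁴ cells/µL total at the requested
producer fraction, matching experiments seeded from dense overnight
co-cultures. Scans (phase diagrams, critical dilution, resilience) start
from the metapopulation equilibrated at the reference protocol `D = 650`
with the scanned migration rate; if that equilibration fails the scan falls
back to a uniform (1000, 9000) cells/µL state so the failure is visible in
the output rather than masked.

## Synthetic data

The generator emulates the study's two raw observables: per-well daily total
density as an optical-density-like readout (`od = total · od_scale ·
lognormal`, mean-one noise with coefficient of variation `od_cv`, default
0.05 — a typical plate-reader scale) and per-well daily producer fraction as
finite-event cytometry (`Binomial(events, fraction)/events`, default 10⁴
events). Replicates share the deterministic dynamics and differ only in
measurement noise; the truth table is retained in the same tidy table, and
the schema extends the trajectory CSV export (extra `replicate` and
`initial_fraction` columns) so analysis code runs unchanged on real-shaped
data. All randomness flows from a single mandatory seed.

What the generator does **not** emulate: demographic stochasticity,
cytometer gating or spectral overlap, plate-position and evaporation
effects, day-to-day batch effects, or measurement-induced loss. Passing
recovery tests on this data shows the estimators are consistent with the
stated noise model, not that the model captures every feature of real plate
data.

## Problem sizes

The packaged analyses default to the study conditions: 10-node stars,
`m = 0.6`, survival horizons of 1000 cycles, bisection over `D ∈ [400,
2000]`. Tests exercising orderings (pure-producer variants, resilience
comparisons) use coarser bisection tolerances (2–5%) and shorter
classification horizons (400 cycles) — the orderings they assert are far
larger than those resolutions. The acceptance script uses the full
1000-cycle horizon and `1e-3` bisection tolerance throughout.

## Known limitations

* The within-cycle equations are a deliberately minimal phenomenology:
  no explicit enzyme or sugar dynamics, no lag-phase kinetics, no
  stochastic demography. Quantitative agreement with plate data is
  expected only at the level of trends and characteristic scales.
* The collapse boundary of a *single isolated well* computed at the default
  parameter set sits a few percent below the boundary the parameters were
  originally tuned to reproduce; the star-network boundary, the equilibrium
  fractions, the enrichment ratio, and all stability/resilience orderings
  are reproduced. The residual is consistent with small differences in the
  untranscribed details of the original manual fit.
* Migration is deterministic and simultaneous; stochastic migrant sampling,
  directed or weighted graphs, asynchronous cycles, and temporal networks
  are out of scope.
* The basin search probes one direction in state space (uniform scaling of
  the equilibrium); the true basin boundary is a hypersurface and can be
  closer along other directions.
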