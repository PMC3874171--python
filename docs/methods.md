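# Methods

## Model

DNA is a lattice of `N` base pairs. A nucleosome occupies `k = 147`
consecutive bp ("hard rod": footprints never overlap). A nucleosome whose
footprint starts at bp `i` has binding energy `V_i` in units of k_BT; the
track of `V_i` values is either homogeneous, read from a bedGraph/wiggle
file, converted from a start-probability track via `V_i = −ln P_i + C`
(with `C` fixed by the target mean level V̄), or generated synthetically.

Three kinetic moves define a continuous-time Markov chain:

| move | propensity | notes |
|---|---|---|
| adsorption | `k_on` per eligible start | a start is eligible when its whole footprint is empty, outside any hard barrier, and not flagged forbidden; the landing site is uniform over eligible starts |
| removal | `k0_off · exp(V_i + V_a)` per nucleosome | `k0_off = k_on` by default, which enforces the thermal Boltzmann condition `k_on/k_off = exp(−V_i)` when `V_a = 0`; `V_a ≥ 0` is the uniform shift representing ATP-driven eviction |
| sliding | `k_slide` per nucleosome | one event moves the nucleosome in a uniformly chosen direction until it abuts the nearest obstacle; the move ignores `V` (active pushing is sequence-independent); a blocked slide consumes the event but changes nothing |

Thermal sliding is omitted: spontaneous nucleosome diffusion is negligible
on the hour timescale the simulations address. There is no explicit ATP
bookkeeping; activity enters only through `V_a` and `k_slide`.

The simulator is an exact Gillespie algorithm (exponential waiting times,
event chosen proportionally to its propensity), compiled with numba. Per
step it enumerates free gaps (O(number of nucleosomes)); eligible-start
counting and uniform sampling under forbidden-start masks use prefix sums
with binary search. Every replica is deterministic given its 31-bit seed;
replica seeds derive from a base seed through `numpy.random.SeedSequence`
with deterministic rejection of birthday collisions.

## Barriers

The nucleosome-free region upstream of the TSS (`j = i − tss_offset`,
barrier at `j ∈ [−150, −1]` by default) is modeled three ways:

* **hard** — all starts whose footprint intersects the interval are
  forbidden and sliding across it is blocked. When a hard barrier is
  inserted *mid-run*, nucleosomes already overlapping it are kept: they can
  no longer slide and cannot be replaced after removal, so the zone clears
  at the active eviction rate. This choice is what ties the
  pattern-formation timescale to the eviction timescale (below).
* **soft** — the potential inside the interval is replaced by the ramp
  `V(j) = m·j`, `m = −13/150` k_BT/bp, rising from ≈0.087 k_BT at `j = −1`
  to +13 k_BT at `j = −150`. The orientation (cost grows with distance
  into the barrier, pushing from the gene side) and the interval convention
  are declared package conventions; only the slope magnitude is taken as
  given.
* **fixed nucleosome** — an immobile, non-removable nucleosome at a stated
  position; a pure steric barrier.

## Parameters, units, defaults

All energies are in k_BT (no separate temperature parameter); times in
seconds.

* `V̄ = −7 k_BT` — homogeneous binding level, the effective in-vivo mean.
* `k_on = 0.06 s⁻¹` per eligible start. Chosen so that (a) the thermal
  off-rate `k_on·e^{−7}` yields ≪1 spontaneous desorption per nucleosome
  per hour — thermal runs stay kinetically frozen in a jammed,
  random-sequential-adsorption-like state, and (b) the calibrated active
  eviction rate (~0.02 s⁻¹) brings barrier-positioning patterns to steady
  state within tens of minutes.
* `k_slide = 0.1 s⁻¹` per nucleosome. Occupancy profiles are only weakly
  sensitive to this rate once density is fixed (we verified amplitude
  changes of <10% over `k_slide` 0.1–2 s⁻¹).
* `V_a` — not a free dial but *calibrated*: `calibrate_activity` bisects
  `V_a` until the steady-state mean coverage hits a target density
  (monotone decreasing in `V_a`). The default target is **0.85**, the
  approximate coverage of gene-rich regions; at `k = 147` this is also the
  density at which the equilibrium (Percus) response of coverage to a
  1 k_BT uniform shift is ≈2%, matching the regime the model is meant to
  describe. With sliding off, calibration uses the exact Percus coverage;
  with sliding on it uses short simulated ensembles (steady state measured
  over the last third of a ~20-eviction-time run). On homogeneous −7 k_BT
  DNA the default calibration gives `V_a ≈ 6.0–6.1`, i.e. an eviction
  rate `k_evict = k_on·e^{V̄+V_a} ≈ 0.02 s⁻¹`.

## Exact oracles

* `percus_occupancy` — the grand-canonical coverage of hard rods with
  activities `z_i = exp(−(V_i+V_a))`, via forward/backward partition-sum
  recursions `Z_f(m) = Z_f(m−1) + z_{m−k} Z_f(m−k)` evaluated entirely in
  log space (`logaddexp`), so `N = 10⁵` and deeply bound tracks are safe.
  Start probability `P(i) = z_i Z_f(i) Z_b(i+k)/Z`, coverage is the
  k-window sum. This is the discrete analog of the continuum hard-rod
  density-functional treatment; its correctness criterion is exact
  agreement (1e−10) with brute-force enumeration, which the suite checks on
  random instances.
* `enumerate_equilibrium` — sums Boltzmann weights over every
  configuration (guarded by a 10⁷ configuration-count limit).
* `master_equation_occupancy` — builds the full generator (including
  slide-to-contact moves) over all configurations of a small lattice and
  integrates `ṗ = pQ` by matrix exponentiation. Two facts the suite
  exploits: with `k_slide = 0` the chain is reversible and its stationary
  law is the hard-rod Gibbs measure at `V + V_a` (so Gillespie must match
  Percus at long times, for any `V_a`); with `k_slide > 0` slide-to-contact
  is irreversible and the stationary state measurably deviates from
  equilibrium.

## Derived statistics

* **Occupancy** `P_i(t)`: fraction of replicas in which bp `i` is covered
  at `t`; binomial standard errors. `oscillation_amplitude` is the SD of
  `P_j` over a TSS-relative window (default `[200, 1500]`).
* **Deviation curves**: `Δ(j) = |P_j^b − P_j^nb|` (barrier vs no barrier)
  and `D(t) = mean_i |P_i(t) − P_i^ss|`, both *means* over positions so
  values are lattice-length-free. Exponential fits are least squares on
  the log over the longest contiguous window where the signal exceeds 3×
  its noise floor (the floor is `sqrt(2/π)` times the combined binomial SE
  — the expected magnitude of `|noise|`); fits never extrapolate outside
  the window, and occupancy deviations are coarse-grained (50-bp bins) so
  oscillation zeros do not poison the log.
* **Relaxation protocol** (`barrier_insertion_relaxation`): 30 min
  barrier-free pre-run from naked DNA, hard-barrier insertion, then `D(t)`
  against the post-insertion steady profile (exact Percus when
  `k_slide = 0`, else a separately simulated long ensemble) over
  `j ∈ [−150, 600]`. The fitted `τ_relax` tracks `1/k_evict` with slope ≈1
  across a decade of eviction rates.
* **Exposure statistics**: non-overlapping 10-bp sites tiling downstream
  from `j = 0`; a site is exposed when all 10 bp are uncovered. Exposure
  intervals are computed exactly from the event log (per-site cover counts
  updated per event), clipped to the observation window; an exposure
  ongoing at the window start counts as an event starting there. `N_e` is
  the mean event count *per replica* (invariant to replica count); `t_e`
  the replica-pooled mean clipped duration, reported as 0 with a
  `never_exposed` flag for sites with no events. Bookkeeping is exact:
  exposed + covered time equals the window length for every site and
  replica.
* **Sensitivity scan**: paired ensembles at `V` and `V + dV` with shared
  replica seeds (common random numbers); reports `|Δρ|/ρ` and the median
  across sites of `|ΔN_e|/N_e` with paired-bootstrap CIs.

## What the synthetic tracks emulate

`synthetic_gene_potential` produces `V_i = V̄ + G_i + a·cos(2πi/10 + φ)`
with `G` a stationary Gaussian AR(1) field (marginal SD 1.5 k_BT,
autocovariance `sd²·e^{−d/20bp}`) and a random-phase 10-bp periodic
component (amplitude 0.3 k_BT). This reproduces the *statistical* character
of sequence-model-derived yeast gene tracks — bp-scale roughness, short
correlation length, weak helical-repeat periodicity, per-gene occupancy
structure that disappears under averaging over many genes. It does not
reproduce dinucleotide-level determinism, long-range composition trends,
promoter-specific poly(dA:dT) elements, or any particular gene; passing
tests demonstrate the machinery and the averaging logic, not agreement
with any specific genome.

## Numerical and design choices

* Coordinates 0-based, footprints half-open `[i, i+k)`; TSS at `j = 0`;
  files use bedGraph half-open convention with the TSS offset in a header
  comment; forbidden starts are serialized as a companion BED file.
* Forbidden starts are stored as `V = +inf` (activity exactly 0).
* Blocked slides consume an event; time still advances.
* Event-capacity overflow in the compiled kernel triggers a deterministic
  rerun with a doubled buffer (same seed), never a truncated log.
* Calibration bisects on a `V_a` bracket `[0, 14]` and refuses silently
  unreachable targets, reporting the achievable coverage.
* The lattice ends act as hard walls and generate their own statistical
  positioning; analyses that must be wall-free either exclude ~2 rod
  lengths at each end or compare against a homogeneous-DNA baseline with
  identical geometry.

## Known limitations

* Assembly/disassembly is single-step (whole octamer); H2A-H2B/H3-H4
  intermediates are out of scope.
* `V_a` is uniform along the DNA; no targeted or position-dependent
  remodeling.
* The kinetic steady state with sliding is genuinely non-equilibrium: its
  density response to a uniform 1 k_BT shift (~5%) is stronger than the
  equilibrium hard-rod response at the same coverage (~2%). Only the
  `k_slide = 0` chain admits the exact Percus reference.
* No upstream/downstream asymmetry mechanism; profiles are symmetric about
  the barrier on homogeneous DNA.
* Problem sizes in the shipped tests and the acceptance script (lattices of
  2.4–10 kb, 150–20,000 replicas, horizons up to one hour of simulated
  time) were chosen as the smallest ensembles at which each statistic's
  sampling noise is well below the effect it measures.
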