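# Model and methods

`canfat` simulates how brief bouts of mechanical loading are transduced,
through intercellular Ca²⁺ signaling and NFAT transcription-factor
dynamics, into periosteal bone formation in a 2-D cross-section of a
murine long-bone diaphysis — and calibrates the model's six free
parameters to observed relative bone formation rates by maximum
likelihood.

## Cell network

The cortex is an idealized elliptical annulus (periosteal semi-axes
600×450 µm, endocortical 450×320 µm by default, ≈0.4 mm² cortical area
and 130–150 µm thickness, typical of a mouse tibia mid-shaft).  It is
tiled into 384 sub-sectors (96 angular wedges × 4 radial bands; sub-sector
areas are derived exactly from the annulus geometry).  Osteocytes are
seeded by non-overlapping rejection sampling, uniform by area within each
sub-sector, with expected counts proportional to sub-sector area at a
configured lacunar density — 626/mm² for young-adult and 940/mm² for
senescent (aged) cross-sections — and a minimum lacunar separation of
15 µm.  A single layer of surface precursor cells (pre-osteoblasts) sits
at 96 equal-angle sectors on each of the two surfaces.

Functional coupling (the ability to pass Ca²⁺): any osteocyte–osteocyte
or osteocyte–precursor pair within a canalicular length of 50 µm, plus
ring edges between immediately adjacent same-surface precursors.
Precursor pairs are never distance-coupled, and precursors on opposite
surfaces never couple.  Emergent statistics of generated young networks
— mean connection length ≈34 µm and ≈4.5 connections per periosteal
precursor — sit inside the histology-derived values (34±12 µm, 4.0±1.6).
Generated osteocyte coordination (≈5 connections) is below the
histology-derived 7.9±2.3: a uniform-random lacunar field at 626/mm²
cannot reproduce the clustering of a real lacuno-canalicular network,
and no clustering mechanism is modeled.

## Mechanics

Loading is 1 Hz; the model's smallest time unit is 1 s, so each load
cycle occupies one full-magnitude 1-s step and rest-inserted protocols
interleave whole seconds of rest.  A bout of `c` cycles with rest `r`
lasts `c + (c−1)·r` seconds.  Tissue strain follows idealized beam
bending: strain magnitude grows linearly with distance from a neutral
axis through the centroid (default: perpendicular to the medio-lateral
load direction), normalized so the extreme periosteal fiber sees the
protocol's peak strain.  Strain magnitude is used as the Ca²⁺ drive;
tension and compression are not distinguished, and strain-rate or
frequency effects are outside the model's resolution.

## Ca²⁺ / ER / NFAT dynamics

Per-cell state: instantaneous Ca²⁺ (0–100 %), ER store filling (0–ER⁰),
and, for precursors, dephosphorylated cytoplasmic NFAT (NFATd) and
accumulated nuclear NFAT (NFATn).  Synchronous 1-s updates:

* **Strain drive** (osteocytes only): smoothstep sigmoid
  `100·(3u²−2u³)`, `u = clamp(ε/T^ε_x, 0, 1)` — 0 at zero strain,
  exactly 100 % at or above the threshold strain `T^ε_x`.  A zero
  threshold is the knock-out limit (any strain saturates).
* **Gap-junction drive**: the mean of coupled neighbors' previous-step
  Ca²⁺, gated below an initiation threshold of 2.5 %.
* **Release**: total drive `D` (clamped to 100) releases
  `Ca = D·(ER/ER⁰)`; the store loses what is released.  With `D = 0`
  the cell is quiescent and the store refills SERCA-like at
  `R⁰·(1−ER/ER⁰)` per second.
* **NFAT**: `NFATd ← min(100, α·NFATd + k_t·Ca)` with memory parameter
  `α ∈ [0,1]` and translocation gain `k_t = 0.05 s⁻¹` (a structural
  constant; the response scale is absorbed by the downstream capacity
  parameter, so its exact value is not critical).  `NFATn` accumulates
  `NFATd` every second and resets at each bout.

Ca²⁺ is simulated for 200 s past the end of each bout (cell-cell
cross-talk unfolds), NFAT dephosphorylation for a further 100 s.  The
bout output maps accumulated nuclear NFAT to a relative mineral
apposition rate, `r.MAR = r.MAR_x·min(1, NFATn/NFAT^n_x)` (binary on/off
in the `NFAT^n_x = 0` knock-out limit; an optional sigmoidal variant is
available behind a switch).

The six free parameters and their admissible ranges used in estimation:
`T^ε_x` 0–5500 µε, `ER⁰` 0–50000 %, `R⁰` 0–200 %/s, `α` 0–1,
`NFAT^n_x` 0–10⁷ %·s, `r.MAR_x` 0–50 µm/d.  Fitted young and aged optima
ship as the `young_mle` / `aged_mle` fixtures.

An engine note: once every cell's Ca²⁺ is zero past the end of loading it
stays zero, so the remaining simulation reduces to geometric NFAT decay;
the kernel applies that closed continuation with arithmetic identical to
the stepped path (results are bit-equal, verified against a naive
reference implementation).

Rest-inserted loading is where store recovery matters: after stores
deplete, quiescent rest seconds refill them and post-rest Ca²⁺ amplitudes
exceed pre-rest amplitudes (secondary transients).  On synthetic networks
the gap-junction ring-down consumes more store per cycle than ~10 s of
rest can refill, so the rebound is demonstrated with extended rest
intervals (tens of seconds); with `R⁰ = 0` amplitudes are non-increasing
after the initial network-propagation transient regardless of protocol.

## Histomorphometry

Per protocol, per-bout r.MAR is averaged over bouts (repeated loading is
assumed not to recondition cells, so identical bouts make this the
single-bout value).  Per surface: r.MS/BS is the fraction of precursors
with non-zero (>10⁻¹²) r.MAR; tissue r.MAR is the mean over that subset;
r.BFR/BS = r.MS/BS × r.MAR.  Only periosteal outcomes are validated;
endocortical outcomes are computed but the model is not expected to
predict endocortical adaptation.

## Likelihood and calibration

Observed per-animal relative formation rates `y_ij` are normal around
per-protocol simulated means `μ_i(θ)` with per-protocol variances.  The
variances profile out analytically (`σ̂_i² = mean squared residual`,
floored at 10⁻⁸ to avoid degeneracy at perfect fits; a pooled-variance
option covers single-animal protocols).  `μ_i` is simulated at the
protocol's mean animal-specific peak strain by default (a per-animal
mode exists but multiplies simulation cost).

The MLE is found by simulated annealing with random restarts inside the
admissible box: Gaussian proposals reflected at the bounds, geometric
cooling, restart-best solutions refined by a deterministic Powell pass.
Parameters whose range spans more than ~1.5 decades are searched in
log coordinates — scale-like parameters (store capacity, DNA-binding
capacity) trade off along ridges spanning decades, and multiplicative
moves are essential there.  Everything is deterministic given the seed.

* **Knock-outs** constrain one parameter to zero and re-optimize the
  rest.  `ER⁰ = 0` or `r.MAR_x = 0` are lethal (all means exactly zero);
  the others are non-lethal but reshape the response.
* **Likelihood-ratio tests** compare nested fits against χ² with df =
  number of constrained parameters.  Age comparisons fit young and aged
  tables jointly with a shared-parameter mask; the constrained fit
  warm-starts the full fit (and is itself re-polished from the projected
  full solution), so the statistic is non-negative by construction and
  not inflated by one-sided optimizer noise.
* **Profile-likelihood intervals**: walk a grid from the MLE toward each
  bound (geometric spacing in the log-searched coordinates, never more
  than ~4× per step), re-optimizing the remaining parameters at a reduced
  budget warm-started from the MLE, the previous grid point, and a pool
  of elite solutions (restart optima, a coarse space-filling scan, and
  every profile optimum found so far).  The interval is the hull of grid
  values whose profile stays within χ²₁(level)/2 of the fitted maximum,
  with endpoints localized by bisection.  Reduced-budget profile values
  are lower bounds on the true profile, so points within a noise margin
  (default 3 log-likelihood units, the typical spread between repeated
  reduced-budget optimizations of the same objective) of the threshold
  still qualify: ambiguity is resolved toward the wider interval.
* **Restoration experiments** override chosen aged parameters with young
  optima and report the per-protocol percent change in simulated
  rp.BFR (undefined where the aged baseline is zero).

## Synthetic studies

`synthetic` generates protocol suites (evenly spaced peak strains,
cycling through configured cycle counts and rest intervals) and
observation tables with the structure the likelihood assumes: animal
peak strains jittered 5 % around the protocol nominal, responses normal
around the simulated mean with SD = 25 % of the mean by default (an
absolute floor, default 10⁻³ µm/d, keeps the SD positive when a mean is
zero).  Observations are centered at the mean simulated at the realized
mean animal strain — the same convention the calibration uses — so
generation and fitting are coherent.

The parameter-recovery harness runs simulate → fit → profile-CI per
replicate and reports bias, RMSE and CI coverage.  Its study runs at
desk scale: a compact cross-section (130×100 / 75×50 µm semi-axes,
20 surface sectors per surface, ≈58 cells), ten protocols spanning
1000–3000 µε with short (15, 30) and long (120) cycle counts and 0/5-s
rests, seven animals per protocol at 25 % relative noise.  The ground
truth is chosen mid-regime (`T^ε_x` 2500 µε, `ER⁰` 1500 %, `R⁰` 10 %/s,
`α` 0.7, `NFAT^n_x` 120 %·s, `r.MAR_x` 2.5 µm/d) so that every mechanism
is active at this scale: stores deplete within the long bouts and refill
during rests, and nuclear NFAT sits in the partially saturating range of
its capacity.  At the published young optima on a ~60-cell network the
capacity sits orders of magnitude above any attainable nuclear NFAT and
the store barely depletes, leaving exact scale ridges that no finite
data can resolve — informative about the full-scale model, not about
desk-scale recovery.

What passing recovery shows — and does not: the calibration pipeline is
self-consistent on data generated by its own forward model with the
assumed noise structure.  It does not show that real histomorphometry
data identify the parameters this well (real residuals need not be
normal, real networks are not elliptical idealizations, and the
published estimates required orders of magnitude more simulator
evaluations on a histology-derived network).

## Numerical choices and limitations

* Time step fixed at 1 s; no sub-second dynamics, strain-rate or
  frequency effects.
* Non-zero apposition test uses an absolute 10⁻¹² tolerance.
* Synchronous updates: results are independent of cell ordering (up to
  float summation order in the neighbor mean).
* The annealer's schedule at desk scale (defaults: 5 restarts, 50
  steps/temperature, cooling 0.95, eval caps) is far below the effort
  behind the published estimates; full-scale budgets are configurable.
* Endocortical prediction, 3-D topology, osteocyte viability, and
  additional messengers/pathways are out of scope.
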