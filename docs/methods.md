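# Methods

## The model

`flexibcd` simulates a binary (A–B) colloidal mixture of `N_tot` hard
spheres of unit diameter σ (the length unit) in a cubic, fully periodic
box of edge `L`, at total volume fraction

    φ_tot = π N_tot σ³ / (6 L³).

The composition is `c_A = N_A / N_tot`.  Particles of the *same* species
attract through a short-range square well of width ε·σ (default
ε = 0.1): when two like particles come within (1+ε)σ they form an
**irreversible bond** (infinite well depth — the athermal, diffusion-
limited aggregation limit).  Unlike pairs interact through hard-core
repulsion only.  Clusters are the connected components of the bond
graph, and are single-species by construction.

The one new control parameter is the **bond flexibility** `p_flex`,
applied per species (only species A is varied here; B is always fully
flexible).  A *bonded* monomer of species X is granted a trial move with
probability `p_flex_X` per attempt: `p_flex = 1` lets monomers rattle
freely within the bond range, `p_flex = 0` freezes every cluster into a
rigid body, and e.g. `p_flex = 0.1` grants on average one move in ten.
Unbonded monomers always move.

## The propagator (Brownian cluster dynamics)

One sweep consists of:

1. **Monomer moves** — `N_tot` trial moves on uniformly random particles
   (with replacement).  A granted move displaces the particle by a fixed
   step `s` (default 0.05 σ = ε/2, so a step cannot jump across the well
   shell) in a random direction, and is rejected if it would overlap any
   particle or stretch any existing bond beyond (1+ε)σ.  Accepted moves
   accumulate into the cluster's net "Rouse" displacement for the sweep.
2. **Bond formation** — every unbonded like pair within (1+ε)σ bonds.
   Internally only particles that moved since the previous pass are
   scanned (a pair can newly enter the well only if one member moved);
   this is exactly equivalent to a full pass from a scanned baseline.
3. **Cluster (Zimm) moves** — every non-spanning cluster of two or more
   particles attempts one rigid translation along its net Rouse
   direction (random for internally frozen clusters).  The magnitude is
   set so that the cluster's total per-sweep centre-of-mass MSD equals
   the Rouse + Zimm target `s²/m + s²·σ/d_c`, with cluster diameter
   `d_c = 2 R_g + σ`.  The translation is rejected wholesale if any
   member would overlap a non-member.

Reduced time advances by `s²/σ²` per sweep, which makes `t₀` the time a
free monomer needs to diffuse its own diameter (monomer MSD = σ² per
unit t/t₀, i.e. D₀ = σ²/6t₀).  The measured free-monomer diffusion and
the isolated-dimer COM diffusion (D₀/2 Rouse + D₀/2 Zimm at d_c = 2)
calibrate this convention in the test suite.

Design choices worth flagging:

* **Zimm magnitude.**  The kick is aligned with the same sweep's Rouse
  displacement, so its MSD contribution includes a cross term; the
  magnitude solves `(R_com + s_c)² = s²/m + s²σ/d_c` exactly.  This also
  restores the ideal Rouse COM diffusion D₀/m: rejections of *internal*
  monomer moves (bond-range constraints) must not slow a cluster's
  centre of mass — in Rouse dynamics of a connected object the COM
  feels no internal forces — while crowding by *other* clusters still
  acts through wholesale rejection of the translation.  Without this
  correction the isolated-dimer COM diffusion measures 0.86·D₀ (naive
  additive accounting) or 1.58·D₀ (ignoring the cross term), both
  inconsistent with the Rouse-plus-Zimm target.
* **Rigid clusters still diffuse.**  At `p_flex = 0` a cluster has no
  internal motion (its Rouse displacement is zero) but receives the full
  rigid-body translation along a random direction; a frozen aggregate is
  still a Brownian particle.
* **Spanning clusters do not translate** (their diameter is the box;
  D → 0) and their Rg is reported as not applicable.
* **Flexibility gate** is a Bernoulli draw per attempt by default; a
  deterministic one-move-in-every-1/p_flex cycle is available behind
  `EngineParams(deterministic_gate=True)` and gives the same mean
  mobility.
* **Bond formation once per sweep** is sufficient because `s < ε`: a
  pair cannot cross the well shell undetected between passes.
* Move order is uniform random with replacement; numerical overlap and
  bond-range tests compare squared distances with a 1e-12 σ² tolerance.

Percolation is tracked online: every particle carries an integer
periodic-image vector kept consistent across its cluster; a bond that
closes a cycle with a nonzero net image shift along axis k marks the
cluster as spanning axis k (it connects to its own periodic image).  The
first reduced time a species owns a spanning cluster is its gel time
t_g.  An independent breadth-first detector in `flexibcd.topology`
cross-checks the online flags in the tests, against a replica-tiling
oracle on hand-built fixtures.

## Initial configurations

Random sequential insertion up to φ_tot = 0.35; above that (up to 0.45)
a simple cubic lattice at the target density with randomized species is
melted for 50 sweeps of hard-sphere-only moves before t = 0.  Species
labels are assigned uniformly at random with exactly round(c_A·N_tot)
A particles.

## Cluster analysis

* `m_w = Σ m²N(m) / Σ m N(m)` — the mass-average aggregation number.
* Rg is computed after unwrapping each cluster across the periodic
  boundaries along a spanning tree of its bonds; wrap-inconsistent
  (percolating) clusters are flagged and excluded from structure fits.
* `Z_c` — mean bond-graph degree over *all* particles of a species
  (unbonded particles count with degree 0, so early-time curves start
  near 0).
* **Fractal dimension d_f** (`m ∝ Rg^d_f`): clusters are log-binned by
  mass (4 bins/decade, default window m ∈ [10, m_max/3]) and d_f is the
  OLS slope of median log m on median log Rg.  Mass-binning is used
  because the mass axis spans ~d_f times more decades than the Rg axis;
  binning by Rg left too few populated bins to fit reliably at desk
  scale.
* **Size-distribution exponent τ** (`N(m) ∝ m^-τ e^{-m/m_c}`):
  estimated by discrete maximum likelihood of the truncated
  power-law-with-cutoff on the raw pooled masses with m ≥ 5.  Binned
  log-log slopes carry a +0.1…0.3 cutoff bias somewhere in τ ∈ [1, 3]
  (measured on inverse-CDF ground-truth samples); the two-parameter MLE
  recovers the whole range within ±0.05 at m_c ≥ 300.  The populated
  log-bin count and mass window are still recorded on the fit object
  for audit, and a ``method="binned"`` option provides the plain
  histogram-slope estimator (the guide-line statistic of a log-log
  plot) for cases where that is the quantity of interest.  The
  flocculation-stage τ of the minority species is the protocol's most
  scale-fragile number: with ~10³ particles of that species there is no
  clean decade between the smallest fitted mass and the exponential
  cutoff, and pooling the flocculation window mixes growing cutoffs, so
  measured values land ~0.2–0.4 above the production-scale 1.5
  whichever estimator is used.
* **Chemical distance l**: the bond count of a shortest path between a
  pseudo-diameter pair of the cluster (double BFS sweep; deterministic
  low-id tie-breaks); everything off the path is a dangling end.  This
  graph formulation replaces iterative dangling-end pruning, which is
  ambiguous on cyclic clusters; on trees the two coincide, and
  flocculation-regime clusters are tree-dominated.  The backbone
  exponent d_f/d_b is the log-binned slope of m vs l over clusters with
  l ≥ 5: below ~5 bonds clusters are trivially chain-like (m ≈ l+1,
  slope → 1) and mask the branched-regime scaling.  Lattice-animal
  statistics give ≈ 2.0/1.36 ≈ 1.47, against ≈ 2 for reaction-limited
  clusters.
* **Near-threshold ensembles.**  The percolation-regime analysis of the
  majority species works on configurations driven to *just below* its
  percolation threshold at single-bond resolution: a sweep-resolution
  replay finds the last pre-spanning state, then the gelling sweep's
  candidate bonds are added one at a time (seeded random order) up to,
  but not including, the first bond that would close a wrap-around
  cycle (`topology.fill_to_percolation`).  Because gelation of the
  majority species takes only a few sweeps at φ_tot = 0.3, such
  configurations are cheap, and the study protocol pools ten replicates
  — the seed-level scatter of the fitted d_f with fewer configurations
  (~±0.25) otherwise swamps the estimate.

## State classification

A phase point (φ_tot, c_A, p_flex) is classified from n independent
replicates (default 10): **bigel** if at least half percolate in both
species (checked first, so it wins exact ties), **one-component gel** if
at least half percolate in B but not A, otherwise **fluid/flocs**.
Spanning along any axis counts.  Degenerate compositions: an absent A
species cannot supply the second network (flag false); an absent B
species makes the majority-gel requirement vacuous (flag true), so a
pure-A gel classifies as bigel and a pure-B gel as one-component.
Critical values (c_A)_c and p_flex^c are grid estimates — the smallest
grid value whose verdict is bigel, ±1 grid step — with replicate seeds
derived deterministically from (base seed, grid indices, replicate).

## Scales, defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| σ | 1 | particle diameter, length unit |
| ε | 0.1 σ | square-well width; bonding range (1+ε)σ |
| s | 0.05 σ | monomer step; must satisfy 0 < s < ε |
| t/t₀ | s²/σ² per sweep | free monomer diffuses σ² per unit |
| L | 20 σ (studies) | ≈ 4.6·10³ particles at φ_tot = 0.3 |
| replicates | 10 | state-diagram half-rule |

The headline analyses in `flexibcd.protocols` run at L = 20
(φ_tot = 0.3): one run per flexibility value (0.1, 0.5, 1.0) to reduced
time 60 plus ten near-threshold majority-species configurations for the
exponent fits, and single runs to reduced time 250 for the Z_c
plateaus — the package's desk-scale study conditions, roughly 2 orders
of magnitude fewer particle-sweeps than a production box of L = 50 run
to t/t₀ ≈ 1.5·10³.  Consequences of the reduced scale, stated as scope
rather than caveat-mining:

* the largest non-spanning clusters reach only m ~ 10²–10³, so exponent
  fits span ~1.5–2 decades instead of 3+; in particular the
  near-threshold d_f of the majority species measures ≈ 2.2–2.4 rather
  than the asymptotic 2.5, because the small-m end of the fit window
  still carries lattice-animal (d_f ≈ 2) structure — the
  2.0 → 2.5 crossover needs cluster masses beyond this box;
* finite-cluster growth at c_A below critical keeps creeping on the
  largest boxes' timescale, so "plateau" quantities are measured over
  the trailing decade of a capped run with a 1%-per-decade stationarity
  check;
* critical-parameter estimates carry a finite-size shift and are always
  reported together with their L;
* full critical scans (e.g. resolving (c_A)_c to ±0.03 at L = 20, which
  needs ten replicates per grid point run to late times near the
  transition) are exposed through `flexibcd.phase` but are not part of
  the default test run; the packaged phase checks instead bracket the
  transition at L = 12 (one-component gel at c_A = 0.15, bigel by 0.35
  at p_flex = 1), verify that fully rigid A bonds suppress the bigel at
  c_A = 0.5, and verify the flexibility-driven verdict flip at
  φ_tot = 0.40, c_A = 0.19 (no A percolation at p_flex = 0, bigel at
  p_flex = 1).

## What the synthetic fixtures emulate

The `fixtures` module builds bonded objects with closed-form or
construction-oracle ground truth (chains, rings, stars, box-wrapping
chains, carved compact blobs, random lattice trees, power-law mass
samples with exponential cutoff, hard-sphere gases).  They exercise
every analysis operation — Rg, Z_c, chemical distance, percolation
flags, exponent fits — without running the simulator, and round-trip
bit-exactly through the snapshot format.  They do not emulate kinetic
trajectories: agreement on fixtures validates the measurement chain,
not the dynamics; the dynamics are validated by the diffusion
calibrations, the invariant checks, and the scaled-down reproduction of
the aggregation observables.

## Known limitations

* No hydrodynamic interactions; no bond breaking (athermal limit); equal
  particle sizes; two species; cubic boxes only.
* The adjacency table caps the bond degree at 32 (kissing-number bound
  is 12 for equal spheres; the cap is never reached in practice, and
  overflow raises rather than corrupts).
* Gel times are resolved to one sweep (s²/σ² in reduced time).
* The Bernoulli gate and the deterministic cycle agree in the mean but
  not in higher moments of the waiting-time distribution.
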