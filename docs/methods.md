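# Methods

This note documents the model, the numerical choices, and what the test
suite does and does not demonstrate.

## The self-avoiding rod-like chain

Circular DNA is discretized at 30 bp resolution into rigid hard-core
cylinders of length l = 10.2 nm and radius r_e = 2 nm (the effective
electrostatic diameter of B-DNA at physiological salt).  Conformations are
closed equilateral polygons; two non-adjacent cylinders may not approach
closer than 2·r_e = 4 nm (center-line distance, exact segment–segment
minimum-distance test).

**Bending.**  Each joint contributes κ(1 − cos θ).  κ is obtained from the
exact discrete worm-like-chain mapping ⟨cos θ⟩ = coth κ − 1/κ = exp(−l/l_p),
giving κ = 5.418 k_BT for l_p = 50 nm at this discretization (the naive
ratio κ = l_p/l = 4.902 is available as `bending_mapping="ratio"`; it
underestimates the persistence length by a few percent at 30 bp resolution,
which the test suite demonstrates).

**Torsion and topology.**  The linking number Lk is a bookkeeping variable:
closure plus non-crossing moves conserve it.  Writhe is computed with the
exact closed form for the Gauss-integral contribution of straight segment
pairs (the method-1a quadrilateral formula); coplanar and adjacent pairs
contribute zero.  The twist deficit ΔTw = (Lk − Lk0) − Wr carries a
uniform-twist energy E_tw = (2π²C/L)·ΔTw² with C = 86 nm and L = N·l.  A
homogeneous twist is the energy minimum of any quadratic per-joint twist
energy at fixed writhe on a chain without intrinsic curvature, so this is
equivalent at equilibrium to per-joint Euler-frame bookkeeping while being
much cheaper.  Whether twist inhomogeneity could matter for observables is
an open modelling question; none of the quantities computed here (R_g,
P_s(r), local writhe) couple to it.

**Relaxed linking number.**  Lk0 = round(n_bp/h) with the helical repeat
h = 30000/2850 bp/turn by default, so a 30 kb circle has Lk0 = 2850; h is
configurable.

## Monte-Carlo sampling

Crankshaft moves: a pivot vertex i is uniform over the chain, the span
uniform over 1..M (default M = 100, and one sweep is N/M moves), and the
vertices strictly between i and j = i + span rotate rigidly about the i–j
chord by an angle uniform in ±π/4.  The proposal is symmetric, so the
Metropolis rule min(1, e^(−ΔE)) needs no Hastings correction.  The fixed
π/4 amplitude keeps acceptance high at these stiffnesses while making
strand passage (which would change Lk) geometrically unlikely; there is no
on-the-fly amplitude adaptation, preserving detailed balance.

Per move, only the two hinge joints change bending energy, and only
moved-vs-static segment pairs change the writhe, so ΔWr costs
O(span·(N − span)) pair evaluations.  Three guards keep the topology exact:

* overlap rejection (checked before energies; adjacent cylinders exempt);
* rejection of any move with |ΔWr| > 1 turn (a strand-passage signature
  that overlap rejection alone could miss for fast-sweeping rotations);
* a full O(N²) writhe recomputation every 1000 accepted moves; drift
  beyond 1e-6 turns is corrected and warned about (in practice the
  incremental updates track the exact writhe to ~1e-12).

**Annealing protocol.**  From a relaxed planar circle (σ = 0, Wr = 0), each
level runs `sweeps_per_level` sweeps at constant σ, stores frames evenly
spaced over the second half of the level (the first half acts as
re-equilibration), then removes helices (Lk ← Lk − k).  For the 30 kb
reference chain k = 14 (Δσ ≈ −0.0049); for scaled-down chains
`AnnealingSchedule.for_chain` keeps the σ grid by allowing fractional k
(Lk is bookkeeping, not a count of physical molecules removed).  Runs use
independent child streams spawned from one master seed and are reproducible
bit-for-bit.

**Equilibrium caveat.**  The marginal distribution of a single joint angle
on a *closed* ring is not the single-joint Boltzmann law sinθ·e^(−κ(1−cosθ));
ring closure biases it (for N = 12 at κ = 5.418, ⟨cos θ⟩ drops from 0.816
to ≈ 0.73, a value reproduced independently by rejection sampling of free
chains conditioned on closure).  Engine correctness is therefore asserted
through exact invariants (topology bookkeeping, hard core, determinism,
writhe oracle) and through the open-chain persistence-length calibration,
where the iid Boltzmann prediction is exact.

## Observables

* **R_g(σ)**: root-mean-square vertex distance from the centroid; per-σ
  mean with the standard error computed across run means
  (√(var(run means)/(n_runs − 1))).
* **P_s(r)**: the chain is sequence-homogeneous, so distances are pooled
  over all reference vertices and both genomic directions — identical
  expectation to a fixed *parS* vertex, much lower variance.  Offsets
  beyond half the circle fold back.
* **Local writhe**: wr(i) = (2π)⁻¹ Σ_{j∈window} Ω_ij with window m = 10
  cylinders (≈ two persistence lengths, sensitive to the smallest curls).
  Summing the full window reproduces 2·Wr exactly.
* **Plectoneme branches**: strict periodic local minima of wr(i) (plateaus
  collapse to their center), thresholded at wr*.  wr* is placed per σ at
  the antimode of the pooled minima distribution: peaks of the log KDE
  density (factor-2 prominence), background mode = the rightmost peak,
  plectonemic candidates must lie below min(background − bandwidth, 0),
  wr* = deepest valley in between, and is rejected unless it is negative
  with at least 1% of minima below it (guards against stray outliers).
  Log-density peaks are used because the plectonemic mode can carry a few
  percent of the mass next to a background peak two orders of magnitude
  higher.  Silverman's bandwidth by default; both bandwidth and wr* can be
  overridden per σ.  This rule recovers planted counts on labelled
  synthetic mixtures with ≥ 95% accuracy.

## The stochastic binding model

C⁰(r) kinds (all with C⁰(0) = 1 and C⁰(ω/2) = 1/2 exactly): quenched
Θ(ω/2 − r) (value ½ at the jump by convention), gaussian
exp(−4 ln2·r²/ω²), exponential exp(−2 ln2·r/ω) — the unique forms meeting
the FWHM constraint — and leaky: saturated core of radius ρ = ω/4 plus a
(ω/4)/r halo.  The halo is the ξ → ∞ limit of the Yukawa solution
A e^(−r/ξ)/r of the stationary source–diffusion–dilution equation; with
D ≥ 1 μm²/s and a per-protein dilution rate ~1e-3 s⁻¹ (one cell cycle),
ξ ≳ 1000 nm, justifying the pure 1/r form inside a cell.  The
exp(−r/ξ)/r variant is available via `screening_length=` on the model.

The cluster center wanders in a ball of radius ρ around *parS*; the
parS-anchored profile is C(r) = ∫ Π_r(x) C⁰(x) dx with the geometric
kernel Π_r(x) (full-sphere regime 3x²/ρ³ for x ≤ ρ − r, partial-overlap
regime 3x(ρ² − (r−x)²)/(4rρ³), zero outside).  Quadrature is adaptive
(absolute tolerance 1e-10) split at the regime boundary and at profile
kinks.  The sharp-core kinds (quenched, leaky) convolve by default; the
smooth kinds use C⁰ directly (the two differ only at small binding
probabilities), with ρ = ω/2 if convolution is requested.

**B(s)** is estimated as the sample mean of C(r) over the distance samples
at offset s — the direct Monte-Carlo estimator of ∫4πr²P_s(r)C(r)dr, with
the finite sampled volume regularizing the large-r tail.  C is tabulated
on a 2048-point radial grid and linearly interpolated; the binned-integral
estimator agrees within 1% (tested).

**Protein count** (leaky only): N_P = (ω/4a)³[1 + (3/2)((4R/ω)² − 1)],
the closed-form radial integral of C⁰ over a sphere of radius R divided by
the effective protein volume 4πa³/3.  With R = 400 nm, the series
(a = 5, 10, 15, 20 nm) → (17277, 2160, 640, 270) is reproduced by ω = 36 nm;
this ω is a reconstruction consistent with that printed series, not an
independently measured cluster width (the best-fit cluster width from
profile fitting is ~44 nm).

## Profile fitting

Coverage input: two-column TSV (point positions) or 4-column bedGraph
(0-based half-open intervals assigned to their centers); duplicates merge
by summing; overlapping bedGraph intervals are an error.
Normalization: subtract a background (explicit value or the mean over a
distal window), clip at zero, divide by the maximum.  Fragment-center
counting shifts + / − strand reads by ±fragment_size/2.  RMSD compares the
model (computed at 30 bp resolution, linearly interpolated onto data
positions) with the data inside the window, by default 1.5–9 kb — below
1.5 kb reproducible promoter/roadblock distortions contaminate the signal,
and only one flank of the profile is fitted.  `grid_fit` scans (σ, ω);
ties break toward smaller ω, then larger |σ|, and the tie count is
reported.

## Synthetic data

The stand-in ensemble draws P_s(r) from a Gaussian chain: 3-D normal
displacements with per-axis scale b·s^ν, defaults ν = 0.5 and b = 3.33
nm/bp^0.5 (an ideal chain with a 100 nm Kuhn segment).  It exists to test
the binding/fitting layers independently of the polymer simulation and is
labelled synthetic in all outputs; it has none of the supercoiling-induced
features (short-range drop, plectonemic compaction) of the real ensemble,
so passing recovery tests demonstrate the *fitting machinery*, not the
polymer physics.

The coverage generator emits λ(s) = depth × B_true(s) × distortions,
prepends a saturated 430 bp centromeric plateau at negative s (ten
specific sites spaced 43 bp; without it the synthetic maximum is a
one-bin spike and fragment smoothing followed by max-normalization
systematically inflates the fit window), applies a fragment-sized boxcar
(the coverage-level analogue of fragment-center counting), and draws
Poisson counts.  Promoter-like distortions are multiplicative Gaussian
dips.  Recovery experiments share the distance ensemble between truth and
fit so that read noise and normalization are the only error sources.

## Problem sizes and defaults used by the tests

The full-scale protocol (30 kb, 17 levels × 1.6e7 sweeps, 20 runs) is
supported but the test suite runs a scaled-down analogue chosen as a
desk-scale experiment: a 6 kb chain (N = 200, M = 20, preserving the
paper-style N/M = 10 sweep ratio), 17 σ levels with 1200 sweeps per level,
5 independent runs, 40 frames per run per level.  At this scale the
compaction of R_g with |σ| is robust, while plectoneme-branch statistics
are at the edge of what the annealing budget resolves: branch-number
distributions are much shallower than for 30 kb chains, and the
non-monotonicity of the branch count in |σ| may not survive the reduced
equilibration.  Parameter-recovery tests use the analytic stand-in with
depth 3000 reads at maximum, a 4 nm ω grid, and 20 replicates.

## Known limitations

* No sequence-dependent elasticity, intrinsic curvature, stretching, or
  explicit electrostatics beyond the hard core; no knotted topologies.
* Uniform-twist representation (see above) — per-joint twist dynamics are
  not modelled.
* DNA–cluster interactions are neglected when computing P_s(r); the
  approximation degrades within ~1 kb of the centromere.
* The branch-count threshold is a heuristic on a density estimate; for
  weakly supercoiled or under-equilibrated ensembles it deliberately
  returns "no plectonemes" rather than guessing.
* Monte-Carlo time has no physical time mapping; only equilibrium
  quantities are meaningful.
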