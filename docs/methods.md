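# Methods

This note documents the models implemented in `etkit`, the defaults and
conventions chosen where the underlying methodology leaves them open, what
the synthetic-data generators do and do not emulate, and the package's known
limitations.  All energies are kcal/mol, distances Å, angles degrees,
temperatures K; k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹ and the Coulomb constant
is 332.0636 kcal·Å·mol⁻¹·e⁻² throughout.

## Structures and connectivity

PDB input follows the fixed-column v3.3 dialect.  MODEL/ENDMDL delimits
trajectory frames; altloc characters other than `' '`/`'A'` are skipped;
insertion codes are rejected loudly (no renumbering heuristics).  HETATM
residues named HEM/HEC, FMN, and FES/SF4 are auto-registered as the cofactor
groups HEME, FMN, and FES.  Atom indexing is 0-based internally; residue
identifiers stay as authored in the file, because published mutation sites
(e.g. F346K, R354M, T681) use author numbering.

Covalent bonds are inferred from consensus single-bond covalent radii
(H 0.31, C 0.76, N 0.71, O 0.66, S 1.05, Fe 1.32 Å, …) with a 0.4 Å
tolerance: pair (i, j) is bonded iff |r_i − r_j| ≤ R_i + R_j + 0.4.
Hydrogens bond to at most one heavy atom (nearest wins) and never to each
other.  This distance criterion is deliberately simple; structures with
severely distorted geometry should supply explicit bonds.

Interatomic distances between selections support three conventions: minimum
pairwise, center of geometry, and the iron-pair mode used for d[FeS–Heme]
(each set restricted to Fe atoms, minimizing pair taken — "one of the iron
atoms of the cluster to the heme iron").  The FMN–FeS distance is reported
under whichever convention the caller picks; no claim is made that any
particular convention reproduces published numbers, since those derive from
structures and snapshots not shipped here.

## Tunneling pathways and the ET rate

The route model is the classic empirical pathways picture: per-step coupling
decays ε_covalent = 0.6, ε_space(d) = 0.6·e^(−1.7(d−1.4)),
ε_hbond(d) = 0.36·e^(−1.7(d−2.8)), every decay clamped to ≤ ε_covalent, all
parameters user-overridable.  The graph is atom-level over heavy atoms;
edges take precedence covalent > hydrogen-bond > space, and through-space
edges are only generated within 6.0 Å — beyond that a space step is worth
under 2.4×10⁻⁴ of a covalent step and never competitive, so the cutoff only
prunes the graph.

The best route maximizes the product of decays, found by Dijkstra search on
additive weights −ln ε (all positive, so the optimum is automatically a
simple path).  Ties are broken by smaller total length R, then
lexicographically on the node sequence, making repeated runs bit-identical.
A disconnected donor/acceptor pair yields an explicit no-pathway result
(`None`), not an exception.  Donors and acceptors default to the metal
atoms (FES irons, heme iron).  The residue-level narrative trace collapses
consecutive same-residue atoms; `path_length` also accepts per-residue step
distances for the convention that sums shortest distances between
neighbouring residues on the route.

The ET rate is the distance-decay law k_ET = A₀·e^(−βR) with defaults
A₀ = 2×10¹² s⁻¹ and β = 1.06 Å⁻¹.  Note the internal-consistency quirk of
those constants: a 4.05 Å shortening corresponds to e^(1.06·4.05) ≈ 73.2-fold
acceleration (sometimes quoted rounded down to ~72-fold).  The package
always computes; it never hard-codes ratios.

## MBAR free energies and PMF projection

Given K umbrella windows with N_k retained samples each, the reduced window
free energies f̂_k satisfy the self-consistent MBAR identities

    e^(−f̂_k) = Σ_n e^(−û_k(x_n)) / D_n,
    D_n = Σ_j N_j e^(f̂_j − û_j(x_n)),   f̂_1 ≡ 0,

with û the reduced (β-scaled) bias energies.  The solver iterates this
update with log-sum-exp stabilization, accelerated by damped Newton steps on
the convex MBAR objective (gradient Σ_n p_kn − N_k and Hessian
diag(Σ_n p_kn) − P Pᵀ over the mixture responsibilities
p_kn = N_k e^(f̂_k − û_kn)/D_n).  Convergence is declared when the
self-consistent residual max_k |Δf_k| drops below 10⁻⁸ kcal/mol (default);
non-convergence is flagged, never silently accepted, and projection refuses
unconverged inputs.  The asymptotic covariance of the free energies is
estimated from the thin SVD of the normalized weight matrix
(Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ) and exposed as `free_energy_se`; the test
suite uses it as the statistical-error scale when comparing against
quadrature oracles.

Conventions and defaults:

- **Bias convention**: `k_full`, U = k(ξ−ξ₀)² with no ½ factor (switchable
  to `k_half`).  A stated force constant such as 100 kcal·mol⁻¹·Å⁻² is only
  meaningful under a declared convention; the two are interconvertible by
  doubling k, and the solver is verified to give identical results under
  that substitution.
- **Temperature**: 300 K default.
- **Burn-in**: the first ⌈fraction·n⌉ samples of each window are discarded
  (default fraction 0.15, i.e. keeping the last 85 % mirrors retaining the
  last 85 ns of 100 ns windows).  Decorrelation subsampling is *not*
  applied by default — only burn-in removal — and can be layered on by the
  caller.
- **Unbiased weights**: ω_n ∝ 1/D_n (U₀ ≡ 0), normalized to Σω = 1 within
  10⁻¹⁰.
- **Projection binning**: 50 equal-width bins over the weighted 0.5–99.5
  percentile range of the collective variable, unless explicit edges are
  given.  Empty bins are masked (NaN), the minimum over non-empty bins is
  shifted to zero, and an all-in-one-bin projection is returned with a
  width-warning flag rather than an error.
- **Dihedral PCA**: each dihedral φ is embedded as (cos φ, sin φ) to remove
  the 2π wrap; the covariance of the mean-centered embedding is
  eigendecomposed; components are sorted by decreasing variance and each
  component's sign is fixed so its largest-magnitude loading is positive —
  the PCA sign is physically arbitrary, so it is pinned for reproducibility.
  Any dihedral selection may be supplied; the machinery does not assume a
  particular backbone subset.
- **Barrier extraction**: given two non-overlapping basin ranges on the
  profile, ΔF‡ is the maximum F on the span between the two basin minima
  relative to the basin-A minimum, and ΔF_AB = F(B min) − F(A min).
- **Conformer classification**: d[FeS–Heme] > 22 Å distal, < 20 Å proximal,
  otherwise intermediate.

Published barrier values for the real enzymes (~1.5, ~6, ~17.5 kcal/mol)
depend on trajectories that are not publicly deposited; the machinery is
therefore validated on analytic potentials (below), not against those
numbers.

## Ensemble observables

- **Attack geometry**: the angle θ is measured with its vertex at the oxo
  oxygen, ∠(Fe, O, target) — the convention consistent with favorable
  values around 130–140° in the near-attack-conformation literature.  The
  attack distance d[Fe═O–H] is measured to the substrate hydrogen when
  hydrogens are present (planted trajectories place an explicit H at 1.09 Å
  from the target carbon).
- **NAC summary**: fraction of frames with d ≤ 4.0 Å (default threshold),
  plus mean ± sd of distance and angle.  Statistics over frames use the
  *population* standard deviation, matching the mean ± sd convention of
  ensemble summaries.
- **Hydrogen bonds**: donor–acceptor ≤ 3.5 Å and D–H–A angle ≥ 135°, a
  common trajectory-analysis default (occupancy criteria are rarely printed
  with published occupancies; these are this package's declared choice).
  The hydrogen must be covalently bonded to the donor in the topology.
- **RMSD**: optimal translation plus proper (Kabsch) rotation over the
  selection, degenerate (collinear or <3-atom) selections rejected.
- **Nonbonded energies**: over all cross pairs within the cutoff (default
  99 Å, hard truncation, no switching), elec = Σ C q_i q_j/(ε_d r) with
  ε_d = 1 by default and vdW = Σ 4ε̄[(σ̄/r)¹² − (σ̄/r)⁶], Lorentz–Berthelot
  (or geometric) combining.  Parameters arrive as a per-atom table
  (serial, charge, σ, ε); no force-field file parsing.  Published
  interaction-energy means for the real systems require their force-field
  charges and trajectories and are context, not validation targets.

## Assay statistics

Conversion = 100·M_P/(M_P+M_S); TTN = product/enzyme with the mM/µM unit
mismatch handled (×1000); coupling = 100·product/NADH consumed.
Michaelis–Menten fits are unweighted nonlinear least squares (optional 1/v²
weighting), log-parameterized so Km and Vmax stay positive, initialized at
Vmax⁰ = max(v), Km⁰ = median(S).  A fitted Km outside the probed substrate
range (below 0.1·min S or above 10·max S) is flagged as unidentifiable —
saturated or linear-regime data — rather than reported as a confident
estimate.  Velocities are interpreted as per-enzyme turnover (s⁻¹) by
default; concentration rates are converted to k_cat via the enzyme
concentration.  Catalytic efficiency is always computed from the fitted
values, never back-filled from rounded printed pairs (which is why, e.g.,
1.47/0.18 gives 8.17 rather than a rounded 8.2x figure).  Pearson
correlation reports a two-sided p from the t-distribution with n−2 degrees
of freedom; no multiple-testing correction is applied.

## Synthetic data: what it emulates and what it does not

The generators provide *exact* ground truth, at the cost of realism:

- **Umbrella sampler**: Metropolis Monte Carlo (not Brownian/molecular
  dynamics) on analytic 1-D potentials, because Metropolis targets the
  exact Boltzmann distribution at any proposal size.  The step size is
  tuned toward ~40 % acceptance during burn-in and then frozen; production
  samples are thinned (default every 10 steps) to reduce autocorrelation.
  Acceptance rates outside [0.1, 0.9] set a warning flag in the metadata.
  The default double well (a = 1.5, b = 1) gives a 1.5 kcal/mol barrier —
  the hardest-to-resolve regime among the landscapes of interest; stiffer
  presets emulate the ~6 and ~17.5 kcal/mol regimes for stress tests.
- **Planted trajectories**: coordinates are *constructed from* the drawn
  distance/angle values, so the measured series equal the draws exactly and
  estimator tests are sharp.  Hydrogen-bond frames are planted as exact
  counts (e.g. 3728 of 10000 frames ⇒ occupancy exactly 37.28 %).  Draws
  are clipped to geometrically embeddable values (distances ≥ 1.6 Å, angles
  in [1°, 179°]); for the default laws the clipped mass is negligible
  (<10⁻³) and clipping cannot move a frame across the 4 Å NAC cutoff.
- **Toy graphs**: random geometric graphs with ≤ 12 nodes so the optimum
  route can be enumerated exhaustively with the same tie-breaking as the
  production search.
- **Two-domain fixture**: ~50 atoms — an Fe₂S₂-like cluster, two short
  backbone chains, a lysine-like donor whose hydrogen bond bridges the
  interdomain gap, and a heme-like Fe — laid out so the optimal tunneling
  route is forced by construction (every alternative hop is provably weaker
  under the default decay parameters).  The seed only jitters coordinates
  by < 0.01 Å, preserving every classification.

None of these emulate solvated force-field dynamics, conformational
heterogeneity beyond the planted laws, or coupling between observables.
Passing tests therefore demonstrate the *estimators and solvers* are
correct on data of known truth; they say nothing about force-field accuracy
or sampling convergence of real MD, which are out of scope.

## Problem sizes and numerical choices

The double-well validation uses 46 windows × 5000 samples (k = 20
kcal·mol⁻¹·Å⁻² on centers spanning [−1.5, 1.5]), recovering the analytic
barrier within 0.3 kcal/mol; the harmonic/quadrature cross-checks use 9–13
windows × 2000–5000 samples, agreeing within 4 estimated standard errors.
These sizes were chosen as the smallest that leave the statistical error
comfortably below the tolerances being tested.  The MBAR solver typically
converges in under ten Newton-accelerated sweeps; pathological window sets
fall back to pure self-consistent iteration, and the iteration cap (10⁵)
marks the result unconverged instead of raising.

## Known limitations

- No mmCIF input, hydrogen placement, or periodic-boundary imaging
  (trajectories are assumed imaged and whole).
- Single-pathway picture only: no multi-route interference, no full Marcus
  treatment (reorganization energy), no flavin redox-state modelling.
- 1-D PMFs only; no bootstrap error bars on profiles (the window-level
  asymptotic covariance is provided instead).
- Plain cutoff electrostatics; no Ewald/PME or generalized-Born solvation.
- The Michaelis–Menten fit does not propagate enzyme-concentration error
  and offers no inhibition models.
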