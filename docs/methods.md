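# Methods

This note documents the models, conventions and numerical choices behind
halopath, in the spirit of a methods appendix: what is simulated, what the
estimators assume, which knobs matter, and what the synthetic benchmarks do
and do not demonstrate.

## Scope and units

halopath analyses two-step enzymatic reaction paths — modelled on the
electrophilic chlorination of tryptophan (chlorine transfer to C7, then
proton abstraction from the arenium intermediate) — through three layers:
geometry/reaction-coordinate analysis of Cartesian trajectories, synthetic
steered-pull generation on analytic surfaces, and nonequilibrium work-based
free-energy estimation with mechanistic post-processing. Energies are
kcal/mol, lengths Å, time fs, charges atomic units, temperatures K;
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹; atom indices are 0-based everywhere.

## Reaction coordinates

Two families cover the common mechanistic choices:

- **Linear distance combinations** `RC = Σ c_i d(a_i, b_i)` (e.g.
  `d[O–Cl] − d[Cl–C]` for simultaneous bond breaking/formation during
  chlorine transfer). Invariant under rigid motions.
- **Mid-plane ratio** `r/R` for proton transfer: R is the donor–acceptor
  distance, r the scalar projection of donor→H onto the donor→acceptor
  axis. Dimensionless, scale-invariant, equal to d(C,H)/d(C,O) for
  collinear arrangements, 0.5 when the proton is halfway, < 0.5 while it
  is still bound to the donor carbon. The projection may be negative (H
  behind the donor); it is reported unclamped.

Hydrogen-bond occupancy is the percentage of frames with
d(donor-H···acceptor) ≤ cutoff (an optional donor–H···acceptor angle
criterion needs the donor heavy atom and is off by default, since distance
criteria are what the underlying experimental analyses quote). The modal
contact distance is the center of the highest-count histogram bin at a
fixed 0.05 Å width, ties toward the smaller distance.

Stationary-state geometry tables report mean ± sample (n−1) standard
deviation of named distances/angles over frames whose reaction coordinate
falls in a window; a single-frame window reports std 0.0.

## Synthetic steered dynamics

The engine is a stand-in for steered QM/MM-MD: it emulates the statistical
structure of work ensembles (forward/reverse pull pairs, harmonic
time-dependent bias, per-step accumulated work, near-Gaussian work
distributions near equilibrium), not the chemistry. Electronic structure,
force fields, solvent and protein environment are out of scope by design.

**Dynamics.** Overdamped (Brownian) motion, `ζ dx = −∇U_total dt + √(2k_BT ζ) dW`,
with drag coefficient ζ in kcal mol⁻¹ fs Å⁻² (diffusion D = k_BT/ζ). The
drag is a single free parameter controlling dissipation per pull,
W_dis ≈ ζ·(range)²/duration. The default ζ = 100 makes a 3000-step pull
over ~1–4 RC units dissipate ~0.1–4 k_BT — the near-equilibrium regime in
which 15-trace ensembles carry usable information, while faster schedules
reach the strongly dissipative regime on demand.

**Integrator.** The bias k = 5000 kcal mol⁻¹ Å⁻² at dt = 0.5 fs is far too
stiff for explicit Euler–Maruyama at any reasonable drag (stability needs
k·dt/ζ < 2). On 1-D surfaces whose configuration is the reaction
coordinate, each substep therefore treats the harmonic bias exactly
(Ornstein–Uhlenbeck update around the instantaneous minimum
μ = λ − U′(x)/k, with the surface gradient frozen over the substep); this
is unconditionally stable and exact for flat and purely harmonic
landscapes. Generic multi-particle surfaces use explicit Euler–Maruyama
with the bias force assembled through the reaction-coordinate gradient
(demonstrations there use softer restraints). Each schedule step is
subdivided into `n_substeps` (default 25) so that the substep resolves the
bias-trap correlation time ζ/k (0.02 fs at the defaults).

**Work convention.** The bias center moves in the same substeps, and each
substep accumulates the exact center-displacement work at the pre-move
configuration, `V(x, λ+δλ) − V(x, λ) = −k(rc(x) − λ_mid) δλ`. Summed over
substeps this is the thermodynamic-integration work ∂V/∂λ (positive when
pulling uphill), and it makes the discrete protocol satisfy the Crooks
fluctuation theorem exactly, which the estimators rely on. A single
first-order increment per schedule step would under-count by k·δλ²/2 per
step — several kcal/mol at the default stiffness — and was rejected for
that reason.

**Ensembles.** `run_msmd` draws each forward pull from an independently
relaxed initial state (default 1000 steps of dynamics with the bias held at
the schedule start — the estimators assume initial states sampled from the
biased equilibrium). Reverse pulls start from the forward endpoints,
re-relaxed at the schedule end, and traverse the schedule backwards. All
per-trace seeds derive from the master seed by counter-based spawning and
are recorded; identical inputs give byte-identical traces.

**Default schedules** mirror the halogenation study: 3000 steps of 0.5 fs
with k = 5000; chlorine-transfer coordinate range (−4.7, −2.6) Å and
mid-plane range (0.3, 0.8) exported as constants.

**Adiabatic mapping** scans a grid of coordinate values, minimizing
`U + k/2 (rc − λ)²` (L-BFGS with analytic gradients) warm-started from the
previous minimizer — deliberately hysteretic, like the potential-energy
reaction-path method it reproduces — and reports the unrestrained energy
shifted to zero at the first grid point.

## Analytic surfaces

- `build_two_step_surface(levels, positions)`: a cubic Hermite spline with
  zero slope at five knots (min/max/min/max/min), so the stationary values
  equal the prescribed levels exactly and segments are monotone; quadratic
  confinement beyond the terminal knots. The default levels
  (0, 3.0, −2.4, 3.6, −22.8 kcal/mol) at positions
  (−4.1, −3.4, −3.0, 0.5, 0.8) place a small first barrier, a shallow
  exothermic intermediate, a rate-limiting second barrier and a strongly
  exothermic product on one concatenated axis.
- `harmonic_surface(κ)`: the analytic PMF oracle (the PMF of a 1-D system
  is its potential).
- `build_collinear_toy()`: four collinear particles (mimicking
  donor-H···O–Cl···C) with a quartic double well along the distance
  combination −d(H,O) − d(Cl,C), harmonic restraints on the orthogonal
  internal coordinates, and a weak tether removing the translational zero
  mode; equilibrium coordinate values are analytic, enabling Cartesian-space
  steering tests.

Every surface's gradient is validated against central finite differences
(relative tolerance 1e-5).

## Free-energy estimators

All exponential averages are computed in log space (log-sum-exp), so βW
spans of hundreds are safe.

- **Jarzynski**: ΔF = −β⁻¹ ln⟨e^{−βW}⟩; biased upward at small n for
  dissipative ensembles (this is the overestimation the bidirectional
  estimator exists to fix).
- **BAR**: the Bennett self-consistent equation solved by bracketed Brent
  root-finding on its monotone residual; forward and reverse works are each
  measured in their own pulling direction.
- **Crooks reweighting**: ⟨F̂ e^{−β(W−ΔF)}⟩ over a path ensemble. The
  documented convention is that `works` and `df` belong to the same process
  direction; recovering a forward average from reverse pulls therefore uses
  the reverse works with ΔF_R = −ΔF_F, under which the normalization
  identity ⟨e^{−β(W̄−ΔF_R)}⟩_R = 1 holds at the true ΔF.
- **Time-slice PMF estimators**: per-slice work-weighted visitation
  histograms combined across slices with inverse-variance (biased-density)
  weights; the biased-state free energies ΔF_t start at zero and iterate
  with the profile to a fixed point (tolerance 1e-6 kcal/mol, cap 1000
  iterations; the profile is dF_t-independent in exact statistics, so the
  iteration only optimizes weights). The Minh–Adib version weights each
  trace by Bennett factors built from total works (endpoint ΔF from BAR
  unless supplied) and aligns reverse slices as λ_{τ−t}; it collapses onto
  forward Hummer–Szabo as reverse weights vanish (except at the single bin
  holding the reverse ensemble's work-free starting slice) and is exactly
  symmetric under swapping directions with ΔF → −ΔF. The δ-function is a
  histogram indicator (default 50 bins over the pull range). Unoccupied
  bins are NaN, never zero. Profiles are reported anchored at their
  minimum; because the PMF carries an arbitrary additive constant,
  quantitative comparisons should match the constant (e.g. by mean offset)
  rather than trust any anchoring convention.
- **Bootstrap**: whole traces resampled with replacement within each
  direction; SEM is the (n−1) standard deviation of replicate estimates;
  replicates in which an estimator fails are dropped and counted, with an
  error beyond a 20% drop rate.

## Mechanistic post-analysis

Transition states are raw bin maxima ("highest point along the profile");
an optional prominence filter (`n_steps`) keeps only the most prominent
peaks, since on estimated profiles every noise wiggle is a strict local
maximum. A local quadratic refinement exists but is off by default. Step
energetics satisfy ΔG‡(back) = ΔG‡(fwd) − ΔG identically; diagrams are
prefix sums of per-step energetics, with the global maximum read relative
to the initial reactant complex. Fragment charges are sums of per-atom
charges over disjoint index sets, reported per frame against the frame's
reaction-coordinate value, with optional bin averaging across an ensemble.

## Benchmark protocol and problem sizes

The surrogate benchmark (tests and `scripts/acceptance.py`) runs the
production protocol at the study scale: for each of the two reaction steps,
15 forward + 15 reverse pulls of 3000 steps (k = 5000, T = 300 K, ζ = 100)
over that step's basin-to-basin range, bidirectional estimation on
0.02-RC-unit bins, stationary-point analysis, and diagram composition. The
two steps are pulled separately and composed — the same per-step workflow
as the study being emulated. Bin width follows a resolution argument: the
prescribed product basin has curvature ~1.8·10³ kcal mol⁻¹ unit⁻², so a
bin of width w displaces the measured minimum by ≈ G″(w/2)²/2 — 0.55
kcal/mol at w = 0.05 but 0.09 at w = 0.02.

The forward-only overestimation of the unidirectional estimator is a
high-pulling-velocity effect; at the near-equilibrium production schedule
it is smaller than seed-to-seed noise. It is therefore demonstrated on a
fast-pulled ensemble of the rate-limiting step (same 15+15 sizes, 300
steps, i.e. 10× the velocity), where the forward-only error exceeds the
bidirectional error several-fold, uniformly across seeds.

## What the synthetic data do and do not show

The Langevin engine reproduces the statistical structure that the
estimators consume: Crooks-consistent forward/reverse work pairs,
near-Gaussian work distributions near equilibrium, growing dissipation and
skew with pulling velocity, and initial-state decorrelation. It does not
reproduce chemistry: no electronic structure, no multidimensional coupling
between the reaction coordinate and orthogonal degrees of freedom (beyond
the collinear toy), no solvent memory, and the drag coefficient is a
phenomenological scalar. Passing the recovery benchmarks therefore
validates the estimator/analysis machinery and its numerical conventions —
not the accuracy of any particular molecular simulation. Similarly, the
per-atom charges consumed by the fragment analysis are synthetic tables;
the package never computes quantum-mechanical populations.

## Known limitations

- Steering and PMF reconstruction are 1-D (one scalar coordinate); no 2-D
  landscapes, no umbrella-sampling WHAM, no MBAR generalization.
- The exact-OU substep freezes the surface gradient over 0.02 fs; for
  surface curvatures approaching the bias stiffness this slightly inflates
  the local stationary variance (k/(k−U″) at worst), a sub-0.1 kcal/mol
  effect at the shipped surfaces.
- The bias potential applied during relaxation and pulling is the only
  constraint; no additional distance constraints are modelled.
- Adiabatic mapping inherits the hysteresis of warm-started minimization on
  surfaces with competing basins; that behavior is intentional but means
  scan direction matters there.
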