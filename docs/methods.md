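# Methods

## Bias summation and the free energy estimate

The estimator implemented is the direct one: the free energy surface is the
negative of the summed bias, F(s) = −V(s), tabulated on a regular grid over
the CV ranges.  For a periodic CV the grid covers one period with the wrap
node appearing once (nodes lo + iΔ, i = 0..r−1); for a non-periodic CV both
endpoints are nodes.  Default ranges are the declared period for periodic
CVs and the hill-center extent padded by 3 mean hill widths otherwise;
default resolution is 256 nodes per CV (64 for 3D grids).  Displacements
on periodic CVs use the minimum-image convention, which equals the full
periodic-image sum to ~1e−10 whenever σ ≪ period (regression-tested
against an explicit three-image sum).

Two summation paths:

* **exact** — every hill's Gaussian is evaluated on the full grid.  The
  Gaussian factorises across dimensions, so per-hill 1D factors are
  combined by outer products, accumulated in chunks through BLAS.  No
  truncation.
* **fast** — valid when all hills of a CV share one width (relative spread
  ≤ 1e−6, the common Plumed setup; otherwise the call is refused with a
  pointer to the exact path).  One kernel is precomputed on the grid
  spacing, truncated where the Gaussian exponent exceeds 6.25 (≈ 3.54σ,
  1.9e−3 of the peak), and stamped at the grid node nearest each hill
  center, wrapping on periodic dimensions (with pre-folding when the
  kernel exceeds the grid).  The error per hill is the truncation tail
  plus a nearest-node placement term of order h·(Δ/2σ)·e^{−1/2}; placement
  errors have zero mean over uniformly distributed center offsets and
  largely cancel in long runs.  At the 2D study conditions below (10 000
  hills, depth ≈ 56 kJ/mol, resolution 256) the measured maximum deviation
  from the exact path is 0.36 kJ/mol.

**Reproducibility.**  Floating-point summation is order-sensitive, so both
paths first sort hills into a canonical order (lexicographic over time,
then centers, widths, heights).  Results are therefore bit-identical under
any permutation of the input hills — a stronger guarantee than fixed file
order, which the deposition times recover anyway for ordinary runs.

**Well-tempered scaling.**  Plumed pre-scales the heights it writes, so
heights are summed exactly as stored by default.  The
`scale_biasfactor=True` switch multiplies each hill by γ/(γ−1) for files
that store the heights actually deposited — which is what the synthetic
generator writes (its −Σ hills estimates V ≈ −(γ−1)/γ·F).  The package
does not assert which convention an arbitrary file uses; the switch makes
either workable.

Surface algebra (add/subtract/scale, with unit relabelling only on
request) requires identical grids and reports the differing attribute
otherwise.  Marginalization removes CVs by a Boltzmann sum,
F′ = −kT ln Σ exp(−F/kT), computed with log-sum-exp and re-normalized; on
a separable surface this identity is exact for the discrete sum, which the
tests exploit as an oracle.  kT defaults to 2.494339 kJ/mol (300 K with
R = 0.0083144621 kJ/mol/K); every function taking kT accepts other values.

## Minima, basins, state free energies

A node is a local minimum iff strictly lower than its full Moore
neighborhood (3^d − 1 neighbors; periodic wrap where declared; missing
neighbors at non-periodic edges count as +∞, so edge nodes can be minima).
Basins are carved by steepest descent: each node points to the
lexicographic minimum of (value, row-major index) over its closed
neighborhood; pointer doubling converges this to fixed points, which are
the strict minima.  Exact plateau ties (essentially impossible on summed
Gaussians, but constructible) fold into the nearest strict minimum by
index distance; a surface with no strict minimum (e.g. constant) is
rejected.  Boundaries are nodes with a face neighbor in another basin,
exported as node masks/coordinates rather than sub-grid contours.

The coarse search divides each CV range into 8 cells by default (8, 8×8,
8×8×8), keeps each cell's lowest node iff it is a strict local minimum of
the full-resolution grid, and de-duplicates — hence at most 64 minima on a
2D surface by default.  Cells whose lowest point sits on the cell edge
(sliding into a deeper well outside) contribute nothing, by construction.

State free energies sum Boltzmann probabilities over whole basins with no
energy cutoff: g_m = −kT ln Σ_{i∈basin m} exp(−F_i/kT) (log-sum-exp),
shifted so the most populated state is 0.  This deliberately weights basin
width as well as depth — a wide shallow basin can outrank a narrow deep
one.  Labels A, B, C, … (then AA, AB, …) follow ascending g, ties broken
by row-major node index; the basin map stores the owning minimum's node
index, so labels can be re-ranked without invalidating it.

## Convergence and error diagnostics

Profiles re-evaluate the basin free energies on surfaces built from hill
prefixes (checkpoints spaced by hill count, robust to irregular deposition
stride), against minima and basins detected once on the full-run surface
and held fixed; each row is shifted to its own global minimum.  Fixing the
reference keeps the series well defined when early surfaces lack some
minima (they then show as large finite g).  Marginal evolution applies the
same prefix logic to lower-dimensional marginals.

Error bars come from autocorrelation analysis of basin-occupancy
indicator series: each hill center (a biased-ensemble CV sample) is
snapped to its nearest grid node and assigned to that node's basin.  The
integrated autocorrelation time uses the initial-positive-sequence rule —
act = 1/2 + Σρ(k), accumulating consecutive pairs ρ(2j−1)+ρ(2j) while
positive (autocovariance via FFT; optional maxlag cap) — giving
n_eff = n/(2·act) and se = sd/√n_eff.  The estimator floors at act = 0.5,
so n_eff ≤ n and the standard error never undercuts the naive i.i.d.
value; zero-variance series are flagged with se = 0.  ΔG between two
states is −kT ln(p_a/p_b) with first-order propagation
SE = kT·√((se_a/p_a)² + (se_b/p_b)²); occupancies at 0 or 1 are reported
as not estimable.

**Limitation — no reweighting.**  Occupancy series are unweighted
indicators of the *biased* ensemble; no per-sample bias reweighting is
applied.  For a converged well-tempered run the biased ensemble is
Boltzmann at effective thermal energy γ·kT (stationary density
∝ exp(−F/(γkT))), so physical-scale differences follow from evaluating
the ΔG formula at kT_eff = γ·kT; the CLI does this automatically when the
file carries bias factors, and discards the first half of the series as
the flooding-transient burn-in.  For non-tempered runs the occupancy ΔG
refers to the flattened ensemble and is mainly a sampling diagnostic.

## Plots and text grids

1D surfaces are line plots with minima letters; 2D surfaces are filled
pseudocolor maps with solid contours (every 10 energy units by default, or
explicit strictly-increasing levels), dotted basin-boundary nodes, and
minima letters whose color flips by the Rec. 709 relative luminance of the
underlying fill (< 0.5 → white, else black; ties black) for readability on
any colormap.  Axis labels default to the CV names parsed from the HILLS
header.  3D surfaces are not rendered.  Text-grid export writes a
commented header (unit; per-CV name, periodicity, range, resolution) and
one coordinates+value row per node, last dimension fastest, at 9
significant digits — the same precision used for HILLS output, chosen so
that write→read→write is byte-stable and values survive to ≤ 5e−9
relative error.

## Synthetic study conditions

The generator integrates overdamped Langevin dynamics,
s_{t+1} = s_t − dt·∇(U+V) + √(2 kT dt)·ξ, where dt is the friction-scaled
(mobility × timestep) increment, with hills deposited every `stride` steps
at height w (standard) or w·exp(−V(s)/((γ−1)kT)) (well-tempered); the bias
is tabulated on a fine internal grid whose multilinear interpolant
supplies the force.  Runs are bit-reproducible for a fixed seed.  Defaults
define the study conditions and were calibrated once against convergence
diagnostics, then frozen:

* `double_well_1d` — U = 10(x²−1)² + 1.25x on [−2.5, 2.5] (barrier ≈ 4.6 kT
  at 300 K; tilt gives an analytic ΔG of 2.34 kJ/mol by quadrature);
  kT = 2.494339, dt = 2e−3, 50 000 steps, stride 150, w = 0.15 kJ/mol,
  σ = 0.12, γ = 10.  At these conditions 20 validation replicates recover
  ΔG to 0.0 ± 0.7 kJ/mol and the late-run profile span stays below
  1 kJ/mol in median.
* `four_well_2d` — U = 5[(x²−1)² + (y²−1)²] + 0.8x + 0.4y; dt = 5e−4,
  50 000 steps, stride 5 (10 000 hills), w = 0.8, σ = 0.2, γ = 10; the
  resulting FES depth is ≈ 56 kJ/mol, the regime used to stress the
  fast-path error budget.
* `periodic_cosine_1d` — U = kT(1−cos φ) on the periodic [−π, π);
  dt = 2e−3, 100 000 steps; with zero hill height this is plain Brownian
  dynamics and its histogram is χ²-consistent with exp(−U/kT), the
  generator's sampling oracle.

What the generator does *not* emulate: real molecular kinetics (no
inertia, no hidden slow degrees of freedom), CV projection error (the CV
is the full state), engine-specific height conventions beyond the one
documented above, and multiple-walker or parallel-tempering protocols.
Passing tests therefore validate the *analysis* chain and its estimators
— not the adequacy of any particular CV choice on real systems.

## Numerical choices and degenerate inputs

Kernel truncation at exponent 6.25; nearest-node placement without
sub-grid interpolation (matching the precomputed-kernel design; the error
budget above covers it); canonical hill ordering for bitwise
reproducibility; log-sum-exp for every Boltzmann sum; half-open 0-based
index conventions throughout; "pi"/"-pi" tokens in HILLS SET lines map to
±π at double precision; restart-duplicated header blocks are skipped and
non-increasing times kept but flagged; hills with zero height are legal
(they contribute nothing); empty hill sets, constant surfaces, occupancies
of exactly 0 or 1, and kT ≤ 0 are rejected with specific errors.

Problem sizes in the shipped tests — 50 000-step 1D runs, a 10 000-hill 2D
run at resolution 256, 20-replicate recovery and 200-replicate interval
calibration at reduced length, AR(1) batches of 100×4000 — were chosen as
the smallest sets at which the statistical assertions are stable.
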