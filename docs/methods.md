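# Methods

## Scope and units

`bindscape` analyzes ensembles of two-protein association trajectories
organized as independent replicas. Lengths are Å, times ns, energies
kcal/mol, temperatures K; k_B = 0.0019872041 kcal/mol/K, so k_BT = 0.596
kcal/mol at the default 300 K. Trajectories are assumed pre-imaged (both
molecules whole, nearest image); the package does no periodic-boundary
handling.

## Contact statistics

A residue of protein A contacts protein B in a frame iff the minimum
particle–particle distance from any of its particles to any B particle is
below the cutoff (default 7 Å, the usual native-contact cutoff at
coarse-grained bead resolution). Contact frequency is the fraction of frames
in contact; profiles are normalized by their largest value before comparison
with a reference perturbation profile, which is likewise max-normalized —
the two vectors must share a scale for the RMSE to be meaningful, and the
reference (e.g. an NMR CSP profile) carries arbitrary units. RMSE is
√(Σᵢ(CGᵢ−REFᵢ)²/N).

The encounter time of a replica is dt × the index of the first frame with
any inter-protein contact; by default the same 7 Å cutoff defines "contact"
here too. Replicas that never form a contact are excluded from means and
reported as a count — the data give only a lower bound on their first-passage
time, and dropping (rather than censoring at the trajectory end) is the
conservative choice. Replica-level means and SEMs come from a bootstrap:
10 000 resamples of size n (the replica count) with replacement; the SEM is
the SD of resample means.

## Occupancy density grids

Frames are rigidly superposed (least-squares Kabsch fit on a reference
selection), then observations of the mobile partner are binned on a regular
grid. Grid extent is the padded bounding box of the observations with edges
snapped to the spacing lattice (the spec of the grid is data-driven because
a sensible extent cannot be fixed a priori). Normalized voxel values are
count × bead-mass / (voxel volume × frames) / reference density, with an
18 Da water-equivalent bead mass and 1.0 g/cm³ reference by default, so a
region sampled at bulk-water number density reads 1.0. High-density regions
are voxels whose value exceeds a *relative* threshold (default 0.6 of the
grid maximum); their 26-connected components count distinct binding modes.

Two caveats follow from the relative threshold. First, a mode with
population p₂ < p₁ peaks at p₂/p₁ of the major mode's density, so a
threshold above that ratio cannot show it: detecting a 70/30 split requires
a threshold below 0.43 (the verification suite uses 0.35, still ~50× the
bulk level). Second, integrating only above-threshold voxels truncates the
weaker basin at the same absolute level as the stronger one and inflates the
apparent population ratio; `component_basin_weights` therefore assigns every
voxel above a low floor (default 5% of max, excluding the diffuse bulk
cloud) to the nearest component and integrates whole basins, which recovers
planted populations within ±0.05.

## Sketch-map embedding and binding modes

Each frame is encoded as a vector of minimum distances between rigid
structural elements of the two proteins: for each of the nA ligand elements,
the minimum distance to any selected receptor particle, then the reverse for
the nB receptor elements (N = nA + nB entries). Rigid elements encode the
binding configuration with low intramolecular noise; the element groups are
caller-supplied since their choice is system-specific.

The 2D embedding minimizes

    χ² = Σ_{i<j} wᵢwⱼ [F(R_ij) − f(r_ij)]² / Σ_{i<j} wᵢwⱼ

with R_ij, r_ij the high-/low-dimensional pairwise distances, weights wᵢ = 1
by default, and sigmoid transfer functions
s(r) = 1 − (1 + (2^{a/b} − 1)(r/σ)^a)^{−b/a} (s(0)=0, s(σ)=½, s(∞)=1). The
squared residual makes χ² a proper sum-of-squares stress; a linear residual
would be sign-indefinite. Defaults σ = 6 Å, (a,b) = (2,6) for F and (2,2)
for f emphasize near-neighbor geometry; all parameters are exposed.
Optimization is L-BFGS-B with an analytic gradient from multiple seeded
starts (the first start is the PCA projection of the encodings, usually an
excellent initialization); the lowest-stress solution wins, and the whole
procedure is deterministic under its seed. The original method's landmark
selection and annealed global schedule are out of scope; multi-start local
minimization is sufficient at the ensemble sizes used here (hundreds of
frames) and is testable.

Binding modes are clusters of the embedded cloud found by mean-shift
(kernel-density local maxima with nearest-maximum assignment; bandwidth
estimated from the data unless given). The most populated cluster is the
*prime* mode; every other cluster with population ≥ `min_population_fraction`
(default 0.05) is a *secondary* mode; smaller clusters are not reported.
Populations are fractions of all embedded points.

## Umbrella sampling, WHAM and binding ΔG

WHAM combines the biased window histograms through the standard
self-consistent equations (computed in log space with logsumexp for
stability):

    P(x_b) ∝ Σ_w n_w(x_b) / Σ_w N_w exp[(f_w − U_w(x_b))/k_BT]
    f_w = −k_BT ln Σ_b P(x_b) exp(−U_w(x_b)/k_BT)

iterated until the window shifts change by < 1e−6 kcal/mol (max 100 000
iterations; non-convergence is an error carrying the residual). The PMF is
−k_BT ln P with its minimum set to zero; unsampled bins are NaN. Adjacent
windows sharing no occupied bin trigger a warning (the pieces are then
poorly connected). Per-bin errors come from a Monte-Carlo bootstrap:
each trial resamples every window's points with replacement and re-solves
WHAM on the same bin grid (warm-started from the original shifts); the
per-bin SD over 100 trials (default) is the error.

Binding ΔG is the PMF difference between a bound and an unbound reaction-
coordinate anchor (defaults 1.5 and 14.5 Å), read at the nearest sampled
bins — with ≤ 0.1 Å bins the nearest-bin offset is below the bin noise, and
the `BindingDG` record stores the actual bin centers used so comparisons
against analytic references can evaluate the reference at the same points.
The ΔG error combines the two bin errors in independent quadrature.

Known limitation: bootstrap errors assume independent samples within each
window. The synthetic Metropolis sampler thins its chain (default every 5th
step), but residual autocorrelation can leave the bootstrap error a factor
~1.5–2 below the true seed-to-seed spread of ΔG; treat the MC error as a
lower bound when sampling is correlated.

Gliding detection classifies an enforced-dissociation window series by
contact turnover: residue pairs first seen in a window are "new"; if more
than 10% (configurable) of all observed pairs first appear in the upper half
of the series, the ligand is still forming fresh interfaces while being
pulled away — gliding — otherwise the series is a clean dissociation. The
underlying published criterion is visual; the 10% late-fraction rule is this
package's quantitative default.

ΔG sets are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite degrees of freedom, two-sided).

## Representative poses and refolding RMSD

Pose selection: (1) keep frames with ligand–receptor COM distance below
30 Å and complex RMSD to a reference structure below 50 Å (aligned on the
ligand, measured over all particles — the permissive RMSD default follows
standard practice for this filter and is configurable); (2) keep frames
whose ligand COM falls inside the high-density region of the occupancy grid;
(3) draw n (default 20) uniformly without replacement, seeded. The survivor
count of every stage is logged. Point-like alignment selections fall back to
a pure centroid translation.

Refolding RMSD: the reference is the first-contact frame; each later frame
is superposed on the *receptor* and the RMSD measured over the *ligand*,
isolating binding-pose rearrangement from rigid tumbling of the whole
complex. A hop between two binding sites appears as a plateau shift well
above the within-site fluctuation.

## The synthetic generator

The generator stands in for large coarse-grained replica campaigns and
defines the package's verification conditions; it is first-class, tested
code. The receptor is a frozen Fibonacci-sphere shell of beads (24 beads,
radius 9 Å). The ligand is a rigid bead core (10 beads, radius 2.5 Å) whose
COM follows overdamped Euler–Maruyama Langevin dynamics in the sum of

- planted binding sites: smoothed flat-bottom spherical wells, U(d) = −depth
  inside the flat radius (default 4 Å) with a cosine ramp to zero over a
  2 Å switch. Equal-volume flat wells make the equilibrium occupancy ratio
  of two sites exactly exp(−ΔE/k_BT), giving closed-form ground truth
  (Gaussian wells of different depth would have depth-dependent effective
  volumes and a ~(E₁/E₂)^{3/2} correction);
- a soft-core radial repulsion keeping the COM off the receptor shell;
- a soft spherical wall (46 Å) bounding the search volume.

Orientation is omitted: binding-mode identity is positional in every
downstream analysis (grids, encodings), so wells act on the COM. Replicas
start uniformly on the shell at 40 Å separation (beyond the range of
specific interactions) and each consumes its own spawned random stream, so
a replica's trajectory is bitwise reproducible and independent of how many
replicas run alongside it.

`friction` is a per-bead drag coefficient γ in kcal/mol·ns/Å² (mobility
1/γ; a collision rate would need a mass the model does not have). Default
γ = 0.005 per bead gives the 10-bead core D = k_BT/(10γ) ≈ 12 Å²/ns — fast
compared to a real protein, deliberately, so that a 1.6 µs default run
(dt = 0.0025 ns × 640 000 steps) contains many capture/escape/exchange
events and site populations equilibrate at desk scale. The stability guard
requires dt·k_max/γ < 2 for the stiffest force constant present.

The optional tail (IDR mimic) is a chain of beads on harmonic springs
(rest length 4 Å, k = 0.5 kcal/mol/Å²) anchored to a core bead. The drag
model is free-draining: flexible tail beads carry their own friction and do
not slow the core, while extending the capture radius — the fly-casting
effect. `tail_rigid` instead freezes the tail compactly against the core:
the conformational search and radius extension vanish and the rigidly
attached beads now add their drag to the COM. This reproduces, in a
translation-only model, the experimental ordering (flexible tail binds
fastest, rigidified tail slowest); a rigid *extended* arm would require
rotational diffusion to model honestly, which the toy omits. Tail beads are
phantom except for contact detection (no excluded volume).

What the generator does **not** emulate: real force fields, side-chain
packing, orientation-dependent binding, hydrodynamic interactions, internal
receptor flexibility, and realistic IDR conformational ensembles. Passing
tests therefore demonstrate that the *analysis* stack is correct against
known ground truth — not that any particular real system behaves this way.

Umbrella-window samples for 1D analytic potentials are drawn by
Metropolis MC per window (proposal SD auto-tuned to 30–50% acceptance
during a 1000-step burn-in, chain thinned 5×), written/read in a plain-text
layout (one file per window with a `# center k` header plus a metadata
list) that doubles as the expected input format for real window data.

## Verification conditions and problem sizes

The acceptance suite runs the full stack at these desk-scale sizes, all
seeded: WHAM recovery of U = 2(x−8)² from 17 windows × 5000 samples
(k = 10 kcal/mol/Å², 0.05 Å bins, bins with ≥ 100 samples, tolerance
0.2 kcal/mol); the ΔG pipeline on a double-Gaussian well over 29 windows
(tolerance 0.25 kcal/mol, MC error bracketing); two-site mode recovery and
Boltzmann occupancy from 50 replicas × 1.6 µs (populations within ±0.05,
ratio within 15%); fly-casting ordering over 50 replicas × 800 ns per tail
variant; and brute-force oracle equivalence (1e−10) for the RMSE, stress,
encoding and t-test kernels on 100 random instances each.
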