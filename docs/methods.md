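# Methods

This note records the models, conventions, numerical choices and known
limitations behind each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Nucleosome model and fiber descriptors

Every structural analysis treats a nucleosome as a rigid oriented disc:
a solid cylinder of radius 5.5 nm and height 6.0 nm whose axis is the
superhelical (disc) normal, with the dyad axis fixing the in-plane
orientation.  A pose is the triple (centre, normal, dyad) with the
frame orthonormalised on construction (tolerance 1e-3 for input
validation, Gram–Schmidt to machine precision internally).

Fiber descriptors, per position N in DNA order:

* `D` (nm) — centre distance of (N, N+2);
* `para` (deg) — plane angle of (N, N+2), **folded** to [0°, 90°]:
  arccos|n_N · n_{N+2}|.  The folded convention is flip-invariant
  (tomographic normals carry an arbitrary sign) and covers every value
  the descriptor tables report; a signed alternative would need a
  consistent normal polarity that pose tables do not provide.
* `alpha` (deg) — signed dihedral of (N, N+1): both normals projected
  onto the plane perpendicular to the N→N+1 centre axis, angle taken by
  the right-hand rule, in [0°, 360°).  Reversing the traversal maps
  alpha to 360° − alpha; the package fixes fiber order as the
  convention.  Fiber summaries use the circular mean/SD for alpha.
* Degenerate geometry (normal within 1e-6 of the centre axis) raises
  rather than returning an arbitrary angle.
* R_g is computed over nucleosome centres, unweighted: pose tables
  carry no mass information, and for rigid identical particles the
  centre trace is the natural mass proxy.

### Idealised fiber builders

*Two-start mode* places two face-to-face stacks (each stack coaxial
along its own axis, members separated by the rise, default 6 nm) whose
axes are tilted symmetrically about the fiber axis.  The tilt is solved
by bracketed root-finding **on the built fiber itself** so that the
circular-mean adjacent dihedral equals the configured alpha; this makes
the builder → descriptor round trip exact (≤1e-6) for the mean, with
D = rise and para = 0 holding exactly for every pair.  Solutions are
cached per parameter set.

*Zig-zag mode* grows an open chain step by step: the next centre lies
`d_adj` along the current step direction; the normal advances by a
rotation of alpha about that direction (hence exact alpha recovery);
the next step direction is the current one rotated about the new normal
by a turn angle solved (grid bracket + Brent) so the (N, N+2) plane
angle equals the configured para.  Because the step construction is
frame-local, the noiseless chain is screw-homogeneous and every
position reproduces the configured parameters exactly.  With per-step
noise the para target may fall outside the reachable range for an
unusual alpha draw; noisy builds then take the nearest achievable value.

Noise models: wrapped-normal on alpha and truncated normal on
d_adj/para (zig-zag); small random tilts of each disc normal
(two-start).  A seed is mandatory whenever any noise scale is positive.
Builders check sterics with a centre-distance floor (default 3 nm,
skipping covalently adjacent pairs in zig-zag mode) and report the
first offending pair.

## Packing statistics

**g(r).** The pair-distance histogram of nucleosome centres is divided
by the mean histogram of `n_reference_draws` uniform placements of the
same number of points inside the same mask.  This Monte-Carlo edge
correction is exact in expectation for any mask shape, so g → 1 at
large r for spatially random input.  Peak positions are refined below
the bin width by the g-weighted centroid of the peak bin and its
neighbours, which recovers peaks that fall on a bin edge.

**Orientation distributions.** Nearest neighbours (default k = 1) come
from an exact KD-tree query with deterministic tie-breaking (ascending
pose id).  The random reference for the folded plane angle is the
sin(θ) density on [0°, 90°], integrated per bin and normalised to the
sample count; its mean is 1 radian = 57.30°.

**Contact classification.** The minimal surface–surface distance
between two disc cylinders is found by sampling one surface on a
structured parameter grid, evaluating the exact point-to-cylinder
signed distance to the other solid, and refining the best sample with a
shrinking local grid on its chart; the sweep runs in both directions.
Accuracy is ~0.02 nm against a dense sampling oracle.  A pair is a
contact when the separation is ≤ 2.0 nm — generous enough to include
tail-bridged contacts (histone tails reach 2–3 nm) — and each side
contributes a facet: "face" when the closest point lies on a flat cap
within 0.9 of the cap radius, else "side".  Exactly degenerate
flat-on-flat geometries produce tied minima; ties resolve in favour of
the face interpretation.  Overlaps deeper than 1 nm are flagged but
classified by the deepest-penetration facet.  Both thresholds are
configurable and recorded in census output.

**Census.** Candidate pairs come from a fixed-radius KD-tree query with
a rigorous reach bound (2·√(r² + (h/2)²) + gate), so no gated pair can
be missed; a brute-force mode verifies this.  Intra-array contacts
exclude |Δsequence| < 2 (covalently adjacent nucleosomes are trivially
proximal).  Per-array counts, class fractions, and ensemble mean ± SD
are reported.

## Interaction networks

Edges carry the count of inter-array nucleosome contacts and a
dimensionless energy: class weights default to 3 : 2 : 1 for
face-to-face : face-to-side : side-to-side, the energetic ordering of
the packing geometries; weights are configurable.

Normalised algebraic connectivity is λ₂ of the **unweighted** Laplacian
divided by λ₂ of a deterministic circulant k-regular graph on the same
node count (k//2 ring neighbours each side; an odd k adds the antipodal
link and requires an even node count, otherwise the degree rounds down
with a warning).  The circulant reference realises "all nodes connected
at the highest degree" reproducibly.  The ratio is clipped to [0, 1];
a disconnected graph returns 0 with a warning.

The digestion curve deletes each nucleosome-level inter-array contact
independently with probability p (an exchangeable model of progressive
tail digestion reducing interaction valence), rebuilds the array graph
and records the largest-component fraction, averaged over replicates.

## Tail-contact profiling

Contacts are bead pairs within the cutoff (default 7.0 Å — about 1.2×
the 3.8-Å bead spacing of one-bead-per-residue models; configurable and
recorded in output), excluding pairs on the same chain within two
residues.  Scopes partition exactly: same nucleosome; same array,
different nucleosome; different arrays.  A residue in three pairs
counts three contacts.  Per-residue means are per frame; SDs across
frames use the population convention (divide by n), which is the
descriptive statistic for a fixed frame set.  The KD-tree search is
exact, verified against all-pairs enumeration.

## Porosity and density

Occupancy voxelises the disc cylinders (voxel 0.5–4 nm, default 1 nm —
fine enough for 14–25-nm pores at tractable memory).  Two mask modes
serve two questions:

* *closing* (default): morphological closing with a 12-nm ball
  (implemented with exact Euclidean distance transforms).  It bridges
  inter-nucleosome gaps but follows the particle network, excluding
  large percolating channels — the region over which interior pores
  are meaningful.
* *convex*: the convex hull of the occupied voxels — the condensate
  envelope including internal voids, the region a **bulk** number
  density refers to.  Density estimates on rasterised models use this
  mode; on rod-like fiber systems the closing mask would attribute the
  channel volume to the exterior and inflate density by tens of
  percent.

Pore size is local thickness: the diameter of the largest ball
containing a void voxel that fits entirely in the void.  Radii are
processed in descending one-voxel steps; each level marks voxels
covered by a ball of at least that radius via two distance transforms,
so the result is exact to the voxel quantisation (±2 voxels on a
diameter).  An optional boundary erosion (off by default) removes the
shell near the mask surface, where closing leaves geometry-dependent
crevices that are not interior pores; the acetylation-mimic comparisons
use a 12-nm erosion.

Genomic content is closed-form: bp/μm³ = density × NRL;
nucleosomes per focus = density × (π/6)d³; genome fraction uses a
diploid human genome (6.2 Gbp) by default.

## Microrheology

The trap-corrected generalised Stokes–Einstein route: with
Π(t) = κ·MSD(t)/(2 k_B T) (normalised so Π → 1 in a purely viscous
medium),

    G*(ω) = κ/(6πa) · ( 1/(iω Π̂(ω)) − 1 ).

Π̂ is evaluated **exactly** for the piecewise-linear interpolant of Π
anchored at (0, 0) with a constant plateau beyond the last lag; for an
exponential Π this returns exactly iωη.  Lag knots are every integer
lag up to 1000 plus ~300 log-spaced beyond, which keeps the
interpolation error negligible across the reported band.  The
frequency band spans one decade inside both the record length and the
Nyquist limit; frequencies with negative moduli are trimmed with a
warning, never silently returned.

Statistical noise in the long-lag MSD (the record holds finitely many
correlation times) is amplified by the 1/(iωΠ̂) inversion.  Before the
transform, Π (averaged over axes) is therefore projected onto a
non-negative combination of relaxation modes a_i(1 − e^(−t/θ_i)) over a
log-spaced θ grid (non-negative least squares, decade-balanced
weights).  Any linear viscoelastic medium in a harmonic trap has a Π of
exactly this completely-monotone-derivative form, so the projection
denoises without restricting the admissible physics; `smooth=False`
gives the raw route.

MSD uses the FFT identity for the overlapping-window time average and
matches the O(n²) double loop to rounding.  Trap stiffness is
equipartition, κ = k_B T / Var(x), per axis, with a linear-drift check
that errors (advising detrending) rather than silently absorbing
non-stationarity.  η₀ is the origin-constrained slope of G″ versus ω
over the lowest decade where G″ > 3·G′ (flagged as a lower bound when
no such region exists); crossovers are sign changes of
log G′ − log G″ located by log-log interpolation.  Stress-correlation
rheology computes G(t) = (V/k_B T)·⟨σ(t₀)σ(t₀+t)⟩ without mean
subtraction, averaged over components and origins, truncating lags with
fewer than 10 origins.

Oracle scales: the Newtonian self-consistency run uses 2×10⁵ samples at
1 ms; the Maxwell crossover run uses 10⁶ samples, at which the
crossover location is reproducible to within a few percent across
seeds.  The Maxwell bead generator adds a small solvent viscosity
η_s = G₀λ/100 (a bare Maxwell element has no well-posed overdamped
bead limit); it shifts the G′/G″ crossover by ~2% and adds a second,
genuine high-frequency crossover near ω ≈ 100/λ where the solvent loss
overtakes the plateau, which the tests ignore by taking the first
crossover.
Both one-variable (Ornstein–Uhlenbeck, exact discretisation) and
two-variable (matrix-exponential with Lyapunov-consistent noise)
integrators satisfy fluctuation–dissipation exactly at the sample
times.

## Single-particle tracking

D comes from the ensemble-averaged time-averaged MSD fitted over lags
1..3 by weighted least squares (weights = displacement-pair counts);
the intercept absorbs localisation error (4σ²) and short-lag fits
minimise confinement bias.  CIs are percentile bootstrap over whole
trajectories (default 1000 resamples, seeded).  Tracks are split at
frame gaps; segments shorter than 5 points are dropped with a warning.
Jump angles take consecutive displacement pairs (zero or sub-threshold
steps excluded and counted); AC = log₂(f_fwd/f_bwd) with forward =
[0°, 30°] and backward = [150°, 180°] windows, following the
single-nucleosome-tracking convention; windows are configurable.  An
empty backward (forward) window yields +∞ (−∞) with a warning; both
empty is an error; fewer than 100 angles triggers a warning.

## Synthetic data: what it emulates, what it does not

The generators are *statistical stand-ins* with bookkeeping, not
molecular dynamics; no thermodynamic realism is claimed.

* **Fibers.** `bp25_like` = zig-zag with alpha 230° (open) / 200°
  (compacted), para 45°/30°, d_adj 10/9 nm, wrapped-normal alpha noise
  (SD 25°); `bp30_like` = two-start with alpha 50° (open) / 80°
  (compacted), 6-nm rise, tilt noise (SD 8°).  The alpha/para targets
  encode the measured fiber geometry of the two linker lengths, whose
  means differ by ~180° (the 10-bp/turn phasing of linker DNA); the
  noise scales are package choices reproducing the heterogeneous
  (zig-zag) versus stereotyped (two-start) contrast and are recorded in
  each fiber's ground-truth metadata, not claimed as measured values.
* **Condensates.** Fibers are placed with random orientations on a
  jittered cubic lattice and relaxed by rigid push-apart sweeps (max
  500) until no inter-fiber centre pair is closer than 4.5 nm; fibers
  whose reach permits it are clamped fully inside the box (the clamp is
  capped at 0.15·box so small boxes stay packable, at the cost of a few
  protruding poses).  Rejection sampling cannot reach the ~34% disc
  volume fraction of the nuclear density, hence lattice + relaxation.
  Real condensates have liquid-like positional correlations and
  surface tension that this construction does not model; passing tests
  show the estimators recover known construction parameters, not that
  the generator reproduces experimental microstructure.
* **CG frames.** Rigid DNA/core bead templates per nucleosome with
  histone tails grown as anchored, loosely self-avoiding walks (3.8-Å
  steps) optionally biased toward a partner face (bridging) or the own
  DNA (sequestered); contacts realised per frame are recorded as ground
  truth.  Tail lengths are approximate residue counts per tail type.
* **Trajectories.** Trapped beads: exact OU / Kelvin–Voigt / Maxwell
  discretisations (above).  SPT: Gaussian steps of variance 2DΔt per
  axis, optional radial reflection at a confinement radius, i.i.d.
  localisation noise.

Every stochastic output is reproducible from (config, seed), and every
generator attaches its construction parameters to the output metadata.

## Problem sizes

The validation suite and the reproduction script run at synthetic desk
scale, chosen as the package's own working sizes: condensates of
200–6250 twelve-mer fibers (2.4×10³–7.5×10⁴ nucleosomes, boxes of
160–500 nm), RDFs with 0.5-nm bins and 100 reference draws, rheology
records of 2×10⁵–10⁶ samples, and 10³–2×10³ tracks of 20 steps.

## Known limitations

* Contact classification treats nucleosomes as ideal cylinders; DNA
  linker paths and tail excluded volume are not modelled.
* The contact gate (2.0 nm) and face fraction (0.9) are geometric
  conventions; census output records them, and class fractions near
  facet boundaries are sensitive to them.
* The closing-mask pore analysis is quantised at the voxel scale and
  its boundary shell is geometry-dependent (use the boundary-erosion
  option when comparing conditions).
* GSER assumes a stationary, equilibrium, linear medium and no-slip
  sphere hydrodynamics; active or aging materials violate it.
* The naive nearest-neighbour SPT linker in the CLI plumbing is a
  convenience, not a validated tracker; detection/linking of raw movies
  is out of scope.
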