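# nucleopack

Multiscale analysis of nucleosome organisation in chromatin condensates:
from the geometry of individual nucleosome fibers, through the packing
and interaction networks of condensed phases, to their material
properties and single-molecule dynamics.

## Who this is for

Cryo-electron tomography of reconstituted and native chromatin yields
tables of nucleosome *poses* — centre coordinates plus disc
orientations.  Coarse-grained simulations of the same systems yield
residue-resolution bead frames and stress series, and optical-trap and
single-molecule microscopy yield bead and molecule trajectories.
`nucleopack` provides one coherent toolkit to analyse all of these, plus
synthetic generators with known ground truth for every stage, so each
estimator can be validated before it touches real data.

## What it computes

**Fiber geometry** (`nucleopack.geometry`).  A nucleosome is an oriented
disc (cylinder, r = 5.5 nm, h = 6 nm; axis = superhelical normal).  For
a fiber of poses in DNA order the package computes, per position N:

* `D` — centre distance of the semi-adjacent pair (N, N+2), nm;
* `para` — folded plane angle of (N, N+2), in [0°, 90°];
* `alpha` — signed plane dihedral of the adjacent pair (N, N+1) about
  the centre axis (right-hand rule), in [0°, 360°);
* `d_adj` and the radius of gyration R_g over nucleosome centres.

Builders produce idealised *two-start helical* fibers (N:N+2 stacked
face-to-face at a configurable rise, as adopted by 30-bp-linker
chromatin) and *zig-zag* fibers (large alpha, no stacking, the
25-bp-linker motif); both invert exactly through the descriptor code.

**Condensate packing** (`nucleopack.packing`).  Radial distribution
function g(r) of nucleosome centres against a uniform random reference
drawn inside the same spatial mask (Monte-Carlo edge correction);
nearest-neighbour plane-angle distributions against the sinusoidal
random baseline; pairwise packing-geometry classification
(face-to-face / face-to-side / side-to-side, from exact
cylinder–cylinder surface distances); and an intra-/inter-array contact
census.

**Interaction networks** (`nucleopack.network`).  Arrays become nodes,
inter-array contacts weighted edges; the normalised algebraic
connectivity λ₂/λ₂(k-regular reference) ∈ [0, 1] summarises cohesion,
and a digestion curve (random deletion of nucleosome-level contacts)
probes how connectivity collapses as interaction valence is reduced.

**Tail contacts** (`nucleopack.tails`).  Residue-level contact profiles
of histone tails (H3, H4, H2A(N), H2B) in coarse-grained frames, split
into intra-nucleosome, intra-array and inter-array scopes; means and
population SDs per residue per frame.

**Porosity and density** (`nucleopack.porosity`).  Voxelised occupancy,
condensate masks (morphological closing or convex envelope), pore-size
distributions by local thickness (largest inscribed ball), nucleosome
number density by mask-and-count, and the closed-form conversion of
density to genomic content (bp/μm³, nucleosomes and bp per focus,
genome fraction).

**Microrheology** (`nucleopack.rheology`).  From a trapped-bead
trajectory: MSD, equipartition trap stiffness, and the complex shear
modulus via the trap-corrected generalised Stokes–Einstein relation

    G*(ω) = κ/(6πa) · ( 1/(iω Π̂(ω)) − 1 ),   Π(t) = κ·MSD(t)/(2 k_B T),

with Π̂ the exact one-sided Fourier transform of the piecewise-linear
interpolant of Π.  Zero-shear viscosity η₀ and G′/G″ crossover
frequencies are derived from G*; the stress-autocorrelation route
G(t) = (V/k_B T)·⟨σ(t₀)σ(t₀+t)⟩ handles simulation stress series.

**Single-particle tracking** (`nucleopack.spt`).  Ensemble diffusion
coefficients from weighted MSD fits with bootstrap CIs, jump-angle
distributions (0° = directed, 180° = back-and-forth), and the asymmetry
coefficient AC = log₂(f_fwd/f_bwd) with 30° windows.

**Synthetic data** (`nucleopack.synthetic`) generates all of the above
with recorded ground truth: fibers, packed condensates at target
density, coarse-grained frames with steered tail contacts, exact
Ornstein–Uhlenbeck / Maxwell trapped-bead trajectories, and free or
confined 2-D tracks.

## Worked example

```python
import numpy as np
from nucleopack import (gen_condensate, radial_distribution, first_rdf_peak,
                        nearest_neighbor_pairs, orientation_distribution,
                        build_interaction_graph, normalized_algebraic_connectivity,
                        number_density)

m = gen_condensate(fiber_kind="bp30_like", n_fibers=200,
                   target_density=6.0e5, seed=7)
rdf = radial_distribution(m, r_max=25.0, bin_width=0.5,
                          n_reference_draws=100, seed=1)
print("first g(r) peak:", round(first_rdf_peak(rdf), 2), "nm")
print("density:", round(number_density(m)), "nucleosomes/um^3")
g = build_interaction_graph(m)
print("normalized connectivity:", round(normalized_algebraic_connectivity(g), 2))
```

prints

```
first g(r) peak: 5.89 nm
density: 588500 nucleosomes/um^3
normalized connectivity: 1.0
```

The g(r) peak sits at the 6-nm disc-height rise because the generator
stacks N and N+2 face-to-face — the condensate remembers its fiber
architecture.  The recovered density matches the 6.0e5/μm³ generation
target within 2%, and a normalised connectivity of 1.0 says this
synthetic condensate's array graph is at least as cohesive as the
k-regular ring reference built at its own maximum degree (the ratio is
clipped to [0, 1]).

A command-line interface mirrors the library (`nucleopack simulate`,
`rdf`, `orient`, `contacts`, `census`, `network`, `digest`, `pores`,
`density`, `genomic`, `pmot`, `gt`, `spt`, `geometry`); every run writes
a YAML log with the package version, arguments and seed.

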