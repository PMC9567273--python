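# Methods

This note records the models, parameter choices and numerical decisions
behind laminafold, and what the synthetic-data tests do and do not
establish about real data.

## SBS polymer model

The chromatin fibre is a bead-spring chain in reduced Lennard-Jones units:
bead/binder diameter σ = 1, mass m = 1, energy kBT = 1. One bead
represents one 20 kb bin of the genomic window being modelled, so a
~5.9 Mb locus is ~295 beads. Each bead carries one binding-site type id or
is inert; binders of the matching type diffuse freely and bridge beads.

Pair interactions:

* **WCA core** between all particle pairs: LJ truncated and cut at
  2^{1/6} σ (purely repulsive).
* **Specific bead–binder attraction**: truncated LJ of depth `e_int`
  between a bead and a binder of its type, cutoff `r_int`. The published
  model family quotes E_int in 3.1–8.2 kBT and R_int in 1.3–1.5 σ; since
  per-type energies are not printed, a single global default of 5 kBT at
  1.5 σ is used, configurable per run.
* **Nonspecific bead–binder attraction** `e_ns` (default 2.5 kBT, the
  middle of the quoted 2–3 kBT band) between any bead — including inert
  beads — and any binder. Restricting it to typed beads is a one-line
  change; nothing in the source model restricts it, so we do not.
* **FENE bonds** between consecutive beads, R0 = 1.6 σ, K = 30 kBT/σ²,
  on top of the WCA core (Kremer–Grest setup).

Binder count defaults to one binder per two beads of the matching type
(binder concentration is a free control parameter of the model class; this
default keeps the globule phase reachable at the default `e_int`). The
bulk phase runs in a cubic periodic box sized to a number density of 0.02
particles/σ³ unless an explicit box is given.

## Langevin integration

Dynamics follow the underdamped Langevin equation with friction ζ = 0.5
and time step Δt = 0.012. The integrator is the GJF
(Grønbech-Jensen–Farago) discretization with 2GJ half-step velocities.
Two properties motivated this choice over a BAOAB splitting, measured in
pilot runs of the actual system:

* the GJF free-particle diffusion coefficient is exactly kBT/(mζ) at any
  stable Δt (BAOAB carries an O((γΔt)²) correction — negligible here —
  but, more importantly, its *full-step* velocities under-estimate kinetic
  temperature by ~4% at Δt = 0.012 because the FENE+WCA bond curvature
  puts ωΔt ≈ 0.6);
* the 2GJ half-step velocity is Maxwellian to high accuracy even for
  stiff harmonic forces; the measured kinetic temperature of a collapsing
  150-particle system is within 0.1% of target.

Each kernel call consumes an independent 32-bit seed derived from the run
seed through `numpy.random.SeedSequence`, making whole trajectories
reproducible bit-for-bit.

A FENE bond reaching R0, a particle outside the NE sphere, or a
non-finite coordinate aborts the run with diagnostics; these signal a time
step too large for the configuration (a deliberately overstretched bond at
1.5 σ, storing ~60 kBT, needs Δt ≈ 0.006 to relax cleanly — the test
suite documents this).

## Initialisation

The chain is grown as a self-avoiding walk with bond lengths uniform in
[0.8, 1.2] σ and a 0.9 σ exclusion among non-bonded beads, with backtrack
on dead ends; all distance checks use the periodic minimum image and the
walk is confined to the box, so no two periodic images overlap. Binders
are placed uniformly with a 0.95 σ clearance. Growth-based walks are
systematically ~20–25% more compact than the equilibrium excluded-volume
coil (Rosenbluth bias); equilibration removes this.

## NE attachment

The NE is a sphere of radius R (production value 40 σ). Attractive beads
(positive binned DamID, see below) feel a truncated LJ along the inward
radial coordinate s = R − |r| with depth `e_ne` (default 1.2 kBT, the
value at which the source model family found adsorption without structure
deformation) and cutoff 2.5 σ; repulsive beads and all binders see a WCA
wall. The NE phase starts from the equilibrated bulk configuration,
re-centred on the bead centre of mass; binders are wrapped to the nearest
periodic image and, if the wrap puts one outside the wall, pulled radially
inside (binders are retained in the sphere by construction).

**Desk scaling.** Default run lengths are 2×10⁶ bulk steps and 1×10⁶ NE
steps sampled every 10⁴ (the production protocol of ~10⁸, 7×10⁷ and
5×10⁵ is a plain configuration change). Two consequences matter:

* adsorption experiments use a smaller sphere (R = 12 σ in tests and
  examples) — with R = 40 σ the polymer centre of mass must diffuse ~35 σ
  to reach the wall, ~10⁵ time units ≈ 10⁷ steps, which is exactly why
  the production protocol runs 7×10⁷ NE steps. The wall physics is
  identical; only the approach time changes.
* ensemble statistics (contact maps, distance distributions) carry more
  sampling noise than production runs; tests therefore assert qualitative
  orderings and hard invariants, not production-scale values.

## DamID processing and LAD calling

Per-fragment RPKM (count / (fragment kb × million mapped reads)) for the
Dam-LaminB1 and Dam-only channels; log2 ratio with a pseudocount (default
0.1 RPKM, configurable; the normalisation source does not state one);
length-weighted binning into 20 kb windows, trailing partial bin dropped,
empty bins missing.

LADs are segmented by a two-state hidden Markov model fit by Baum–Welch.
Emissions are Student-t with fixed degrees of freedom (default 3; the
heavy tails absorb DamID outliers that would drag Gaussian state means), a
Gaussian mode is available. Location/scale updates use the standard
latent-gamma weighting of the t distribution; scales are floored at 1e-4
so zero-noise tracks decode exactly. Initial locations are the 5th/95th
percentiles (widened to min/max when degenerate) so a minority state
covering <25% of bins is still found. Missing bins are excluded from the
likelihood and break LAD runs. If the two fitted locations differ by less
than `mean_sep_tol` (default 0.01 log2 units) the track is declared
single-state: zero LADs. The state with the larger location is LAD; bins
are assigned by posterior decoding; per-LAD scores are mean log2 values
and percentiles use mean-rank ties on a 0–100 scale.

Per-bead NE affinity for the simulator is the sign rule: binned mean
DamID > 0 → attractive, ≤ 0 or missing → repulsive.

## Ensemble quantification

* **Contact maps**: fraction of sampled frames (pooled over independent
  simulations) with |r_i − r_j| < 7.5 σ; diagonal fixed at 1.
* **Map comparison**: Pearson r over upper-triangle entries at genomic
  separation > 100 kb; the distance-corrected r′ subtracts each
  diagonal's mean from both maps first (an observed-minus-expected
  normalisation; the original distance-corrected statistic is defined in
  software we do not reimplement, and per-diagonal centering is the
  standard approximation).
* **Overlaps**: bead coordinates are projected along a configurable axis
  (default z; the source quantification does not state the plane), each
  region is replaced by a circle of its 2D gyration radius, and the
  piecewise circle-intersection formula (disjoint / partial / containment
  with 1e-12 slack at case boundaries) gives A12;
  overlap12 = A12/(A1+A2−A12) and
  overlap123 = (A12+A13)/(A1+A2+A3−A12−A13−A23).
* **Sphericity**: π^{1/3}(6V)^{2/3}/A from the scipy convex hull.
* **Calibration**: mean over probe pairs of (experimental median /
  model median), for lengths (nm/σ) and overlaps (dimensionless).

## FISH volumetrics

Voxels are anisotropic (40 nm xy, 125 nm z by default); every volume,
area and distance is physical. Segmentation: isotropic 3D Gaussian
smoothing in pixel units (σ = 0.5 px), Otsu or fixed-fraction (20% of
max) thresholding, 26-connected labelling, 0.04 μm³ minimum volume.
Intermingling is |A∩B|/|A| by voxel count; Jaccard is |A∩B|/|A∪B|.

Combined sphericity merges the two channels' masks (the ROI is rejected
if the merge is disconnected), takes V as summed voxel volume and A from
a marching-cubes mesh with the physical voxel spacing. The binary mask is
smoothed with σ = (1.0, 0.5, 0.5) voxels (z heavier, where the staircase
is worst) before meshing: a raw voxel mesh inflates A ~10% and biases
sphericity low; with this anti-aliasing a planted 0.4 μm ball reads
~0.97 and never exceeds 1 in the discretization study that fixed the
sigma.

Distance-to-lamina: the lamin channel is Otsu-segmented, components below
0.02 μm³ discarded, holes filled morphologically in 3D, and the
anisotropic Euclidean distance transform of the background is sampled at
the FISH object's centroid. Hole filling presumes the lamina rim is an
open tube within the analysed z-slab, as it is for real ROIs cropped
around a spot; the synthetic fixtures therefore clip the shell in z — a
closed synthetic shell would be filled solid and read distance 0.

## TAD co-expression

CAGE-style preprocessing with boundary-exact filters: samples with fewer
than 1,000,000 reads are dropped (exactly 1,000,000 is kept); peaks with
a cross-sample sum below 32 are dropped (exactly 32 is kept); peaks map
to a gene when they overlap one of its exons or lie within 200 bp
upstream of its TSS (strand-aware); per-gene counts are summed and
CPM-normalised.

Metasample merging: complete-linkage hierarchical clustering on 1 − r
distance cut at 1 − 0.95, which guarantees every within-group pair has
r ≥ 0.95; merged profiles are member means; constant samples are dropped
with a warning. Note that strong gene-level expression differences alone
push sample–sample correlations near 1, so merging is meaningful for
libraries with genuine replicate structure, not for white-noise toys.

Ubiquity classes: genes whose maximum expression never exceeds the
detection cutoff are unclassified; detected genes split at a median-
expression cutoff. No universal cutoff exists — it is the valley of the
max/median density of the dataset at hand; `suggest_median_cutoff`
implements that heuristic and the value is always overridable.

Census: genes are assigned to the TAD of maximum overlap; per-TAD tables
report gene counts, class composition, and the mean pairwise Pearson r of
non-ubiquitous genes (TADs with fewer than two are flagged and excluded);
summary fractions cover single- vs multi-gene TADs and the fraction of
scoreable TADs at or above a configurable "high co-regulation" cutoff
(default mean r ≥ 0.5; the threshold behind published "% of TADs highly
co-regulated" statements is not printed anywhere, so it is explicit
configuration here). Pair profiles sort same-chromosome gene pairs by
log10 TSS distance within intra-/inter-TAD strata and average in a
2,000-pair sliding window (smaller strata collapse to a flagged global
mean).

## Synthetic data: what it does and does not show

The generators plant exactly the structure each analysis is supposed to
recover: two-level DamID tracks with t-distributed noise, block binder
layouts, geometric phantoms with analytic volumes/overlaps/distances, and
expression matrices where non-ubiquitous genes of a TAD share one latent
factor (expected pairwise r = factor²/(factor²+noise²)). Passing tests
demonstrate the estimators are unbiased and the formulas exact under the
declared noise models; they do not demonstrate robustness to properties
real data have and the generators lack — mappability artefacts and
copy-number waves in DamID, optical aberrations, chromatic shift and
uneven background in microscopy, library-composition effects in CAGE, or
binder-type inference error in the polymer annotation (binding sites are
planted blocks, not inferred from contact maps; that inference is a
separate method and out of scope).

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; the pipeline derives one stream per stage
from the master seed by a (seed, stage-index) counter scheme, so stages
are reproducible independently of execution order, and manifests of two
runs with the same configuration are byte-identical (TIFF outputs are
written without timestamps for this reason). Problem sizes in the test
suite and acceptance script — 100-bead chains, 2×10⁵-step invariant runs,
10-seed adsorption replicates, 300-bin LAD tracks, 5,000-sample
expression matrices — are the package's desk-scale defaults chosen to
make the statistical checks sharp at interactive runtimes.
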