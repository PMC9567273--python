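# laminafold

Coarse-grained chromatin polymer modelling with nuclear-envelope (NE)
attachment, and the quantification stack that goes with it: DamID LAD
segmentation, polymer-ensemble contact maps and 3D geometry metrics, 3D
FISH volumetrics, and a genome-wide TAD co-expression census.

The package is aimed at researchers studying how lamina association shapes
locus architecture — e.g. a developmental TAD whose inactive portions
attach to the nuclear envelope in one cell type and detach in another —
who want a simulate-and-measure loop that mirrors how such loci are
analysed experimentally (capture Hi-C, DamID, Oligopaint FISH, CAGE).

## The model

**Strings-and-binders (SBS) polymer.** A locus is a chain of N beads of
diameter σ = 1 (one bead per 20 kb bin). Each bead carries at most one
binding-site type; free diffusing binders of the cognate type bridge beads
through a truncated attractive Lennard-Jones potential (depth E_int within
3.1–8.2 kBT, cutoff R_int = 1.3–1.5 σ, plus a weaker nonspecific
attraction of 2–3 kBT). Consecutive beads are linked by FENE bonds
(R0 = 1.6 σ, K = 30 kBT/σ²); all pairs repel through a WCA core. Beads and
binders evolve by Langevin dynamics (m = 1, kBT = 1, ζ = 0.5, Δt = 0.012),
integrated with the GJF scheme whose half-step velocities give an unbiased
kinetic temperature. Above a threshold in binder concentration and E_int
the chain undergoes the coil–globule transition.

**NE attachment.** After bulk equilibration the system is confined in a
sphere of radius R (40 σ at production scale). Beads whose 20 kb bin has a
positive mean DamID log2(Dam-LaminB1/Dam) signal feel a truncated
attractive LJ wall potential (E_NE, default 1.2 kBT, cutoff 2.5 σ); all
other particles see a purely repulsive wall.

**Quantification.** Contact maps threshold inter-bead distances at 7.5 σ;
NE distance is d_NE = R − |r_CM − r_NE|; projected pairwise and three-body
overlaps use the exact circle-intersection formula on 2D gyration radii;
sphericity is π^{1/3}(6V)^{2/3}/A on the convex hull; model σ units are
calibrated to nm by equalising model and experimental median pairwise
distances (44 nm/σ for the locus this model family was built for).

Around the simulator: a two-state Student-t HMM segments binned DamID
tracks into LADs; the FISH module segments two-channel 3D stacks
(anisotropic 40/125 nm voxels) and measures intermingling, Jaccard
overlap, merged-object sphericity and lamina distance; the co-expression
module collapses CAGE peaks to genes, merges correlated libraries into
metasamples, classifies ubiquitous vs non-ubiquitous genes and censuses
per-TAD co-regulation. A synthetic-data module generates every input with
planted ground truth.

## Worked example

`examples/03_ne_attachment.py` equilibrates a 60-bead polymer whose first
half is NE-attractive (LAD-like), attaches it to a desk-scale envelope
(R = 12 σ) at E_NE = 3 kBT and measures the result:

```
mean NE distance, attractive beads : 2.09 sigma
mean NE distance, repulsive beads  : 3.66 sigma
region NE distance (first half COM): 2.05 sigma
mean contact-map change after attachment: +0.0120
```

The DamID-positive half sits roughly 1.6 σ (≈ 70 nm at the 44 nm/σ
calibration) closer to the envelope than the repulsive half, and contact
frequencies rise on average once the chain is adsorbed — the same
readouts, on synthetic data, that distinguish an NE-attached from a
detached locus in imaging.

The other examples cover LAD calling (`01`), the coil–globule transition
(`02`), geometry metrics and calibration (`04`), FISH volumetrics (`05`),
the TAD census (`06`) and the reproducible end-to-end pipeline (`07`).
Each prints the numbers it computes and states what they mean. A thin CLI
(`laminafold synthgen|lads|simulate|quantify|fishquant|coexpr|run`) wraps
the same functions for shell use.

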