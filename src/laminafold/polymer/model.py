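"""Data model for the strings-and-binders (SBS) polymer simulation.

The chromatin fibre is a chain of ``n_beads`` beads of diameter sigma = 1
(dimensionless units).  Each bead carries at most one binding-site type;
diffusing binder particles of the cognate type bridge beads and drive the
coil--globule transition.  A per-bead nuclear-envelope (NE) affinity flag,
derived from DamID, decides whether the bead is attracted to the confining
spherical wall once the NE phase is switched on.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

INERT = -1  #: binding-site type id of beads with no specific binder


class SimulationError(RuntimeError):
    """Raised when the integrator detects a broken invariant.

    Carries a ``diagnostics`` dict (step reached, offending quantity) so a
    failed run can be inspected; a bond at or beyond the FENE divergence or a
    particle outside the NE sphere signals a too-large time step.
    """

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class PolymerSpec:
    """Bead annotations for one simulated locus.

    Parameters
    ----------
    type_of_bead:
        Integer array, one entry per bead; values in ``[0, n_types)`` or
        :data:`INERT` for beads without a specific binding site.
    ne_affinity:
        Boolean array; ``True`` marks beads attracted to the nuclear
        envelope (positive mean DamID signal in the matching 20 kb bin).
    chrom, start, bin_size:
        Genomic anchor: bead ``i`` represents
        ``[start + i*bin_size, start + (i+1)*bin_size)`` on ``chrom``.
    """

    type_of_bead: np.ndarray
    ne_affinity: np.ndarray
    chrom: str = "chrS"
    start: int = 0
    bin_size: int = 20_000

    def __post_init__(self):
        t = np.asarray(self.type_of_bead, dtype=np.int64)
        a = np.asarray(self.ne_affinity, dtype=bool)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("type_of_bead and ne_affinity must be equal-length 1D arrays")
        if t.size == 0:
            raise ValueError("empty polymer")
        if (t < INERT).any():
            raise ValueError("bead types must be >= -1")
        nonin = np.unique(t[t >= 0])
        if nonin.size and not np.array_equal(nonin, np.arange(nonin.size)):
            raise ValueError("non-inert type ids must be dense in [0, K)")
        object.__setattr__(self, "type_of_bead", t)
        object.__setattr__(self, "ne_affinity", a)

    @property
    def n_beads(self) -> int:
        return self.type_of_bead.size

    @property
    def n_types(self) -> int:
        t = self.type_of_bead
        return int(t.max()) + 1 if (t >= 0).any() else 0

    def binder_counts(self, binders_per_matching_bead: float = 0.5) -> np.ndarray:
        """Number of binders per type: default one binder per two matching beads."""
        counts = np.zeros(self.n_types, dtype=np.int64)
        for k in range(self.n_types):
            counts[k] = max(1, int(round(binders_per_matching_bead
                                         * int((self.type_of_bead == k).sum()))))
        return counts


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters in dimensionless (LJ) units.

    Energies are in units of kBT, lengths in bead diameters sigma, the unit
    of time is the standard LJ time.  Defaults follow the published model:
    bead/binder diameter sigma = 1, mass 1, temperature kBT = 1, friction
    0.5, time step 0.012; FENE bonds with R0 = 1.6 sigma and K = 30; specific
    bead--binder attraction within 3.1-8.2 kBT (single global default 5) at
    cutoff 1.3-1.5 sigma; weaker nonspecific attraction 2-3 kBT; NE sphere of
    radius 40 sigma with attachment energy 1.2 kBT at cutoff 2.5 sigma.

    Step counts default to desk scale (2e6 equilibration / 1e6 NE phase,
    sampled every 1e4); production-scale values (1e8 / 7e7, sampled every
    5e5) are plain configuration changes.
    """

    sigma: float = 1.0
    mass: float = 1.0
    kbt: float = 1.0
    friction: float = 0.5
    dt: float = 0.012
    e_int: float = 5.0
    e_ns: float = 2.5
    r_int: float = 1.5
    fene_r0: float = 1.6
    fene_k: float = 30.0
    binders_per_matching_bead: float = 0.5
    box_size: Optional[float] = None     # None -> from target number density
    number_density: float = 0.02         # particles per sigma^3 for default box
    ne_radius: float = 40.0
    e_ne: float = 1.2
    ne_cutoff: float = 2.5
    n_steps_equil: int = 2_000_000
    n_steps_ne: int = 1_000_000
    sample_every: int = 10_000
    equil_burnin: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.fene_r0 <= self.sigma:
            raise ValueError("FENE R0 must exceed sigma")
        for name in ("e_int", "e_ns", "e_ne", "kbt", "friction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)

    def box_for(self, n_particles: int) -> float:
        if self.box_size is not None:
            return float(self.box_size)
        return float((n_particles / self.number_density) ** (1.0 / 3.0))


@dataclass
class Configuration:
    """One snapshot: bead + binder coordinates and velocities (sigma units)."""

    pos: np.ndarray            # (n_beads + n_binders, 3)
    vel: np.ndarray
    n_beads: int
    binder_type: np.ndarray    # (n_binders,)
    frame_index: int = 0

    @property
    def bead_xyz(self) -> np.ndarray:
        return self.pos[: self.n_beads]

    @property
    def binder_xyz(self) -> np.ndarray:
        return self.pos[self.n_beads:]

    def copy(self) -> "Configuration":
        return Configuration(self.pos.copy(), self.vel.copy(), self.n_beads,
                             self.binder_type.copy(), self.frame_index)


@dataclass
class Trajectory:
    """Ordered sampled frames from one simulation phase.

    ``frames`` holds bead *and* binder coordinates, shape
    ``(n_frames, n_particles, 3)``; beads come first.  ``phase`` is ``"bulk"``
    (periodic box, no wall) or ``"ne"`` (spherical confinement).
    """

    frames: np.ndarray
    n_beads: int
    spec: PolymerSpec
    params: SimParams
    phase: str
    binder_type: np.ndarray
    final: Configuration
    kinetic_temperature: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def bead_frames(self) -> np.ndarray:
        return self.frames[:, : self.n_beads, :]
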