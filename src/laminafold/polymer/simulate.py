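"""Drivers for the SBS polymer simulation: initialisation, stepping, phases.

A run has two phases.  The *bulk* phase equilibrates polymer + binders in a
cubic periodic box; with binders present and a specific attraction above the
coil--globule threshold the chain collapses.  The *NE* phase then confines
the equilibrated system in a sphere of radius R (default 40 sigma) whose
wall attracts DamID-positive beads.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from ._kernel import run_steps
from .model import Configuration, PolymerSpec, SimParams, SimulationError, Trajectory

_STATUS_MSG = {
    1: "FENE bond reached R0 (integration failure; reduce dt)",
    2: "particle escaped the NE sphere (integration failure)",
    3: "non-finite coordinate (integration failure)",
}


def _chunk_seeds(seed: int, n: int, salt: int) -> np.ndarray:
    """Independent uint32 streams for successive kernel calls."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, salt])
    return ss.generate_state(max(n, 1)).astype(np.uint32)


def init_saw(spec: PolymerSpec, params: SimParams, seed: Optional[int] = None,
             box_size: Optional[float] = None, max_retries: int = 500) -> Configuration:
    """Initial configuration: self-avoiding walk chain + uniformly placed binders.

    Bond lengths are drawn in [0.8, 1.2] sigma and every non-bonded bead pair
    is kept at >= 0.9 sigma; binder positions are uniform in the box,
    resampled only if they overlap a bead closer than 0.95 sigma so the first
    force evaluation is finite.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 101]))
    n = spec.n_beads
    counts = spec.binder_counts(params.binders_per_matching_bead)
    n_bind = int(counts.sum())
    box = params.box_for(n + n_bind) if box_size is None else float(box_size)

    def _mi_dist(arr: np.ndarray, cand: np.ndarray) -> float:
        d = arr - cand
        d -= box * np.rint(d / box)       # minimum image: forces are periodic
        return float(np.sqrt((d * d).sum(axis=1)).min())

    pos = np.zeros((n, 3))
    i, stuck, backoffs = 1, 0, 0
    while i < n:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        cand = pos[i - 1] + rng.uniform(0.8, 1.2) * u
        inside = bool((np.abs(cand) <= 0.5 * box).all())
        ok = inside and (i < 2 or _mi_dist(pos[: i - 1], cand) >= 0.9)
        if ok:
            pos[i] = cand
            i += 1
            stuck = 0
        else:
            stuck += 1
            if stuck > max_retries:
                i = max(1, i - 10)      # back off and regrow
                stuck = 0
                backoffs += 1
                if backoffs > max_retries:
                    raise SimulationError(
                        "self-avoiding walk placement failed",
                        {"placed": i, "n_beads": n, "backoffs": backoffs})

    binder_type = np.repeat(np.arange(counts.size, dtype=np.int64), counts)
    bpos = np.empty((n_bind, 3))
    for j in range(n_bind):
        for _ in range(max_retries):
            cand = rng.uniform(-box / 2, box / 2, size=3)
            clear = _mi_dist(pos, cand) >= 0.95
            if clear and j > 0:
                clear = _mi_dist(bpos[:j], cand) >= 0.95
            if clear:
                bpos[j] = cand
                break
        else:
            raise SimulationError("binder placement failed",
                                  {"binder": j, "box": box})
    allpos = np.vstack([pos, bpos])
    vel = rng.normal(scale=np.sqrt(params.kbt / params.mass), size=allpos.shape)
    return Configuration(allpos, vel, n, binder_type)


def step_langevin(state: Configuration, spec: PolymerSpec, params: SimParams,
                  n_steps: int, ne_active: bool = False, seed: int = 0,
                  box: Optional[float] = None) -> float:
    """Advance ``state`` in place by ``n_steps``; returns the kinetic
    temperature (from 2GJ half-step velocities) over the chunk.

    Raises :class:`SimulationError` on broken bonds, wall escape or
    non-finite coordinates.
    """
    n_tot = state.pos.shape[0]
    box = params.box_for(n_tot) if box is None else float(box)
    frc = np.zeros_like(state.pos)
    acc = np.zeros(2)
    ne_attr = spec.ne_affinity.astype(np.int64)
    status = run_steps(
        state.pos, state.vel, frc, acc, spec.type_of_bead, state.binder_type,
        ne_attr, state.n_beads, params.e_int, params.e_ns, params.r_int,
        params.fene_k, params.fene_r0, params.mass, params.friction,
        params.kbt, params.dt, int(n_steps), box, not ne_active, ne_active,
        params.ne_radius, params.e_ne, params.ne_cutoff, np.uint32(seed))
    if status != 0:
        raise SimulationError(_STATUS_MSG[status], {
            "status": status, "phase": "ne" if ne_active else "bulk",
            "frame_index": state.frame_index,
            "max_radius": float(np.linalg.norm(state.pos, axis=1).max()),
        })
    if acc[1] > 0:
        return float(acc[0] / (acc[1] * 3 * n_tot))
    return float("nan")


def _sample_phase(state: Configuration, spec: PolymerSpec, params: SimParams,
                  n_steps: int, burnin: int, ne_active: bool,
                  seed_salt: int, box: Optional[float]) -> Trajectory:
    sample = max(1, min(params.sample_every, n_steps))
    n_chunks_burn = int(np.ceil(burnin / sample)) if burnin else 0
    n_chunks = int(np.ceil(n_steps / sample))
    seeds = _chunk_seeds(params.seed, n_chunks_burn + n_chunks, seed_salt)
    temps = []
    for c in range(n_chunks_burn):
        step_langevin(state, spec, params, sample, ne_active, seeds[c], box)
    frames = np.empty((n_chunks, state.pos.shape[0], 3))
    for c in range(n_chunks):
        t = step_langevin(state, spec, params, sample, ne_active,
                          seeds[n_chunks_burn + c], box)
        temps.append(t)
        frames[c] = state.pos
        state.frame_index += 1
    return Trajectory(frames, state.n_beads, spec, params,
                      "ne" if ne_active else "bulk", state.binder_type.copy(),
                      state, float(np.mean(temps)))


def run_equilibration(spec: PolymerSpec, params: SimParams,
                      state: Optional[Configuration] = None) -> Trajectory:
    """Bulk-phase run: SAW init, burn-in, then sampled frames every
    ``params.sample_every`` steps for ``params.n_steps_equil`` steps."""
    if state is None:
        state = init_saw(spec, params)
    return _sample_phase(state, spec, params, params.n_steps_equil,
                         params.equil_burnin, ne_active=False,
                         seed_salt=11, box=None)


def attach_ne(state: Configuration, spec: PolymerSpec, params: SimParams) -> Trajectory:
    """NE-phase run from an equilibrated bulk configuration.

    The system is re-centred on the bead centre of mass, binders are wrapped
    into the periodic image nearest the polymer, and everything must fit
    strictly inside the sphere of radius ``params.ne_radius``.
    """
    box = params.box_for(state.pos.shape[0])
    com = state.bead_xyz.mean(axis=0)
    state.pos -= com
    bind = state.pos[state.n_beads:]
    bind -= box * np.rint(bind / box)
    # binders are retained inside the sphere: any that the periodic box
    # placed beyond the wall is pulled radially inward
    br = np.linalg.norm(bind, axis=1)
    outside = br > params.ne_radius - 1.0
    if outside.any():
        bind[outside] *= ((params.ne_radius - 1.0) / br[outside])[:, None]
        for j in np.flatnonzero(outside):     # resolve any landing overlap
            k = state.n_beads + j
            others = np.delete(state.pos, k, axis=0)
            for _ in range(40):
                if np.linalg.norm(others - state.pos[k], axis=1).min() >= 0.95:
                    break
                state.pos[k] *= max(1.0 - 0.5 / np.linalg.norm(state.pos[k]),
                                    0.05)
    rmax = float(np.linalg.norm(state.pos[: state.n_beads], axis=1).max())
    if rmax >= params.ne_radius - 0.6:
        raise SimulationError(
            "configuration does not fit inside the NE sphere",
            {"max_radius": rmax, "ne_radius": params.ne_radius})
    return _sample_phase(state, spec, params, params.n_steps_ne,
                         burnin=0, ne_active=True, seed_salt=13, box=box)
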