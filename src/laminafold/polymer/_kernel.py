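"""Numba force/integration kernel for the SBS Langevin dynamics.

Forces: FENE bonds along the chain, WCA hard core between all pairs,
truncated-and-shifted attractive LJ between beads and binders (depth e_int
for matching binding-site types, e_ns for any other bead-binder pair), and
an optional spherical wall felt along the inward radial direction (LJ with
depth e_ne for NE-attractive beads, WCA for everything else).

Integration is the GJF (Gronbech-Jensen/Farago) Langevin scheme; the 2GJ
half-step velocity, whose stationary distribution is Maxwellian to high
accuracy even for stiff bonded forces, is accumulated for the kinetic
temperature diagnostic.  One force evaluation per step.

Status codes returned by :func:`run_steps`: 0 ok, 1 FENE bond reached R0,
2 particle outside the NE sphere, 3 non-finite coordinate.
"""
import numpy as np
from numba import njit

WCA_CUT2 = 2.0 ** (1.0 / 3.0)   # (2^(1/6))^2


@njit(cache=True, fastmath=False)
def _forces(pos, frc, bead_type, binder_type, ne_attr, n_beads,
            e_int, e_ns, r_int, k_fene, r0sq,
            box, pbc, ne_on, R_ne, e_ne, rc_ne):
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    ri2 = r_int * r_int
    cut2 = ri2 if ri2 > WCA_CUT2 else WCA_CUT2
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if pbc:
                dx -= box * np.rint(dx / box)
                dy -= box * np.rint(dy / box)
                dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cut2 or r2 < 1e-12:
                continue
            eps = -1.0          # <=0 means plain WCA
            rc2 = WCA_CUT2
            if i < n_beads and j >= n_beads:
                bt = bead_type[i]
                st = binder_type[j - n_beads]
                if bt >= 0 and bt == st:
                    if e_int > 0.0:
                        eps = e_int
                        rc2 = ri2
                elif e_ns > 0.0:
                    eps = e_ns
                    rc2 = ri2
            if r2 >= rc2:
                continue
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            f = 24.0 * inv2 * (2.0 * inv6 * inv6 - inv6)
            if eps > 0.0:
                f *= eps
            frc[i, 0] += f * dx
            frc[i, 1] += f * dy
            frc[i, 2] += f * dz
            frc[j, 0] -= f * dx
            frc[j, 1] -= f * dy
            frc[j, 2] -= f * dz
    for i in range(n_beads - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r0sq:
            return 1
        f = -k_fene / (1.0 - r2 / r0sq)
        frc[i, 0] += f * dx
        frc[i, 1] += f * dy
        frc[i, 2] += f * dz
        frc[i + 1, 0] -= f * dx
        frc[i + 1, 1] -= f * dy
        frc[i + 1, 2] -= f * dz
    if ne_on:
        wca_cut = 2.0 ** (1.0 / 6.0)
        for i in range(n):
            r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            s = R_ne - r
            if s <= 0.0:
                return 2
            attractive = (i < n_beads) and (ne_attr[i] == 1) and (e_ne > 0.0)
            rc = rc_ne if attractive else wca_cut
            if s >= rc:
                continue
            inv2 = 1.0 / (s * s)
            inv6 = inv2 * inv2 * inv2
            fm = 24.0 / s * (2.0 * inv6 * inv6 - inv6)
            if attractive:
                fm *= e_ne
            if r > 1e-12:
                # force along -r_hat when fm>0 (wall pushes inward)
                frc[i, 0] -= fm * pos[i, 0] / r
                frc[i, 1] -= fm * pos[i, 1] / r
                frc[i, 2] -= fm * pos[i, 2] / r
    return 0


@njit(cache=True, fastmath=False)
def run_steps(pos, vel, frc, acc, bead_type, binder_type, ne_attr, n_beads,
              e_int, e_ns, r_int, k_fene, r0, mass, gamma, kbt, dt, n_steps,
              box, pbc, ne_on, R_ne, e_ne, rc_ne, seed):
    """Advance n_steps of GJF Langevin dynamics in place.

    acc[0] += sum over steps/dofs of half-step velocity squared,
    acc[1] += number of steps (for the kinetic temperature estimate).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    a = (1.0 - 0.5 * gamma * dt / mass) / (1.0 + 0.5 * gamma * dt / mass)
    b = 1.0 / (1.0 + 0.5 * gamma * dt / mass)
    sb = np.sqrt(b)
    sig = np.sqrt(2.0 * gamma * kbt * dt)
    r0sq = r0 * r0
    st = _forces(pos, frc, bead_type, binder_type, ne_attr, n_beads, e_int,
                 e_ns, r_int, k_fene, r0sq, box, pbc, ne_on, R_ne, e_ne, rc_ne)
    if st != 0:
        return st
    for _ in range(n_steps):
        ssum = 0.0
        for i in range(n):
            for k in range(3):
                beta = sig * np.random.normal()
                step = (b * dt * vel[i, k]
                        + 0.5 * b * dt * dt * frc[i, k] / mass
                        + 0.5 * b * dt * beta / mass)
                pos[i, k] += step
                if not np.isfinite(pos[i, k]):
                    return 3
                u = step / (sb * dt)
                ssum += u * u
                vel[i, k] = (a * vel[i, k]
                             + 0.5 * dt * a * frc[i, k] / mass
                             + b * beta / mass)
        st = _forces(pos, frc, bead_type, binder_type, ne_attr, n_beads,
                     e_int, e_ns, r_int, k_fene, r0sq, box, pbc, ne_on,
                     R_ne, e_ne, rc_ne)
        if st != 0:
            return st
        for i in range(n):
            for k in range(3):
                vel[i, k] += 0.5 * dt * frc[i, k] / mass
        acc[0] += mass * ssum
        acc[1] += 1.0
    return 0
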