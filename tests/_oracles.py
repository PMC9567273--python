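"""Independent test oracles, kept free of the implementation under test."""
import numpy as np
from numba import njit


@njit(cache=True)
def mc_circle_overlap(r1, r2, d, n_points, seed):
    """Monte-Carlo rasterization estimate of overlap12 = A12/(A1+A2-A12).

    Circle 1 is centred at the origin, circle 2 at (d, 0).  Points are
    sampled uniformly in the bounding square of the smaller circle (which
    contains the whole intersection), so only A12 carries sampling noise;
    A1 and A2 are exact.  Uses an inline xorshift128+ stream (one 64-bit
    draw per point, split into the two coordinates) for throughput.
    """
    if r1 <= r2:
        rs, cx = r1, 0.0
    else:
        rs, cx = r2, d
    s0 = np.uint64(seed * np.uint64(0x9E3779B97F4A7C15) + np.uint64(1))
    s1 = np.uint64(seed * np.uint64(0xBF58476D1CE4E5B9) + np.uint64(0x94D049BB133111EB))
    inv32 = 1.0 / 4294967296.0
    mask32 = np.uint64(0xFFFFFFFF)
    hits = 0
    for _ in range(n_points):
        # xorshift128+
        x64 = s0
        y64 = s1
        s0 = y64
        x64 ^= x64 << np.uint64(23)
        s1 = x64 ^ y64 ^ (x64 >> np.uint64(17)) ^ (y64 >> np.uint64(26))
        v = s1 + y64
        ux = np.float64(v & mask32) * inv32
        uy = np.float64(v >> np.uint64(32)) * inv32
        x = cx + (2.0 * ux - 1.0) * rs
        y = (2.0 * uy - 1.0) * rs
        if x * x + y * y <= r1 * r1:
            dx = x - d
            if dx * dx + y * y <= r2 * r2:
                hits += 1
    a12 = hits / n_points * (2.0 * rs) ** 2
    a1 = np.pi * r1 * r1
    a2 = np.pi * r2 * r2
    return a12 / (a1 + a2 - a12)


@njit(cache=True)
def mc_sphere_overlap_volume(c1z, c1y, c1x, r1, c2z, c2y, c2x, r2,
                             n_points, seed):
    """Monte-Carlo overlap volume of two spheres (sampling in sphere 1's
    bounding cube)."""
    np.random.seed(seed)
    hits = 0
    for _ in range(n_points):
        z = c1z + (2.0 * np.random.random() - 1.0) * r1
        y = c1y + (2.0 * np.random.random() - 1.0) * r1
        x = c1x + (2.0 * np.random.random() - 1.0) * r1
        if ((z - c1z) ** 2 + (y - c1y) ** 2 + (x - c1x) ** 2 <= r1 * r1
                and (z - c2z) ** 2 + (y - c2y) ** 2 + (x - c2x) ** 2 <= r2 * r2):
            hits += 1
    return hits / n_points * (2.0 * r1) ** 3
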