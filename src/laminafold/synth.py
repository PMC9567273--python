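"""Synthetic inputs with known ground truth.

Each generator emulates the statistical structure of one real input of the
analysis stack -- binder-type annotations for the polymer, DamID log2
tracks with planted LADs and heavy-tailed noise, two-channel nucleus image
volumes with a lamina shell, expression matrices with a planted intra-TAD
factor, and block-structured contact maps -- and returns a
:class:`SyntheticTruth` record rich enough to compute every downstream
metric analytically in the zero-noise limit.  All generators are
deterministic given (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .coexpr import ExpressionSet, NON_UBIQ, UBIQ
from .damid import BinTrack
from .polymer import INERT, PolymerSpec

Interval = Tuple[int, int]


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator (JSON-serialisable content)."""

    lad_intervals: List[Interval] = field(default_factory=list)
    binder_blocks: List[Tuple[Interval, int]] = field(default_factory=list)
    object_geometry: Dict[str, object] = field(default_factory=dict)
    coexpr_factors: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lad_intervals": [list(map(int, iv)) for iv in self.lad_intervals],
            "binder_blocks": [[list(map(int, iv)), int(t)]
                              for iv, t in self.binder_blocks],
            "object_geometry": self.object_geometry,
            "coexpr_factors": self.coexpr_factors,
        }


def _check_intervals(intervals: Sequence[Interval], n: int, what: str) -> None:
    ivs = sorted(intervals)
    for a, b in ivs:
        if not (0 <= a < b <= n):
            raise ValueError(f"{what} interval ({a},{b}) outside [0,{n})")
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 < b1:
            raise ValueError(f"overlapping {what} intervals "
                             f"({a1},{b1}) and ({a2},{b2})")


# ---------------------------------------------------------------------------
# polymer spec
# ---------------------------------------------------------------------------

def make_polymer_spec(n_beads: int, n_types: int = 13,
                      block_layout: Optional[Sequence[Tuple[Interval, int]]] = None,
                      inert_fraction: float = 0.0, seed: int = 0,
                      chrom: str = "chrS", start: int = 0,
                      bin_size: int = 20_000) -> Tuple[PolymerSpec, SyntheticTruth]:
    """Block-structured binder-type annotation standing in for inferred
    binding sites (the published locus model uses 13 distinct types).

    Without an explicit ``block_layout`` the chain is tiled with ``n_types``
    contiguous equal blocks.  Beads left uncovered by the layout are inert;
    ``inert_fraction`` additionally flips a random subset of covered beads
    to inert.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    if not 0 <= inert_fraction <= 1:
        raise ValueError("inert_fraction must be in [0,1]")
    if block_layout is None:
        edges = np.linspace(0, n_beads, n_types + 1).astype(int)
        block_layout = [((int(edges[k]), int(edges[k + 1])), k)
                        for k in range(n_types) if edges[k] < edges[k + 1]]
    _check_intervals([iv for iv, _ in block_layout], n_beads, "block")
    for iv, t in block_layout:
        if not 0 <= t < n_types:
            raise ValueError(f"block type {t} outside [0,{n_types})")

    types = np.full(n_beads, INERT, dtype=np.int64)
    for (a, b), t in block_layout:
        types[a:b] = t
    rng = np.random.default_rng(seed)
    if inert_fraction > 0:
        covered = np.flatnonzero(types >= 0)
        k = int(round(inert_fraction * covered.size))
        types[rng.choice(covered, size=k, replace=False)] = INERT
    # re-densify type ids in case a whole type was erased
    used = np.unique(types[types >= 0])
    remap = {int(t): i for i, t in enumerate(used)}
    types = np.array([remap.get(int(t), INERT) for t in types], dtype=np.int64)
    spec = PolymerSpec(types, np.zeros(n_beads, dtype=bool), chrom, start, bin_size)
    truth = SyntheticTruth(binder_blocks=[(iv, remap.get(t, INERT))
                                          for iv, t in block_layout])
    return spec, truth


# ---------------------------------------------------------------------------
# DamID track
# ---------------------------------------------------------------------------

def make_damid_track(n_bins: int, lad_intervals: Sequence[Interval],
                     mu_in: float = 1.0, mu_out: float = -1.0,
                     noise_df: float = 3.0, noise_scale: float = 0.4,
                     seed: int = 0, chrom: str = "chrS", start: int = 0,
                     bin_size: int = 20_000) -> Tuple[BinTrack, SyntheticTruth]:
    """DamID log2 track with planted LAD blocks and Student-t noise.

    Bins inside a planted LAD have location ``mu_in``, the rest ``mu_out``;
    noise is ``noise_scale`` times a t(df=noise_df) variate, matching the
    heavy-tailed emissions the LAD caller assumes.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if mu_in <= mu_out:
        raise ValueError("mu_in must exceed mu_out")
    _check_intervals(lad_intervals, n_bins, "LAD")
    rng = np.random.default_rng(seed)
    vals = np.full(n_bins, float(mu_out))
    for a, b in lad_intervals:
        vals[a:b] = mu_in
    if noise_scale > 0:
        vals = vals + noise_scale * rng.standard_t(noise_df, size=n_bins)
    track = BinTrack(chrom, start, start + n_bins * bin_size, bin_size, vals)
    return track, SyntheticTruth(lad_intervals=list(lad_intervals))


# ---------------------------------------------------------------------------
# nucleus volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageObject:
    """Planted sphere/ellipsoid: center in um (z,y,x), radii in um, channel."""

    center_um: Tuple[float, float, float]
    radius_um: float
    channel: str
    radii_um: Optional[Tuple[float, float, float]] = None   # ellipsoid

    @property
    def radii(self) -> Tuple[float, float, float]:
        return self.radii_um if self.radii_um is not None else (
            self.radius_um,) * 3

    @property
    def volume_um3(self) -> float:
        rz, ry, rx = self.radii
        return 4.0 / 3.0 * np.pi * rz * ry * rx


def _sphere_overlap_volume(c1, r1, c2, r2) -> float:
    d = float(np.linalg.norm(np.asarray(c1) - np.asarray(c2)))
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rm = min(r1, r2)
        return 4.0 / 3.0 * np.pi * rm ** 3
    return (np.pi * (r1 + r2 - d) ** 2
            * (d * d + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2) / (12 * d))


def make_nucleus_volume(shape: Tuple[int, int, int] = (40, 128, 128),
                        voxel_size_nm: Tuple[float, float] = (40.0, 125.0),
                        objects: Sequence[ImageObject] = (),
                        lamina_shell: Optional[Tuple[float, float]] = None,
                        intensity: Tuple[float, float] = (1000.0, 100.0),
                        psf_sigma: float = 1.0, noise_sd: float = 5.0,
                        seed: int = 0) -> Tuple[Dict[str, np.ndarray], SyntheticTruth]:
    """Two-channel nucleus image stack with known object geometry.

    ``shape`` is (z, y, x) voxels; ``voxel_size_nm`` is (xy, z) following the
    acquisition defaults of 40 nm reconstructed pixels and a 125 nm z-step.
    Objects are rendered at ``peak`` intensity over ``background``, blurred
    with an isotropic Gaussian PSF of ``psf_sigma`` voxels and given additive
    Gaussian read noise.  ``lamina_shell=(inner_radius_um, thickness_um)``
    adds a spherical shell channel ``"lamin"`` centred in the volume.

    Returns per-channel float arrays plus a truth record with analytic
    volumes, pairwise sphere overlap volumes, and centroid-to-lamina
    distances.
    """
    xy_nm, z_nm = voxel_size_nm
    spacing = np.array([z_nm, xy_nm, xy_nm]) / 1000.0   # um per voxel, (z,y,x)
    extent = np.asarray(shape) * spacing
    peak, background = intensity
    rng = np.random.default_rng(seed)

    zz, yy, xx = np.meshgrid(*[(np.arange(s) + 0.5) * sp
                               for s, sp in zip(shape, spacing)], indexing="ij")
    channels: Dict[str, np.ndarray] = {}
    geom: Dict[str, object] = {"objects": [], "voxel_size_nm": list(voxel_size_nm)}

    for k, ob in enumerate(objects):
        c = np.asarray(ob.center_um)
        radii = np.asarray(ob.radii)
        if ((c - radii) < 0).any() or ((c + radii) > extent).any():
            raise ValueError(f"object {k} does not fit inside the volume "
                             f"(extent {extent} um)")
        mask = (((zz - c[0]) / radii[0]) ** 2 + ((yy - c[1]) / radii[1]) ** 2
                + ((xx - c[2]) / radii[2]) ** 2) <= 1.0
        img = channels.setdefault(ob.channel, np.full(shape, float(background)))
        img[mask] = peak
        geom["objects"].append({
            "channel": ob.channel, "center_um": [float(v) for v in c],
            "radii_um": [float(v) for v in radii],
            "volume_um3": float(ob.volume_um3)})

    overlaps = []
    for a in range(len(objects)):
        for b in range(a + 1, len(objects)):
            oa, ob_ = objects[a], objects[b]
            if oa.radii_um is None and ob_.radii_um is None:
                v = _sphere_overlap_volume(oa.center_um, oa.radius_um,
                                           ob_.center_um, ob_.radius_um)
                overlaps.append({"pair": [a, b], "volume_um3": float(v)})
    geom["pairwise_overlap_um3"] = overlaps

    if lamina_shell is not None:
        inner, thick = lamina_shell
        center = extent / 2.0
        r = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                    + (xx - center[2]) ** 2)
        shell = (r >= inner) & (r <= inner + thick)
        img = np.full(shape, float(background))
        img[shell] = peak
        channels["lamin"] = img
        geom["lamina"] = {"center_um": [float(v) for v in center],
                          "inner_radius_um": float(inner),
                          "thickness_um": float(thick)}
        for rec, ob in zip(geom["objects"], objects):
            d = inner - float(np.linalg.norm(np.asarray(ob.center_um) - center))
            rec["centroid_to_lamina_um"] = d

    for name, img in channels.items():
        if psf_sigma > 0:
            img = gaussian_filter(img, sigma=psf_sigma)
        if noise_sd > 0:
            img = img + rng.normal(scale=noise_sd, size=img.shape)
        channels[name] = img
    return channels, SyntheticTruth(object_geometry=geom)


# ---------------------------------------------------------------------------
# expression set
# ---------------------------------------------------------------------------

def make_expression_set(n_genes: int, n_samples: int,
                        tads: Sequence[Interval],
                        frac_ubiq: float = 0.3, factor_sd: float = 1.0,
                        noise_sd: float = 1.0,
                        coregulated_tads: Optional[Sequence[int]] = None,
                        seed: int = 0, chrom: str = "chrS",
                        baseline_non_ubiq: float = 20.0,
                        baseline_ubiq: float = 100.0,
                        ) -> Tuple[ExpressionSet, SyntheticTruth]:
    """Expression matrix with a planted shared factor inside chosen TADs.

    Genes are spread over the TAD intervals (bp coordinates; every TAD hosts
    at least one gene).  Non-ubiquitous genes in a co-regulated TAD share a
    per-sample latent factor with unit loading and SD ``factor_sd`` plus
    independent noise of SD ``noise_sd``, so their expected pairwise Pearson
    correlation is ``factor_sd**2 / (factor_sd**2 + noise_sd**2)``.
    Ubiquitous genes sit at a high flat baseline.
    """
    if not 0 <= frac_ubiq <= 1:
        raise ValueError("frac_ubiq must be in [0,1]")
    tads = [tuple(map(int, t)) for t in tads]
    _check_intervals(tads, max(e for _, e in tads), "TAD")
    if n_genes < len(tads):
        raise ValueError("need at least one gene per TAD")
    if coregulated_tads is None:
        coregulated_tads = list(range(len(tads)))
    rng = np.random.default_rng(seed)

    tad_of_gene = np.arange(n_genes) % len(tads)
    tad_of_gene.sort()
    names, rows = [], []
    per_tad_counter: Dict[int, int] = {}
    counts = np.bincount(tad_of_gene, minlength=len(tads))
    for gi, ti in enumerate(tad_of_gene):
        a, b = tads[ti]
        j = per_tad_counter.get(ti, 0)
        per_tad_counter[ti] = j + 1
        pos = a + int((j + 1) * (b - a) / (counts[ti] + 1))
        names.append(f"g{gi:04d}")
        rows.append(dict(chrom=chrom, start=pos, end=pos + 1000,
                         strand="+", tss=pos))
    genes = pd.DataFrame(rows, index=names)

    n_ubiq = int(round(frac_ubiq * n_genes))
    ubiq_mask = np.zeros(n_genes, dtype=bool)
    ubiq_mask[rng.choice(n_genes, size=n_ubiq, replace=False)] = True

    mat = np.empty((n_genes, n_samples))
    factors = {ti: rng.normal(scale=factor_sd, size=n_samples)
               if factor_sd > 0 else np.zeros(n_samples)
               for ti in coregulated_tads}
    for gi in range(n_genes):
        if ubiq_mask[gi]:
            mat[gi] = baseline_ubiq + rng.normal(scale=noise_sd, size=n_samples)
        else:
            x = baseline_non_ubiq + rng.normal(scale=noise_sd, size=n_samples)
            ti = int(tad_of_gene[gi])
            if ti in factors:
                x = x + factors[ti]
            mat[gi] = x
    mat = np.clip(mat, 0.0, None)

    matrix = pd.DataFrame(mat, index=names,
                          columns=[f"s{j:04d}" for j in range(n_samples)])
    tad_df = pd.DataFrame([dict(chrom=chrom, start=a, end=b) for a, b in tads])
    ubiq = pd.Series(np.where(ubiq_mask, UBIQ, NON_UBIQ), index=names,
                     name="ubiquity")
    es = ExpressionSet(matrix, genes, tad_df, ubiq)
    rho = (factor_sd ** 2 / (factor_sd ** 2 + noise_sd ** 2)
           if factor_sd ** 2 + noise_sd ** 2 > 0 else 0.0)
    truth = SyntheticTruth(coexpr_factors={
        "expected_rho": float(rho),
        "factor_sd": float(factor_sd), "noise_sd": float(noise_sd),
        "coregulated_tads": [int(t) for t in coregulated_tads],
        "tad_of_gene": [int(t) for t in tad_of_gene],
        "ubiq_genes": [names[i] for i in range(n_genes) if ubiq_mask[i]],
    })
    return es, truth


# ---------------------------------------------------------------------------
# contact map
# ---------------------------------------------------------------------------

def make_block_contact_map(n_bins: int, boundaries: Sequence[int],
                           within_level: float = 1.0,
                           between_level: float = 0.2,
                           decay_exponent: float = 1.0,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> np.ndarray:
    """Block contact map with power-law distance decay.

    Entry (i,j) is ``level / (1 + |i-j|)**decay_exponent`` where ``level``
    is ``within_level`` when i and j fall in the same block (blocks are
    delimited by ``boundaries``) and ``between_level`` otherwise; optional
    multiplicative log-normal noise, symmetrised.
    """
    if within_level <= 0 or between_level <= 0:
        raise ValueError("levels must be positive")
    bnd = sorted(int(b) for b in boundaries)
    if bnd and (bnd[0] <= 0 or bnd[-1] >= n_bins):
        raise ValueError("boundaries must lie strictly inside (0, n_bins)")
    edges = np.array([0] + bnd + [n_bins])
    block = np.searchsorted(edges, np.arange(n_bins), side="right") - 1
    i, j = np.meshgrid(np.arange(n_bins), np.arange(n_bins), indexing="ij")
    level = np.where(block[i] == block[j], within_level, between_level)
    m = level / (1.0 + np.abs(i - j)) ** decay_exponent
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ln = np.exp(rng.normal(scale=noise_sd, size=m.shape))
        ln = np.sqrt(ln * ln.T)            # symmetric noise field
        m = m * ln
    return 0.5 * (m + m.T)
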