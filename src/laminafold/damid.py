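"""DamID processing and LAD segmentation.

DamID tethers Dam methyltransferase to Lamin B1; reads mapped to DpnII
(GATC) restriction fragments report nuclear-envelope contact.  The pipeline
here mirrors the standard analysis: per-fragment RPKM for the Dam-LaminB1
and Dam-only channels, their log2 ratio, length-weighted binning into 20 kb
windows, two-state hidden-Markov segmentation of the binned track into
LAD / non-LAD states with Student-t emissions, percentile ranking of LAD
strength, and the per-bead attractive/repulsive nuclear-envelope affinity
used by the polymer model (positive mean DamID signal -> attractive).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata

_MIN_SCALE = 1e-4


@dataclass(frozen=True)
class FragmentCounts:
    """Read counts per GATC restriction fragment for both DamID channels."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    counts_lmnb1: np.ndarray
    counts_dam: np.ndarray
    total_lmnb1: int
    total_dam: int

    def __post_init__(self):
        s = np.asarray(self.starts, dtype=np.int64)
        e = np.asarray(self.ends, dtype=np.int64)
        if (e <= s).any():
            raise ValueError("zero- or negative-length fragment")
        if (np.diff(s) < 0).any():
            raise ValueError("fragments must be sorted by start")
        if (s[1:] < e[:-1]).any():
            raise ValueError("fragments overlap")
        for name, c, tot in (("lmnb1", self.counts_lmnb1, self.total_lmnb1),
                             ("dam", self.counts_dam, self.total_dam)):
            c = np.asarray(c)
            if (c < 0).any():
                raise ValueError(f"negative counts in channel {name}")
            if tot < c.sum():
                raise ValueError(f"total reads below summed counts ({name})")
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "ends", e)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts


@dataclass
class BinTrack:
    """Fixed-width binned scalar track over a genomic window.

    The window is 0-based half-open; the trailing partial bin is dropped, so
    ``n_bins = (end - start) // bin_size``.  Missing bins are NaN.
    """

    chrom: str
    start: int
    end: int
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        n = (self.end - self.start) // self.bin_size
        v = np.asarray(self.values, dtype=float)
        if v.size != n:
            raise ValueError(f"expected {n} bins for window, got {v.size}")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_interval(self, i: int) -> Tuple[int, int]:
        s = self.start + i * self.bin_size
        return s, s + self.bin_size


@dataclass
class LadSegmentation:
    """Per-bin LAD states plus merged intervals with scores and percentiles."""

    track: BinTrack
    states: np.ndarray                  # 1 = LAD, 0 = non-LAD, -1 = missing
    intervals: List[Tuple[int, int]]    # bin-index intervals, half-open
    scores: np.ndarray                  # mean log2 per LAD interval
    percentiles: np.ndarray             # mean-rank percentile of each score
    converged: bool = True
    n_iter: int = 0


def fragment_rpkm(fc: FragmentCounts, channel: str) -> np.ndarray:
    """Reads per kilobase of fragment per million mapped reads."""
    if channel == "lmnb1":
        counts, total = fc.counts_lmnb1, fc.total_lmnb1
    elif channel == "dam":
        counts, total = fc.counts_dam, fc.total_dam
    else:
        raise ValueError("channel must be 'lmnb1' or 'dam'")
    if total <= 0:
        raise ValueError("total mapped reads must be positive")
    return np.asarray(counts, dtype=float) / (
        (fc.lengths / 1e3) * (total / 1e6))


def log2_ratio(lmnb1_rpkm: np.ndarray, dam_rpkm: np.ndarray,
               pseudocount: float = 0.1) -> np.ndarray:
    """log2((LmnB1 + p) / (Dam + p)); the pseudocount keeps zeros finite."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2((np.asarray(lmnb1_rpkm, float) + pseudocount)
                   / (np.asarray(dam_rpkm, float) + pseudocount))


def bin_track(fragment_starts: np.ndarray, fragment_ends: np.ndarray,
              fragment_values: np.ndarray, chrom: str, start: int, end: int,
              bin_size: int = 20_000) -> BinTrack:
    """Length-weighted mean of fragment values in each bin of the window.

    Bins with no overlapping fragment are NaN; a window entirely outside the
    fragment span yields an all-NaN track with a warning.
    """
    fs = np.asarray(fragment_starts, dtype=np.int64)
    fe = np.asarray(fragment_ends, dtype=np.int64)
    fv = np.asarray(fragment_values, dtype=float)
    if (np.diff(fs) < 0).any():
        raise ValueError("fragments must be sorted")
    n_bins = (end - start) // bin_size
    sums = np.zeros(n_bins)
    wts = np.zeros(n_bins)
    for s, e, v in zip(fs, fe, fv):
        lo = max(s, start)
        hi = min(e, start + n_bins * bin_size)
        if hi <= lo:
            continue
        b0 = (lo - start) // bin_size
        b1 = (hi - 1 - start) // bin_size
        for b in range(b0, b1 + 1):
            bs = start + b * bin_size
            ov = min(hi, bs + bin_size) - max(lo, bs)
            sums[b] += ov * v
            wts[b] += ov
    vals = np.full(n_bins, np.nan)
    np.divide(sums, wts, out=vals, where=wts > 0)
    if n_bins and not (wts > 0).any():
        warnings.warn("window does not overlap any fragment; all bins missing")
    return BinTrack(chrom, start, start + n_bins * bin_size, bin_size, vals)


# ---------------------------------------------------------------------------
# two-state HMM with Student-t emissions
# ---------------------------------------------------------------------------

def _t_logpdf(x: np.ndarray, mu: float, scale: float, df: float) -> np.ndarray:
    z = (x - mu) / scale
    return (gammaln((df + 1) / 2) - gammaln(df / 2)
            - 0.5 * np.log(df * np.pi) - np.log(scale)
            - (df + 1) / 2 * np.log1p(z * z / df))


def _gauss_logpdf(x: np.ndarray, mu: float, scale: float) -> np.ndarray:
    z = (x - mu) / scale
    return -0.5 * z * z - np.log(scale) - 0.5 * np.log(2 * np.pi)


def _forward_backward(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray):
    """Scaled forward-backward for one observation segment.

    Returns (gamma, xi_sum, loglik): posterior state probabilities, summed
    pairwise posteriors, and the segment log-likelihood.
    """
    T, K = logB.shape
    la = np.zeros((T, K))
    la[0] = logpi + logB[0]
    for t in range(1, T):
        la[t] = logB[t] + np.logaddexp.reduce(la[t - 1][:, None] + logA, axis=0)
    loglik = float(np.logaddexp.reduce(la[-1]))
    lb = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        lb[t] = np.logaddexp.reduce(logA + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
    lg = la + lb - loglik
    gamma = np.exp(lg)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        lxi = (la[t][:, None] + logA + (logB[t + 1] + lb[t + 1])[None, :]) - loglik
        xi_sum += np.exp(lxi)
    return gamma, xi_sum, loglik


def call_lads(track: BinTrack, emission: str = "t", df: float = 3.0,
              max_iter: int = 200, tol: float = 1e-6,
              mean_sep_tol: float = 0.01, seed: int = 0) -> LadSegmentation:
    """Segment a binned DamID log2 track into LAD / non-LAD states.

    A two-state HMM is fit by EM (Baum-Welch); emissions are Student-t with
    fixed degrees of freedom ``df`` (heavy tails absorb DamID outliers) or
    Gaussian with ``emission="gaussian"``.  The state with the larger fitted
    location is labelled LAD and bins are assigned by posterior decoding.
    Missing (NaN) bins carry no state and split both the likelihood and the
    merged LAD runs.  If the two fitted locations differ by less than
    ``mean_sep_tol`` the track is treated as single-state: zero LADs.
    """
    if emission not in ("t", "gaussian"):
        raise ValueError("emission must be 't' or 'gaussian'")
    x = track.values
    obs_mask = np.isfinite(x)
    xo = x[obs_mask]
    if xo.size < 10:
        raise ValueError("need at least 10 non-missing bins")

    # contiguous observed segments
    segs: List[np.ndarray] = []
    idx = np.flatnonzero(obs_mask)
    brk = np.flatnonzero(np.diff(idx) > 1)
    for part in np.split(idx, brk + 1):
        segs.append(part)

    lo, hi = np.percentile(xo, [5, 95])
    if hi - lo < 1e-8:       # minority state smaller than 5%: widen the init
        lo, hi = float(xo.min()), float(xo.max())
    spread = max(float(np.median(np.abs(xo - np.median(xo))) * 1.4826), _MIN_SCALE)
    mus = np.array([lo, hi], dtype=float)
    scales = np.array([spread, spread], dtype=float)
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    pi = np.array([0.5, 0.5])

    def emis_logpdf(vals):
        out = np.empty((vals.size, 2))
        for k in range(2):
            if emission == "t":
                out[:, k] = _t_logpdf(vals, mus[k], scales[k], df)
            else:
                out[:, k] = _gauss_logpdf(vals, mus[k], scales[k])
        return out

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gsum = np.zeros(2)
        xsum = np.zeros((2, 2))
        pisum = np.zeros(2)
        wx = np.zeros(2)
        wsum = np.zeros(2)
        ll = 0.0
        gammas = []
        for part in segs:
            vals = x[part]
            g, xi, l = _forward_backward(emis_logpdf(vals), np.log(A), np.log(pi))
            gammas.append((part, vals, g))
            gsum += g.sum(axis=0)
            xsum += xi
            pisum += g[0]
            ll += l
        # M step: transitions / initial
        A = xsum / np.clip(xsum.sum(axis=1, keepdims=True), 1e-300, None)
        A = np.clip(A, 1e-8, None)
        A /= A.sum(axis=1, keepdims=True)
        pi = np.clip(pisum / pisum.sum(), 1e-8, None)
        pi /= pi.sum()
        # M step: t emissions via the latent-gamma weights
        new_mus = np.empty(2)
        new_s2 = np.zeros(2)
        for k in range(2):
            num = den = 0.0
            for part, vals, g in gammas:
                if emission == "t":
                    z2 = ((vals - mus[k]) / scales[k]) ** 2
                    u = (df + 1.0) / (df + z2)
                else:
                    u = np.ones_like(vals)
                num += float(np.sum(g[:, k] * u * vals))
                den += float(np.sum(g[:, k] * u))
            new_mus[k] = num / max(den, 1e-300)
            s2num = 0.0
            for part, vals, g in gammas:
                if emission == "t":
                    z2 = ((vals - mus[k]) / scales[k]) ** 2
                    u = (df + 1.0) / (df + z2)
                else:
                    u = np.ones_like(vals)
                s2num += float(np.sum(g[:, k] * u * (vals - new_mus[k]) ** 2))
            new_s2[k] = s2num / max(gsum[k], 1e-300)
        mus = new_mus
        scales = np.sqrt(np.maximum(new_s2, _MIN_SCALE ** 2))
        if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll

    lad_state = int(np.argmax(mus))
    states = np.full(track.n_bins, -1, dtype=np.int64)
    if abs(mus[1] - mus[0]) >= mean_sep_tol:
        for part in segs:
            g, _, _ = _forward_backward(emis_logpdf(x[part]), np.log(A), np.log(pi))
            dec = (np.argmax(g, axis=1) == lad_state).astype(np.int64)
            states[part] = dec
    else:
        for part in segs:
            states[part] = 0

    intervals: List[Tuple[int, int]] = []
    in_run = False
    run_start = 0
    for i in range(track.n_bins + 1):
        is_lad = i < track.n_bins and states[i] == 1
        if is_lad and not in_run:
            in_run, run_start = True, i
        elif not is_lad and in_run:
            intervals.append((run_start, i))
            in_run = False
    scores = np.array([np.nanmean(x[a:b]) for a, b in intervals])
    if scores.size:
        pct = 100.0 * rankdata(scores, method="average") / scores.size
    else:
        pct = np.empty(0)
    return LadSegmentation(track, states, intervals, scores, pct,
                           converged=converged, n_iter=it)


def classify_ne_affinity(track: BinTrack, n_beads: Optional[int] = None) -> np.ndarray:
    """Per-bead NE affinity for the polymer model.

    Bins map 1:1 onto beads; a positive mean DamID signal makes the bead
    attractive to the envelope, zero/negative/missing makes it repulsive.
    Returns a boolean array (True = attractive).
    """
    if n_beads is not None and n_beads != track.n_bins:
        raise ValueError(f"bead count {n_beads} != bin count {track.n_bins}")
    v = track.values
    return np.where(np.isfinite(v), v > 0, False)


def lad_percentile(seg: LadSegmentation, query: Tuple[int, int]) -> float:
    """Percentile rank (mean-rank ties, scale 0-100) of the LAD a query
    bin-interval overlaps; the query must hit exactly one LAD."""
    qs, qe = query
    hits = [i for i, (a, b) in enumerate(seg.intervals) if qs < b and qe > a]
    if len(hits) != 1:
        raise ValueError(f"query overlaps {len(hits)} LADs, need exactly 1")
    return float(seg.percentiles[hits[0]])
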