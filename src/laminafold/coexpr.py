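"""Genome-wide TAD co-expression census.

Works on CAGE-style expression data: peak counts are collapsed to genes,
normalised to counts-per-million, highly correlated libraries are merged
into metasamples, genes are split into ubiquitously and non-ubiquitously
expressed classes, and gene-pair Pearson co-expression is profiled inside
versus outside topologically associating domains (TADs).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

UBIQ = "Ubiq"
NON_UBIQ = "non-Ubiq"
UNCLASSIFIED = "unclassified"


@dataclass
class ExpressionSet:
    """Gene x sample expression with gene intervals and TAD annotations.

    ``matrix``: DataFrame, rows = genes, columns = samples (CPM or any
    non-negative normalised scale).  ``genes``: DataFrame indexed like the
    matrix with columns chrom/start/end/strand/tss.  ``tads``: DataFrame
    with chrom/start/end (one cell type).  ``ubiquity``: optional per-gene
    class series.
    """

    matrix: pd.DataFrame
    genes: pd.DataFrame
    tads: Optional[pd.DataFrame] = None
    ubiquity: Optional[pd.Series] = None

    def __post_init__(self):
        if (self.matrix.values < 0).any():
            raise ValueError("expression matrix must be non-negative")
        missing = set(self.matrix.index) - set(self.genes.index)
        if missing:
            raise ValueError(f"genes without intervals: {sorted(missing)[:5]}")
        if self.genes.index.has_duplicates:
            raise ValueError("gene intervals must be unique per gene")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def preprocess_cage(peak_counts: pd.DataFrame, peak_intervals: pd.DataFrame,
                    gene_annotation: pd.DataFrame,
                    min_sample_reads: float = 1_000_000,
                    min_peak_reads: float = 32,
                    tss_upstream: int = 200) -> ExpressionSet:
    """Collapse CAGE peak counts to a CPM gene x sample matrix.

    Samples with total reads strictly below ``min_sample_reads`` are dropped
    (a library at exactly 1,000,000 reads is kept); peaks whose cross-sample
    sum is strictly below ``min_peak_reads`` are dropped (a peak at exactly
    32 is kept).  A peak is assigned to a gene if it overlaps one of the
    gene's exons or lies less than ``tss_upstream`` bp upstream of its TSS;
    unassigned peaks are discarded and a gene's peak counts are summed.

    Parameters
    ----------
    peak_counts:
        peaks x samples integer counts, indexed by peak id.
    peak_intervals:
        DataFrame indexed by peak id with columns chrom/start/end.
    gene_annotation:
        one row per exon: columns gene/chrom/start/end/strand/tss.
    """
    totals = peak_counts.sum(axis=0)
    keep_samples = totals[totals >= min_sample_reads].index
    if len(keep_samples) == 0:
        raise ValueError("no samples pass the minimum read-depth filter")
    counts = peak_counts[keep_samples]
    keep_peaks = counts.sum(axis=1) >= min_peak_reads
    counts = counts.loc[keep_peaks]

    trees: Dict[str, IntervalTree] = {}
    gene_info = {}
    for row in gene_annotation.itertuples():
        t = trees.setdefault(row.chrom, IntervalTree())
        t.addi(int(row.start), int(row.end), row.gene)
        if row.strand == "+":
            t.addi(max(0, int(row.tss) - tss_upstream), int(row.tss) + 1, row.gene)
        else:
            t.addi(int(row.tss), int(row.tss) + tss_upstream + 1, row.gene)
        g = gene_info.setdefault(row.gene, dict(chrom=row.chrom,
                                                start=int(row.start),
                                                end=int(row.end),
                                                strand=row.strand,
                                                tss=int(row.tss)))
        g["start"] = min(g["start"], int(row.start))
        g["end"] = max(g["end"], int(row.end))

    assign: Dict[str, List[str]] = {}
    for pid in counts.index:
        iv = peak_intervals.loc[pid]
        t = trees.get(iv["chrom"])
        if t is None:
            continue
        hits = {h.data for h in t.overlap(int(iv["start"]), int(iv["end"]))}
        for g in hits:
            assign.setdefault(g, []).append(pid)
    if not assign:
        raise ValueError("no peak could be assigned to any gene")

    rows = {g: counts.loc[pids].sum(axis=0) for g, pids in assign.items()}
    gene_mat = pd.DataFrame(rows).T.sort_index()
    cpm = gene_mat / gene_mat.sum(axis=0) * 1e6
    genes = pd.DataFrame.from_dict(
        {g: gene_info[g] for g in gene_mat.index}, orient="index")
    return ExpressionSet(cpm, genes)


def merge_metasamples(expr: ExpressionSet, r_threshold: float = 0.95,
                      method: str = "complete") -> Tuple[ExpressionSet, pd.Series]:
    """Merge highly correlated libraries into metasamples.

    Hierarchical clustering on ``1 - Pearson r`` distance cut at
    ``1 - r_threshold``; under complete linkage every within-cluster pair
    then has r >= r_threshold.  Merged expression is the member mean.
    Constant (zero-variance) samples have no defined correlation and are
    dropped with a warning.  Returns the merged set and the sample ->
    metasample assignment.
    """
    mat = expr.matrix
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = mat.std(axis=0, ddof=0)
    const = sd[sd == 0].index
    if len(const):
        warnings.warn(f"dropping {len(const)} constant sample(s): "
                      f"{list(const)[:3]}")
        mat = mat.drop(columns=const)
    corr = np.corrcoef(mat.values.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = scipy_linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=1.0 - r_threshold, criterion="distance")
    assignment = pd.Series(labels, index=mat.columns, name="metasample")
    merged = mat.T.groupby(assignment).mean().T
    merged.columns = [f"meta{int(c)}" for c in merged.columns]
    out = ExpressionSet(merged, expr.genes, expr.tads, expr.ubiquity)
    return out, assignment


def classify_ubiquity(expr: ExpressionSet, median_cutoff: float,
                      detection_cutoff: float = 0.0) -> pd.Series:
    """Split genes into ubiquitous / non-ubiquitous / unclassified.

    Genes whose maximum expression does not exceed ``detection_cutoff``
    cannot be classified; among the detected ones a median expression at or
    above ``median_cutoff`` marks a ubiquitously expressed (housekeeping-
    like) gene.  ``median_cutoff`` has no universal value: it is the valley
    of the 2D max/median expression density of the dataset at hand.
    """
    med = expr.matrix.median(axis=1)
    mx = expr.matrix.max(axis=1)
    cls = pd.Series(UNCLASSIFIED, index=expr.matrix.index, name="ubiquity")
    detected = mx > detection_cutoff
    cls[detected & (med >= median_cutoff)] = UBIQ
    cls[detected & (med < median_cutoff)] = NON_UBIQ
    return cls


def suggest_median_cutoff(expr: ExpressionSet, bins: int = 64) -> float:
    """Data-driven ubiquity cutoff: the deepest valley of the log1p median-
    expression histogram between its outermost modes."""
    med = np.log1p(expr.matrix.median(axis=1).values)
    hist, edges = np.histogram(med, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [i for i in range(1, bins - 1)
             if hist[i] >= hist[i - 1] and hist[i] >= hist[i + 1] and hist[i] > 0]
    if len(peaks) < 2:
        return float(np.expm1(np.median(med)))
    lo, hi = peaks[0], peaks[-1]
    valley = lo + int(np.argmin(hist[lo:hi + 1]))
    return float(np.expm1(centers[valley]))


def coexpression(expr: ExpressionSet, gene_a: str, gene_b: str) -> float:
    """Pearson correlation of two genes across metasamples."""
    xa = expr.matrix.loc[gene_a].values.astype(float)
    xb = expr.matrix.loc[gene_b].values.astype(float)
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("zero-variance gene; correlation undefined")
    return float(np.corrcoef(xa, xb)[0, 1])


def assign_genes_to_tads(genes: pd.DataFrame, tads: pd.DataFrame) -> pd.Series:
    """Gene -> TAD index by maximum overlap; genes missing every TAD get -1."""
    tad_trees: Dict[str, IntervalTree] = {}
    for i, row in enumerate(tads.itertuples()):
        tad_trees.setdefault(row.chrom, IntervalTree()).addi(
            int(row.start), int(row.end), i)
    out = {}
    for g, row in genes.iterrows():
        t = tad_trees.get(row["chrom"])
        best, best_ov = -1, 0
        if t is not None:
            for h in t.overlap(int(row["start"]), int(row["end"])):
                ov = min(h.end, int(row["end"])) - max(h.begin, int(row["start"]))
                if ov > best_ov:
                    best, best_ov = h.data, ov
        out[g] = best
    return pd.Series(out, name="tad")


def _pairwise_corr(mat: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.corrcoef(mat)


def pair_profiles(expr: ExpressionSet, tads: pd.DataFrame,
                  window: int = 2000) -> pd.DataFrame:
    """Moving-average co-expression versus log10 TSS distance, stratified by
    shared-TAD status.

    All same-chromosome gene pairs are formed; each stratum (intra- vs
    inter-TAD) is sorted by log10 TSS-to-TSS distance and averaged in a
    sliding window of ``window`` pairs.  A stratum smaller than the window
    collapses to its global mean and is flagged.
    """
    genes = expr.genes.loc[expr.matrix.index]
    tad_of = assign_genes_to_tads(genes, tads)
    mat = expr.matrix.values.astype(float)
    ok = mat.std(axis=1) > 0
    names = np.asarray(expr.matrix.index)[ok]
    corr = _pairwise_corr(mat[ok])
    tss = genes.loc[names, "tss"].values
    chrom = genes.loc[names, "chrom"].values
    tad = tad_of.loc[names].values

    iu, ju = np.triu_indices(len(names), k=1)
    same_chrom = chrom[iu] == chrom[ju]
    iu, ju = iu[same_chrom], ju[same_chrom]
    dist = np.abs(tss[iu] - tss[ju]).astype(float)
    dist = np.maximum(dist, 1.0)
    rvals = corr[iu, ju]
    shared = (tad[iu] == tad[ju]) & (tad[iu] >= 0)

    frames = []
    for label, mask in (("intra", shared), ("inter", ~shared)):
        d = np.log10(dist[mask])
        r = rvals[mask]
        order = np.argsort(d, kind="stable")
        d, r = d[order], r[order]
        if d.size == 0:
            continue
        if d.size < window:
            frames.append(pd.DataFrame({
                "stratum": label, "log10_distance": [float(d.mean())],
                "mean_r": [float(r.mean())], "n_pairs": [int(d.size)],
                "underfilled": [True]}))
            continue
        kern = np.ones(window) / window
        mr = np.convolve(r, kern, mode="valid")
        md = np.convolve(d, kern, mode="valid")
        frames.append(pd.DataFrame({
            "stratum": label, "log10_distance": md, "mean_r": mr,
            "n_pairs": window, "underfilled": False}))
    if not frames:
        return pd.DataFrame(columns=["stratum", "log10_distance", "mean_r",
                                     "n_pairs", "underfilled"])
    return pd.concat(frames, ignore_index=True)


def tad_census(expr: ExpressionSet, tads: pd.DataFrame,
               ubiquity: Optional[pd.Series] = None,
               high_corr_cutoff: float = 0.5) -> Dict[str, object]:
    """Per-TAD gene composition and non-Ubiq co-regulation statistics.

    Returns a dict with a per-TAD ``table`` (gene counts, class composition,
    mean pairwise non-Ubiq Pearson r where >= 2 such genes exist) and summary
    fractions: single- vs multi-gene TADs among gene-containing TADs and the
    fraction of scoreable TADs whose mean non-Ubiq correlation reaches
    ``high_corr_cutoff``.
    """
    if len(tads) == 0:
        raise ValueError("empty TAD set")
    ubiq = ubiquity if ubiquity is not None else expr.ubiquity
    if ubiq is None:
        raise ValueError("ubiquity classes required (run classify_ubiquity)")
    genes = expr.genes.loc[expr.matrix.index]
    tad_of = assign_genes_to_tads(genes, tads)
    mat = expr.matrix
    recs = []
    for ti in range(len(tads)):
        members = tad_of[tad_of == ti].index
        n = len(members)
        n_ub = int((ubiq.loc[members] == UBIQ).sum()) if n else 0
        nu_genes = [g for g in members if ubiq.loc[g] == NON_UBIQ]
        mean_r = np.nan
        flag = ""
        if len(nu_genes) >= 2:
            sub = mat.loc[nu_genes].values.astype(float)
            keep = sub.std(axis=1) > 0
            if keep.sum() >= 2:
                c = _pairwise_corr(sub[keep])
                iu, ju = np.triu_indices(int(keep.sum()), k=1)
                mean_r = float(c[iu, ju].mean())
            else:
                flag = "degenerate-expression"
        else:
            flag = "lt2-non-ubiq"
        recs.append(dict(tad=ti, n_genes=n, n_ubiq=n_ub,
                         n_non_ubiq=len(nu_genes), mean_non_ubiq_r=mean_r,
                         flag=flag))
    table = pd.DataFrame(recs).set_index("tad")
    withg = table[table.n_genes > 0]
    n_withg = len(withg)
    scoreable = table.mean_non_ubiq_r.dropna()
    summary = {
        "table": table,
        "n_tads": len(tads),
        "n_tads_with_genes": n_withg,
        "single_gene_fraction": float((withg.n_genes == 1).mean()) if n_withg else np.nan,
        "multi_gene_fraction": float((withg.n_genes > 1).mean()) if n_withg else np.nan,
        "high_coreg_fraction": (float((scoreable >= high_corr_cutoff).mean())
                                if len(scoreable) else np.nan),
    }
    return summary
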