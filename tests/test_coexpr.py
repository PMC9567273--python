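"""CAGE preprocessing, metasample merging, ubiquity classes, TAD census."""
import numpy as np
import pandas as pd
import pytest

from laminafold import synth
from laminafold.coexpr import (NON_UBIQ, UBIQ, UNCLASSIFIED, ExpressionSet,
                               assign_genes_to_tads, classify_ubiquity,
                               coexpression, merge_metasamples, pair_profiles,
                               preprocess_cage, tad_census)


def _cage_inputs():
    """Three peaks, two genes, four samples."""
    peaks = pd.DataFrame(
        {"s1": [40, 10, 5], "s2": [30, 12, 6], "s3": [20, 8, 7],
         "s4": [25, 9, 9]},
        index=["p1", "p2", "p3"])
    scale = pd.Series({"s1": 40_000, "s2": 40_000, "s3": 50_000, "s4": 30})
    peaks = (peaks * scale).astype(int)
    intervals = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [1_000, 2_050, 50_000],
        "end": [1_200, 2_250, 50_200]},
        index=["p1", "p2", "p3"])
    genes = pd.DataFrame([
        dict(gene="gA", chrom="chr1", start=1_100, end=1_800, strand="+",
             tss=1_100),
        dict(gene="gA", chrom="chr1", start=2_000, end=2_300, strand="+",
             tss=1_100),
        dict(gene="gB", chrom="chr1", start=50_150, end=52_000, strand="-",
             tss=52_000),
    ])
    return peaks, intervals, genes


class TestPreprocessCage:
    def test_peak_sum_boundary_31_dropped_32_kept(self):
        counts = pd.DataFrame({"s1": [31, 32, 2_000_000],
                               "s2": [0, 0, 2_000_000]},
                              index=["p31", "p32", "big"])
        intervals = pd.DataFrame({"chrom": ["chr1"] * 3,
                                  "start": [100, 300, 500],
                                  "end": [200, 400, 600]},
                                 index=["p31", "p32", "big"])
        genes = pd.DataFrame([
            dict(gene="g1", chrom="chr1", start=100, end=200, strand="+", tss=100),
            dict(gene="g2", chrom="chr1", start=300, end=400, strand="+", tss=300),
            dict(gene="g3", chrom="chr1", start=500, end=600, strand="+", tss=500)])
        es = preprocess_cage(counts, intervals, genes)
        assert "g1" not in es.matrix.index        # peak sum 31 < 32 dropped
        assert "g2" in es.matrix.index            # exactly 32 kept

    def test_sample_depth_boundary_exactly_one_million_kept(self):
        counts = pd.DataFrame({"keep": [1_000_000], "drop": [999_999]},
                              index=["p"])
        intervals = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                                  "end": [200]}, index=["p"])
        genes = pd.DataFrame([dict(gene="g", chrom="chr1", start=50, end=400,
                                   strand="+", tss=50)])
        es = preprocess_cage(counts, intervals, genes)
        assert list(es.matrix.columns) == ["keep"]

    def test_gene_peak_summation_and_cpm(self):
        peaks, intervals, genes = _cage_inputs()
        es = preprocess_cage(peaks, intervals, genes)
        # sample s4 (depth 30*sum < 1e6 after scaling? it was scaled by 30)
        assert "s4" not in es.matrix.columns
        # gA gets p1 (exon overlap) + p2 (second exon); gB gets p3 (within
        # 200 bp upstream of its minus-strand TSS at 52.. no: exon overlap)
        assert set(es.matrix.index) == {"gA", "gB"}
        raw_gA = 40 + 10
        raw_gB = 5
        ratio = es.matrix.loc["gA", "s1"] / es.matrix.loc["gB", "s1"]
        assert ratio == pytest.approx(raw_gA / raw_gB)
        assert es.matrix["s1"].sum() == pytest.approx(1e6)

    def test_upstream_window_strand_aware(self):
        counts = pd.DataFrame({"s": [2_000_000]}, index=["p"])
        intervals = pd.DataFrame({"chrom": ["chr1"], "start": [890],
                                  "end": [950]}, index=["p"])
        plus = pd.DataFrame([dict(gene="g", chrom="chr1", start=1_000,
                                  end=1_500, strand="+", tss=1_000)])
        es = preprocess_cage(counts, intervals, plus)
        assert "g" in es.matrix.index     # 50-110 bp upstream of + TSS
        minus = pd.DataFrame([dict(gene="g", chrom="chr1", start=400,
                                   end=800, strand="-", tss=800)])
        es2 = preprocess_cage(counts, intervals, minus)
        assert "g" in es2.matrix.index    # 90-150 bp upstream of - TSS

    def test_no_surviving_samples_rejected(self):
        counts = pd.DataFrame({"s": [10]}, index=["p"])
        intervals = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                  "end": [10]}, index=["p"])
        genes = pd.DataFrame([dict(gene="g", chrom="chr1", start=0, end=10,
                                   strand="+", tss=0)])
        with pytest.raises(ValueError, match="sample"):
            preprocess_cage(counts, intervals, genes)


def _es(mat, chrom="chrS"):
    genes = pd.DataFrame(
        {"chrom": chrom, "start": np.arange(len(mat)) * 10_000,
         "end": np.arange(len(mat)) * 10_000 + 1_000, "strand": "+",
         "tss": np.arange(len(mat)) * 10_000},
        index=mat.index)
    return ExpressionSet(mat, genes)


class TestMergeMetasamples:
    def test_duplicated_column_merges(self, rng):
        base = rng.random((20, 1))
        mat = pd.DataFrame(np.hstack([base, base, rng.random((20, 1))]),
                           index=[f"g{i}" for i in range(20)],
                           columns=["a", "a2", "b"])
        merged, assign = merge_metasamples(_es(mat))
        assert merged.n_samples == 2
        assert assign["a"] == assign["a2"] != assign["b"]

    def test_independent_noise_not_merged(self, rng):
        mat = pd.DataFrame(rng.random((50, 4)),
                           index=[f"g{i}" for i in range(50)],
                           columns=list("abcd"))
        merged, _ = merge_metasamples(_es(mat))
        assert merged.n_samples == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_pairs_recovered(self, seed):
        rng = np.random.default_rng(seed)
        cols = {}
        for k in range(3):
            base = rng.random(80) * 10
            cols[f"p{k}x"] = base + rng.normal(scale=0.05, size=80)
            cols[f"p{k}y"] = base + rng.normal(scale=0.05, size=80)
        mat = pd.DataFrame(cols, index=[f"g{i}" for i in range(80)]).clip(0)
        merged, assign = merge_metasamples(_es(mat))
        assert merged.n_samples == 3
        for k in range(3):
            assert assign[f"p{k}x"] == assign[f"p{k}y"]

    def test_complete_linkage_guarantee(self, rng):
        # merged groups never contain a pair below the threshold
        mat = pd.DataFrame(rng.random((60, 10)) ** 2,
                           index=[f"g{i}" for i in range(60)],
                           columns=[f"s{i}" for i in range(10)])
        es = _es(mat)
        merged, assign = merge_metasamples(es, r_threshold=0.5)
        corr = np.corrcoef(mat.values.T)
        for lbl in assign.unique():
            members = np.flatnonzero(assign.values == lbl)
            for i in members:
                for j in members:
                    assert corr[i, j] >= 0.5 - 1e-12

    def test_constant_sample_dropped_with_warning(self, rng):
        mat = pd.DataFrame({"a": rng.random(30), "b": rng.random(30),
                            "c": np.ones(30)},
                           index=[f"g{i}" for i in range(30)])
        with pytest.warns(UserWarning, match="constant"):
            merged, _ = merge_metasamples(_es(mat))
        assert "c" not in merged.matrix.columns


class TestClassifyUbiquity:
    def test_three_classes(self):
        mat = pd.DataFrame(
            {f"s{i}": [100.0, 0.0, 0.0] for i in range(99)} | {"s99": [100.0, 5.0, 0.0]},
            index=["high", "rare", "zero"])
        es = _es(mat)
        cls = classify_ubiquity(es, median_cutoff=50.0)
        assert cls["high"] == UBIQ
        assert cls["rare"] == NON_UBIQ          # detected in 1 of 100 samples
        assert cls["zero"] == UNCLASSIFIED


class TestCoexpression:
    def test_exact_limits(self):
        x = np.arange(10, dtype=float)
        mat = pd.DataFrame({"s" + str(i): [x[i], x[i], 9 - x[i]]
                            for i in range(10)},
                           index=["a", "b", "c"])
        es = _es(mat)
        assert coexpression(es, "a", "b") == pytest.approx(1.0)
        assert coexpression(es, "a", "c") == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        mat = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 3.0]},
                           index=["flat", "var"])
        with pytest.raises(ValueError, match="variance"):
            coexpression(_es(mat), "flat", "var")

    def test_planted_factor_recovered_at_half(self):
        tads = [(0, 200_000), (200_000, 400_000)]
        es, truth = synth.make_expression_set(
            20, 5_000, tads, frac_ubiq=0.0, factor_sd=1.0, noise_sd=1.0,
            seed=7)
        tad_of = np.array(truth.coexpr_factors["tad_of_gene"])
        g = es.matrix.index.to_numpy()
        same_tad = [(a, b) for i, a in enumerate(g) for b in g[i + 1:]
                    if tad_of[list(g).index(a)] == tad_of[list(g).index(b)]]
        rs = [coexpression(es, a, b) for a, b in same_tad[:40]]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.03)


class TestPairProfiles:
    def test_identical_expression_everywhere_constant_one(self):
        base = np.linspace(1, 9, 30)
        mat = pd.DataFrame({f"s{i}": base[i] * np.ones(12) for i in range(30)},
                           index=[f"g{i}" for i in range(12)])
        es = _es(mat)
        tads = pd.DataFrame([dict(chrom="chrS", start=0, end=60_000),
                             dict(chrom="chrS", start=60_000, end=200_000)])
        prof = pair_profiles(es, tads, window=5)
        assert np.allclose(prof.mean_r, 1.0)

    def test_planted_intra_above_inter(self):
        tads = [(i * 100_000, (i + 1) * 100_000) for i in range(6)]
        es, _ = synth.make_expression_set(60, 300, tads, frac_ubiq=0.0,
                                          factor_sd=1.0, noise_sd=1.0, seed=3)
        tad_df = es.tads
        prof = pair_profiles(es, tad_df, window=30)
        intra = prof[prof.stratum == "intra"].mean_r.mean()
        inter = prof[prof.stratum == "inter"].mean_r.mean()
        assert intra > inter + 0.2

    def test_shuffled_tads_destroy_gap(self):
        tads = [(i * 100_000, (i + 1) * 100_000) for i in range(6)]
        es, _ = synth.make_expression_set(60, 300, tads, frac_ubiq=0.0,
                                          factor_sd=1.0, noise_sd=1.0, seed=4)
        rng = np.random.default_rng(0)
        genes_shuf = es.genes.copy()
        pos = rng.permutation(len(genes_shuf)) * 10_000
        genes_shuf["start"] = pos
        genes_shuf["end"] = pos + 1_000
        genes_shuf["tss"] = pos
        es_shuf = ExpressionSet(es.matrix, genes_shuf, es.tads, es.ubiquity)
        prof = pair_profiles(es_shuf, es.tads, window=30)
        intra = prof[prof.stratum == "intra"].mean_r.mean()
        inter = prof[prof.stratum == "inter"].mean_r.mean()
        assert abs(intra - inter) < 0.15

    def test_small_stratum_flagged(self):
        mat = pd.DataFrame(np.random.default_rng(1).random((4, 8)),
                           index=[f"g{i}" for i in range(4)])
        mat.columns = [f"s{i}" for i in range(8)]
        es = _es(mat)
        tads = pd.DataFrame([dict(chrom="chrS", start=0, end=1_000_000)])
        prof = pair_profiles(es, tads, window=2000)
        assert prof.underfilled.all()


class TestTadCensus:
    def _planted(self, seed=0):
        tads = [(i * 100_000, (i + 1) * 100_000) for i in range(10)]
        # 3 single-gene TADs + 7 multi-gene: 3*1 + 7*3 = 24 genes
        layout = [1] * 3 + [3] * 7
        rows, names, mats = [], [], []
        rng = np.random.default_rng(seed)
        gi = 0
        for ti, cnt in enumerate(layout):
            for k in range(cnt):
                names.append(f"g{gi:03d}")
                pos = tads[ti][0] + (k + 1) * 100_000 // (cnt + 1)
                rows.append(dict(chrom="chrS", start=pos, end=pos + 500,
                                 strand="+", tss=pos))
                mats.append(10 + rng.normal(size=50))
                gi += 1
        mat = pd.DataFrame(np.clip(mats, 0, None), index=names,
                           columns=[f"s{i}" for i in range(50)])
        genes = pd.DataFrame(rows, index=names)
        ubiq = pd.Series(NON_UBIQ, index=names)
        tad_df = pd.DataFrame([dict(chrom="chrS", start=a, end=b)
                               for a, b in tads])
        return ExpressionSet(mat, genes, tad_df, ubiq), tad_df

    def test_planted_composition_recovered_exactly(self):
        es, tads = self._planted()
        census = tad_census(es, tads)
        assert census["single_gene_fraction"] == pytest.approx(0.3)
        assert census["multi_gene_fraction"] == pytest.approx(0.7)
        assert census["n_tads_with_genes"] == 10

    def test_single_non_ubiq_gene_tad_flagged(self):
        es, tads = self._planted()
        table = tad_census(es, tads)["table"]
        singles = table[table.n_genes == 1]
        assert (singles.flag == "lt2-non-ubiq").all()
        assert singles.mean_non_ubiq_r.isna().all()

    def test_all_genes_one_tad(self, rng):
        mat = pd.DataFrame(rng.random((6, 20)),
                           index=[f"g{i}" for i in range(6)])
        mat.columns = [f"s{i}" for i in range(20)]
        es = _es(mat)
        es.ubiquity = pd.Series(NON_UBIQ, index=mat.index)
        tads = pd.DataFrame([dict(chrom="chrS", start=0, end=1_000_000)])
        census = tad_census(es, tads, es.ubiquity)
        assert census["multi_gene_fraction"] == 1.0

    def test_empty_tads_rejected(self, rng):
        mat = pd.DataFrame(rng.random((3, 5)),
                           index=["a", "b", "c"],
                           columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="empty"):
            tad_census(_es(mat), pd.DataFrame(columns=["chrom", "start", "end"]),
                       pd.Series(NON_UBIQ, index=mat.index))

    def test_fractions_partition(self):
        es, tads = self._planted(seed=3)
        census = tad_census(es, tads)
        assert census["single_gene_fraction"] + census["multi_gene_fraction"] \
            == pytest.approx(1.0)

    def test_max_overlap_assignment(self):
        genes = pd.DataFrame(
            [dict(chrom="chr1", start=90_000, end=130_000, strand="+",
                  tss=90_000)], index=["g"])
        tads = pd.DataFrame([dict(chrom="chr1", start=0, end=100_000),
                             dict(chrom="chr1", start=100_000, end=200_000)])
        # 10 kb in TAD0, 30 kb in TAD1 -> TAD1
        assert assign_genes_to_tads(genes, tads)["g"] == 1
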