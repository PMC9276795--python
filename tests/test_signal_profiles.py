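"""Binned tracks, log-scale correlation, metaprofiles, and RPKM tertiles."""

import numpy as np
import pytest

from peakconcord.annotation import GeneModel
from peakconcord.signal_profiles import (
    BinnedTrack,
    Coverage,
    binned_correlation,
    compute_rpkm_tertiles,
    coverage_to_bins,
    genebody_profile,
    outlier_trim,
    read_bedgraph,
    read_chrom_sizes,
    tss_profile,
)


def make_coverage(chrom_sizes, fill=0.0):
    cov = Coverage(chrom_sizes)
    for c in cov.values:
        cov.values[c][:] = fill
    return cov


class TestCoverageToBins:
    def test_uniform_coverage_gives_uniform_bins(self):
        cov = make_coverage({"chr1": 20_000}, fill=1.0)
        track = coverage_to_bins(cov, bin_size=10_000, normalize="raw")
        np.testing.assert_allclose(track.values["chr1"], [1.0, 1.0])

    def test_bin_mean_averages_over_full_bin(self):
        cov = make_coverage({"chr1": 10_000})
        cov.add_interval("chr1", 0, 5000, 2.0)
        track = coverage_to_bins(cov, bin_size=10_000, normalize="raw")
        np.testing.assert_allclose(track.values["chr1"], [1.0])

    def test_partial_final_bin_uses_true_width(self):
        cov = make_coverage({"chr1": 15_000}, fill=3.0)
        track = coverage_to_bins(cov, bin_size=10_000, normalize="raw")
        np.testing.assert_allclose(track.values["chr1"], [3.0, 3.0])
        assert len(track.values["chr1"]) == 2  # ceil(15000/10000)

    def test_cpm_scale_factor_recovers_raw_total(self, rng):
        cov = make_coverage({"chr1": 30_000, "chr2": 12_345})
        for c in cov.values:
            cov.values[c][:] = rng.random(len(cov.values[c]))
        total = cov.total()
        track = coverage_to_bins(cov, bin_size=7_000, normalize="CPM")
        assert track.normalization == "CPM"
        np.testing.assert_allclose(track.scale_factor * total, 1e6, rtol=1e-9)

    def test_bin_means_match_per_base_oracle(self, rng):
        n = 25_000
        cov = make_coverage({"chr1": n})
        for _ in range(50):
            s = int(rng.integers(0, n - 500))
            cov.add_interval("chr1", s, s + int(rng.integers(1, 500)), float(rng.random() * 4))
        bin_size = 3_000
        track = coverage_to_bins(cov, bin_size=bin_size, normalize="raw")
        arr = cov.values["chr1"]
        expected = [
            arr[i : i + bin_size].mean() for i in range(0, n, bin_size)
        ]
        np.testing.assert_allclose(track.values["chr1"], expected)

    def test_unknown_chromosome_named_in_error(self, tmp_path):
        bg = tmp_path / "cov.bedgraph"
        bg.write_text("chrZ\t0\t100\t1.0\n")
        with pytest.raises(KeyError, match="chrZ"):
            read_bedgraph(bg, {"chr1": 1000})


class TestBedgraphIO:
    def test_roundtrip_values(self, tmp_path):
        bg = tmp_path / "cov.bedgraph"
        bg.write_text("track type=bedGraph\nchr1\t0\t5000\t2\nchr1\t5000\t10000\t0\n")
        cov = read_bedgraph(bg, {"chr1": 10_000})
        track = coverage_to_bins(cov, bin_size=10_000, normalize="raw")
        np.testing.assert_allclose(track.values["chr1"], [1.0])

    def test_chrom_sizes_reader(self, tmp_path):
        p = tmp_path / "chrom.sizes"
        p.write_text("chr1\t1000\nchr2\t2000\n")
        assert read_chrom_sizes(p) == {"chr1": 1000, "chr2": 2000}


class TestBinnedCorrelation:
    @staticmethod
    def track(values, bin_size=100):
        return BinnedTrack(
            bin_size=bin_size,
            values={"chr1": np.asarray(values, dtype=float)},
            chrom_sizes={"chr1": len(values) * bin_size},
        )

    def test_self_correlation_is_one(self, rng):
        t = self.track(rng.random(50) * 10)
        assert binned_correlation(t, t) == pytest.approx(1.0)

    def test_matches_textbook_pearson_after_log(self, rng):
        a = rng.random(20) * 5
        b = rng.random(20) * 5
        la, lb = np.log(a + 1), np.log(b + 1)
        expected = (
            ((la - la.mean()) * (lb - lb.mean())).sum()
            / np.sqrt(((la - la.mean()) ** 2).sum() * ((lb - lb.mean()) ** 2).sum())
        )
        got = binned_correlation(self.track(a), self.track(b))
        assert got == pytest.approx(expected, abs=1e-12)
        # symmetry and bounds
        assert binned_correlation(self.track(b), self.track(a)) == pytest.approx(got)
        assert -1.0 <= got <= 1.0

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            binned_correlation(self.track([1, 2, 3]), self.track([1, 2]))

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            binned_correlation(self.track([2.0, 2.0, 2.0]), self.track([1.0, 2.0, 3.0]))


class TestOutlierTrim:
    def test_policy_none_is_identity(self, rng):
        a, b = rng.random(30), rng.random(30)
        ta, tb = outlier_trim(a, b, policy="none")
        assert ta is a and tb is b

    def test_extreme_bin_removed_under_mad(self, rng):
        a = np.ones(200) + rng.random(200) * 0.01
        b = a.copy()
        a[7] = 1e6
        ta, tb = outlier_trim(a, b, policy="mad", mad_threshold=200.0)
        assert len(ta) == len(tb) == 199
        assert ta.max() < 1e6

    def test_trimming_never_lengthens(self, rng):
        a, b = rng.random(50), rng.random(50)
        ta, tb = outlier_trim(a, b, policy="mad", mad_threshold=1.0)
        assert len(ta) <= 50 and len(ta) == len(tb)


def plus_gene(gid, chrom, tss, length=5000):
    return GeneModel(gid, chrom, "+", tss, tss + length)


def minus_gene(gid, chrom, tss, length=5000):
    return GeneModel(gid, chrom, "-", tss, tss - length)


class TestTssProfile:
    def test_delta_coverage_peaks_at_offset_zero(self):
        cov = make_coverage({"chr1": 50_000})
        cov.add_interval("chr1", 20_000, 20_001, 5.0)
        prof = tss_profile(cov, [plus_gene("g", "chr1", 20_000)], flank=1000)
        avg = prof.average_profile()
        assert prof.positions[np.nanargmax(avg)] == 0

    def test_minus_strand_flips_orientation(self):
        cov = make_coverage({"chr1": 50_000})
        # signal 500 bp downstream of a minus-strand TSS = 500 bp to the left
        cov.add_interval("chr1", 19_500, 19_501, 7.0)
        prof = tss_profile(cov, [minus_gene("g", "chr1", 20_000)], flank=1000)
        avg = prof.average_profile()
        assert prof.positions[np.nanargmax(avg)] == 500

    def test_strand_symmetric_coverage_is_strand_invariant(self):
        cov = make_coverage({"chr1": 50_000})
        for off in range(-800, 801):
            cov.values["chr1"][20_000 + off] = 1.0 / (1 + abs(off))
        plus = tss_profile(cov, [plus_gene("g", "chr1", 20_000)], flank=700)
        minus = tss_profile(cov, [minus_gene("g", "chr1", 20_000)], flank=700)
        np.testing.assert_allclose(plus.matrix, minus.matrix)

    def test_out_of_bounds_tss_excluded_and_edge_window_clipped(self):
        cov = make_coverage({"chr1": 10_000}, fill=1.0)
        genes = [plus_gene("edge", "chr1", 100), GeneModel("out", "chr2", "+", 5, 50)]
        prof = tss_profile(cov, genes, flank=500)
        assert prof.n_excluded == 1
        assert prof.n_clipped == 1
        assert np.isnan(prof.matrix[0, 0])  # before chromosome start
        assert not np.isnan(prof.matrix[0, -1])

    def test_column_means_match_direct_window_oracle(self, rng):
        n = 100_000
        cov = make_coverage({"chr1": n})
        cov.values["chr1"][:] = rng.random(n)
        genes = []
        for i in range(50):
            tss = int(rng.integers(2000, n - 2000))
            genes.append(plus_gene(f"g{i}", "chr1", tss, 1000))
        flank = 1500
        prof = tss_profile(cov, genes, flank=flank)
        expected = np.mean(
            [cov.values["chr1"][g.tss - flank : g.tss + flank + 1] for g in genes],
            axis=0,
        )
        np.testing.assert_allclose(prof.average_profile(), expected)


class TestGenebodyProfile:
    def test_uniform_coverage_gives_flat_profile(self):
        cov = make_coverage({"chr1": 100_000}, fill=2.0)
        genes = [plus_gene("a", "chr1", 30_000, 8000), minus_gene("b", "chr1", 70_000, 9000)]
        prof = genebody_profile(cov, genes, flank=1000, meta_bins=50)
        np.testing.assert_allclose(prof.matrix, 2.0)

    def test_short_gene_excluded(self):
        cov = make_coverage({"chr1": 10_000}, fill=1.0)
        prof = genebody_profile(
            cov, [GeneModel("tiny", "chr1", "+", 5000, 5040)], meta_bins=100
        )
        assert prof.n_excluded == 1
        assert prof.matrix.shape[0] == 0

    def test_rescaling_conserves_body_signal(self, rng):
        n = 60_000
        cov = make_coverage({"chr1": n})
        cov.values["chr1"][:] = rng.random(n) * 3
        g = plus_gene("g", "chr1", 10_000, 7_777)
        meta_bins = 100
        prof = genebody_profile(cov, [g], flank=1000, meta_bins=meta_bins, flank_bins=10)
        body = prof.matrix[0, 10 : 10 + meta_bins]
        body_len = 7_777 + 1  # span is TSS..TES inclusive
        integral = body.sum() * (body_len / meta_bins)
        direct = cov.values["chr1"][g.tss : g.tes + 1].sum()
        assert integral == pytest.approx(direct, rel=1e-6)

    def test_group_averages_follow_planted_signal_order(self):
        cov = make_coverage({"chr1": 100_000})
        genes, groups = [], {}
        for i, (grp, level) in enumerate(
            [("high", 9.0), ("medium", 3.0), ("low", 1.0)] * 3
        ):
            tss = 5000 + i * 10_000
            g = plus_gene(f"g{i}", "chr1", tss, 6000)
            cov.values["chr1"][tss : g.tes + 1] = level
            genes.append(g)
            groups[g.gene_id] = grp
        prof = genebody_profile(cov, genes, flank=500, meta_bins=40, groups=groups)
        means = {
            grp: np.nanmean(prof.average_profile(group=grp)[10:50])
            for grp in ("high", "medium", "low")
        }
        assert means["high"] > means["medium"] > means["low"]


class TestRpkmTertiles:
    def test_rpkm_formula_and_assignment(self):
        table = compute_rpkm_tertiles(
            {"a": 10, "b": 10, "c": 10}, {"a": 1000, "b": 2000, "c": 4000}
        )
        # rpkm ratio 4:2:1 for a:b:c
        assert table.rpkm["a"] == pytest.approx(2 * table.rpkm["b"])
        assert table.rpkm["b"] == pytest.approx(2 * table.rpkm["c"])
        assert table.tertile == {"a": "high", "b": "medium", "c": "low"}

    def test_ties_break_deterministically_by_gene_id(self):
        counts = {f"g{i}": 5 for i in range(6)}
        lengths = {f"g{i}": 1000 for i in range(6)}
        t1 = compute_rpkm_tertiles(counts, lengths)
        t2 = compute_rpkm_tertiles(dict(reversed(list(counts.items()))), lengths)
        assert t1.tertile == t2.tertile
        assert t1.tertile["g0"] == "low" and t1.tertile["g5"] == "high"

    def test_remainder_goes_to_lower_groups(self):
        counts = {f"g{i:03d}": float(i + 1) for i in range(100)}
        lengths = {g: 1000 for g in counts}
        table = compute_rpkm_tertiles(counts, lengths)
        sizes = {t: list(table.tertile.values()).count(t) for t in ("low", "medium", "high")}
        assert sizes == {"low": 34, "medium": 33, "high": 33}

    def test_zero_gene_length_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm_tertiles({"a": 1}, {"a": 0})
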