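"""Peak-to-TSS assignment, positional histograms, genomic annotation,
window-level Venn overlaps, and meta-profiles."""

import numpy as np
import pytest

from promsig.genomic_io import GenomicInterval, PromoterCatalog, \
    extract_promoter_windows
from promsig.peak_analysis import (
    PeakSet,
    annotate_peaks,
    assign_peaks_to_promoters,
    meta_profile,
    overlap_sets,
    positional_histogram,
    windows_hit,
)


def catalog_and_windows(tss_list):
    cat = PromoterCatalog([
        (f"p{i}", f"g{i}", contig, tss, strand)
        for i, (contig, tss, strand) in enumerate(tss_list)
    ])
    return cat, extract_promoter_windows(cat, 150, 50)


def peak_at(contig, center, halfwidth=50, name=None):
    return GenomicInterval(contig, center - halfwidth, center + halfwidth + 1,
                           ".", name=name)


class TestAssignment:
    def test_peak_on_tss_has_offset_zero_inside_window(self):
        cat, windows = catalog_and_windows([("c1", 5000, "+")])
        ps = PeakSet("f", [peak_at("c1", 5000)])
        (asg,) = assign_peaks_to_promoters(ps, cat, windows)
        assert asg.tss_relative_offset == 0 and asg.in_window

    def test_minus_strand_offset_is_gene_oriented(self):
        """A peak 100 bp 3' of a minus-strand TSS has offset +100, mirroring
        the equivalent plus-strand construction."""
        cat_m, win_m = catalog_and_windows([("c1", 5000, "-")])
        ps_m = PeakSet("f", [peak_at("c1", 4900)])  # genomically below = 3' on -
        (asg_m,) = assign_peaks_to_promoters(ps_m, cat_m, win_m)
        cat_p, win_p = catalog_and_windows([("c1", 5000, "+")])
        ps_p = PeakSet("f", [peak_at("c1", 5100)])
        (asg_p,) = assign_peaks_to_promoters(ps_p, cat_p, win_p)
        assert asg_m.tss_relative_offset == asg_p.tss_relative_offset == 100

    def test_equidistant_tie_goes_to_lower_coordinate_tss(self):
        cat, windows = catalog_and_windows([("c1", 4000, "+"), ("c1", 6000, "+")])
        ps = PeakSet("f", [peak_at("c1", 5000)])
        (asg,) = assign_peaks_to_promoters(ps, cat, windows)
        assert asg.promoter_id == "p0"

    def test_unknown_contig_unassigned_with_warning(self):
        cat, windows = catalog_and_windows([("c1", 5000, "+")])
        ps = PeakSet("f", [peak_at("cX", 100)])
        with pytest.warns(UserWarning, match="cX"):
            (asg,) = assign_peaks_to_promoters(ps, cat, windows)
        assert asg.promoter_id is None

    def test_summit_overrides_midpoint(self):
        cat, windows = catalog_and_windows([("c1", 5000, "+")])
        ps = PeakSet("f", [GenomicInterval("c1", 4000, 4500)],
                     summits={0: 5000})
        (asg,) = assign_peaks_to_promoters(ps, cat, windows)
        assert asg.tss_relative_offset == 0


class TestPositionalHistogram:
    def test_all_peaks_at_tss_land_in_the_window_bin(self):
        cat, windows = catalog_and_windows([("c1", 5000 * (i + 1), "+")
                                            for i in range(10)])
        ps = PeakSet("f", [peak_at("c1", 5000 * (i + 1)) for i in range(10)])
        hist = positional_histogram(ps, cat, windows)
        assert hist.percentages[hist.labels.index("-150/+50")] == 100.0

    def test_split_between_1kb_bins(self):
        cat, windows = catalog_and_windows([("c1", 50_000, "+")])
        ps = PeakSet("f", [peak_at("c1", 55_500), peak_at("c1", 44_500)])
        hist = positional_histogram(ps, cat, windows)
        assert hist.percentages[hist.labels.index("5000:6000")] == 50.0
        assert hist.percentages[hist.labels.index("-6000:-5000")] == 50.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        cat, windows = catalog_and_windows([("c1", 100_000, "+")])
        ps = PeakSet("f", [peak_at("c1", int(100_000 + d))
                           for d in rng.integers(-20_000, 20_000, size=200)])
        hist = positional_histogram(ps, cat, windows)
        assert hist.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_peaks_put_half_beyond_10kb(self):
        """Uniform placement over +/-20 kb puts about half the peaks beyond
        +/-10 kb of the TSS."""
        rng = np.random.default_rng(3)
        cat, windows = catalog_and_windows([("c1", 100_000, "+")])
        offsets = rng.integers(-20_000, 20_000, size=4000)
        ps = PeakSet("f", [peak_at("c1", int(100_000 + d)) for d in offsets])
        hist = positional_histogram(ps, cat, windows)
        beyond = (hist.percentages[hist.labels.index("< -10kb")]
                  + hist.percentages[hist.labels.index("> +10kb")])
        assert beyond == pytest.approx(50.0, abs=3.0)

    def test_no_peaks_is_an_error(self):
        cat, windows = catalog_and_windows([("c1", 5000, "+")])
        with pytest.raises(ValueError):
            positional_histogram(PeakSet("f", []), cat, windows)


class TestAnnotate:
    GENE = dict(contig="c1", strand="+", tss=10_000, tts=20_000,
                exons=[(10_000, 10_500), (15_000, 15_500), (19_500, 20_000)])

    def test_category_calls(self):
        ps = PeakSet("f", [
            peak_at("c1", 9_950),    # 50 bp upstream of TSS -> promoter
            peak_at("c1", 15_200),   # inside exon 2, 5 kb from TSS -> exon
            peak_at("c1", 13_000),   # gene body, no exon -> intron
            peak_at("c1", 20_500),   # downstream flank -> TTS
            peak_at("c1", 60_000),   # desert -> intergenic
        ])
        fractions = annotate_peaks(ps, [self.GENE])
        assert fractions == {"promoter": 0.2, "TTS": 0.2, "exon": 0.2,
                             "intron": 0.2, "intergenic": 0.2}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        ps = PeakSet("f", [peak_at("c1", int(c))
                           for c in rng.integers(1000, 60_000, size=97)])
        fractions = annotate_peaks(ps, [self.GENE])
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_empty_annotation_all_intergenic(self):
        ps = PeakSet("f", [peak_at("c1", 5000)])
        with pytest.warns(UserWarning):
            fractions = annotate_peaks(ps, [])
        assert fractions["intergenic"] == 1.0


class TestOverlap:
    def make(self, hits_a, hits_b, shared, n=1000):
        cat, windows = catalog_and_windows([("c1", 2000 * (i + 1), "+")
                                            for i in range(n)])
        tss = lambda i: 2000 * (i + 1)
        a_idx = list(range(hits_a))
        b_idx = list(range(hits_a - shared, hits_a - shared + hits_b))
        ps_a = PeakSet("A", [peak_at("c1", tss(i)) for i in a_idx])
        ps_b = PeakSet("B", [peak_at("c1", tss(i)) for i in b_idx])
        return cat, windows, ps_a, ps_b

    def test_constructed_counts(self):
        """A hits 100, B hits 80, 20 shared -> pair 20, exclusive 80/60."""
        _cat, windows, ps_a, ps_b = self.make(100, 80, 20)
        venn = overlap_sets([ps_a, ps_b], windows)
        assert venn.count("A", "B") == 20
        assert venn.exclusive("A") == 80 and venn.exclusive("B") == 60

    def test_identical_sets_fully_overlap(self):
        _cat, windows, ps_a, _ = self.make(50, 0, 0)
        ps_b = PeakSet("B", list(ps_a.peaks))
        venn = overlap_sets([ps_a, ps_b], windows)
        assert venn.count("A", "B") == venn.count("A") == 50

    def test_disjoint_sets(self):
        _cat, windows, ps_a, ps_b = self.make(50, 50, 0)
        assert overlap_sets([ps_a, ps_b], windows).count("A", "B") == 0

    def test_order_invariance(self):
        _cat, windows, ps_a, ps_b = self.make(30, 40, 10)
        v1 = overlap_sets([ps_a, ps_b], windows)
        v2 = overlap_sets([ps_b, ps_a], windows)
        assert v1.regions == v2.regions

    def test_more_than_three_sets_is_an_error(self):
        _cat, windows, ps_a, ps_b = self.make(5, 5, 0)
        with pytest.raises(ValueError):
            overlap_sets([ps_a, ps_b, ps_a, ps_b], windows)

    def test_polii_mode_uses_tss_distance(self):
        cat, windows = catalog_and_windows([("c1", 5000, "+")])
        ps = PeakSet("PolII", [peak_at("c1", 5800)])  # outside window, within 1 kb
        assert windows_hit(ps, windows) == set()
        assert windows_hit(ps, windows, catalog=cat, polii_mode=True) == {"p0"}


class TestMetaProfile:
    def test_delta_signal_spikes_at_center(self):
        cov = {"c1": np.zeros(20_000)}
        anchors = [("c1", 5000, "+"), ("c1", 12_000, "+")]
        for _c, pos, _s in anchors:
            cov["c1"][pos] = 1.0
        prof = meta_profile(cov, anchors, half_width=500, bin_size=25)
        peak_bin = prof["mean_signal"].idxmax()
        assert abs(prof.loc[peak_bin, "position"]) <= 25

    def test_flat_coverage_gives_flat_profile(self):
        cov = {"c1": np.ones(10_000)}
        prof = meta_profile(cov, [("c1", 5000, "+")], half_width=1000)
        assert np.allclose(prof["mean_signal"], 1.0)

    def test_gaussian_coverage_peaks_within_one_bin(self):
        rng = np.random.default_rng(6)
        cov = {"c1": np.zeros(40_000)}
        anchors = []
        xs = np.arange(40_000)
        for pos in (10_000, 20_000, 30_000):
            cov["c1"] += np.exp(-0.5 * ((xs - pos) / 200.0) ** 2)
            anchors.append(("c1", pos + int(rng.integers(-3, 4)), "+"))
        prof = meta_profile(cov, anchors, half_width=3000, bin_size=25)
        assert abs(prof.loc[prof["mean_signal"].idxmax(), "position"]) <= 50

    def test_contig_edge_bins_excluded_not_zeroed(self):
        cov = {"c1": np.ones(2000)}
        prof = meta_profile(cov, [("c1", 500, "+")], half_width=1000)
        # bins fully off the left edge carry no data
        assert np.isnan(prof["mean_signal"].iloc[0])
        assert prof["mean_signal"].iloc[-1] == pytest.approx(1.0)

    def test_minus_strand_anchor_flips_profile(self):
        cov = {"c1": np.concatenate([np.zeros(5000), np.ones(5000)])}
        plus = meta_profile(cov, [("c1", 5000, "+")], half_width=1000)
        minus = meta_profile(cov, [("c1", 5000, "-")], half_width=1000)
        assert np.allclose(plus["mean_signal"].to_numpy(),
                           minus["mean_signal"].to_numpy()[::-1])
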