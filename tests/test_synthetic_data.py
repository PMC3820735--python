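"""Generator correctness: determinism, planted marginals/odds ratios, peak
conditioning, and round-tripping of every emitted file through the readers."""

import json

import numpy as np
import pandas as pd
import pytest

from promsig.genomic_io import read_bed, read_fasta, read_tss_catalog, \
    extract_promoter_windows, window_sequence
from promsig.motif_engine import build_occurrence_matrix, default_motif_library
from promsig.peak_analysis import positional_histogram
from promsig.synthetic_data import (
    BindingModel,
    ExpressionDesign,
    SimulationConfig,
    TssShapeMixture,
    copula_correlation,
    generate_expression,
    generate_genome,
    generate_peaks,
    generate_promoters,
    generate_tss_profiles,
    joint_from_odds_ratio,
    sample_presence,
    simulate_all,
)
from promsig.tss_shape import read_profiles_tsv


class TestGenome:
    def test_gc_content_within_tolerance(self):
        genome = generate_genome(1, 1_000_000, 0.5, seed=1)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.01)

    def test_deterministic_under_seed(self):
        assert generate_genome(2, 5000, 0.4, seed=7) == \
            generate_genome(2, 5000, 0.4, seed=7)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            generate_genome(1, 1000, gc, seed=0)


class TestJointModel:
    def test_independence_gives_product_joint(self):
        assert joint_from_odds_ratio(0.2, 0.3, 1.0) == pytest.approx(0.06)

    def test_odds_ratio_round_trips(self):
        for orr in (0.2, 5.0, 2.0):
            p11 = joint_from_odds_ratio(0.2, 0.2, orr)
            p10 = p01 = 0.2 - p11
            p00 = 1 - 0.4 + p11
            assert p11 * p00 / (p10 * p01) == pytest.approx(orr, rel=1e-6)

    def test_invalid_odds_ratio_rejected(self):
        with pytest.raises(ValueError):
            joint_from_odds_ratio(0.2, 0.2, 0.0)

    def test_copula_correlation_reproduces_joint(self):
        from scipy import stats

        p11 = joint_from_odds_ratio(0.2, 0.2, 5.0)
        rho = copula_correlation(0.2, 0.2, p11)
        za = stats.norm.isf(0.2)
        cov = [[1, rho], [rho, 1]]
        joint = stats.multivariate_normal(cov=cov).cdf([-za, -za])
        assert joint == pytest.approx(p11, abs=1e-8)

    def test_realized_marginals_and_or_at_n10000(self):
        """Marginals 0.2/0.2 with OR = 1 at n = 10,000: realized marginals
        within +/-2%, realized OR in [0.8, 1.25]."""
        config = SimulationConfig(n_promoters=10_000,
                                  marginals={"A": 0.2, "B": 0.2})
        pres = sample_presence(config, seed=2)
        assert pres["A"].mean() == pytest.approx(0.2, abs=0.02)
        assert pres["B"].mean() == pytest.approx(0.2, abs=0.02)
        t11 = (pres["A"] & pres["B"]).sum()
        t10 = (pres["A"] & ~pres["B"]).sum()
        t01 = (~pres["A"] & pres["B"]).sum()
        t00 = (~pres["A"] & ~pres["B"]).sum()
        orr = (t11 * t00) / (t10 * t01)
        assert 0.8 <= orr <= 1.25

    def test_planted_or5_realized_within_20pct(self):
        config = SimulationConfig(n_promoters=10_000,
                                  marginals={"A": 0.2, "B": 0.2},
                                  odds_ratios={("A", "B"): 5.0})
        pres = sample_presence(config, seed=3)
        t11 = (pres["A"] & pres["B"]).sum()
        t10 = (pres["A"] & ~pres["B"]).sum()
        t01 = (~pres["A"] & pres["B"]).sum()
        t00 = (~pres["A"] & ~pres["B"]).sum()
        orr = (t11 * t00) / (t10 * t01)
        assert orr == pytest.approx(5.0, rel=0.2)

    def test_infeasible_joint_model_rejected(self):
        # three mutually near-exclusive motifs: no joint law exists
        config = SimulationConfig(
            marginals={"A": 0.5, "B": 0.5, "C": 0.5},
            odds_ratios={("A", "B"): 0.05, ("A", "C"): 0.05,
                         ("B", "C"): 0.05},
        )
        with pytest.raises(ValueError, match="positive-definite"):
            sample_presence(config, seed=0)


class TestPromoterGeneration:
    def test_scanner_detects_every_planted_instance(self, small_dataset,
                                                    small_occurrence):
        truth = small_dataset["truth"]
        pres = small_occurrence >= 1
        planted = truth.motif_presence.values
        assert (pres.values & planted).sum() == planted.sum()

    def test_copy_counts_at_least_planted(self, small_dataset,
                                          small_occurrence):
        truth = small_dataset["truth"]
        assert (small_occurrence.values >= truth.motif_copies.values).all()

    def test_mean_copies_matches_distribution(self):
        """Copy-number distribution {1: 0.5, 3: 0.5} gives mean about 2
        among present promoters."""
        config = SimulationConfig(n_promoters=800,
                                  marginals={"NRF1": 0.5},
                                  copy_number={1: 0.5, 3: 0.5})
        _g, _c, _w, _s, truth = generate_promoters(config, seed=5)
        copies = truth.motif_copies["NRF1"].to_numpy()
        present = copies[truth.motif_presence["NRF1"].to_numpy()]
        assert present.mean() == pytest.approx(2.0, abs=0.15)

    def test_windows_round_trip_through_extraction(self, small_dataset):
        """Re-extracting windows from the emitted genome reproduces the
        generator's window sequences exactly (planted instances never
        straddle edges)."""
        genome = small_dataset["genome"]
        catalog = small_dataset["catalog"]
        windows = extract_promoter_windows(
            catalog, 150, 50, {c: len(s) for c, s in genome.items()})
        assert window_sequence(windows, genome) == small_dataset["seqs"]

    def test_deterministic(self):
        config = SimulationConfig(n_promoters=50)
        out1 = generate_promoters(config, seed=9)
        out2 = generate_promoters(config, seed=9)
        assert out1[0] == out2[0] and out1[3] == out2[3]


class TestPeaks:
    def test_conditional_rate_one_base_zero_binds_exactly_motif_promoters(
            self, small_dataset):
        truth = small_dataset["truth"]
        models = {"X": BindingModel(0.0, {"NRF1": 1.0}, jitter_sd=0.0)}
        _sets, bound = generate_peaks(small_dataset["catalog"],
                                      truth.motif_presence, models, seed=6)
        nrf1_promoters = set(
            truth.motif_presence.index[truth.motif_presence["NRF1"]])
        assert bound["X"] == nrf1_promoters

    def test_zero_jitter_puts_all_peaks_in_window(self, small_dataset):
        truth = small_dataset["truth"]
        models = {"X": BindingModel(0.5, {}, jitter_sd=0.0)}
        sets, _ = generate_peaks(small_dataset["catalog"],
                                 truth.motif_presence, models, seed=7)
        hist = positional_histogram(sets["X"], small_dataset["catalog"],
                                    small_dataset["windows"])
        assert hist.percentages[hist.labels.index("-150/+50")] == 100.0

    def test_base_rate_binomial_mean(self):
        config = SimulationConfig(n_promoters=2000, marginals={"M": 0.0001})
        pres = sample_presence(config, seed=8)
        cat_records = [(p, f"g{i}", "chr1", 2000 * (i + 1), "+")
                       for i, p in enumerate(pres.index)]
        from promsig.genomic_io import PromoterCatalog
        models = {"X": BindingModel(0.05, {}, jitter_sd=10.0)}
        _sets, bound = generate_peaks(PromoterCatalog(cat_records), pres,
                                      models, seed=9)
        assert len(bound["X"]) == pytest.approx(100, abs=30)

    def test_conditional_binding_fraction_matches_generator(self):
        """The fraction of factor-A windows also bound by factor B matches
        the generator's conditional probability within 3 percentage points
        at 2,000 promoters."""
        config = SimulationConfig(n_promoters=2000, marginals={"NRF1": 0.3})
        pres = sample_presence(config, seed=10)
        from promsig.genomic_io import PromoterCatalog
        cat = PromoterCatalog([(p, f"g{i}", "chr1", 2000 * (i + 1), "+")
                               for i, p in enumerate(pres.index)])
        models = {
            "A": BindingModel(0.0, {"NRF1": 1.0}, jitter_sd=0.0),
            "B": BindingModel(0.0, {"NRF1": 0.6}, jitter_sd=0.0),
        }
        _sets, bound = generate_peaks(cat, pres, models, seed=11)
        frac = len(bound["A"] & bound["B"]) / len(bound["A"])
        assert frac == pytest.approx(0.6, abs=0.03)

    def test_invalid_rates_rejected(self, small_dataset):
        models = {"X": BindingModel(1.5, {})}
        with pytest.raises(ValueError):
            generate_peaks(small_dataset["catalog"],
                           small_dataset["truth"].motif_presence, models, 0)


class TestExpression:
    def test_null_effect_mostly_unaffected(self):
        from promsig.response_classes import assign_classes, call_de_table, \
            class_counts
        design = ExpressionDesign(
            class_sizes={c: 50 for c in
                         ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]},
            effect=0.0, n_unaffected=600)
        expr, arms, _ = generate_expression(design, seed=12)
        counts = class_counts(assign_classes(
            call_de_table(expr, arms, "A"), call_de_table(expr, arms, "B")))
        assert counts["Unaffected"] / len(expr) >= 0.90

    def test_deterministic(self):
        design = ExpressionDesign()
        t1, _, _ = generate_expression(design, seed=13)
        t2, _, _ = generate_expression(design, seed=13)
        pd.testing.assert_frame_equal(t1, t2)


class TestSimulateAll:
    def test_every_file_round_trips_and_truth_is_consistent(self, tmp_path):
        config = SimulationConfig(
            n_promoters=60,
            expression=ExpressionDesign(
                class_sizes={c: 10 for c in
                             ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]},
                n_unaffected=40),
            tss_shape=TssShapeMixture(reads_per_promoter=30),
        )
        manifest = simulate_all(config, seed=99, outdir=tmp_path)
        genome = read_fasta(tmp_path / manifest["files"]["genome"])
        catalog = read_tss_catalog(tmp_path / manifest["files"]["tss_catalog"])
        assert len(catalog) == 60
        for factor in config.binding_models:
            peaks = read_bed(tmp_path / manifest["files"][f"peaks_{factor}"])
            assert all(p.contig in genome for p in peaks)
        profiles = read_profiles_tsv(tmp_path / manifest["files"]["tss_profiles"])
        assert {p.promoter_id for p in profiles} == set(catalog.promoter_ids)
        expr = pd.read_csv(tmp_path / manifest["files"]["expression"],
                           sep="\t", index_col=0)
        assert len(expr) == 120
        truth_presence = pd.read_csv(
            tmp_path / manifest["files"]["truth_motif_presence"],
            sep="\t", index_col=0)
        windows = extract_promoter_windows(
            catalog, 150, 50, {c: len(s) for c, s in genome.items()})
        occ = build_occurrence_matrix(window_sequence(windows, genome),
                                      default_motif_library())
        planted = truth_presence.to_numpy(dtype=bool)
        assert ((occ.to_numpy() >= 1) & planted).sum() == planted.sum()
        with open(tmp_path / "manifest.json") as fh:
            assert json.load(fh) == manifest

    def test_same_seed_same_files(self, tmp_path):
        config = SimulationConfig(n_promoters=30)
        m1 = simulate_all(config, 5, tmp_path / "r1")
        m2 = simulate_all(config, 5, tmp_path / "r2")
        assert m1["stage_seeds"] == m2["stage_seeds"]
        for f in m1["files"].values():
            assert (tmp_path / "r1" / f).read_bytes() == \
                (tmp_path / "r2" / f).read_bytes()
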