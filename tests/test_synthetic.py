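"""Synthetic experiment generator: determinism, planted structure, errors."""

import numpy as np
import pandas as pd
import pytest

from dtapipe.synthetic import (AnnotationConfig, SimConfig, SimConfigError,
                               SyntheticTruth, generate_annotation,
                               generate_ct_table, generate_experiment,
                               pattern_signs)


class TestSimConfigValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(SimConfigError, match="sum"):
            SimConfig(planted_fractions={"+00": 0.7, "-00": 0.5})

    def test_zero_genes_and_zero_depth_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_genes=0)
        with pytest.raises(SimConfigError):
            SimConfig(library_depth=0)

    def test_bad_pattern_labels_rejected(self):
        for bad in ("0000", "x00", "000"):
            with pytest.raises(SimConfigError):
                SimConfig(planted_fractions={bad: 0.1})

    def test_subfourfold_effect_rejected(self):
        with pytest.raises(SimConfigError, match="four-fold"):
            SimConfig(effect_log2fc=1.5)

    def test_term_size_range_larger_than_universe_rejected(self):
        with pytest.raises(SimConfigError, match="universe"):
            SimConfig(n_genes=30,
                      annotation=AnnotationConfig(term_size_range=(10, 60)))


class TestGenerateExperiment:
    def test_all_fractions_zero_means_all_null(self):
        counts, truth = generate_experiment(
            SimConfig(n_genes=200, planted_fractions={}, seed=1))
        assert (truth.genes["pattern"] == "null").all()
        assert (truth.genes[["lfc_1d", "lfc_2d", "lfc_3d"]] == 0).all().all()

    def test_seven_libraries_and_nonnegative_integer_counts(self, default_run):
        _, counts, _ = default_run
        assert counts.libraries == ("CK0", "CK1", "CK2", "CK3",
                                    "ETH1", "ETH2", "ETH3")
        assert (counts.counts.to_numpy() >= 0).all()
        assert counts.counts.dtypes.eq(np.int64).all()

    def test_identical_seed_reproduces_bitwise(self):
        config = SimConfig(n_genes=300, seed=77)
        counts_a, truth_a = generate_experiment(config)
        counts_b, truth_b = generate_experiment(config)
        pd.testing.assert_frame_equal(counts_a.counts, counts_b.counts)
        pd.testing.assert_series_equal(counts_a.lengths, counts_b.lengths)
        pd.testing.assert_frame_equal(truth_a.genes, truth_b.genes)

    def test_different_seeds_differ(self):
        counts_a, _ = generate_experiment(SimConfig(n_genes=300, seed=1))
        counts_b, _ = generate_experiment(SimConfig(n_genes=300, seed=2))
        assert not counts_a.counts.equals(counts_b.counts)

    def test_planted_fraction_counts(self):
        config = SimConfig(n_genes=1000, seed=5)
        _, truth = generate_experiment(config)
        for pattern, frac in config.planted_fractions.items():
            assert (truth.genes["pattern"] == pattern).sum() == int(
                np.floor(frac * 1000))

    def test_expected_ratio_matches_planted_fold(self):
        """dispersion 0, effect_log2fc 2, pattern (+,+,+): mean observed
        ETH1:CK1 count ratio over 1000 seeds is 4 within 3 SE."""
        ratios = []
        for seed in range(1000):
            config = SimConfig(n_genes=50, library_depth=200_000,
                               dispersion=0.0, effect_log2fc=2.0,
                               planted_fractions={"+++": 0.02},
                               annotation=AnnotationConfig(
                                   term_size_range=(5, 20)),
                               seed=seed)
            counts, truth = generate_experiment(config)
            gene = truth.non_null["gene_id"].iloc[0]
            x = counts.counts.loc[gene, "CK1"]
            y = counts.counts.loc[gene, "ETH1"]
            if x > 0:
                ratios.append(y / x)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - 4.0) <= 3 * se

    def test_effect_realized_in_log2_count_ratio(self):
        """At depth 1e6 and dispersion 0, the mean empirical log2 ratio
        of well-expressed planted day-1 genes is within 0.2 of the
        planted effect."""
        config = SimConfig(n_genes=500, dispersion=0.0, seed=9)
        counts, truth = generate_experiment(config)
        genes = truth.genes.set_index("gene_id")
        planted_up = genes[(genes["lfc_1d"] == 3.0)
                           & (genes["baseline_mean"] >= 300)]
        observed = np.log2(counts.counts.loc[planted_up.index, "ETH1"]
                           / counts.counts.loc[planted_up.index, "CK1"])
        assert len(planted_up) >= 3
        assert abs(observed.mean() - 3.0) <= 0.2

    def test_control_libraries_share_baseline_without_drift(self):
        config = SimConfig(n_genes=400, seed=13)
        counts, truth = generate_experiment(config)
        # no drift configured: CK0..CK3 totals all near the target depth
        # and per-gene control means statistically indistinguishable
        totals = counts.totals()
        for lib in ("CK0", "CK1", "CK2", "CK3"):
            assert abs(totals[lib] - config.library_depth) \
                < 0.05 * config.library_depth

    def test_drift_recorded_in_truth(self):
        config = SimConfig(n_genes=400, seed=13, control_drift_fraction=0.1)
        _, truth = generate_experiment(config)
        assert len(truth.drift_genes) == 40

    def test_truth_json_roundtrip(self, tmp_path, default_run):
        _, _, truth = default_run
        path = tmp_path / "truth.json"
        truth.to_json(path)
        again = SyntheticTruth.from_json(path)
        pd.testing.assert_frame_equal(truth.genes, again.genes)
        assert again.enriched_terms == truth.enriched_terms


class TestGenerateAnnotation:
    def test_no_enriched_terms_records_none(self):
        config = SimConfig(
            n_genes=300, seed=2,
            annotation=AnnotationConfig(n_enriched_terms=0))
        _, truth = generate_experiment(config)
        annot = generate_annotation(config, truth)
        assert truth.enriched_terms["GO-like"] == ()
        assert len(annot.terms) == config.annotation.n_terms

    def test_maximal_strength_fills_terms_with_planted_genes(self):
        config = SimConfig(
            n_genes=500, seed=3,
            annotation=AnnotationConfig(enrichment_strength=1.0,
                                        term_size_range=(5, 20)))
        _, truth = generate_experiment(config)
        annot = generate_annotation(config, truth)
        non_null = set(truth.non_null["gene_id"])
        for term in truth.enriched_terms["GO-like"]:
            assert annot.terms[term] <= non_null

    def test_term_sizes_within_range(self, default_run):
        config, _, truth = default_run
        annot = generate_annotation(config, truth, "KEGG-like")
        lo, hi = config.annotation.term_size_range
        for members in annot.terms.values():
            assert lo <= len(members) <= hi

    def test_vocabularies_are_independent_draws(self, default_run):
        config, _, truth = default_run
        go = generate_annotation(config, truth, "GO-like")
        kegg = generate_annotation(config, truth, "KEGG-like")
        assert set(go.terms) != set(kegg.terms)

    def test_annotation_tsv_roundtrip(self, tmp_path, default_run):
        from dtapipe.enrichment import AnnotationMap
        config, _, truth = default_run
        annot = generate_annotation(config, truth)
        path = tmp_path / "annot.tsv"
        annot.to_tsv(path)
        again = AnnotationMap.from_tsv(path)
        assert again.vocabulary == annot.vocabulary
        assert again.terms == annot.terms


class TestPatternSigns:
    @pytest.mark.parametrize("pattern,signs", [
        ("+00", (1, 0, 0)), ("0-0", (0, -1, 0)), ("+-+", (1, -1, 1)),
        ("null", (0, 0, 0)),
    ])
    def test_mapping(self, pattern, signs):
        assert pattern_signs(pattern) == signs


class TestCtDeterminism:
    def test_same_seed_same_table(self, default_run):
        _, _, truth = default_run
        a = generate_ct_table(truth, 10, seed=4)
        b = generate_ct_table(truth, 10, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_targets_rejected(self, default_run):
        _, _, truth = default_run
        with pytest.raises(SimConfigError, match="exceeds"):
            generate_ct_table(truth, 10_000)
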