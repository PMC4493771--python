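"""2^-ddCt relative quantification and cross-platform concordance."""

import numpy as np
import pandas as pd
import pytest

from dtapipe.qpcr import (QpcrError, concordance, delta_delta_ct,
                          load_ct_table)
from dtapipe.quantify import ExpressionMatrix
from dtapipe.synthetic import (SimConfig, generate_ct_table,
                               generate_experiment)
from oracles import ddct_from_definition

SAMPLES = ("0d", "1d", "2d", "3d")


def _ct_frame(target_cts, ref_shift=0.0, replicates=1):
    """target_cts: {sample: ct}; references EF1a=19, GAPDH=21 (+shift)."""
    rows = []
    for sample, ct in target_cts.items():
        for rep in range(1, replicates + 1):
            rows.append(["tg", sample, rep, ct, False])
            rows.append(["REF_EF1a", sample, rep, 19.0 + ref_shift, True])
            rows.append(["REF_GAPDH", sample, rep, 21.0 + ref_shift, True])
    return pd.DataFrame(
        rows, columns=["gene_id", "sample", "replicate", "ct",
                       "is_reference"])


class TestDeltaDeltaCt:
    def test_calibrator_sample_is_exactly_one(self):
        table = delta_delta_ct(_ct_frame(dict.fromkeys(SAMPLES, 25.0)))
        lookup = table.set_index("sample")["relative_expression"]
        assert lookup["0d"] == 1.0
        assert (table["relative_expression"] == 1.0).all()

    def test_two_cycles_lower_is_fourfold(self):
        table = delta_delta_ct(
            _ct_frame({"0d": 25.0, "1d": 23.0, "2d": 25.0, "3d": 25.0}))
        lookup = table.set_index("sample")["relative_expression"]
        assert lookup["1d"] == pytest.approx(4.0)

    def test_matches_definition_oracle_on_noisy_replicates(self):
        rng = np.random.default_rng(2)
        rows = []
        for gene in ["t1", "t2"]:
            base = rng.uniform(24, 28)
            for sample in SAMPLES:
                for rep in range(1, 4):
                    rows.append([gene, sample, rep,
                                 base + rng.normal(0, 0.3), False])
        for ref, base in [("REF_EF1a", 19.0), ("REF_GAPDH", 21.0)]:
            for sample in SAMPLES:
                for rep in range(1, 4):
                    rows.append([ref, sample, rep,
                                 base + rng.normal(0, 0.3), True])
        frame = pd.DataFrame(rows, columns=["gene_id", "sample", "replicate",
                                            "ct", "is_reference"])
        table = delta_delta_ct(frame)
        expected = ddct_from_definition(
            frame[["gene_id", "sample", "ct", "is_reference"]]
            .itertuples(index=False), "0d")
        for _, row in table.iterrows():
            assert row["relative_expression"] == pytest.approx(
                expected[(row["gene_id"], row["sample"])], rel=1e-12)

    def test_reference_invariance_constant_sample_shift(self):
        base = delta_delta_ct(
            _ct_frame({"0d": 25.0, "1d": 22.0, "2d": 25.0, "3d": 26.0}))
        shifted_frame = _ct_frame(
            {"0d": 25.0, "1d": 22.0 + 1.7, "2d": 25.0, "3d": 26.0})
        # shift target AND references of sample 1d by +1.7 cycles
        mask = shifted_frame["sample"] == "1d"
        shifted_frame.loc[mask & shifted_frame["is_reference"], "ct"] += 1.7
        shifted = delta_delta_ct(shifted_frame)
        pd.testing.assert_frame_equal(base, shifted)

    def test_uniform_target_shift_leaves_re_unchanged(self):
        cts = {"0d": 25.0, "1d": 22.0, "2d": 25.0, "3d": 26.0}
        base = delta_delta_ct(_ct_frame(cts))
        shifted = delta_delta_ct(
            _ct_frame({s: c - 1.0 for s, c in cts.items()}))
        pd.testing.assert_frame_equal(base, shifted)

    def test_missing_reference_in_a_sample_is_an_error(self):
        frame = _ct_frame(dict.fromkeys(SAMPLES, 25.0))
        frame = frame[~((frame["gene_id"] == "REF_GAPDH")
                        & (frame["sample"] == "2d"))]
        with pytest.raises(QpcrError, match="reference"):
            delta_delta_ct(frame)

    def test_missing_calibrator_is_an_error(self):
        frame = _ct_frame({"1d": 23.0, "2d": 25.0})
        with pytest.raises(QpcrError, match="calibrator"):
            delta_delta_ct(frame)

    def test_load_rejects_nonpositive_ct(self, tmp_path):
        frame = _ct_frame(dict.fromkeys(SAMPLES, 25.0))
        frame.loc[0, "ct"] = -1.0
        path = tmp_path / "ct.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(QpcrError, match="positive"):
            load_ct_table(path)


def _expr(profile, genes=("tg",)):
    """ExpressionMatrix with one RPKM profile over the seven libraries."""
    libs = ["CK0", "CK1", "CK2", "CK3", "ETH1", "ETH2", "ETH3"]
    values = {
        "CK0": profile[0], "CK1": profile[0], "CK2": profile[0],
        "CK3": profile[0], "ETH1": profile[1], "ETH2": profile[2],
        "ETH3": profile[3],
    }
    frame = pd.DataFrame([[values[l] for l in libs]] * len(genes),
                         index=pd.Index(genes, name="gene_id"), columns=libs)
    return ExpressionMatrix(rpkm=frame, denominators=frame.sum(axis=0))


class TestConcordance:
    def test_identical_direction_is_concordant(self):
        qpcr = delta_delta_ct(
            _ct_frame({"0d": 25.0, "1d": 22.0, "2d": 25.0, "3d": 25.0}))
        table, summary = concordance(qpcr, _expr((10.0, 80.0, 10.0, 10.0)))
        assert bool(table["concordant"].iloc[0])
        assert summary == {"method": "day1", "concordant": 1, "total": 1}

    def test_opposite_direction_is_discordant(self):
        qpcr = delta_delta_ct(
            _ct_frame({"0d": 25.0, "1d": 23.0, "2d": 25.0, "3d": 25.0}))
        table, _ = concordance(qpcr, _expr((40.0, 10.0, 40.0, 40.0)))
        assert not bool(table["concordant"].iloc[0])

    def test_spearman_metric(self):
        qpcr = delta_delta_ct(
            _ct_frame({"0d": 25.0, "1d": 22.0, "2d": 23.0, "3d": 21.0}))
        table, summary = concordance(
            qpcr, _expr((5.0, 40.0, 20.0, 80.0)), method="spearman")
        assert bool(table["concordant"].iloc[0])
        assert summary["method"] == "spearman"

    def test_absent_gene_is_an_error(self):
        qpcr = delta_delta_ct(_ct_frame(dict.fromkeys(SAMPLES, 25.0)))
        with pytest.raises(QpcrError, match="absent"):
            concordance(qpcr, _expr((1.0, 1.0, 1.0, 1.0), genes=("other",)))


class TestGenerateCtTable:
    def test_noiseless_null_gene_constant(self):
        config = SimConfig(n_genes=100, seed=3,
                           planted_fractions={"0+0": 0.05})
        _, truth = generate_experiment(config)
        # pattern 0+0: zero planted day-1/day-3 effect
        table = generate_ct_table(truth, 2, noise_sd=0.0, seed=3)
        targets = table[~table["is_reference"]]
        for _, block in targets.groupby("gene_id"):
            cts = block.groupby("sample")["ct"].mean()
            assert cts["0d"] == cts["1d"] == cts["3d"]
            assert cts["2d"] == cts["0d"] - 3.0  # planted effect_log2fc

    def test_noiseless_planted_shift_in_cycles(self):
        config = SimConfig(n_genes=100, seed=4, effect_log2fc=2.0,
                           planted_fractions={"+00": 0.05})
        _, truth = generate_experiment(config)
        table = generate_ct_table(truth, 3, noise_sd=0.0, seed=4)
        targets = table[~table["is_reference"]]
        for _, block in targets.groupby("gene_id"):
            cts = block.groupby("sample")["ct"].mean()
            assert cts["1d"] == pytest.approx(cts["0d"] - 2.0)

    def test_negative_noise_rejected(self):
        config = SimConfig(n_genes=200, seed=5)
        _, truth = generate_experiment(config)
        from dtapipe.synthetic import SimConfigError
        with pytest.raises(SimConfigError):
            generate_ct_table(truth, 2, noise_sd=-0.1)

    def test_direction_recovery_under_noise(self):
        """ddCt recovers the planted day-1 direction for >= 95% of
        targets (41-gene panels, noise 0.2, aggregated over seeds)."""
        agree = total = 0
        for seed in range(30):
            config = SimConfig(seed=seed)
            _, truth = generate_experiment(config)
            table = generate_ct_table(truth, 41, noise_sd=0.2, seed=seed)
            re_table = delta_delta_ct(table)
            day1 = re_table[re_table["sample"] == "1d"] \
                .set_index("gene_id")["relative_expression"]
            planted = truth.genes.set_index("gene_id")["lfc_1d"]
            for gene, re_value in day1.items():
                expected = planted[gene]
                observed = (1 if re_value >= 1.5
                            else -1 if re_value <= 1 / 1.5 else 0)
                agree += observed == np.sign(expected)
                total += 1
        assert agree / total >= 0.95
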