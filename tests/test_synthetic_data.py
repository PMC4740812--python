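"""Generator contracts: determinism, planted structure, configured effects."""

import numpy as np
import pandas as pd
import pytest

from tbpnoise.cofactor_classes import classify_coactivator
from tbpnoise.synthetic_data import (
    GeneratorConfig,
    gen_cytometry,
    gen_noise_table,
    gen_occupancy,
    gen_pbm,
    gen_promoters,
    gen_turnover,
    write_promoter_fasta,
)
from tbpnoise.tbs_classify import count_mismatches, scan_promoter


@pytest.fixture(scope="module")
def truth(small_config):
    return gen_promoters(small_config)


class TestGenPromoters:
    def test_empty_config_gives_empty_outputs(self):
        out = gen_promoters(GeneratorConfig(seed=0, n_genes=0))
        assert out.empty and "tbs_class" in out.columns

    def test_planted_sequence_sits_at_recorded_offset(self, truth):
        for row in truth.itertuples():
            assert row.sequence[row.offset : row.offset + 8] == row.planted_seq

    def test_planted_mismatch_counts_match_class(self, truth):
        mm = truth["planted_seq"].map(count_mismatches)
        assert (mm[truth["tbs_class"] == "TATA-box"] == 0).all()
        assert mm[truth["tbs_class"] == "TATA-like"].isin([1, 2]).all()
        assert (mm[truth["tbs_class"] == "other"] >= 3).all()

    def test_scanner_recovers_planted_class_and_offset(self, truth):
        for row in truth.itertuples():
            rec = scan_promoter(row.sequence)
            assert rec.tbs_class == row.tbs_class
            assert rec.subset == row.subset
            if row.tbs_class != "other":
                assert rec.offset == row.offset

    def test_seed_determinism_bytes(self, small_config, tmp_path):
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_promoter_fasta(gen_promoters(small_config), a)
        write_promoter_fasta(gen_promoters(small_config), b)
        assert a.read_bytes() == b.read_bytes()


class TestGenOccupancy:
    def test_zero_sigma_means_exactly_at_configured_effects(self, truth, small_config):
        config = small_config.replace(occupancy_sigma=0.0, missing_rate=0.0)
        table, reg = gen_occupancy(config, truth)
        merged = table.merge(reg, on="gene_id")
        # unregulated Taf1p sits exactly at the configured low level
        low = merged.loc[~merged["tfiid_regulated"], "Taf1p"]
        assert np.allclose(low, np.exp(-np.log(config.regulation_shift) / 2))

    def test_class_ordering_of_medians(self, default_config):
        truth = gen_promoters(default_config)
        table, _ = gen_occupancy(default_config, truth)
        merged = table.merge(
            truth[["gene_id", "tbs_class", "subset"]], on="gene_id"
        )
        spt = merged.groupby("subset")["Spt20p"].median()
        assert spt["T5"] > spt["A5"]
        by_class = merged.groupby("tbs_class")[["Spt20p", "Taf1p", "Mot1p"]].median()
        assert (
            by_class.loc["TATA-box", "Spt20p"]
            > by_class.loc["TATA-like", "Spt20p"]
            > by_class.loc["other", "Spt20p"]
        )
        # TFIID occupancy stays flat across TBS classes (mean within 25%;
        # the 50/50 regulated mixture is bimodal, so medians are unstable)
        taf = merged.groupby("tbs_class")["Taf1p"].mean()
        assert taf.max() / taf.min() < 1.25
        assert (
            by_class.loc["TATA-box", "Mot1p"] > by_class.loc["other", "Mot1p"]
        )

    def test_missing_rate_honoured(self, truth, small_config):
        config = small_config.replace(missing_rate=0.1)
        table, _ = gen_occupancy(config, truth)
        frac = table["Spt20p"].isna().mean()
        assert frac == pytest.approx(0.1, abs=0.05)

    def test_planted_regulation_recoverable_by_median_split(self, default_config):
        truth = gen_promoters(default_config)
        table, reg = gen_occupancy(default_config, truth)
        classes = classify_coactivator(table)
        recovery = (
            classes["coactivator_class"]
            == reg.set_index("gene_id").loc[classes.index, "coactivator_class"]
        ).mean()
        assert recovery >= 0.9


class TestGenPbm:
    def test_single_replicate_flag_propagates(self):
        config = GeneratorConfig(seed=2, pbm_replicates=1)
        from tbpnoise.pbm import aggregate_probe_signal

        medians = aggregate_probe_signal(gen_pbm(config))
        assert medians["single_replicate"].all()

    def test_determinism(self, small_config):
        pd.testing.assert_frame_equal(
            gen_pbm(small_config), gen_pbm(small_config)
        )

    def test_contains_all_eight_consensus_instances(self, small_config):
        probes = gen_pbm(small_config)
        exact = {
            m for m in probes["motif"].unique() if count_mismatches(m) == 0
        }
        assert len(exact) == 8


class TestGenNoiseTable:
    def test_zero_offsets_and_residual_give_exact_inverse_relation(self, truth, small_config):
        config = small_config.replace(
            dm_offsets=(0.0, 0.0, 0.0, 0.0), dm_residual_sigma=0.0
        )
        table = gen_noise_table(config, truth)
        np.testing.assert_allclose(
            table["cv"], config.cv_scale / np.sqrt(table["mean"]), rtol=1e-12
        )

    def test_inverse_mean_cv_relationship(self, truth, small_config):
        from scipy.stats import spearmanr

        table = gen_noise_table(small_config, truth)
        rho = spearmanr(table["mean"], table["cv"]).statistic
        assert rho < -0.5

    def test_empty_truth_gives_empty_table(self, small_config):
        empty = gen_promoters(small_config.replace(n_genes=0))
        assert gen_noise_table(small_config, empty).empty


class TestGenTurnover:
    def test_values_within_observed_range(self, truth, small_config):
        values = gen_turnover(small_config, truth)
        assert values.between(0.008, 0.051).all()

    def test_class_ordering_at_large_n(self, default_config):
        truth = gen_promoters(default_config)
        values = gen_turnover(default_config, truth)
        by_class = values.groupby(truth.set_index("gene_id")["tbs_class"]).mean()
        assert by_class["TATA-box"] > by_class["TATA-like"]

    def test_single_gene(self, small_config):
        truth = gen_promoters(small_config.replace(n_genes=1))
        values = gen_turnover(small_config, truth)
        assert len(values) == 1 and 0.008 <= values.iloc[0] <= 0.051


class TestGenCytometry:
    def test_events_within_adc_bounds(self, small_config):
        events = gen_cytometry(small_config)
        assert (events["fsc_a"] > 0).all() and (events["fsc_a"] < 2**18 - 1).all()
        assert (events["ssc_a"] > 0).all() and (events["ssc_a"] < 2**18 - 1).all()

    def test_no_confound_raw_cv_matches_true_cv(self):
        config = GeneratorConfig(seed=4, n_events=20000, size_confound=0.0)
        events = gen_cytometry(config)
        raw = events["gfp"]
        assert raw.std(ddof=1) / raw.mean() == pytest.approx(
            config.true_cv, rel=0.05
        )

    def test_replicate_structure(self, small_config):
        events = gen_cytometry(small_config)
        assert events["replicate"].value_counts().tolist() == [
            small_config.n_events
        ] * small_config.n_replicates

    def test_determinism(self, small_config):
        pd.testing.assert_frame_equal(
            gen_cytometry(small_config), gen_cytometry(small_config)
        )
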