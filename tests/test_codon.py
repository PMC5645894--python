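"""Codon counting, frequency normalization, FPKM weighting, tRNA correlation."""

import numpy as np
import pandas as pd
import pytest

from atlaskit import codon
from atlaskit.errors import DimensionError, DomainError, InputError


class TestCountCodons:
    def test_three_codon_cds(self):
        table = codon.count_codons_cds(["ATGAAATAA"])
        assert table.values["ATG"] == 1 and table.values["AAA"] == 1 and table.values["TAA"] == 1
        freq = codon.to_frequency(table)
        assert freq.values["ATG"] == pytest.approx(1000 / 3)

    def test_empty_input_all_zero(self):
        table = codon.count_codons_cds([])
        assert table.total == 0

    def test_concatenation_additivity(self):
        s1, s2 = "ATGAAATAA", "ATGCCCGGGTGA"
        both = codon.count_codons_cds([s1, s2]).values
        sep = codon.count_codons_cds([s1]).values + codon.count_codons_cds([s2]).values
        pd.testing.assert_series_equal(both, sep)

    def test_partial_codon_names_record(self):
        with pytest.raises(InputError, match="bad_rec"):
            codon.count_codons_cds({"bad_rec": "ATGAA"})

    def test_n_codons_excluded_and_tallied(self):
        table = codon.count_codons_cds(["ATGNNAAAA"])  # NNA skipped
        assert table.n_excluded == 1
        assert table.total == 2


class TestFrequencyUnits:
    def test_unit_totals(self):
        table = codon.count_codons_cds(["ATGAAACCCGGGTTTTAA"])
        per_k = codon.to_frequency(table, "per-thousand")
        pct = codon.to_frequency(table, "percent")
        assert per_k.total == pytest.approx(1000, abs=1e-6)
        assert pct.total == pytest.approx(100, abs=1e-6)

    def test_zero_table_rejected(self):
        with pytest.raises(DomainError):
            codon.to_frequency(codon.count_codons_cds([]))


class TestTranscriptomeUsage:
    def test_single_transcript_weight_cancels(self):
        counts = pd.DataFrame(
            [{"AAA": 2.0, "GGG": 6.0}], index=["t1"]
        ).reindex(columns=codon.CODONS, fill_value=0.0)
        fpkm = pd.DataFrame({"lib1": [5.0], "lib2": [0.25]}, index=["t1"])
        out = codon.transcriptome_usage(counts, fpkm)
        for lib in ("lib1", "lib2"):
            assert out.per_library.loc["AAA", lib] == pytest.approx(25.0)
            assert out.per_library.loc["GGG", lib] == pytest.approx(75.0)

    def test_weighted_arithmetic(self):
        counts = pd.DataFrame(
            [{"AAA": 2.0}, {"GGG": 2.0}], index=["t1", "t2"]
        ).reindex(columns=codon.CODONS).fillna(0.0)
        fpkm = pd.DataFrame({"lib": [1.0, 3.0]}, index=["t1", "t2"])
        out = codon.transcriptome_usage(counts, fpkm)
        assert out.per_library.loc["AAA", "lib"] == pytest.approx(25.0)
        assert out.per_library.loc["GGG", "lib"] == pytest.approx(75.0)

    def test_identical_libraries_mean_equals_each(self):
        counts = pd.DataFrame(
            [{"AAA": 1.0, "CCC": 3.0}], index=["t1"]
        ).reindex(columns=codon.CODONS, fill_value=0.0)
        fpkm = pd.DataFrame({f"lib{i}": [2.0] for i in range(4)}, index=["t1"])
        out = codon.transcriptome_usage(counts, fpkm)
        pd.testing.assert_series_equal(
            out.mean.values, out.per_library["lib0"], check_names=False
        )

    def test_equal_fpkm_reduces_to_pooled_counts(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(0, 9, (5, 64)).astype(float),
            index=[f"t{i}" for i in range(5)], columns=list(codon.CODONS),
        )
        fpkm = pd.DataFrame({"lib": [7.0] * 5}, index=counts.index)
        out = codon.transcriptome_usage(counts, fpkm)
        pooled = counts.sum(axis=0)
        expected = pooled / pooled.sum() * 100.0
        np.testing.assert_allclose(out.per_library["lib"].to_numpy(), expected.to_numpy())

    def test_zero_weight_library_flagged_and_excluded(self):
        counts = pd.DataFrame(
            [{"AAA": 2.0}], index=["t1"]
        ).reindex(columns=codon.CODONS, fill_value=0.0)
        fpkm = pd.DataFrame({"ok": [1.0], "dead": [0.0]}, index=["t1"])
        out = codon.transcriptome_usage(counts, fpkm)
        assert out.flagged_libraries == ["dead"]
        assert out.mean.values["AAA"] == pytest.approx(100.0)


class TestAggregateByAa:
    def test_single_codon_amino_acid(self):
        table = codon.CodonTable(
            values=pd.Series({"ATG": 100.0}), unit="percent", basis="genome"
        )
        aa, stop = codon.aggregate_by_aa(table)
        assert aa["M"] == pytest.approx(100.0)
        assert stop == 0.0

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        table = codon.CodonTable(
            values=pd.Series(rng.random(64), index=list(codon.CODONS)), unit="count"
        )
        aa, stop = codon.aggregate_by_aa(table)
        assert aa.sum() + stop == pytest.approx(table.total, abs=1e-9)

    def test_leucine_pools_six_codons(self):
        vals = pd.Series(0.0, index=list(codon.CODONS))
        for c in ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"):
            vals[c] = 1.0
        vals["TTT"] = 5.0  # Phe, must not leak into Leu
        aa, _ = codon.aggregate_by_aa(codon.CodonTable(values=vals, unit="count"))
        assert aa["L"] == pytest.approx(6.0)
        assert aa["F"] == pytest.approx(5.0)


class TestCorrelateTrna:
    def usage(self):
        rng = np.random.default_rng(1)
        return pd.Series(rng.uniform(1, 10, 20), index=list(codon.AMINO_ACIDS))

    def test_proportional_counts_give_r_one(self):
        u = self.usage()
        assert codon.correlate_trna(u, u * 3) == pytest.approx(1.0)
        assert codon.correlate_trna(u, -u + 20) == pytest.approx(-1.0)

    def test_noisy_proportional_recovery(self):
        u = self.usage()
        rng = np.random.default_rng(7)
        noisy = u * 2 + rng.normal(0, 0.1 * (u.max() - u.min()), 20)
        assert codon.correlate_trna(u, noisy) > 0.8

    def test_degenerate_inputs(self):
        u = self.usage()
        with pytest.raises(DomainError):
            codon.correlate_trna(u, pd.Series(2.0, index=u.index))
        with pytest.raises(DimensionError):
            codon.correlate_trna(u.iloc[:2], u.iloc[:2])


class TestOrfCodonCounts:
    def test_stop_excluded_by_default(self):
        seqs = {"t1": "TTATGAAACCCTAGTT"}
        counts = codon.orf_codon_counts(seqs)
        assert counts.loc["t1", "ATG"] == 1
        assert counts.loc["t1", "AAA"] == 1
        assert counts.loc["t1", "TAG"] == 0
        with_stop = codon.orf_codon_counts(seqs, include_stop=True)
        assert with_stop.loc["t1", "TAG"] == 1

    def test_no_orf_is_all_zero(self):
        counts = codon.orf_codon_counts({"t1": "CCCCCCCC"})
        assert counts.loc["t1"].sum() == 0


def test_trna_table_reader(tmp_path):
    path = tmp_path / "trna.tsv"
    path.write_text("Ala\t10\nGLY\t7\nM\t3\n")
    counts = codon.read_trna_counts(path)
    assert counts["A"] == 10 and counts["G"] == 7 and counts["M"] == 3
    bad = tmp_path / "bad.tsv"
    bad.write_text("Xx\t1\n")
    with pytest.raises(InputError):
        codon.read_trna_counts(bad)
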