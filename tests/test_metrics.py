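"""Frequency metrics, genome baseline, gene-set selection, and T-statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonmod import (
    CodingSequence,
    count_matrix,
    ending_bias_summary,
    gene_set_tstat,
    genome_baseline,
    isoacceptor_frequency,
    select_gene_sets,
    significance_cutoff_p,
    total_frequency,
)
from codonmod.metrics import MetricsError

from conftest import random_cds


def _iso_freq_oracle(sequence: str, table) -> dict:
    """Independent brute-force per-family ratio from a raw string scan."""
    counts = {}
    for i in range(0, len(sequence), 3):
        c = sequence[i : i + 3]
        counts[c] = counts.get(c, 0) + 1
    out = {}
    for fam in table.families.values():
        fam_total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = counts.get(c, 0) / fam_total if fam_total else np.nan
    return out


def _total_freq_oracle(sequence: str, table) -> dict:
    counts = {}
    for i in range(0, len(sequence), 3):
        c = sequence[i : i + 3]
        counts[c] = counts.get(c, 0) + 1
    total = sum(counts.get(c, 0) for c in table.sense_codons)
    return {c: counts.get(c, 0) / total for c in table.sense_codons}


class TestIsoacceptorFrequency:
    def test_hand_count(self, table):
        cds = CodingSequence("g", "ATG" + "AAC" * 2 + "AAT" + "TAA")
        freq = isoacceptor_frequency(count_matrix([cds], table), table).iloc[0]
        assert freq["AAC"] == pytest.approx(2 / 3)
        assert freq["AAT"] == pytest.approx(1 / 3)

    def test_single_member_occurrence(self, table):
        cds = CodingSequence("g", "ATGAACTAA")
        freq = isoacceptor_frequency(count_matrix([cds], table), table).iloc[0]
        assert freq["AAC"] == 1.0 and freq["AAT"] == 0.0

    def test_absent_family_is_undefined_not_zero(self, table):
        cds = CodingSequence("g", "ATGAACTAA")  # no His codons
        freq = isoacceptor_frequency(count_matrix([cds], table), table).iloc[0]
        assert np.isnan(freq["CAC"]) and np.isnan(freq["CAT"])

    def test_family_sums_to_one_where_present(self, table):
        rng = np.random.default_rng(3)
        counts = count_matrix([random_cds(rng, table, 200) for _ in range(10)], table)
        freq = isoacceptor_frequency(counts, table)
        for fam in table.families.values():
            sums = freq[list(fam)].sum(axis=1, min_count=1).dropna()
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_invariant_to_duplicating_the_gene(self, table):
        rng = np.random.default_rng(4)
        cds = random_cds(rng, table, 100)
        doubled = CodingSequence("dup", cds.sequence[:-3] * 2 + "TAA")
        f1 = isoacceptor_frequency(count_matrix([cds], table), table).iloc[0]
        f2 = isoacceptor_frequency(count_matrix([doubled], table), table).iloc[0]
        pd.testing.assert_series_equal(f1, f2, check_names=False)


class TestTotalFrequency:
    def test_hand_count_excludes_stop(self, table):
        cds = CodingSequence("g", "ATGAACAACAATTAA")
        freq = total_frequency(count_matrix([cds], table), table).iloc[0]
        assert freq["AAC"] == pytest.approx(0.5)  # 2 of the 4 sense codons
        assert "TAA" not in freq.index

    def test_sums_to_one(self, table):
        rng = np.random.default_rng(5)
        counts = count_matrix([random_cds(rng, table, 150) for _ in range(8)], table)
        freq = total_frequency(counts, table)
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-9)

    def test_single_codon_gene(self, table):
        freq = total_frequency(count_matrix([CodingSequence("g", "AAC")], table), table)
        assert freq.iloc[0]["AAC"] == 1.0

    def test_all_zero_counts_error(self, table):
        counts = count_matrix([CodingSequence("g", "TAA")], table)
        with pytest.raises(MetricsError, match="zero sense-codon"):
            total_frequency(counts, table)


class TestOracleEquivalence:
    def test_100_random_cds_match_brute_force(self, table):
        rng = np.random.default_rng(100)
        cds_list = [random_cds(rng, table, int(rng.integers(50, 400))) for _ in range(100)]
        counts = count_matrix(cds_list, table)
        iso = isoacceptor_frequency(counts, table)
        tot = total_frequency(counts, table)
        for cds, (_, iso_row), (_, tot_row) in zip(
            cds_list, iso.iterrows(), tot.iterrows()
        ):
            iso_expected = _iso_freq_oracle(cds.sequence, table)
            tot_expected = _total_freq_oracle(cds.sequence, table)
            for codon in table.sense_codons:
                if np.isnan(iso_expected[codon]):
                    assert np.isnan(iso_row[codon])
                else:
                    assert iso_row[codon] == pytest.approx(iso_expected[codon], abs=1e-9)
                assert tot_row[codon] == pytest.approx(tot_expected[codon], abs=1e-9)


class TestGenomeBaseline:
    def test_two_point_closed_form(self, table):
        freqs = pd.DataFrame({"AAC": [0.4, 0.6], "AAT": [0.6, 0.4]})
        base = genome_baseline(freqs, "isoacceptor")
        assert base.loc["AAC", "mu"] == pytest.approx(0.5)
        assert base.loc["AAC", "sigma"] == pytest.approx(0.1414214, abs=1e-6)
        assert base.loc["AAC", "n_genes"] == 2

    def test_identical_genes_have_zero_sd(self, table):
        freqs = pd.DataFrame({"AAC": [0.5] * 4, "AAT": [0.5] * 4})
        base = genome_baseline(freqs, "isoacceptor")
        assert (base["sigma"] == 0).all()

    def test_single_gene_universe_errors(self):
        with pytest.raises(MetricsError, match="at least 2"):
            genome_baseline(pd.DataFrame({"AAC": [0.5]}), "isoacceptor")

    def test_undefined_entries_excluded_per_codon(self):
        freqs = pd.DataFrame({"CAC": [0.2, np.nan, 0.4]})
        base = genome_baseline(freqs, "isoacceptor")
        assert base.loc["CAC", "mu"] == pytest.approx(0.3)
        assert base.loc["CAC", "n_genes"] == 2


class TestGeneSetSelection:
    def test_order_statistic(self):
        expr = pd.DataFrame(
            {"brain": [10, 9, 5, 2, 1]}, index=["g1", "g2", "g3", "g4", "g5"]
        )
        top, bottom = select_gene_sets(expr, "brain", 2)
        assert top == ["g1", "g2"]
        assert sorted(bottom) == ["g4", "g5"]

    def test_tie_break_is_lexicographic(self):
        expr = pd.DataFrame({"brain": [1.0] * 4}, index=["gd", "gb", "gc", "ga"])
        top, _ = select_gene_sets(expr, "brain", 2)
        assert top == ["ga", "gb"]

    def test_half_split_partitions_universe(self):
        expr = pd.DataFrame({"brain": [4, 3, 2, 1]}, index=list("abcd"))
        top, bottom = select_gene_sets(expr, "brain", 2)
        assert sorted(top + bottom) == list("abcd")

    def test_too_few_genes_errors(self):
        expr = pd.DataFrame({"brain": [1, 2, 3]}, index=list("abc"))
        with pytest.raises(MetricsError, match="at least 4"):
            select_gene_sets(expr, "brain", 2)

    def test_nan_dropped_with_warning(self):
        expr = pd.DataFrame(
            {"brain": [5, 4, np.nan, 2, 1]}, index=["g1", "g2", "g3", "g4", "g5"]
        )
        with pytest.warns(UserWarning, match="NaN"):
            top, bottom = select_gene_sets(expr, "brain", 2)
        assert "g3" not in top + bottom

    def test_replicate_columns_averaged(self):
        expr = pd.DataFrame(
            {"brain_1": [10, 1, 5, 6], "brain_2": [8, 3, 5, 6]},
            index=["g1", "g2", "g3", "g4"],
        )
        top, bottom = select_gene_sets(expr, "brain", 1)
        assert top == ["g1"] and bottom == ["g2"]


class TestGeneSetTStat:
    def _frame(self, values, codon="AAC"):
        return pd.DataFrame({codon: values}, index=[f"g{i}" for i in range(len(values))])

    def test_hand_computation(self, table):
        freqs = pd.DataFrame(
            {"AAC": [0.6, 0.7, 0.65, 0.65], "AAT": [0.4, 0.3, 0.35, 0.35]},
            index=list("abcd"),
        )
        base = genome_baseline(freqs, "isoacceptor")
        base["mu"] = 0.5  # genome average fixed by the worked example
        ts = gene_set_tstat(freqs, list("abcd"), base, table, metric="isoacceptor")
        assert ts.loc["AAC", "xbar"] == pytest.approx(0.65)
        assert ts.loc["AAC", "s"] == pytest.approx(0.0408248, abs=1e-6)
        assert ts.loc["AAC", "n"] == 4
        assert ts.loc["AAC", "T"] == pytest.approx(7.3485, abs=1e-4)

    def test_sample_mean_equal_mu_gives_zero(self, table):
        freqs = pd.DataFrame({"AAC": [0.4, 0.6], "AAT": [0.6, 0.4]}, index=list("ab"))
        base = genome_baseline(freqs, "isoacceptor")
        ts = gene_set_tstat(freqs, list("ab"), base, table, metric="isoacceptor")
        assert ts.loc["AAC", "T"] == pytest.approx(0.0)

    def test_significance_cutoff_matches_student_t(self):
        p = significance_cutoff_p(2.0, 200)
        assert p == pytest.approx(0.0468, abs=5e-4)
        assert p < 0.05

    def test_matches_textbook_one_sample_t(self, table):
        """Dual route: the explicit formula vs scipy's one-sample t test."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            values = rng.uniform(0.1, 0.9, size=n)
            mu = float(rng.uniform(0.2, 0.8))
            freqs = pd.DataFrame({"AAC": values, "AAT": 1 - values},
                                 index=[f"g{i}" for i in range(n)])
            base = genome_baseline(freqs, "isoacceptor")
            base["mu"] = mu
            ts = gene_set_tstat(freqs, list(freqs.index), base, table,
                                metric="isoacceptor")
            expected_t, expected_p = stats.ttest_1samp(values, mu)
            assert ts.loc["AAC", "T"] == pytest.approx(expected_t, abs=1e-9)
            assert ts.loc["AAC", "p"] == pytest.approx(expected_p, abs=1e-9)

    def test_whole_genome_as_sample_gives_zero_t(self, table):
        rng = np.random.default_rng(12)
        counts = count_matrix([random_cds(rng, table, 200) for _ in range(30)], table)
        freqs = isoacceptor_frequency(counts, table)
        base = genome_baseline(freqs, "isoacceptor")
        ts = gene_set_tstat(freqs, list(freqs.index), base, table, metric="isoacceptor")
        assert np.allclose(ts["T"].dropna(), 0.0, atol=1e-9)

    def test_metric_mismatch_errors(self, table):
        freqs = pd.DataFrame({"AAC": [0.4, 0.6]}, index=list("ab"))
        base = genome_baseline(freqs, "total")
        with pytest.raises(MetricsError, match="metric"):
            gene_set_tstat(freqs, list("ab"), base, table, metric="isoacceptor")

    def test_single_codon_families_flagged_ineligible(self, table):
        rng = np.random.default_rng(13)
        counts = count_matrix([random_cds(rng, table, 300) for _ in range(10)], table)
        freqs = isoacceptor_frequency(counts, table)
        base = genome_baseline(freqs, "isoacceptor")
        ts = gene_set_tstat(freqs, list(freqs.index)[:5], base, table,
                            metric="isoacceptor")
        assert not ts.loc["ATG", "family_eligible"]
        assert np.isnan(ts.loc["ATG", "T"]) and np.isnan(ts.loc["TGG", "T"])


class TestEndingBias:
    def test_symmetric_gap(self, table):
        ts = pd.DataFrame(
            {
                "ending_class": ["AT_ending", "GC_ending"] * 2,
                "T": [3.0, -3.0, 3.0, -3.0],
            }
        )
        summary = ending_bias_summary(ts)
        assert summary["gap"] == pytest.approx(6.0)

    def test_zero_t_gives_zero_gap(self):
        ts = pd.DataFrame(
            {"ending_class": ["AT_ending", "GC_ending"], "T": [0.0, 0.0]}
        )
        assert ending_bias_summary(ts)["gap"] == 0.0

    def test_empty_class_warns(self):
        ts = pd.DataFrame({"ending_class": ["AT_ending"], "T": [1.0]})
        with pytest.warns(UserWarning, match="GC_ending"):
            summary = ending_bias_summary(ts)
        assert np.isnan(summary["gap"])
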