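import numpy as np
import pandas as pd
import pytest

from guanodiet.read_pipeline import (
    MotuTable,
    SequenceRead,
    TaxonRecord,
    cluster_motus,
    dereplicate,
    exclude_nontarget,
    exclusion_percentages,
    length_min_count_filter,
    merge_read_pair,
    quality_filter,
    run_table_pipeline,
    within_sample_relative_filter,
)
from guanodiet.synthetic import SyntheticConfig, generate_dataset, random_amplicon, simulate_read_pairs

Q = 38


def _read(bases, quals=None, rid="r"):
    quals = quals if quals is not None else tuple([Q] * len(bases))
    return SequenceRead(rid, bases, tuple(quals))


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestMergeReadPair:
    def test_exact_overlap_arithmetic(self):
        rng = np.random.default_rng(0)
        template = random_amplicon(rng, 28)
        fwd = _read(template[:20])
        rev = _read(_revcomp(template[-20:]))
        merged = merge_read_pair(fwd, rev)
        assert merged is not None
        assert len(merged) == 28
        assert merged.bases == template

    def test_overlap_below_minimum_is_null(self):
        rng = np.random.default_rng(1)
        template = random_amplicon(rng, 31)  # 20 + 20 - 9: best overlap length 9
        fwd = _read(template[:20])
        rev = _read(_revcomp(template[-20:]))
        assert merge_read_pair(fwd, rev) is None

    def test_mismatch_fraction_above_8_percent_is_null(self):
        rng = np.random.default_rng(2)
        template = random_amplicon(rng, 28)  # overlap 12
        fwd_bases = list(template[:20])
        fwd_bases[14] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd_bases[14]]
        fwd = _read("".join(fwd_bases))
        rev = _read(_revcomp(template[-20:]))
        # 1/12 ~ 8.3% > 8%
        assert merge_read_pair(fwd, rev) is None
        # but allowed with a looser threshold
        assert merge_read_pair(fwd, rev, max_mismatch_frac=0.09) is not None

    def test_consensus_prefers_higher_quality_base(self):
        rng = np.random.default_rng(3)
        template = random_amplicon(rng, 30)
        fwd_bases = list(template[:20])
        pos = 15
        true_base = fwd_bases[pos]
        fwd_bases[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[true_base]
        quals = [Q] * 20
        quals[pos] = 5
        fwd = _read("".join(fwd_bases), quals)
        rev = _read(_revcomp(template[-20:]))
        merged = merge_read_pair(fwd, rev, max_mismatch_frac=0.2)
        assert merged.bases[pos] == true_base
        assert merged.qualities[pos] == Q  # max of the two

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            merge_read_pair(_read(""), _read("ACGTACGTACGT"))


class TestQualityFilter:
    def test_exactly_90_percent_inclusive(self):
        read = _read("A" * 10, [31] * 9 + [2])
        assert quality_filter(read) is True

    def test_q30_is_not_greater_than_q30(self):
        read = _read("A" * 10, [30] * 9 + [40])
        assert quality_filter(read) is False

    def test_all_high_quality(self):
        assert quality_filter(_read("ACGT", [40] * 4)) is True

    def test_empty_read_error(self):
        with pytest.raises(ValueError):
            quality_filter(_read(""))


class TestLengthMinCount:
    @staticmethod
    def _table(specs):
        rng = np.random.default_rng(7)
        cols, counts = [], []
        for length, count in specs:
            cols.append(random_amplicon(rng, length))
            counts.append(count)
        return pd.DataFrame([counts], index=["s1"], columns=cols)

    def test_long_but_rare_and_short_but_abundant_removed(self):
        table = self._table([(148, 1000), (157, 4)])
        assert length_min_count_filter(table).shape[1] == 0

    def test_threshold_cases(self):
        table = self._table([(157, 4), (157, 5), (149, 5), (148, 5)])
        kept = length_min_count_filter(table)
        lengths = sorted((len(c), int(table[c].iloc[0])) for c in kept.columns)
        assert lengths == [(149, 5), (157, 5)]

    def test_six_sequence_fixture(self):
        table = self._table([(150, 5), (149, 5), (148, 5), (157, 4), (157, 5), (200, 100)])
        assert length_min_count_filter(table).shape[1] == 4


class TestWithinSampleFilter:
    def test_tenth_permille_of_100k(self):
        table = pd.DataFrame(
            [[9, 10, 99_981]], index=["s1"], columns=["a", "b", "c"]
        )
        out = within_sample_relative_filter(table)
        assert out.loc["s1", "a"] == 0
        assert out.loc["s1", "b"] == 10

    def test_one_permille_of_1000_kept(self):
        table = pd.DataFrame([[1, 999]], index=["s1"], columns=["a", "b"])
        out = within_sample_relative_filter(table)
        assert out.loc["s1", "a"] == 1

    def test_per_sample_independence(self):
        table = pd.DataFrame(
            [[50, 99_950], [1, 99_999]], index=["sA", "sB"], columns=["x", "y"]
        )
        out = within_sample_relative_filter(table)
        assert out.loc["sA", "x"] == 50  # 0.5 permille of 100k
        assert out.loc["sB", "x"] == 0  # 0.01 permille

    def test_never_increases_reads(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.integers(0, 100, (5, 20)))
        out = within_sample_relative_filter(table, threshold=0.01)
        assert out.to_numpy().sum() <= table.to_numpy().sum()


def _mutate(seq, positions):
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestClustering:
    def test_one_mutation_joins_one_motu(self):
        rng = np.random.default_rng(4)
        a = random_amplicon(rng, 157)
        b = _mutate(a, [10])
        table = pd.DataFrame([[100, 10]], index=["s1"], columns=[a, b])
        motus = cluster_motus(table)
        assert len(motus.motu_ids) == 1
        assert motus.centroids[motus.motu_ids[0]] == a  # abundance-sorted centroid
        assert int(motus.counts.iloc[0, 0]) == 110

    def test_two_mutations_stay_separate(self):
        rng = np.random.default_rng(5)
        a = random_amplicon(rng, 157)
        b = _mutate(a, [10, 50])
        table = pd.DataFrame([[100, 10]], index=["s1"], columns=[a, b])
        assert len(cluster_motus(table).motu_ids) == 2

    def test_chain_breaks_at_centroid_distance(self):
        rng = np.random.default_rng(6)
        a = random_amplicon(rng, 157)
        b = _mutate(a, [10])
        c = _mutate(a, [10, 50])  # d(b,c)=1, d(a,c)=2
        table = pd.DataFrame([[100, 50, 40]], index=["s1"], columns=[a, b, c])
        motus = cluster_motus(table)
        assert len(motus.motu_ids) == 2
        sizes = sorted(int(v) for v in motus.counts.iloc[0])
        assert sizes == [40, 150]

    def test_zero_mismatch_is_identity_partition(self):
        rng = np.random.default_rng(7)
        seqs = [random_amplicon(rng, 157) for _ in range(5)]
        table = pd.DataFrame([[3, 5, 8, 2, 9]], index=["s1"], columns=seqs)
        motus = cluster_motus(table, max_mismatch=0)
        assert len(motus.motu_ids) == len(seqs)

    def test_length_difference_beyond_mismatch_is_distinct(self):
        rng = np.random.default_rng(8)
        a = random_amplicon(rng, 157)
        table = pd.DataFrame([[10, 5]], index=["s1"], columns=[a, a[:150]])
        assert len(cluster_motus(table, max_mismatch=1).motu_ids) == 2


def _tax(motu, similarity=99.0, **kw):
    defaults = dict(
        class_="Insecta", order="Lepidoptera", family="Noctuidae",
        genus="Agrotis", species="Agrotis exclamationis",
    )
    defaults.update(kw)
    return TaxonRecord(motu_id=motu, match_similarity=similarity, **defaults)


class TestExcludeNontarget:
    def _table(self, counts, samples, motus):
        return MotuTable(counts=pd.DataFrame(counts, index=samples, columns=motus))

    def test_similarity_threshold_is_strict(self):
        table = self._table([[5, 5]], ["s1"], ["m1", "m2"])
        tax = {"m1": _tax("m1", similarity=39.9), "m2": _tax("m2", similarity=40.0)}
        cleaned, report = exclude_nontarget(table, tax)
        assert cleaned.motu_ids == ["m2"]
        assert report.iloc[0]["reason"] == "no_match"

    def test_blank_contaminant_removed_and_blank_dropped(self):
        table = self._table([[5, 100], [0, 50]], ["s1", "blank1"], ["m1", "m2"])
        tax = {"m1": _tax("m1"), "m2": _tax("m2")}
        cleaned, report = exclude_nontarget(table, tax, blank_sample_ids=["blank1"])
        assert cleaned.motu_ids == ["m1"]
        assert cleaned.sample_ids == ["s1"]
        assert set(report["reason"]) == {"blank_contaminant"}

    def test_exclusion_taxa_categories(self):
        table = self._table([[5, 5, 5, 5]], ["s1"], ["m1", "m2", "m3", "m4"])
        tax = {
            "m1": _tax("m1"),
            "m2": _tax("m2", class_="", order="", family="Dermestidae"),
            "m3": _tax("m3", class_="Gastropoda", order="", family=""),
            "m4": _tax("m4", class_="", order="Rotifera", family=""),
        }
        cleaned, report = exclude_nontarget(table, tax)
        reasons = dict(zip(report["motu_id"], report["reason"]))
        assert cleaned.motu_ids == ["m1"]
        assert reasons == {"m2": "guano_fauna", "m3": "secondary_prey", "m4": "non_animal"}

    def test_missing_taxonomy_is_no_match(self):
        table = self._table([[5]], ["s1"], ["m1"])
        _, report = exclude_nontarget(table, {})
        assert report.iloc[0]["reason"] == "no_match"

    def test_unknown_blank_id_rejected(self):
        table = self._table([[5]], ["s1"], ["m1"])
        with pytest.raises(KeyError):
            exclude_nontarget(table, {"m1": _tax("m1")}, blank_sample_ids=["nope"])

    def test_percentage_report(self):
        report = pd.DataFrame(
            {"motu_id": [f"m{i}" for i in range(111)], "reason": ["no_match"] * 111,
             "similarity": [10.0] * 111}
        )
        pct = exclusion_percentages(report, n_input_motus=654)
        assert round(pct["no_match"]) == 17


class TestPipelineProperties:
    def test_synthetic_recovery_matches_truth(self):
        ds = generate_dataset(SyntheticConfig(rng_seed=3, bias_sigma=0.5))
        cleaned, report, _ = run_table_pipeline(
            ds.table, ds.taxonomy, blank_sample_ids=ds.blank_ids
        )
        genuine = ds.truth.genuine_motus() & set(ds.table.motu_ids)
        assert set(cleaned.motu_ids) == genuine

    def test_idempotent_on_own_output(self):
        ds = generate_dataset(SyntheticConfig(rng_seed=5, bias_sigma=0.5))
        cleaned, _, _ = run_table_pipeline(ds.table, ds.taxonomy, blank_sample_ids=ds.blank_ids)
        again, report, _ = run_table_pipeline(cleaned, ds.taxonomy, blank_sample_ids=[])
        assert report.empty
        assert again.counts.equals(cleaned.counts)

    def test_retained_reads_never_increase(self):
        ds = generate_dataset(SyntheticConfig(rng_seed=6))
        _, _, log = run_table_pipeline(ds.table, ds.taxonomy, blank_sample_ids=ds.blank_ids)
        assert log["output_reads"] <= log["input_reads"]

    def test_fastq_level_roundtrip(self):
        """Merge+quality+dereplicate+cluster a tiny simulated FASTQ run."""
        rng = np.random.default_rng(11)
        templates = [random_amplicon(rng, 157) for _ in range(3)]
        reads_by_sample = {"s1": [], "s2": []}
        for i, tpl in enumerate(templates):
            for sample in reads_by_sample:
                pairs = simulate_read_pairs(tpl, 10 + 5 * i, rng, id_prefix=f"{sample}_t{i}_")
                for fwd, rev in pairs:
                    merged = merge_read_pair(fwd, rev)
                    assert merged is not None and merged.bases == tpl
                    if quality_filter(merged):
                        reads_by_sample[sample].append(merged.bases)
        table = dereplicate(reads_by_sample)
        table = length_min_count_filter(table)
        table = within_sample_relative_filter(table)
        motus = cluster_motus(table)
        assert len(motus.motu_ids) == 3
        assert set(motus.centroids.values()) == set(templates)

    def test_substitution_errors_cluster_into_template_motu(self):
        rng = np.random.default_rng(13)
        tpl = random_amplicon(rng, 157)
        merged = []
        for fwd, rev in simulate_read_pairs(tpl, 60, rng, substitution_rate=0.002):
            m = merge_read_pair(fwd, rev)
            if m is not None and quality_filter(m):
                merged.append(m.bases)
        table = dereplicate({"s1": merged})
        table = length_min_count_filter(table, min_reads=1)
        motus = cluster_motus(table, max_mismatch=1)
        # the dominant centroid is the template; 1-off variants fold in
        assert motus.centroids[motus.motu_ids[0]] == tpl
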