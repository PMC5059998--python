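"""Read classification, proportional counting, RPKM, filtering, exports."""

import numpy as np
import pandas as pd
import pytest

from teheat.annotation import TECatalogue, TEFeature
from teheat.comex import (
    NMM,
    SMM,
    UM,
    UNANNOTATED,
    CountingConfig,
    CountMatrix,
    ReadMappingSet,
    class_statistics,
    classify_read,
    collect_mappings,
    count_sample,
    export_deseq_matrix,
    family_counts,
    filter_expressed,
    proportional_counts,
    rpkm,
    summarize_regulation,
)
from teheat.simulate import SimSpec, simulate_dataset

from _oracles import groupby_family_sums


def rms(read_id, *spans):
    return ReadMappingSet(read_id, [("chr1", s, e, "+") for s, e in spans])


class TestClassifyRead:
    def test_unique_read_in_te_is_um(self, small_catalogue):
        r = classify_read(rms("r", (150, 249)), small_catalogue)
        assert (r.read_class, r.assigned_family) == (UM, "ONSEN")

    def test_unique_read_outside_te_is_unannotated(self, small_catalogue):
        r = classify_read(rms("r", (600, 699)), small_catalogue)
        assert (r.read_class, r.assigned_family) == (UNANNOTATED, None)

    def test_two_hits_same_family_is_smm(self, small_catalogue):
        r = classify_read(rms("r", (150, 249), (1050, 1149)), small_catalogue)
        assert (r.read_class, r.assigned_family) == (SMM, "ONSEN")

    def test_hits_across_families_is_nmm(self, small_catalogue):
        r = classify_read(rms("r", (150, 249), (2050, 2149)), small_catalogue)
        assert (r.read_class, r.assigned_family) == (NMM, None)

    def test_mixed_te_and_unannotated_is_smm(self, small_catalogue):
        # two ONSEN hits plus one unannotated position
        r = classify_read(
            rms("r", (150, 249), (1050, 1149), (600, 699)), small_catalogue
        )
        assert (r.read_class, r.assigned_family) == (SMM, "ONSEN")
        assert r.hits.count(None) == 1

    def test_multimapper_with_single_te_hit_follows_policy(self, small_catalogue):
        spans = ((150, 249), (600, 699))
        r = classify_read(rms("r", *spans), small_catalogue)
        assert r.read_class == NMM  # default: discard
        r = classify_read(
            rms("r", *spans), small_catalogue,
            CountingConfig(single_te_hit_policy="keep"),
        )
        assert (r.read_class, r.assigned_family) == (SMM, "ONSEN")

    def test_unknown_chromosome_counts_as_non_te(self, small_catalogue):
        r = ReadMappingSet("r", [("chrZ", 1, 100, "+"), ("chr1", 150, 249, "+")])
        assert classify_read(r, small_catalogue).read_class == NMM

    def test_nested_features_attributed_to_larger_overlap(self):
        cat = TECatalogue(
            [
                TEFeature("chr1", 100, 400, "+", "OUTER", "FAMA"),
                TEFeature("chr1", 150, 180, "+", "INNER", "FAMB"),
            ]
        )
        r = classify_read(rms("r", (140, 239)), cat)
        # OUTER overlaps 100 bp, INNER only 31 bp
        assert (r.assigned_family, r.hits) == ("FAMA", ["OUTER"])

    def test_partition_is_total(self, small_catalogue):
        reads = [
            rms("a", (150, 249)),
            rms("b", (600, 699)),
            rms("c", (150, 249), (1050, 1149)),
            rms("d", (150, 249), (2050, 2149)),
            rms("e", (600, 699), (700, 799)),
        ]
        classified = [classify_read(r, small_catalogue) for r in reads]
        stats = class_statistics(classified)
        assert stats["total"] == len(reads) == sum(
            stats[c] for c in (UM, SMM, NMM, UNANNOTATED)
        )


class TestProportionalCounts:
    def test_um_read_contributes_one(self, small_catalogue):
        m = proportional_counts([rms("r", (150, 249))], small_catalogue)
        assert m.counts.loc["ONSEN_1", "sample"] == 1.0

    def test_smm_read_splits_weight_evenly(self, small_catalogue):
        m = proportional_counts(
            [rms("r", (150, 249), (1050, 1149))], small_catalogue
        )
        assert m.counts.loc["ONSEN_1", "sample"] == pytest.approx(0.5)
        assert m.counts.loc["ONSEN_2", "sample"] == pytest.approx(0.5)

    def test_unannotated_position_absorbs_its_share(self, small_catalogue):
        # k=3, two TE hits: each gets 1/3, total weight 2/3
        m = proportional_counts(
            [rms("r", (150, 249), (1050, 1149), (600, 699))], small_catalogue
        )
        col = m.counts["sample"]
        assert col["ONSEN_1"] == pytest.approx(1 / 3)
        assert col["ONSEN_2"] == pytest.approx(1 / 3)
        assert col.sum() == pytest.approx(2 / 3)

    def test_discarded_reads_contribute_nothing(self, small_catalogue):
        m = proportional_counts(
            [rms("r", (150, 249), (2050, 2149))], small_catalogue
        )
        assert m.counts.values.sum() == 0.0

    def test_weight_never_exceeds_one_per_read(self, small_catalogue):
        reads = [
            rms("a", (150, 249)),
            rms("b", (150, 249), (1050, 1149)),
            rms("c", (150, 249), (1050, 1149), (600, 699)),
        ]
        m = proportional_counts(reads, small_catalogue)
        assert m.counts.values.sum() <= len(reads) + 1e-12

    def test_empty_input_gives_zero_matrix(self, small_catalogue):
        m = proportional_counts([], small_catalogue, library_size=1)
        assert (m.counts.values == 0).all()


class TestFamilyCounts:
    def test_family_is_sum_of_members(self, small_catalogue):
        copy = proportional_counts(
            [rms("a", (150, 249)), rms("b", (1050, 1149)),
             rms("c", (150, 249), (1050, 1149))],
            small_catalogue,
        )
        fam = family_counts(copy, small_catalogue)
        assert fam.counts.loc["ONSEN", "sample"] == pytest.approx(3.0)
        assert fam.counts.loc["COPIA37", "sample"] == 0.0
        assert fam.lengths["ONSEN"] == 800

    def test_matches_independent_groupby(self, small_catalogue):
        rng = np.random.default_rng(7)
        te_ids = [f.te_id for f in small_catalogue]
        counts = pd.DataFrame(
            {"s1": rng.random(3) * 10, "s2": rng.random(3) * 10}, index=te_ids
        )
        copy = CountMatrix(
            counts,
            pd.Series([f.length for f in small_catalogue], index=te_ids, dtype=float),
            pd.Series([100.0, 100.0], index=["s1", "s2"]),
        )
        fam = family_counts(copy, small_catalogue)
        fam_of = {t: small_catalogue.family_of(t) for t in te_ids}
        for col in ("s1", "s2"):
            expect = groupby_family_sums(counts[col].to_dict(), fam_of)
            for f, v in expect.items():
                assert fam.counts.loc[f, col] == pytest.approx(v, abs=1e-12)


class TestRPKMAndFilter:
    def _matrix(self, values, lengths, libs, samples=("s1",)):
        idx = [f"te{i}" for i in range(len(lengths))]
        return CountMatrix(
            pd.DataFrame(np.asarray(values, float), index=idx, columns=list(samples)),
            pd.Series(lengths, index=idx, dtype=float),
            pd.Series(libs, index=list(samples), dtype=float),
        )

    def test_unit_case(self):
        m = rpkm(self._matrix([[10.0]], [1000], [1e6]))
        assert m.counts.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_zero_rpkm(self):
        m = rpkm(self._matrix([[0.0]], [1000], [1e6]))
        assert m.counts.iloc[0, 0] == 0.0

    def test_terestra_length_case(self):
        # 5.5 fractional reads over a 5116 bp element in a 15e6-read library
        m = rpkm(self._matrix([[5.5]], [5116], [15e6]))
        assert m.counts.iloc[0, 0] == pytest.approx(5.5 / (5.116 * 15), rel=1e-12)

    def test_zero_library_size_is_error(self):
        with pytest.raises(ValueError):
            rpkm(self._matrix([[1.0]], [100], [0]))

    def test_filter_keeps_row_reaching_threshold_in_one_sample(self):
        m = self._matrix(
            [[0.1, 0.6, 0.0], [0.54, 0.54, 0.54]],
            [100, 100],
            [1e6, 1e6, 1e6],
            samples=("t0", "t6", "t48"),
        )
        kept = filter_expressed(m, CountingConfig(rpkm_threshold=0.55))
        assert list(kept.counts.index) == ["te0"]

    def test_zero_threshold_keeps_everything(self):
        m = self._matrix([[0.0], [0.0]], [100, 100], [1e6])
        kept = filter_expressed(m, CountingConfig(rpkm_threshold=0.0))
        assert len(kept.counts) == 2

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(11)
        m = self._matrix(rng.random((20, 3)), [100] * 20, [1e6] * 3,
                         samples=("a", "b", "c"))
        prev = None
        for thr in (0.0, 0.2, 0.5, 0.8, 1.1):
            kept = set(filter_expressed(m, CountingConfig(rpkm_threshold=thr)).counts.index)
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestSummarizeRegulation:
    @pytest.mark.parametrize(
        "n_sig,n_tot,expected",
        [(7156, 32793, 21.8), (6165, 32678, 18.9), (4, 32, 12.5), (0, 100, 0.0)],
    )
    def test_printed_percentages(self, n_sig, n_tot, expected):
        assert summarize_regulation(n_sig, n_tot) == expected

    def test_round_half_up(self):
        assert summarize_regulation(25, 1000) == 2.5
        assert summarize_regulation(145, 1000) == 14.5
        assert summarize_regulation(1, 800) == 0.1  # 0.125 -> 0.1
        assert summarize_regulation(15, 10000) == 0.2  # 0.15 rounds up

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            summarize_regulation(0, 0)


class TestDESeqExport:
    def _matrix(self):
        return CountMatrix(
            pd.DataFrame(
                [[1.25, 0.5], [3.0, 0.0]], index=["a", "b"], columns=["s1", "s2"]
            ),
            pd.Series([100.0, 100.0], index=["a", "b"]),
            pd.Series([10.0, 10.0], index=["s1", "s2"]),
        )

    def test_integerizes_round_half_to_even(self, tmp_path):
        p, fp = export_deseq_matrix(self._matrix(), tmp_path / "m.tsv")
        ints = pd.read_csv(p, sep="\t", index_col=0)
        # half-to-even: 1.25 -> 1, 0.5 -> 0, 3.0 -> 3
        assert ints.values.tolist() == [[1, 0], [3, 0]]

    def test_fractional_companion_round_trips(self, tmp_path):
        m = self._matrix()
        _, fp = export_deseq_matrix(m, tmp_path / "m.tsv")
        back = pd.read_csv(fp, sep="\t", index_col=0)
        assert np.allclose(back.values, m.counts.values)

    def test_empty_matrix_writes_header_only(self, tmp_path):
        m = CountMatrix(
            pd.DataFrame(columns=["s1"], dtype=float),
            pd.Series(dtype=float),
            pd.Series([1.0], index=["s1"]),
        )
        p, _ = export_deseq_matrix(m, tmp_path / "e.tsv")
        lines = p.read_text().strip().split("\n")
        assert lines == ["copy\ts1"]


class TestCollectMappings:
    def test_k_counts_records_per_read(self, tmp_path):
        paths = simulate_dataset(
            SimSpec(seed=5, copy_divergence=0.0, copies_per_family=3,
                    n_families=2, depth_per_family=10),
            tmp_path,
        )
        reads, dropped = collect_mappings(paths["sam"])
        truth = pd.read_csv(paths["truth"], sep="\t")
        k_by_read = dict(zip(truth["read_id"], truth["k"]))
        assert len(reads) == len(truth)
        for r in reads:
            assert r.k == k_by_read[r.read_id]
        # record-count conservation: sum of k equals SAM record count
        n_records = sum(
            1 for line in open(paths["sam"]) if not line.startswith("@")
        )
        assert sum(r.k for r in reads) == n_records

    def test_count_sample_library_size_definitions(self, tmp_path, small_catalogue):
        paths = simulate_dataset(SimSpec(seed=5, depth_per_family=5), tmp_path)
        from teheat.annotation import read_te_gff

        cat = read_te_gff(paths["gff"])
        res_all = count_sample(paths["sam"], cat)
        assert res_all.copy_counts.library_sizes.iloc[0] == res_all.class_stats["total"]
        res_te = count_sample(
            paths["sam"], cat,
            CountingConfig(library_size_definition="retained_te_reads"),
        )
        retained = res_te.class_stats[UM] + res_te.class_stats[SMM]
        assert res_te.copy_counts.library_sizes.iloc[0] == retained
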