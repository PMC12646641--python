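"""Benchmark matching arithmetic and the trio Mendelian violation rate."""

import json

import pytest

from svmeld.bench import BenchParams, match_truth, mendelian_violation_rate, write_bench_outputs
from svmeld.merge import MergeParams

from conftest import mk_sv


class TestMatchTruth:
    def test_self_benchmark_is_perfect(self):
        calls = [mk_sv(rid=f"d{i}", pos=1000 * (i + 1), svlen=-200) for i in range(4)]
        calls += [mk_sv(rid="t", svtype="TRA", chrom="chr1", pos=99_000,
                        chrom2="chr5", pos2=5000)]
        report = match_truth(calls, calls)
        assert report.metrics["overall"] == {
            "tp": 5, "fp": 0, "fn": 0, "precision": 1.0, "recall": 1.0, "f1": 1.0}
        for stats in report.metrics["by_type"].values():
            assert stats["precision"] == stats["recall"] == stats["f1"] == 1.0

    def test_three_tp_one_fp_two_fn(self):
        truth = [mk_sv(rid=f"t{i}", pos=10_000 * (i + 1), svlen=-300) for i in range(5)]
        calls = [t.copy(record_id=f"c{i}") for i, t in enumerate(truth[:3])]
        calls.append(mk_sv(rid="fp", pos=900_000, svlen=-300))
        report = match_truth(calls, truth)
        overall = report.metrics["overall"]
        assert (overall["tp"], overall["fp"], overall["fn"]) == (3, 1, 2)
        assert overall["precision"] == pytest.approx(0.75)
        assert overall["recall"] == pytest.approx(0.6)
        assert overall["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_size_ratio_boundary_is_inclusive(self):
        truth = [mk_sv(rid="t", pos=1000, svlen=-1000)]
        at_boundary = [mk_sv(rid="c", pos=1000, svlen=-700)]
        below = [mk_sv(rid="c", pos=1000, svlen=-699)]
        assert match_truth(at_boundary, truth).metrics["overall"]["tp"] == 1
        assert match_truth(below, truth).metrics["overall"]["tp"] == 0

    def test_conservation_of_counts(self):
        truth = [mk_sv(rid=f"t{i}", pos=5000 * (i + 1), svlen=-200) for i in range(6)]
        calls = [mk_sv(rid=f"c{i}", pos=5000 * (i + 1) + 30, svlen=-200)
                 for i in range(4)] + [mk_sv(rid="x", pos=700_000, svlen=-200)]
        r = match_truth(calls, truth)
        assert len(r.tp) + len(r.fp) == len(calls)
        assert len(r.tp) + len(r.fn) == len(truth)

    def test_tp_monotone_in_position_threshold(self):
        truth = [mk_sv(rid=f"t{i}", pos=10_000 * (i + 1), svlen=-400) for i in range(8)]
        calls = [t.copy(record_id=f"c{i}", pos=t.pos + 120 * i, end=t.end + 120 * i)
                 for i, t in enumerate(truth)]
        previous = 0
        for threshold in (100, 250, 500, 1000):
            tp = match_truth(calls, truth,
                             BenchParams(position_threshold=threshold)
                             ).metrics["overall"]["tp"]
            assert tp >= previous
            previous = tp

    def test_each_truth_consumed_at_most_once(self):
        truth = [mk_sv(rid="t", pos=1000, svlen=-300)]
        calls = [mk_sv(rid="near", pos=1010, svlen=-300),
                 mk_sv(rid="nearer", pos=1001, svlen=-300)]
        r = match_truth(calls, truth)
        assert len(r.tp) == 1 and r.tp[0][0].record_id == "nearer"

    def test_tra_matched_on_both_breakpoints(self):
        truth = [mk_sv(rid="t", svtype="TRA", chrom="chr1", pos=1000,
                       chrom2="chr5", pos2=2000)]
        near = [mk_sv(rid="c", svtype="TRA", chrom="chr1", pos=4000,
                      chrom2="chr5", pos2=2000)]
        far = [mk_sv(rid="c", svtype="TRA", chrom="chr1", pos=7000,
                     chrom2="chr5", pos2=2000)]
        assert match_truth(near, truth).metrics["overall"]["tp"] == 1  # 3000 <= 5000
        assert match_truth(far, truth).metrics["overall"]["tp"] == 0

    def test_empty_truth_reports_zero_recall_with_warning(self):
        report = match_truth([mk_sv(rid="c", pos=1000, svlen=-100)], [])
        assert report.metrics["overall"]["recall"] == 0.0
        assert report.warnings


class TestOutputs:
    def test_outputs_round_trip(self, tmp_path):
        truth = [mk_sv(rid=f"t{i}", pos=10_000 * (i + 1), svlen=-300) for i in range(3)]
        calls = [truth[0].copy(record_id="c0"), mk_sv(rid="fp", pos=900_000, svlen=-300)]
        report = match_truth(calls, truth)
        paths = write_bench_outputs(report, tmp_path / "bench")
        from svmeld.vcf_io import read_vcf

        assert len(read_vcf(paths["tp"])) == 1
        assert len(read_vcf(paths["fp"])) == 1
        assert len(read_vcf(paths["fn"])) == 2
        stats = json.loads(paths["stats"].read_text())
        assert stats["overall"] == report.metrics["overall"]
        assert set(stats["by_type"]) == {"DEL"}

    def test_empty_partition_gives_header_only_vcf(self, tmp_path):
        calls = [mk_sv(rid="c", pos=1000, svlen=-300)]
        report = match_truth(calls, calls)
        paths = write_bench_outputs(report, tmp_path / "self")
        from svmeld.vcf_io import read_vcf

        assert read_vcf(paths["fp"]) == []

    def test_per_type_keys_cover_calls_union_truth(self):
        calls = [mk_sv(rid="c", svtype="DEL", pos=1000, svlen=-100)]
        truth = [mk_sv(rid="t", svtype="INS", pos=5000, end=5000, svlen=80)]
        report = match_truth(calls, truth)
        assert set(report.metrics["by_type"]) == {"DEL", "INS"}


class TestMVR:
    def _trio(self):
        child = [mk_sv(rid=f"v{i}", pos=10_000 * (i + 1), svlen=-400, caller="c")
                 for i in range(4)]
        father = [v.copy(record_id=f"f{i}") for i, v in enumerate(child[:2])]
        mother = [v.copy(record_id=f"m{i}") for i, v in enumerate(child[1:3])]
        return child, father, mother

    def test_counting_oracle(self):
        child, father, mother = self._trio()
        result = mendelian_violation_rate(child, father, mother)
        # v0..v2 are in at least one parent; v3 in neither
        assert result.denominator == 4 and result.violations == 1
        assert result.mvr == pytest.approx(0.25)

    def test_zero_when_child_subset_of_father(self):
        child, _, _ = self._trio()
        father = [v.copy(record_id=f"f{i}") for i, v in enumerate(child)]
        result = mendelian_violation_rate(child, father, [])
        assert result.mvr == 0.0

    def test_short_child_variants_excluded_from_denominator(self):
        child, father, mother = self._trio()
        child.append(mk_sv(rid="tiny", pos=990_000, svlen=-29, caller="c"))
        result = mendelian_violation_rate(child, father, mother)
        assert result.excluded_short == 1
        assert result.denominator == 4  # the 29 bp DEL does not count

    def test_tra_exempt_from_length_filter(self):
        child, father, mother = self._trio()
        child.append(mk_sv(rid="tra", svtype="TRA", chrom="chr1", pos=990_000,
                           chrom2="chr5", pos2=1234, caller="c"))
        result = mendelian_violation_rate(child, father, mother)
        assert result.denominator == 5
        assert "TRA" in result.by_type

    def test_shared_variant_never_increases_mvr(self):
        child, father, mother = self._trio()
        base = mendelian_violation_rate(child, father, mother).mvr
        shared = mk_sv(rid="s", pos=500_000, svlen=-600, caller="c")
        child2 = child + [shared]
        father2 = father + [shared.copy(record_id="fs")]
        mother2 = mother + [shared.copy(record_id="ms")]
        assert mendelian_violation_rate(child2, father2, mother2).mvr <= base

    def test_exclusion_mask_removes_child_variants(self):
        child, father, mother = self._trio()
        mask = [("chr1", 9_000, 11_000)]  # covers v0 at pos 10_000
        result = mendelian_violation_rate(child, father, mother, exclude_bed=mask)
        assert result.excluded_masked == 1 and result.denominator == 3

    def test_empty_child_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            mendelian_violation_rate([], [], [])

    def test_mvr_bounded(self):
        child, father, mother = self._trio()
        r = mendelian_violation_rate(child, father, mother,
                                     merge_params=MergeParams(max_distance=150))
        assert 0.0 <= r.mvr <= 1.0
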