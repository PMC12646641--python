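"""Merging: pairwise matching, clustering vs a brute-force oracle, genotype
resolution, quality filtering."""

import random

import networkx as nx
import numpy as np
import pytest

from svmeld.merge import (
    MergeParams,
    cluster,
    pairwise_match,
    quality_filter,
    resolve_genotype,
)
from svmeld.records import SVType

from conftest import mk_sv


PARAMS = MergeParams()


class TestPairwiseMatch:
    def test_identical_records_match(self):
        a = mk_sv(pos=1000, end=2000)
        assert pairwise_match(a, a, PARAMS)

    def test_shifted_del_within_thresholds(self):
        # distance 40 <= 50, equal sizes, Jaccard 960/1040 ~ 0.923 >= 0.7
        a = mk_sv(pos=1000, end=2000)
        b = mk_sv(rid="r2", pos=1040, end=2040, caller="c2")
        assert pairwise_match(a, b, PARAMS)

    def test_size_ratio_violation(self):
        a = mk_sv(pos=1000, end=2000)           # size 1000
        b = mk_sv(rid="r2", pos=1000, end=1400)  # size 400, ratio 2.5 > 1.3
        assert not pairwise_match(a, b, PARAMS)

    def test_type_mismatch_is_contract_violation(self):
        a = mk_sv(svtype="DEL", pos=1000, end=2000)
        b = mk_sv(svtype="DUP", pos=1000, end=2000)
        with pytest.raises(ValueError, match="type mismatch"):
            pairwise_match(a, b, PARAMS)

    def test_ins_matches_on_position_and_length_only(self):
        a = mk_sv(svtype="INS", pos=1000, end=1000, svlen=300)
        b = mk_sv(rid="r2", svtype="INS", pos=1030, end=1030, svlen=320)
        assert pairwise_match(a, b, PARAMS)
        c = mk_sv(rid="r3", svtype="INS", pos=1030, end=1030, svlen=600)
        assert not pairwise_match(a, c, PARAMS)  # ratio 2.0

    def test_tra_uses_flexible_distance_and_strands(self):
        a = mk_sv(svtype="TRA", chrom="chr1", pos=1000, chrom2="chr7",
                  pos2=5000, strands="+-", end=None, svlen=None)
        b = mk_sv(rid="r2", svtype="TRA", chrom="chr1", pos=1400, chrom2="chr7",
                  pos2=5400, strands="+-", end=None, svlen=None)
        assert pairwise_match(a, b, PARAMS)
        far = mk_sv(rid="r3", svtype="TRA", chrom="chr1", pos=1600, chrom2="chr7",
                    pos2=5000, strands="+-", end=None, svlen=None)
        assert not pairwise_match(a, far, PARAMS)  # 600 > 500
        flipped = mk_sv(rid="r4", svtype="TRA", chrom="chr1", pos=1000,
                        chrom2="chr7", pos2=5000, strands="-+", end=None, svlen=None)
        assert not pairwise_match(a, flipped, PARAMS)
        unknown = mk_sv(rid="r5", svtype="TRA", chrom="chr1", pos=1000,
                        chrom2="chr7", pos2=5000, strands="..", end=None, svlen=None)
        assert pairwise_match(a, unknown, PARAMS)


def _random_records(rng, n):
    recs = []
    for i in range(n):
        svtype = rng.choice(["DEL", "DUP", "INV", "INS", "TRA"])
        chrom = rng.choice(["chr1", "chr2"])
        pos = rng.randrange(1, 3000)
        if svtype == "TRA":
            recs.append(mk_sv(rid=f"r{i}", svtype="TRA", chrom=chrom, pos=pos,
                              chrom2="chr9", pos2=rng.randrange(1, 3000),
                              strands=rng.choice(["+-", "-+", ".."]),
                              caller=f"c{rng.randrange(4)}"))
        elif svtype == "INS":
            recs.append(mk_sv(rid=f"r{i}", svtype="INS", chrom=chrom, pos=pos,
                              end=pos, svlen=rng.randrange(50, 800),
                              caller=f"c{rng.randrange(4)}"))
        else:
            size = rng.randrange(50, 1500)
            recs.append(mk_sv(rid=f"r{i}", svtype=svtype, chrom=chrom, pos=pos,
                              end=pos + size, caller=f"c{rng.randrange(4)}"))
    return recs


def brute_force_components(records, params):
    """Independent oracle: transitive closure over pairwise_match via networkx."""
    g = nx.Graph()
    g.add_nodes_from(r.record_id for r in records)
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            if a.svtype is b.svtype and pairwise_match(a, b, params):
                g.add_edge(a.record_id, b.record_id)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestCluster:
    def test_three_concordant_callers_one_consensus(self):
        recs = [mk_sv(rid=f"r{i}", pos=1000 + i, end=2000 + i, caller=f"c{i}")
                for i in range(3)]
        (m,) = cluster(recs, PARAMS)
        assert m.support == {"c0", "c1", "c2"} and m.support_count == 3

    def test_distant_events_stay_separate(self):
        recs = [mk_sv(rid="a", pos=1000, end=2000),
                mk_sv(rid="b", pos=11_000, end=12_000)]
        assert len(cluster(recs, PARAMS)) == 2

    def test_transitive_chain_forms_one_component(self):
        # A~B and B~C but A and C are 80 apart (> 50): single-linkage closure
        a = mk_sv(rid="a", pos=1000, end=2000)
        b = mk_sv(rid="b", pos=1040, end=2040, caller="c2")
        c = mk_sv(rid="c", pos=1080, end=2080, caller="c3")
        assert not pairwise_match(a, c, PARAMS)
        (m,) = cluster([a, b, c], PARAMS)
        assert len(m.members) == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        records = _random_records(rng, 120)
        got = {frozenset(r.record_id for r in m.members)
               for m in cluster(records, PARAMS)}
        assert got == brute_force_components(records, PARAMS)

    def test_partition_property(self):
        rng = random.Random(99)
        records = _random_records(rng, 150)
        merged = cluster(records, PARAMS)
        member_ids = [r.record_id for m in merged for r in m.members]
        assert sorted(member_ids) == sorted(r.record_id for r in records)
        for m in merged:
            assert m.support == {r.source_caller for r in m.members}
            assert m.support_count == len(m.support)

    def test_order_invariance(self):
        rng = random.Random(7)
        records = _random_records(rng, 100)
        base = {frozenset(r.record_id for r in m.members)
                for m in cluster(records, PARAMS, caller_order=["c0", "c1", "c2", "c3"])}
        shuffled = records[:]
        random.Random(8).shuffle(shuffled)
        again = {frozenset(r.record_id for r in m.members)
                 for m in cluster(shuffled, PARAMS, caller_order=["c0", "c1", "c2", "c3"])}
        assert base == again

    def test_representative_prefers_quality_then_ad(self):
        recs = [
            mk_sv(rid="low", pos=1000, end=2000, qual=10.0, ad=(5, 40), caller="c1"),
            mk_sv(rid="high", pos=1001, end=2001, qual=50.0, ad=(5, 5), caller="c2"),
        ]
        (m,) = cluster(recs, PARAMS)
        assert m.representative.record_id == "high"


class TestResolveGenotype:
    def test_majority_vote(self):
        members = [mk_sv(rid="a", gt="0/1", caller="x"),
                   mk_sv(rid="b", gt="0/1", caller="y"),
                   mk_sv(rid="c", gt="1/1", caller="z")]
        assert resolve_genotype(members, ["x", "y", "z"]).gt == "0/1"

    def test_tie_broken_by_variant_read_count(self):
        members = [mk_sv(rid="a", gt="0/1", ad=(10, 30), caller="x"),
                   mk_sv(rid="b", gt="1/1", ad=(2, 12), caller="y")]
        assert resolve_genotype(members, ["x", "y"]).gt == "0/1"
        members_rev = [mk_sv(rid="a", gt="0/1", ad=(10, 3), caller="x"),
                       mk_sv(rid="b", gt="1/1", ad=(2, 12), caller="y")]
        assert resolve_genotype(members_rev, ["x", "y"]).gt == "1/1"

    def test_final_tie_broken_by_caller_input_order(self):
        members = [mk_sv(rid="a", gt="1/1", caller="y"),
                   mk_sv(rid="b", gt="0/1", caller="x")]
        assert resolve_genotype(members, ["x", "y"]).gt == "0/1"
        assert resolve_genotype(members, ["y", "x"]).gt == "1/1"

    def test_phased_and_unphased_tokens_pool_together(self):
        members = [mk_sv(rid="a", gt="0|1", caller="x"),
                   mk_sv(rid="b", gt="1/0", caller="y"),
                   mk_sv(rid="c", gt="1/1", caller="z")]
        call = resolve_genotype(members, ["x", "y", "z"])
        assert call.gt in ("0|1", "1/0")


class TestQualityFilter:
    def _merged(self, **kw):
        (m,) = cluster([mk_sv(**kw)], PARAMS)
        return m

    def test_no_thresholds_is_identity(self):
        ms = [self._merged(rid="a", qual=5.0)]
        kept, report = quality_filter(ms)
        assert kept == ms and report.passed == 1

    def test_qual_threshold(self):
        ms = [self._merged(rid="a", qual=10.0), self._merged(rid="b", qual=30.0)]
        kept, report = quality_filter(ms, min_qual=20)
        assert [m.representative.record_id for m in kept] == ["b"]
        assert report.dropped_below_threshold == 1

    def test_missing_attribute_dropped_and_counted(self):
        ms = [self._merged(rid="a", ad=None)]
        kept, report = quality_filter(ms, min_support_reads=5)
        assert kept == [] and report.dropped_missing_attribute == 1
        assert report.dropped_missing_by == {"AD": 1}
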