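"""CNVR aggregation, catalogue summaries, and catalogue comparisons."""

import random

import numpy as np
import pytest
from intervaltree import IntervalTree

from cghcnv import cnvr
from cghcnv.core import CnvCall, GenomeSpec


def call(sample, chrom, start, end, mean=-1.0):
    return CnvCall(sample_id=sample, chrom=chrom, probe_start_index=0,
                   probe_end_index=1, start=start, end=end, n_probes=8,
                   mean_log2=mean, score=10.0)


def brute_force_components(intervals):
    """Union-find oracle: transitive overlap components via an interval tree."""
    tree = IntervalTree()
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idx, (s, e) in enumerate(intervals):
        tree.addi(s, e, idx)
    for idx, (s, e) in enumerate(intervals):
        for hit in tree.overlap(s, e):
            ri, rj = find(idx), find(hit.data)
            if ri != rj:
                parent[ri] = rj
    groups = {}
    for idx in range(len(intervals)):
        groups.setdefault(find(idx), []).append(idx)
    return sorted(sorted(g) for g in groups.values())


class TestMerge:
    def test_union_arithmetic(self):
        calls = [call("A", "1", 100, 200), call("B", "1", 150, 300)]
        out = cnvr.merge_cnvrs(calls, n_test_samples=12)
        assert len(out) == 1
        r = out[0]
        assert (r.start, r.end) == (100, 300)
        assert r.frequency == pytest.approx(16.67, abs=0.01)
        assert r.cnvr_type == "loss"
        assert r.samples == frozenset({"A", "B"})

    def test_gain_plus_loss_is_both(self):
        calls = [call("A", "1", 0, 100, mean=-0.9),
                 call("B", "1", 50, 150, mean=+0.8)]
        out = cnvr.merge_cnvrs(calls, n_test_samples=2)
        assert out[0].cnvr_type == "both"

    def test_transitive_chain(self):
        # a overlaps b, b overlaps c, a does not overlap c
        calls = [call("A", "1", 0, 100), call("B", "1", 90, 200),
                 call("C", "1", 190, 300)]
        out = cnvr.merge_cnvrs(calls, n_test_samples=3)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (0, 300)

    def test_abutting_calls_do_not_merge(self):
        # half-open: [0,100) and [100,200) share no base
        calls = [call("A", "1", 0, 100), call("B", "1", 100, 200)]
        assert len(cnvr.merge_cnvrs(calls, n_test_samples=2)) == 2

    def test_order_independent(self):
        rng = random.Random(1)
        calls = [call(f"S{i % 5}", "1", s := rng.randrange(0, 100_000),
                      s + rng.randrange(500, 5_000)) for i in range(60)]
        a = cnvr.merge_cnvrs(calls, n_test_samples=5)
        shuffled = calls[:]
        rng.shuffle(shuffled)
        b = cnvr.merge_cnvrs(shuffled, n_test_samples=5)
        assert [(r.chrom, r.start, r.end, r.samples) for r in a] == \
               [(r.chrom, r.start, r.end, r.samples) for r in b]

    def test_matches_union_find_oracle(self):
        rng = random.Random(2)
        for _ in range(100):
            n = rng.randrange(2, 40)
            ivs = []
            for _ in range(n):
                s = rng.randrange(0, 10_000)
                ivs.append((s, s + rng.randrange(1, 800)))
            calls = [call(f"S{i}", "1", s, e) for i, (s, e) in enumerate(ivs)]
            merged = cnvr.merge_cnvrs(calls, n_test_samples=n)
            got = sorted(sorted(int(m.sample_id[1:]) for m in r.member_calls)
                         for r in merged)
            assert got == brute_force_components(ivs)

    def test_members_contained_and_chry_excluded(self):
        calls = [call("A", "1", 0, 100), call("A", "Y", 0, 100)]
        out = cnvr.merge_cnvrs(calls, n_test_samples=1)
        assert len(out) == 1 and out[0].chrom == "1"
        for r in out:
            for m in r.member_calls:
                assert r.start <= m.start and m.end <= r.end

    def test_empty_input_empty_catalog(self):
        assert cnvr.merge_cnvrs([], n_test_samples=3) == []


class TestSummaries:
    GENOME = GenomeSpec((("1", 10_000_000),))

    def _regions(self, sizes_kb):
        out = []
        pos = 0
        for i, kb in enumerate(sizes_kb):
            c = call("A", "1", pos, pos + int(kb * 1000))
            r = cnvr.merge_cnvrs([c], n_test_samples=12)[0]
            r.id = f"CNVR_{i + 1}"
            out.append(r)
            pos += int(kb * 1000) + 10_000
        return out

    def test_mean_and_median_length(self):
        s = cnvr.summarize_catalog(self._regions([10, 20, 30]), self.GENOME)
        assert s["mean_length_kb"] == pytest.approx(20.0)
        assert s["median_length_kb"] == pytest.approx(20.0)

    def test_per_sample_count_summary(self):
        counts = [180, 144, 229, 153, 211, 224, 262, 118, 291, 260, 139, 65]
        s = cnvr.call_count_summary(counts)
        assert s["mean_cnvs_per_sample"] == 189.67
        assert s["total_cnvs"] == 2276

    def test_type_composition_percentages(self):
        s = cnvr.type_composition({"loss": 529, "gain": 200, "both": 29})
        assert s["loss_percent"] == 69.79
        assert s["gain_percent"] == 26.39
        assert s["both_percent"] == 3.83
        assert s["loss_gain_ratio"] == 2.65
        total = s["loss_percent"] + s["gain_percent"] + s["both_percent"]
        assert total == pytest.approx(100.0, abs=0.011)  # 2-dp rounding

    def test_size_histogram_bins(self):
        s = cnvr.summarize_catalog(self._regions([5, 15, 35, 70, 200, 600]),
                                   self.GENOME)
        assert list(s["size_histogram_kb"].values()) == [1, 1, 1, 1, 1, 1]

    def test_region_past_chromosome_end_rejected(self):
        r = self._regions([50])[0]
        tiny = GenomeSpec((("1", 10_000),))
        with pytest.raises(ValueError, match="past the end"):
            cnvr.summarize_catalog([r], tiny)


class TestCompare:
    def test_single_overlap_full_percentages(self):
        c = cnvr.compare_catalogs([("1", 0, 100)], [("1", 50, 150)])
        assert (c.n_overlapping, c.count_percent) == (1, 100.0)
        assert c.length_percent == 100.0

    def test_disjoint_sets(self):
        c = cnvr.compare_catalogs([("1", 0, 100)], [("1", 200, 300)])
        assert c.n_overlapping == 0 and c.count_percent == 0.0

    def test_self_comparison_is_total(self):
        regions = [("1", i * 1000, i * 1000 + 500) for i in range(20)]
        c = cnvr.compare_catalogs(regions, regions)
        assert c.count_percent == 100.0 and c.length_percent == 100.0

    def test_matches_all_pairs_oracle(self):
        rng = random.Random(3)
        for _ in range(30):
            def rand_set(n):
                out = []
                for i in range(n):
                    s = rng.randrange(0, 50_000)
                    out.append((rng.choice("12"), s, s + rng.randrange(1, 2_000)))
                return out
            q, r = rand_set(200), rand_set(200)
            got = cnvr.compare_catalogs(q, r)
            hits = {i for i, (qc, qs, qe) in enumerate(q)
                    if any(rc == qc and qs < re_ and rs < qe
                           for rc, rs, re_ in r)}
            assert got.n_overlapping == len(hits)
            assert got.overlap_length_kb == pytest.approx(
                sum(q[i][2] - q[i][1] for i in hits) / 1e3, abs=0.01)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            cnvr.compare_catalogs([], [("1", 0, 10)])


class TestMultiCatalogUnion:
    def test_same_hit_counted_once(self):
        q = [("1", 0, 100, "q1")]
        a = cnvr.compare_catalogs(q, [("1", 50, 60)])
        b = cnvr.compare_catalogs(q, [("1", 10, 20)])
        assert cnvr.multi_catalog_union([a, b]) == 1

    def test_disjoint_hit_sets_add(self):
        q = [("1", i * 100, i * 100 + 50, f"q{i}") for i in range(10)]
        a = cnvr.compare_catalogs(q, [("1", 0, 250)])      # hits q0..q2
        b = cnvr.compare_catalogs(q, [("1", 300, 700)])    # hits q3..q6
        assert a.n_overlapping == 3 and b.n_overlapping == 4
        assert cnvr.multi_catalog_union([a, b]) == 7

    def test_matches_set_union_oracle(self):
        rng = random.Random(4)
        q = []
        for i in range(100):
            s = rng.randrange(0, 30_000)
            q.append(("1", s, s + rng.randrange(1, 500), f"q{i}"))
        refs = []
        for _ in range(3):
            ref = []
            for _ in range(40):
                s = rng.randrange(0, 30_000)
                ref.append(("1", s, s + rng.randrange(1, 500)))
            refs.append(ref)
        comps = [cnvr.compare_catalogs(q, ref) for ref in refs]
        expected = set()
        for ref in refs:
            for qid_i, (qc, qs, qe, qid) in enumerate(q):
                if any(rc == qc and qs < re_ and rs < qe for rc, rs, re_ in ref):
                    expected.add(qid)
        assert cnvr.multi_catalog_union(comps) == len(expected)
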