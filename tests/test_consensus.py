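"""Consensus merging: breakpoint CIs, reciprocal overlap, clustering."""

import numpy as np
import pytest

import dupscape as d
from dupscape.consensus import (
    brute_force_clusters,
    single_linkage_clusters,
    _ci_link,
)

from conftest import random_ci_calls


BIG = d.GenomeIndex([("chr1", 10_000_000)])


class TestBreakpointCI:
    @pytest.mark.parametrize(
        "method,start_ci,end_ci",
        [
            ("PE_SR", (9950, 10100), (19900, 20050)),  # 50 out / 100 in
            ("RD", (9000, 10400), (19600, 21000)),     # 1 kb out / 400 in
            ("SR", (9990, 10010), (19990, 20010)),     # +/- 10
        ],
    )
    def test_method_resolution_geometry(self, method, start_ci, end_ci):
        call = d.RawCall("chr1", 10000, 20000, method, "s1",
                         support_pairs=5, support_mq=60)
        cc = d.assign_breakpoint_ci(call, BIG)
        assert cc.start_ci == start_ci
        assert cc.end_ci == end_ci

    def test_clamped_to_chromosome(self):
        genome = d.GenomeIndex([("chr1", 600)])
        call = d.RawCall("chr1", 30, 500, "PE_SR", "s1", 5, 60)
        cc = d.assign_breakpoint_ci(call, genome)
        assert cc.start_ci == (0, 130)
        assert cc.end_ci == (400, 550)

    def test_unknown_method_and_bad_coords(self):
        with pytest.raises(ValueError):
            d.RawCall("chr1", 0, 100, "XX", "s1")
        call = d.RawCall("chrX", 0, 100, "SR", "s1")
        with pytest.raises(KeyError):
            d.assign_breakpoint_ci(call, BIG)
        off = d.RawCall("chr1", 100, 20_000_000, "SR", "s1")
        with pytest.raises(ValueError):
            d.assign_breakpoint_ci(off, BIG)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100), (0, 100), 1.0),
            ((0, 100), (90, 190), 0.1),
            ((0, 100), (200, 300), 0.0),
            ((0, 1000), (50, 1050), 0.95),
            ((0, 100), (0, 200), 0.5),
        ],
    )
    def test_values(self, a, b, expected):
        assert d.reciprocal_overlap(a, b) == pytest.approx(expected)

    def test_different_chromosomes_disjoint(self):
        assert d.reciprocal_overlap(("chr1", 0, 100), ("chr2", 0, 100)) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            d.reciprocal_overlap((5, 5), (0, 100))

    def test_symmetry_random(self, rng):
        for _ in range(100):
            a = sorted(rng.integers(0, 1000, 2))
            b = sorted(rng.integers(0, 1000, 2))
            if a[0] == a[1] or b[0] == b[1]:
                continue
            assert d.reciprocal_overlap(tuple(a), tuple(b)) == pytest.approx(
                d.reciprocal_overlap(tuple(b), tuple(a))
            )


class TestMergeWithinTool:
    def _ci(self, start, end, sample="s1", method="PE_SR", cid=None):
        return d.assign_breakpoint_ci(
            d.RawCall("chr1", start, end, method, sample, 5, 60, id=cid), BIG
        )

    def test_overlapping_cis_merge(self):
        # startCIs [9950,10100] and [10010,10160] intersect; ends likewise
        loci = d.merge_within_tool([self._ci(10000, 20000), self._ci(10060, 19980)])
        assert len(loci) == 1
        assert loci[0].methods == frozenset({"PE_SR"})

    def test_requires_both_breakpoints(self):
        # startCIs intersect but endCIs are 150 bp apart > CI reach
        loci = d.merge_within_tool([self._ci(10000, 20000), self._ci(10060, 21000)])
        assert len(loci) == 2

    def test_single_call_is_own_locus(self):
        (locus,) = d.merge_within_tool([self._ci(10000, 20000, cid="a")])
        assert (locus.start, locus.end) == (10000, 20000)
        assert locus.members == ("a",)

    def test_representative_is_median(self):
        loci = d.merge_within_tool(
            [self._ci(10000, 20000), self._ci(10020, 20020), self._ci(10040, 20040)]
        )
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (10020, 20020)

    def test_idempotent(self, rng):
        for _ in range(30):
            calls = random_ci_calls(rng, int(rng.integers(2, 40)))
            once = d.merge_within_tool(calls)
            again = d.merge_within_tool(
                [
                    d.CICall(
                        call=d.RawCall(l.chrom, l.start, l.end, "PE_SR", "rep"),
                        start_ci=l.start_ci, end_ci=l.end_ci,
                    )
                    for l in once
                ]
            )
            assert [(l.chrom, l.start, l.end) for l in again] == [
                (l.chrom, l.start, l.end) for l in once
            ]

    def test_order_invariant(self, rng):
        calls = random_ci_calls(rng, 30)
        ref = [(l.start, l.end, l.members) for l in d.merge_within_tool(calls)]
        for _ in range(5):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            got = [(l.start, l.end, l.members) for l in d.merge_within_tool(perm)]
            assert got == ref


class TestClusteringOracle:
    def test_matches_brute_force_transitive_closure(self, rng):
        """Sweep clustering equals the all-pairs transitive-closure oracle."""
        for _ in range(60):
            calls = random_ci_calls(rng, int(rng.integers(2, 50)))
            fast = single_linkage_clusters(
                calls, _ci_link, lambda c: c.start_ci[0], lambda c: c.start_ci[1]
            )
            fast_parts = {frozenset(c.call.id for c in cl) for cl in fast}
            oracle = brute_force_clusters(calls, _ci_link)
            oracle_parts = {
                frozenset(calls[i].call.id for i in comp) for comp in oracle
            }
            assert fast_parts == oracle_parts


class TestFilterSupport:
    def _call(self, pairs, mq):
        return d.RawCall("chr1", 0, 100, "PE_SR", "s1", pairs, mq)

    @pytest.mark.parametrize(
        "pairs,mq,kept",
        [(3, 21, True), (2, 60, False), (3, 20, False), (10, 21, True)],
    )
    def test_thresholds(self, pairs, mq, kept):
        out = d.filter_support([self._call(pairs, mq)])
        assert bool(out) is kept

    def test_other_methods_pass_through(self):
        c = d.RawCall("chr1", 0, 100, "RD", "s1")
        assert d.filter_support([c]) == [c]

    def test_missing_support_fields_rejected(self):
        with pytest.raises(ValueError):
            d.filter_support([d.RawCall("chr1", 0, 100, "PE_SR", "s1")])


class TestDropUbiquitous:
    def _locus(self, samples):
        return d.DupLocus("chr1", 0, 100, samples=frozenset(samples),
                          members=("m",), methods=frozenset({"PE_SR"}))

    def test_all_reference_samples_removed(self):
        refs = [f"r{i}" for i in range(10)]
        assert d.drop_ubiquitous([self._locus(refs)], refs) == []

    def test_nine_of_ten_kept(self):
        refs = [f"r{i}" for i in range(10)]
        l = self._locus(refs[:9])
        assert d.drop_ubiquitous([l], refs) == [l]

    def test_absent_everywhere_kept(self):
        refs = [f"r{i}" for i in range(10)]
        l = self._locus(["x1"])
        assert d.drop_ubiquitous([l], refs) == [l]

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError):
            d.drop_ubiquitous([self._locus(["a"])], [])


def _locus(chrom, start, end, method, sample="s1", species=frozenset()):
    return d.DupLocus(chrom, start, end, methods=frozenset({method}),
                      members=(f"{method}:{start}",), samples=frozenset({sample}),
                      species=species)


class TestConsensusAcrossTools:
    def test_two_methods_kept_one_dropped(self):
        per_tool = {
            "PE_SR": [_locus("chr1", 0, 1000, "PE_SR")],
            "SR": [_locus("chr1", 0, 1000, "SR")],
            "RD": [_locus("chr1", 500_000, 501_000, "RD")],
        }
        out = d.consensus_across_tools(per_tool)
        assert len(out) == 1
        assert out[0].methods == frozenset({"PE_SR", "SR"})

    def test_90_percent_reciprocal_overlap_links(self):
        per_tool = {
            "PE_SR": [_locus("chr1", 0, 1000, "PE_SR")],
            "SR": [_locus("chr1", 50, 1050, "SR")],  # RO 0.95
        }
        assert len(d.consensus_across_tools(per_tool)) == 1

    def test_below_threshold_not_linked(self):
        per_tool = {
            "PE_SR": [_locus("chr1", 0, 1000, "PE_SR")],
            "SR": [_locus("chr1", 200, 1200, "SR")],  # RO 0.8
        }
        assert d.consensus_across_tools(per_tool) == []

    def test_bad_min_overlap_rejected(self):
        with pytest.raises(ValueError):
            d.consensus_across_tools({"SR": []}, min_overlap=1.5)

    def test_every_output_lists_two_methods_and_no_residual_overlap(self, rng):
        per_tool = {m: [] for m in d.METHODS}
        for i in range(60):
            start = int(rng.integers(0, 500_000))
            size = int(rng.integers(500, 5000))
            for m in d.METHODS:
                if rng.random() < 0.7:
                    js = start + int(rng.integers(-20, 20))
                    per_tool[m].append(_locus("chr1", js, js + size, m, f"s{i}"))
        out = d.consensus_across_tools(per_tool)
        for l in out:
            assert len(l.methods) >= 2
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                assert d.reciprocal_overlap(a, b) < 0.9


class TestMergeCrossSpecies:
    def test_disjoint_retained(self):
        a = [_locus("chr1", 0, 1000, "SR")]
        b = [_locus("chr1", 100_000, 101_000, "SR")]
        out = d.merge_cross_species(a, b)
        assert len(out) == 2
        assert {tuple(sorted(l.species)) for l in out} == {("A",), ("B",)}

    def test_high_overlap_pair_merges_with_both_tags(self):
        a = [_locus("chr1", 0, 1000, "SR")]
        b = [_locus("chr1", 25, 1025, "SR")]  # RO 0.975 > 0.9
        (merged,) = d.merge_cross_species(a, b)
        assert merged.species == frozenset({"A", "B"})

    def test_exactly_90_percent_not_merged(self):
        # strict > threshold for the cross-species merge
        a = [_locus("chr1", 0, 1000, "SR")]
        b = [_locus("chr1", 100, 1100, "SR")]  # RO exactly 0.9
        assert len(d.merge_cross_species(a, b)) == 2

    def test_counting_identity(self):
        a = [_locus("chr1", i * 100_000, i * 100_000 + 1000, "SR") for i in range(5)]
        b = [_locus("chr1", i * 100_000 + 300_000 + 10, i * 100_000 + 301_000, "SR")
             for i in range(5)]
        # loci a[3], a[4] overlap b[0], b[1] at RO > 0.9 -> 2 pairs merged
        out = d.merge_cross_species(a, b)
        assert len(out) == 8


class TestDiscoveryPipeline:
    def test_consensus_subset_of_input_space(self, sim_small):
        data = sim_small
        cfg = data.config
        calls = data.calls[cfg.species_a]
        loci = d.discovery_set(calls, data.genome)
        starts = [c.start for m in calls.values() for c in m]
        ends = [c.end for m in calls.values() for c in m]
        for l in loci:
            assert min(starts) - 2000 <= l.start <= l.end <= max(ends) + 2000
            assert len(l.methods) >= 2
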