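"""Somatic filter cascade: stage semantics, ordering, and oracle equivalence."""

import numpy as np
import pytest

from conftest import make_call

from sbaexome.filtering import (
    apply_hard_filters,
    filter_finnish_wgs,
    filter_inhouse,
    filter_pooled_normals,
    filter_population_af,
    restrict_to_targets,
    run_cascade,
)
from sbaexome.intervals import GenomicIntervals
from sbaexome.variants import PooledEvidence, PopulationResource, TargetRegions


class TestHardFilters:
    def test_low_qd_snv_removed(self):
        bad = make_call(hard_filter_annotations={"QD": 1.5})
        good = make_call(pos=1600, hard_filter_annotations={"QD": 25.0})
        kept = apply_hard_filters([bad, good])
        assert kept == [good]
        assert "hard_filter" in bad.filter_trace

    def test_missing_annotations_pass_by_default(self):
        call = make_call()
        assert apply_hard_filters([call]) == [call]

    def test_empty_input(self):
        assert apply_hard_filters([]) == []

    def test_unknown_operator_is_configuration_error(self):
        with pytest.raises(ValueError, match="operator"):
            apply_hard_filters([make_call()], {"SNV": {"QD": ("gt", 2.0)}})

    def test_indel_thresholds_differ_from_snv(self):
        # FS = 100 fails the SNV cutoff (60) but passes the indel cutoff (200)
        snv = make_call(hard_filter_annotations={"FS": 100.0})
        indel = make_call(pos=1600, ref="AT", alt="A", hard_filter_annotations={"FS": 100.0})
        assert apply_hard_filters([snv, indel]) == [indel]


class TestFinnishStage:
    def test_exact_key_removed_regardless_of_af(self, empty_resource):
        empty_resource.finnish_keys.add(("1", 1500, "A", "C"))
        call = make_call()
        assert filter_finnish_wgs([call], empty_resource) == []

    def test_different_alt_allele_retained(self, empty_resource):
        empty_resource.finnish_keys.add(("1", 1500, "A", "C"))
        call = make_call(alt="G")
        assert filter_finnish_wgs([call], empty_resource) == [call]

    def test_indel_single_bp_overlap_removed(self, empty_resource):
        empty_resource.finnish_indel_sites.add("1", 1502, 1510)
        # deletion at 1500 of AGC: footprint 1501-1502 overlaps by exactly 1 bp
        indel = make_call(pos=1500, ref="AGC", alt="A")
        assert filter_finnish_wgs([indel], empty_resource) == []


class TestPopulationAfStage:
    def test_af_above_threshold_removed(self, empty_resource):
        empty_resource.snv_af[("1", 1500, "A", "C")] = 0.0002
        assert filter_population_af([make_call()], empty_resource) == []

    def test_af_exactly_at_threshold_retained(self, empty_resource):
        empty_resource.snv_af[("1", 1500, "A", "C")] = 0.0001
        call = make_call()
        assert filter_population_af([call], empty_resource) == [call]

    def test_absent_from_resource_retained(self, empty_resource):
        call = make_call()
        assert filter_population_af([call], empty_resource) == [call]

    def test_bad_threshold_rejected(self, empty_resource):
        with pytest.raises(ValueError):
            filter_population_af([], empty_resource, max_af=1.5)


class TestInhouseStage:
    def test_key_match_removed_and_labeled(self, empty_resource):
        empty_resource.inhouse_keys.add(("1", 1500, "A", "C"))
        call = make_call()
        assert filter_inhouse([call], empty_resource) == []
        assert call.filter_trace == ["inhouse"]

    def test_duplicate_keys_treated_identically(self, empty_resource):
        empty_resource.inhouse_keys.add(("1", 1500, "A", "C"))
        dup1, dup2 = make_call(), make_call(sample_id="S2")
        assert filter_inhouse([dup1, dup2], empty_resource) == []


class TestPooledNormalsStage:
    def test_snv_read_threshold(self, empty_pool):
        empty_pool.snv_pool_reads[("1", 1500, "A", "C")] = 3
        assert filter_pooled_normals([make_call()], empty_pool) == []
        empty_pool.snv_pool_reads[("1", 1500, "A", "C")] = 2
        call = make_call()
        assert filter_pooled_normals([call], empty_pool) == [call]

    def test_indel_two_samples_over_three_reads_removed(self):
        pool = PooledEvidence(
            snv_pool_reads={},
            indel_window_support={("1", 1450): (4, 4, 0, 0, 0, 0, 0, 0, 0, 0)},
        )
        indel = make_call(pos=1500, ref="AT", alt="A")  # 50 bp from the pool locus
        assert filter_pooled_normals([indel], pool) == []

    def test_indel_single_deep_sample_retained(self):
        pool = PooledEvidence(
            snv_pool_reads={},
            indel_window_support={("1", 1450): (10, 0, 0, 0, 0, 0, 0, 0, 0, 0)},
        )
        indel = make_call(pos=1500, ref="AT", alt="A")
        assert filter_pooled_normals([indel], pool) == [indel]

    def test_indel_outside_window_retained(self):
        pool = PooledEvidence(
            snv_pool_reads={},
            indel_window_support={("1", 1000): (4, 4, 0, 0, 0, 0, 0, 0, 0, 0)},
        )
        indel = make_call(pos=1101, ref="AT", alt="A")  # 101 bp away
        assert filter_pooled_normals([indel], pool) == [indel]


class TestTargetRestriction:
    def test_boundary_inclusive(self, toy_targets):
        at_start = make_call(pos=1000)
        past_end = make_call(pos=2001)
        assert restrict_to_targets([at_start, past_end], toy_targets) == [at_start]

    def test_empty_regions(self):
        regions = TargetRegions(GenomicIntervals([("2", 1, 2)]), total_mb=0.001)
        assert restrict_to_targets([make_call()], regions) == []


def _toy_cascade_fixture():
    """20 hand-written calls: 5 Finnish, 4 common, 3 in-house, 2 pool, 2 off-target, 4 clean."""
    resource = PopulationResource(
        snv_af={("1", 1000 + i, "A", "C"): 0.01 for i in range(6, 10)},
        indel_sites=GenomicIntervals(),
        finnish_keys={("1", 1000 + i, "A", "C") for i in range(1, 6)},
        finnish_indel_sites=GenomicIntervals(),
        inhouse_keys={("1", 1000 + i, "A", "C") for i in range(10, 13)},
    )
    pool = PooledEvidence(
        snv_pool_reads={("1", 1013, "A", "C"): 5, ("1", 1014, "A", "C"): 3},
        indel_window_support={},
    )
    targets = TargetRegions(GenomicIntervals([("1", 1000, 1100)]), total_mb=0.0001)
    calls = [make_call(pos=1000 + i) for i in range(1, 15)]  # 5+4+3+2 filterable
    calls += [make_call(pos=5000), make_call(pos=6000)]  # off-target
    calls += [make_call(pos=1020 + i) for i in range(4)]  # clean
    return calls, resource, pool, targets


def test_cascade_matches_hand_enumeration():
    calls, resource, pool, targets = _toy_cascade_fixture()
    somatic, table = run_cascade(calls, resource, pool, targets)
    assert len(somatic) == 4
    removed = dict(zip(table["stage"], table["n_removed"]))
    assert removed == {
        "hard_filter": 0,
        "finnish_wgs": 5,
        "population_af": 4,
        "inhouse": 3,
        "pooled_normals": 2,
        "target_regions": 2,
    }
    assert all("somatic" in c.filter_trace for c in somatic)


def test_cascade_counts_non_increasing():
    calls, resource, pool, targets = _toy_cascade_fixture()
    _, table = run_cascade(calls, resource, pool, targets)
    assert (table["n_out"] <= table["n_in"]).all()
    assert list(table["n_in"][1:]) == list(table["n_out"][:-1])


def test_all_germline_fixture_yields_zero_somatic(empty_pool, toy_targets):
    resource = PopulationResource(
        snv_af={("1", 1500 + i, "A", "C"): 0.2 for i in range(10)},
        indel_sites=GenomicIntervals(),
        finnish_keys=set(),
        finnish_indel_sites=GenomicIntervals(),
        inhouse_keys=set(),
    )
    calls = [make_call(pos=1500 + i) for i in range(10)]
    somatic, _ = run_cascade(calls, resource, empty_pool, toy_targets)
    assert somatic == []


def _brute_force_rule(call, resource, pool, targets, max_af=1e-4):
    """Independent per-variant somatic rule (no cascade machinery)."""
    if call.is_indel:
        start, end = call.footprint
        if resource.finnish_indel_sites.overlaps(call.chrom, start, end):
            return False
        if resource.indel_sites.overlaps(call.chrom, start, end):
            return False
        n_pool = max((len(v) for v in pool.indel_window_support.values()), default=0)
        per_sample = [0] * n_pool
        for (c, p), counts in pool.indel_window_support.items():
            if c == call.chrom and abs(p - call.pos) <= 100:
                per_sample = [max(a, b) for a, b in zip(per_sample, counts)]
        if sum(c > 3 for c in per_sample) >= 2:
            return False
    else:
        if call.key in resource.finnish_keys:
            return False
        if resource.snv_af.get(call.key, 0.0) > max_af:
            return False
        if pool.snv_pool_reads.get(call.key, 0) >= 3:
            return False
    if call.key in resource.inhouse_keys:
        return False
    return targets.intervals.contains(call.chrom, call.pos)


def test_cascade_equals_brute_force_oracle_on_random_calls(tiny_resource, tiny_cohort):
    calls_by_sample, pool, targets, _, _ = tiny_cohort
    rng = np.random.default_rng(42)
    sample = next(iter(calls_by_sample))
    pool_calls = list(calls_by_sample[sample])
    subset = [pool_calls[i] for i in rng.choice(len(pool_calls), size=min(800, len(pool_calls)), replace=False)]
    somatic, _ = run_cascade(list(subset), tiny_resource, pool, targets)
    got = {c.key for c in somatic}
    expected = {c.key for c in subset if _brute_force_rule(c, tiny_resource, pool, targets)}
    assert got == expected
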