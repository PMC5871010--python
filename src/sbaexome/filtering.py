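"""Tumor-only somatic filter cascade.

Without a matched normal, somatic status is inferred by subtraction: calls
matching population variation (a population-specific whole-genome set, then
the full population allele-frequency resource at AF > 1e-4), an in-house
artifact panel, or read-level evidence in pooled normal genomes are removed,
and the survivors inside the capture target are labeled somatic. Stage order
is part of the contract and is recorded in the per-stage count table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from sbaexome.variants import PooledEvidence, PopulationResource, TargetRegions, VariantCall

# GATK's published recommended hard-filter thresholds, overridable per run.
# Each entry: annotation -> ("ge" keep if >=, "le" keep if <=, value).
DEFAULT_HARD_FILTERS: dict[str, dict[str, tuple[str, float]]] = {
    "SNV": {
        "QD": ("ge", 2.0),
        "FS": ("le", 60.0),
        "MQ": ("ge", 40.0),
        "MQRankSum": ("ge", -12.5),
        "ReadPosRankSum": ("ge", -8.0),
        "SOR": ("le", 3.0),
    },
    "indel": {
        "QD": ("ge", 2.0),
        "FS": ("le", 200.0),
        "ReadPosRankSum": ("ge", -20.0),
        "SOR": ("le", 10.0),
    },
}

_STAGES = ["hard_filter", "finnish_wgs", "population_af", "inhouse", "pooled_normals", "target_regions"]


def _passes_thresholds(call: VariantCall, thresholds: dict[str, tuple[str, float]]) -> bool:
    for name, (op, value) in thresholds.items():
        if op not in ("ge", "le"):
            raise ValueError(f"unknown hard-filter operator {op!r} for {name!r}")
        annot = call.hard_filter_annotations.get(name)
        if annot is None:
            continue  # missing annotations pass by default
        if op == "ge" and annot < value:
            return False
        if op == "le" and annot > value:
            return False
    return True


def apply_hard_filters(
    calls: Iterable[VariantCall],
    thresholds: dict[str, dict[str, tuple[str, float]]] | None = None,
) -> list[VariantCall]:
    """Apply variant-calling hard filters (QD, FS, MQ, ...) per variant class."""
    thresholds = DEFAULT_HARD_FILTERS if thresholds is None else thresholds
    for class_thresholds in thresholds.values():
        for name, (op, _) in class_thresholds.items():
            if op not in ("ge", "le"):
                raise ValueError(f"unknown hard-filter operator {op!r} for {name!r}")
    kept = []
    for call in calls:
        table = thresholds.get("SNV" if call.variant_class == "SNV" else "indel", {})
        if _passes_thresholds(call, table):
            kept.append(call)
        else:
            call.filter_trace.append("hard_filter")
    return kept


def filter_finnish_wgs(calls: Iterable[VariantCall], resource: PopulationResource) -> list[VariantCall]:
    """Remove all variants found in the Finnish whole-genome sample set.

    SNVs match on exact (chrom, pos, ref, alt); indels are removed on any
    reference-footprint overlap with a Finnish indel site, regardless of AF.
    """
    kept = []
    for call in calls:
        if call.is_indel:
            start, end = call.footprint
            hit = resource.finnish_indel_sites.overlaps(call.chrom, start, end)
        else:
            hit = call.key in resource.finnish_keys
        if hit:
            call.filter_trace.append("finnish_wgs")
        else:
            kept.append(call)
    return kept


def filter_population_af(
    calls: Iterable[VariantCall],
    resource: PopulationResource,
    max_af: float = 0.0001,
) -> list[VariantCall]:
    """Remove variants common in the full population resource.

    SNVs with resource AF strictly greater than ``max_af`` are excluded
    (exact key match required); indels are excluded on any footprint overlap
    with a known population indel. Calls absent from the resource are kept.
    """
    if not 0.0 <= max_af <= 1.0:
        raise ValueError(f"max_af must be in [0,1], got {max_af}")
    kept = []
    for call in calls:
        if call.is_indel:
            start, end = call.footprint
            hit = resource.indel_sites.overlaps(call.chrom, start, end)
        else:
            hit = resource.snv_af.get(call.key, 0.0) > max_af
        if hit:
            call.filter_trace.append("population_af")
        else:
            kept.append(call)
    return kept


def filter_inhouse(calls: Iterable[VariantCall], resource: PopulationResource) -> list[VariantCall]:
    """Remove exact-key matches to the in-house panel (platform/pipeline errors)."""
    kept = []
    for call in calls:
        if call.key in resource.inhouse_keys:
            call.filter_trace.append("inhouse")
        else:
            kept.append(call)
    return kept


def filter_pooled_normals(
    calls: Iterable[VariantCall],
    pool: PooledEvidence,
    snv_min_reads: int = 3,
    indel_min_samples: int = 2,
    indel_reads_gt: int = 3,
    window_bp: int = 100,
) -> list[VariantCall]:
    """Refine calls against read evidence in pooled normal genomes.

    An SNV is removed iff the pool holds >= ``snv_min_reads`` mutant reads at
    its key. An indel is removed iff >= ``indel_min_samples`` pooled samples
    each have > ``indel_reads_gt`` reads supporting an indel within
    ``window_bp`` (one read length) of the locus.
    """
    kept = []
    n_pool_samples = max(
        (len(v) for v in pool.indel_window_support.values()), default=0
    )
    for call in calls:
        if call.is_indel:
            per_sample = [0] * n_pool_samples
            for locus in pool.indel_loci_near(call.chrom, call.pos, window_bp):
                counts = pool.indel_window_support[locus]
                for i, c in enumerate(counts):
                    if c > per_sample[i]:
                        per_sample[i] = c
            hit = sum(c > indel_reads_gt for c in per_sample) >= indel_min_samples
        else:
            hit = pool.snv_pool_reads.get(call.key, 0) >= snv_min_reads
        if hit:
            call.filter_trace.append("pooled_normals")
        else:
            kept.append(call)
    return kept


def restrict_to_targets(calls: Iterable[VariantCall], regions: TargetRegions) -> list[VariantCall]:
    """Keep only calls whose (leftmost) position lies inside the capture target."""
    kept = []
    for call in calls:
        if regions.contains(call):
            kept.append(call)
        else:
            call.filter_trace.append("target_regions")
    return kept


def run_cascade(
    calls: Sequence[VariantCall],
    resource: PopulationResource,
    pool: PooledEvidence,
    regions: TargetRegions,
    thresholds: dict | None = None,
    max_af: float = 0.0001,
) -> tuple[list[VariantCall], pd.DataFrame]:
    """Run the ordered somatic filter cascade.

    Order: hard filters (from the variant-calling stage), Finnish WGS, full
    population AF, in-house panel, pooled-normal refinement, target
    restriction. Returns the surviving (somatic) calls and a per-stage count
    table with columns ``stage``, ``n_in``, ``n_out``, ``n_removed``.
    """
    stages = [
        ("hard_filter", lambda c: apply_hard_filters(c, thresholds)),
        ("finnish_wgs", lambda c: filter_finnish_wgs(c, resource)),
        ("population_af", lambda c: filter_population_af(c, resource, max_af)),
        ("inhouse", lambda c: filter_inhouse(c, resource)),
        ("pooled_normals", lambda c: filter_pooled_normals(c, pool)),
        ("target_regions", lambda c: restrict_to_targets(c, regions)),
    ]
    current = list(calls)
    rows = []
    for name, stage in stages:
        n_in = len(current)
        current = stage(current)
        rows.append({"stage": name, "n_in": n_in, "n_out": len(current), "n_removed": n_in - len(current)})
    for call in current:
        call.filter_trace.append("somatic")
    return current, pd.DataFrame(rows)
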