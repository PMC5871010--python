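"""End-to-end study driver.

Runs the whole tumor-only analysis on a cohort: somatic filter cascade,
MSI/MSS classification, allelic-imbalance calling against a normal-panel
normalization model, mutational-signature extraction (all samples first to
detect the MSI signature, then MSS-only as a refinement run), and the
cohort summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from sbaexome import baf as baf_mod
from sbaexome import filtering, mmr, signatures, stats
from sbaexome.intervals import GenomicIntervals
from sbaexome.variants import PooledEvidence, PopulationResource, TargetRegions, VariantCall


@dataclass
class StudyResult:
    somatic_by_sample: dict[str, list[VariantCall]]
    stage_tables: dict[str, pd.DataFrame]
    profiles: list[mmr.SampleProfile]
    ai_segments: dict[str, list[baf_mod.AISegment]]
    ai_summary: dict[str, pd.DataFrame]
    weights: pd.DataFrame | None
    exposures: pd.DataFrame | None
    matches: dict[str, tuple[str, float]] = field(default_factory=dict)
    mss_weights: pd.DataFrame | None = None
    discordant: list[str] = field(default_factory=list)

    @property
    def class_labels(self) -> dict[str, str]:
        return {p.sample_id: p.mmr_class for p in self.profiles}


def run_study(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    resource: PopulationResource,
    pool: PooledEvidence,
    targets: TargetRegions,
    ms_loci: GenomicIntervals,
    genome,
    normal_points: Mapping[str, Sequence[baf_mod.BafPoint]] | None = None,
    normal_sexes: Mapping[str, str] | None = None,
    sample_sexes: Mapping[str, str] | None = None,
    reference: pd.DataFrame | None = None,
    n_signatures: int = 3,
    msi_signature_id: str = "6",
    seed: int = 0,
    n_restarts: int = 10,
    params: baf_mod.SegmentationParams | None = None,
) -> StudyResult:
    reference = reference if reference is not None else signatures.load_reference_catalog()
    params = params or baf_mod.SegmentationParams()
    sample_sexes = sample_sexes or {}

    # 1. somatic filter cascade
    somatic_by_sample: dict[str, list[VariantCall]] = {}
    stage_tables: dict[str, pd.DataFrame] = {}
    for sample, calls in calls_by_sample.items():
        somatic, table = filtering.run_cascade(list(calls), resource, pool, targets)
        somatic_by_sample[sample] = somatic
        stage_tables[sample] = table

    # 2. MMR classification from burden and microsatellite indels
    profiles = [
        mmr.compute_sample_profile(sample, somatic, ms_loci, targets.total_mb)
        for sample, somatic in somatic_by_sample.items()
    ]
    profiles = mmr.classify_mmr(profiles)
    labels = {p.sample_id: p.mmr_class for p in profiles}

    # 3. allelic imbalance
    if normal_points:
        model = baf_mod.compute_chrom_normalization(normal_points, normal_sexes)
        model.blacklist = baf_mod.derive_blacklist(normal_points, params)
    else:
        chroms = {c for calls in calls_by_sample.values() for c in {x.chrom for x in calls}}
        model = baf_mod.NormalizationModel(chrom_coeff={c: 1.0 for c in chroms})
    ai_segments: dict[str, list[baf_mod.AISegment]] = {}
    for sample, calls in calls_by_sample.items():
        somatic_keys = {c.key for c in somatic_by_sample[sample]}
        points, _ = baf_mod.select_informative_snps(
            calls, somatic_keys, targets, model.blacklist
        )
        ai_segments[sample] = baf_mod.call_ai(
            sample, points, model, params, sex=sample_sexes.get(sample, "F")
        )
    ai_summary = baf_mod.summarize_ai(ai_segments)

    # 4. mutational signatures: all samples (detect MSI signature), then MSS-only
    catalog, _ = signatures.build_catalog(somatic_by_sample, genome)
    weights = exposures = None
    matches: dict[str, tuple[str, float]] = {}
    mss_weights = None
    discordant: list[str] = []
    k = min(n_signatures, len(catalog))
    if k >= 1 and catalog.to_numpy().sum() > 0:
        weights = signatures.extract_signatures(catalog, k, n_restarts=n_restarts, seed=seed)
        exposures = signatures.project_exposures(catalog, weights)
        matches = signatures.match_reference(weights, reference)
        named = exposures.copy()
        named.columns = [matches[c][0] for c in exposures.columns]
        named = named.T.groupby(level=0).sum().T
        if msi_signature_id in named.columns:
            profiles, discordant = mmr.confirm_with_signature(
                profiles, named, msi_signature_id
            )
        mss_samples = [s for s, c in labels.items() if c == mmr.MSS]
        if len(mss_samples) >= k:
            mss_weights = signatures.extract_signatures(
                catalog.loc[mss_samples], k, n_restarts=n_restarts, seed=seed + 1
            )

    return StudyResult(
        somatic_by_sample=somatic_by_sample,
        stage_tables=stage_tables,
        profiles=profiles,
        ai_segments=ai_segments,
        ai_summary=ai_summary,
        weights=weights,
        exposures=exposures,
        matches=matches,
        mss_weights=mss_weights,
        discordant=discordant,
    )


def cohort_summary(result: StudyResult, targets: TargetRegions) -> dict[str, pd.DataFrame]:
    """Standard cohort tables from a finished study run."""
    labels = result.class_labels
    return {
        "burden": stats.mutation_burden_table(result.somatic_by_sample, labels, targets.total_mb),
        "genes": stats.gene_frequency_table(result.somatic_by_sample, labels),
        "hotspots": stats.hotspot_table(
            [c for calls in result.somatic_by_sample.values() for c in calls]
        ),
        "ai_per_sample": result.ai_summary["per_sample"],
        "ai_totals": result.ai_summary["totals"],
    }
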