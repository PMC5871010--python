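"""Allelic-imbalance calling from B-allele frequencies and normalized log-R.

Germline heterozygous SNPs carry a B-allele frequency (BAF) near 0.5 in
allelically balanced regions; losses, gains and copy-neutral LOH push the
mirrored BAF (mBAF = max(BAF, 1-BAF)) toward 1. Segments of shifted mBAF are
found by change-point segmentation, and each segment is classified gain or
loss by its median log-R ratio,

    logR = log2(varCoverage / (sampleMedian * chromNormalize[chr])),

where sampleMedian is the sample's median coverage outside AI regions and
chromNormalize[chr] a chromosome-specific coefficient derived from a panel of
normal exomes. The tumor analysis runs segmentation twice: the first pass
locates AI regions so the sample median (and hence log-R) can be recomputed
from balanced territory only; the second pass produces the reported
segments, called gain when median log-R > 0.1 and loss otherwise (the loss
class includes copy-number-neutral LOH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from sbaexome.intervals import GenomicIntervals, strip_chr
from sbaexome.variants import VariantCall, VariantKey


def chrom_sort_key(chrom: str):
    c = strip_chr(chrom)
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass
class BafPoint:
    """One informative germline SNP with BAF, coverage and (optional) log-R."""

    chrom: str
    pos: int
    baf: float
    coverage: int
    logr: float | None = None
    informative: bool = True

    @property
    def mbaf(self) -> float:
        return max(self.baf, 1.0 - self.baf)


@dataclass
class SegmentationParams:
    """BAF-segmentation parameters.

    mBAF >= ``non_informative`` marks a point presumed homozygous; isolated
    points above ``triplet_threshold`` are discarded as noise; a reported
    segment needs mean mBAF >= ``ai_threshold`` over >= ``ai_size`` SNPs.
    Segments with median log-R above ``gain_logr_cutoff`` are gains.
    """

    non_informative: float = 0.97
    ai_threshold: float = 0.6
    ai_size: int = 4
    triplet_threshold: float = 0.8
    gain_logr_cutoff: float = 0.1
    penalty: float | None = None  # change-point penalty; None = data-driven
    penalty_scale: float = 10.0

    def __post_init__(self) -> None:
        if not 0.5 < self.ai_threshold <= self.triplet_threshold < self.non_informative <= 1.0:
            raise ValueError(
                "require 0.5 < ai_threshold <= triplet_threshold < non_informative <= 1"
            )
        if self.ai_size < 1:
            raise ValueError("ai_size must be >= 1")


@dataclass
class NormalizationModel:
    """Chromosome coefficients, per-sample medians and the AI blacklist."""

    chrom_coeff: dict[str, float]
    sample_median: dict[str, float] = field(default_factory=dict)
    blacklist: GenomicIntervals = field(default_factory=GenomicIntervals)
    undefined_chroms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chrom_coeff.values()):
            raise ValueError("normalization coefficients must be > 0")
        self.blacklist.merge()


@dataclass
class AISegment:
    """A called allelic-imbalance segment (SNP-span bounds, 1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    mean_mbaf: float
    median_logr: float | None = None
    call: str | None = None  # "gain" or "loss"


def select_informative_snps(
    calls: Iterable[VariantCall],
    somatic_keys: set[VariantKey],
    regions,
    blacklist: GenomicIntervals,
    min_coverage: int = 10,
) -> tuple[list[BafPoint], int]:
    """Select germline SNPs for AI analysis.

    Five criteria: rs-coded; coverage >= ``min_coverage``; not flagged
    somatic; inside the exome target; not overlapping the blacklist of
    AI-artifact-prone regions. Returns the BAF points (sorted by chromosome
    and position) and the number of records skipped for missing depth
    fields.
    """
    points: list[BafPoint] = []
    n_skipped = 0
    for call in calls:
        if call.depth is None or call.alt_depth is None:
            n_skipped += 1
            continue
        if call.rs_id is None:
            continue
        if call.depth < min_coverage:
            continue
        if call.key in somatic_keys:
            continue
        if not regions.contains(call):
            continue
        if blacklist.contains(call.chrom, call.pos):
            continue
        points.append(BafPoint(call.chrom, call.pos, call.alt_depth / call.depth, call.depth))
    points.sort(key=lambda p: (chrom_sort_key(p.chrom), p.pos))
    return points, n_skipped


def compute_chrom_normalization(
    normal_points: Mapping[str, Sequence[BafPoint]],
    sex: Mapping[str, str] | None = None,
) -> NormalizationModel:
    """Derive chromosome normalization coefficients from a normal panel.

    coeff[c] = (median coverage on c across all normals) / (global median
    across all normals, autosomes). The X coefficient uses only female
    samples; with no females it is left undefined and flagged.
    """
    if not normal_points:
        raise ValueError("at least one normal sample required")
    sex = sex or {}
    by_chrom: dict[str, list[int]] = {}
    autosomal: list[int] = []
    for sample, pts in normal_points.items():
        for p in pts:
            chrom = strip_chr(p.chrom)
            if chrom == "X" and sex.get(sample, "F") != "F":
                continue
            by_chrom.setdefault(chrom, []).append(p.coverage)
            if chrom != "X":
                autosomal.append(p.coverage)
    global_median = float(np.median(autosomal))
    coeff: dict[str, float] = {}
    undefined: list[str] = []
    for chrom, covs in by_chrom.items():
        if covs:
            coeff[chrom] = float(np.median(covs)) / global_median
        else:
            undefined.append(chrom)
    has_females = any(v == "F" for v in sex.values()) if sex else True
    if "X" not in coeff and not has_females:
        undefined.append("X")
    return NormalizationModel(chrom_coeff=coeff, undefined_chroms=undefined)


def compute_logr(
    points: Sequence[BafPoint],
    model: NormalizationModel,
    sample_id: str,
) -> list[BafPoint]:
    """Set each point's log-R: log2(coverage / (sample_median * chrom_coeff)).

    Points with zero coverage or an uncovered chromosome coefficient are
    dropped.
    """
    median = model.sample_median.get(sample_id)
    if median is None or median <= 0:
        raise ValueError(f"sample_median for {sample_id!r} missing or <= 0")
    out = []
    for p in points:
        coeff = model.chrom_coeff.get(strip_chr(p.chrom))
        if p.coverage <= 0 or coeff is None:
            continue
        p.logr = math.log2(p.coverage / (median * coeff))
        out.append(p)
    return out


# --- change-point segmentation ------------------------------------------------

def _default_penalty(x: np.ndarray, scale: float) -> float:
    # robust noise estimate from first differences; median(|X1-X2|) ~ 0.954 sigma
    if len(x) < 2:
        return 1.0
    med_diff = float(np.median(np.abs(np.diff(x))))
    sigma = med_diff / 0.9539 if med_diff > 0 else float(np.std(x))
    return max(scale * sigma * sigma * math.log(len(x)), 1e-12)


def optimal_partition(x: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Exact least-squares change-point partition of ``x``.

    Minimizes sum of per-segment squared errors plus ``penalty`` per
    breakpoint (BIC-style linear penalty), by O(n^2) dynamic programming.
    Ties are broken toward fewer segments. Returns half-open index spans.
    """
    n = len(x)
    if n == 0:
        return []
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    best = np.empty(n + 1)
    nseg = np.zeros(n + 1, dtype=int)
    back = np.zeros(n + 1, dtype=int)
    best[0] = -penalty
    for j in range(1, n + 1):
        i = np.arange(j)
        lengths = j - i
        sse = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / lengths
        cand = best[:j] + sse + penalty
        # tie-break: fewest segments among (near-)equal costs
        order = np.lexsort((nseg[:j], cand))
        k = order[0]
        cmin = cand[k]
        close = np.flatnonzero(cand <= cmin + 1e-12)
        k = close[np.argmin(nseg[close])]
        best[j] = cand[k]
        nseg[j] = nseg[k] + 1
        back[j] = k
    spans = []
    j = n
    while j > 0:
        i = int(back[j])
        spans.append((i, j))
        j = i
    return spans[::-1]


def segment_baf(
    points: Sequence[BafPoint],
    params: SegmentationParams | None = None,
    sample_id: str = "",
) -> list[AISegment]:
    """Call AI segments from an mBAF series (gain/loss calls left unset).

    Per chromosome: (1) mirror BAF; (2) drop presumed-homozygous points
    (mBAF >= non_informative); (3) triplet filter — drop an informative
    point with mBAF > triplet_threshold unless an adjacent informative
    neighbor also exceeds it; (4) exact change-point segmentation of the
    remaining series; (5) report segments with mean mBAF >= ai_threshold
    and >= ai_size SNPs, merging adjacent qualifying segments.
    """
    params = params or SegmentationParams()
    by_chrom: dict[str, list[BafPoint]] = {}
    for p in points:
        by_chrom.setdefault(strip_chr(p.chrom), []).append(p)
    segments: list[AISegment] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        pts = sorted(by_chrom[chrom], key=lambda p: p.pos)
        informative = [p for p in pts if p.mbaf < params.non_informative]
        keep = []
        for idx, p in enumerate(informative):
            if p.mbaf > params.triplet_threshold:
                left = informative[idx - 1].mbaf > params.triplet_threshold if idx > 0 else False
                right = (
                    informative[idx + 1].mbaf > params.triplet_threshold
                    if idx + 1 < len(informative)
                    else False
                )
                if not (left or right):
                    continue
            keep.append(p)
        if len(keep) < params.ai_size:
            continue
        x = np.array([p.mbaf for p in keep])
        penalty = params.penalty if params.penalty is not None else _default_penalty(
            x, params.penalty_scale
        )
        spans = optimal_partition(x, penalty)
        qualifying = [
            (i, j)
            for i, j in spans
            if (j - i) >= params.ai_size and float(np.mean(x[i:j])) >= params.ai_threshold
        ]
        # merge qualifying segments that are adjacent in the retained series
        merged: list[tuple[int, int]] = []
        for i, j in qualifying:
            if merged and merged[-1][1] == i:
                merged[-1] = (merged[-1][0], j)
            else:
                merged.append((i, j))
        for i, j in merged:
            seg_pts = keep[i:j]
            logrs = [p.logr for p in seg_pts if p.logr is not None]
            segments.append(
                AISegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=seg_pts[0].pos,
                    end=seg_pts[-1].pos,
                    n_snps=len(seg_pts),
                    mean_mbaf=float(np.mean(x[i:j])),
                    median_logr=float(np.median(logrs)) if logrs else None,
                )
            )
    return segments


def derive_blacklist(
    normal_points: Mapping[str, Sequence[BafPoint]],
    params: SegmentationParams | None = None,
    recurrence_fraction: float = 0.10,
) -> GenomicIntervals:
    """Find regions recurrently AI-called in a panel of normal exomes.

    Normal samples carry no true somatic AI, so recurrent calls mark
    technical artifacts (low-complexity loci, centromeres, chromosome ends).
    Regions called in >= ``recurrence_fraction`` of normals are returned
    merged; tumor SNPs overlapping them are excluded from AI analysis.
    """
    params = params or SegmentationParams()
    n = len(normal_points)
    threshold = max(1, math.ceil(recurrence_fraction * n - 1e-9))
    events: dict[str, list[tuple[int, int]]] = {}
    for sample, pts in normal_points.items():
        for seg in segment_baf(pts, params, sample_id=sample):
            events.setdefault(seg.chrom, []).append((seg.start, +1))
            events.setdefault(seg.chrom, []).append((seg.end + 1, -1))
    out = GenomicIntervals()
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        region_start = None
        for pos, delta in evs:
            depth += delta
            if depth >= threshold and region_start is None:
                region_start = pos
            elif depth < threshold and region_start is not None:
                out.add(chrom, region_start, pos - 1)
                region_start = None
    return out.merge()


def call_ai(
    sample_id: str,
    points: Sequence[BafPoint],
    model: NormalizationModel,
    params: SegmentationParams | None = None,
    sex: str = "F",
) -> list[AISegment]:
    """Two-pass AI calling with refined sample-median log-R.

    Pass 1 segments the mBAF series with the sample median taken over all
    points; the median is then recomputed excluding points inside pass-1
    segments, log-R is refined, and pass 2 produces the final segments,
    classified gain (median log-R > cutoff) or loss (includes copy-neutral
    LOH). The X chromosome is excluded for male samples (no reliable het
    SNPs).
    """
    params = params or SegmentationParams()
    pts = list(points)
    if sex == "M":
        pts = [p for p in pts if strip_chr(p.chrom) != "X"]
    if not pts:
        return []
    # pass 1: median over all points
    model.sample_median[sample_id] = float(np.median([p.coverage for p in pts]))
    pts = compute_logr(pts, model, sample_id)
    pass1 = segment_baf(pts, params, sample_id=sample_id)
    in_segment = GenomicIntervals((s.chrom, s.start, s.end) for s in pass1)
    outside = [p for p in pts if not in_segment.contains(p.chrom, p.pos)]
    if outside:
        model.sample_median[sample_id] = float(np.median([p.coverage for p in outside]))
    # pass 2 on refined log-R
    pts = compute_logr(pts, model, sample_id)
    segments = segment_baf(pts, params, sample_id=sample_id)
    for seg in segments:
        if seg.median_logr is not None:
            seg.call = "gain" if seg.median_logr > params.gain_logr_cutoff else "loss"
    return segments


def summarize_ai(
    segments_by_sample: Mapping[str, Sequence[AISegment]],
    gene_annotations: Mapping[str, tuple[str, int, int]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort AI summary: per-sample gain/loss counts and per-gene overlaps.

    A gene counts once per sample per event kind when its locus overlaps any
    segment of that kind in the sample.
    """
    rows = []
    for sample, segs in segments_by_sample.items():
        gains = sum(1 for s in segs if s.call == "gain")
        losses = sum(1 for s in segs if s.call == "loss")
        rows.append({"sample_id": sample, "gains": gains, "losses": losses})
    per_sample = pd.DataFrame(rows, columns=["sample_id", "gains", "losses"])
    gene_rows = []
    for gene, (chrom, start, end) in (gene_annotations or {}).items():
        chrom = strip_chr(chrom)
        n_gain = n_loss = 0
        for sample, segs in segments_by_sample.items():
            kinds = {
                s.call
                for s in segs
                if strip_chr(s.chrom) == chrom and s.start <= end and s.end >= start
            }
            n_gain += "gain" in kinds
            n_loss += "loss" in kinds
        gene_rows.append({"gene": gene, "samples_with_gain": n_gain, "samples_with_loss": n_loss})
    per_gene = pd.DataFrame(gene_rows, columns=["gene", "samples_with_gain", "samples_with_loss"])
    totals = pd.DataFrame(
        [{"gains": int(per_sample["gains"].sum()), "losses": int(per_sample["losses"].sum())}]
    )
    return {"per_sample": per_sample, "per_gene": per_gene, "totals": totals}
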