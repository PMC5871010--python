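"""Variant records and the lookup resources backing the somatic filter cascade."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from sbaexome.intervals import GenomicIntervals, strip_chr

#: variant key: (chrom, 1-based pos, ref, alt), chromosome in bare dialect
VariantKey = tuple[str, int, str, str]

NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift", "splice"})


@dataclass
class VariantCall:
    """One called variant in one tumor sample.

    ``depth``/``alt_depth`` come from the VCF FORMAT fields DP and AD and feed
    both the somatic filters (coverage criteria) and the B-allele frequency
    (alt_depth / depth) used by allelic-imbalance calling.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_depth: int
    rs_id: str | None = None
    hard_filter_annotations: dict[str, float] = field(default_factory=dict)
    gene: str | None = None
    consequence: str = "other"
    protein_change: str | None = None
    filter_trace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = strip_chr(self.chrom)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_indel(self) -> bool:
        return self.variant_class != "SNV"

    @property
    def footprint(self) -> tuple[int, int]:
        """1-based inclusive reference footprint.

        Deletions span the deleted bases; an insertion's footprint is the
        single base before the insertion point.
        """
        if self.variant_class == "deletion":
            return (self.pos + 1, self.pos + len(self.ref) - 1)
        return (self.pos, self.pos)

    @property
    def baf(self) -> float:
        return self.alt_depth / self.depth if self.depth else float("nan")

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence in NONSYNONYMOUS


@dataclass
class TargetRegions:
    """Merged capture-target intervals with the declared capture size in Mb."""

    intervals: GenomicIntervals
    total_mb: float

    def __post_init__(self) -> None:
        if self.total_mb <= 0:
            raise ValueError("total_mb must be > 0")
        self.intervals.merge()

    def contains(self, call: VariantCall) -> bool:
        # the leftmost affected base decides for indels
        return self.intervals.contains(call.chrom, call.pos)

    @classmethod
    def from_bed(cls, path: str | Path, total_mb: float | None = None) -> "TargetRegions":
        ivs = GenomicIntervals.from_bed(path).merge()
        if total_mb is None:
            total_mb = ivs.total_bp() / 1e6
        return cls(ivs, total_mb)


@dataclass
class PopulationResource:
    """Population allele frequencies and exclusion panels.

    ``snv_af`` maps exact variant keys to population allele frequency;
    ``indel_sites`` holds known population indel footprints (any overlap
    excludes a called indel). The Finnish whole-genome set and the in-house
    panel are separate exclusion sets applied regardless of frequency.
    """

    snv_af: dict[VariantKey, float]
    indel_sites: GenomicIntervals
    finnish_keys: set[VariantKey]
    finnish_indel_sites: GenomicIntervals
    inhouse_keys: set[VariantKey]

    def __post_init__(self) -> None:
        bad = [af for af in self.snv_af.values() if not 0.0 <= af <= 1.0]
        if bad:
            raise ValueError(f"allele frequencies outside [0,1]: {bad[:3]}")
        self.indel_sites.merge()
        self.finnish_indel_sites.merge()

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [(c, p, r, a, af) for (c, p, r, a), af in sorted(self.snv_af.items())]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
            outdir / "population_af.tsv", sep="\t", index=False
        )
        self.indel_sites.to_bed(outdir / "population_indels.bed")
        self.finnish_indel_sites.to_bed(outdir / "finnish_indels.bed")
        for name, keys in [("finnish_snvs", self.finnish_keys), ("inhouse", self.inhouse_keys)]:
            rows = sorted(keys)
            pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(
                outdir / f"{name}.tsv", sep="\t", index=False
            )

    @classmethod
    def from_dir(cls, indir: str | Path) -> "PopulationResource":
        indir = Path(indir)
        af = pd.read_csv(indir / "population_af.tsv", sep="\t", dtype={"chrom": str})
        snv_af = {
            (strip_chr(r.chrom), int(r.pos), r.ref, r.alt): float(r.af)
            for r in af.itertuples()
        }

        def read_keys(name: str) -> set[VariantKey]:
            df = pd.read_csv(indir / f"{name}.tsv", sep="\t", dtype={"chrom": str})
            return {(strip_chr(r.chrom), int(r.pos), r.ref, r.alt) for r in df.itertuples()}

        return cls(
            snv_af=snv_af,
            indel_sites=GenomicIntervals.from_bed(indir / "population_indels.bed"),
            finnish_keys=read_keys("finnish_snvs"),
            finnish_indel_sites=GenomicIntervals.from_bed(indir / "finnish_indels.bed"),
            inhouse_keys=read_keys("inhouse"),
        )


@dataclass
class PooledEvidence:
    """Read evidence from a pooled set of normal blood genomes.

    ``snv_pool_reads`` gives the mutant read count for a variant key summed
    over the pool; ``indel_window_support`` gives, per indel locus, the
    supporting read count of each pooled sample (used with a +/- window).
    """

    snv_pool_reads: dict[VariantKey, int]
    indel_window_support: dict[tuple[str, int], tuple[int, ...]]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.snv_pool_reads.values()):
            raise ValueError("pooled read counts must be >= 0")
        self._indel_pos: dict[str, list[int]] = {}
        for chrom, pos in sorted(self.indel_window_support):
            self._indel_pos.setdefault(chrom, []).append(pos)

    def indel_loci_near(self, chrom: str, pos: int, window_bp: int) -> list[tuple[str, int]]:
        import bisect

        chrom = strip_chr(chrom)
        positions = self._indel_pos.get(chrom, [])
        lo = bisect.bisect_left(positions, pos - window_bp)
        hi = bisect.bisect_right(positions, pos + window_bp)
        return [(chrom, p) for p in positions[lo:hi]]


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Tabulate calls for reporting."""
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "class": c.variant_class,
            "depth": c.depth,
            "alt_depth": c.alt_depth,
            "rs_id": c.rs_id,
            "gene": c.gene,
            "consequence": c.consequence,
            "protein_change": c.protein_change,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
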