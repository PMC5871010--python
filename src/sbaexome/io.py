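"""Reading and writing the study's file formats.

VCFv4.2 per sample (FORMAT DP and AD; gene annotations in INFO), 0-based
half-open BED for targets and microsatellite loci, TSV for the allele
frequency resource, panels, pooled evidence, and truth tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from sbaexome.intervals import GenomicIntervals, strip_chr
from sbaexome.synthetic import CohortConfig, CohortTruth, _KARYOTYPE_MB
from sbaexome.variants import PooledEvidence, PopulationResource, TargetRegions, VariantCall

_ANNOT_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


def write_vcf(path: str | Path, calls: Sequence[VariantCall], sample_id: str,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write one sample's calls as uncompressed VCFv4.2.

    Germline draws taken from the population resource carry their rs id in
    the ID column; gene, consequence and protein change travel in INFO so a
    re-read loses nothing the pipeline needs.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##INFO=<ID=PC,Number=1,Type=String,Description="Protein change">\n')
        for f in _ANNOT_FIELDS:
            fh.write(f'##INFO=<ID={f},Number=1,Type=Float,Description="Hard-filter annotation">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for c in calls:
            info = [f"GENE={c.gene}"] if c.gene else []
            info.append(f"CSQ={c.consequence}")
            if c.protein_change:
                info.append(f"PC={c.protein_change}")
            for f in _ANNOT_FIELDS:
                if f in c.hard_filter_annotations:
                    info.append(f"{f}={c.hard_filter_annotations[f]:g}")
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.rs_id or '.'}\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tDP:AD\t{c.depth}:{c.depth - c.alt_depth},{c.alt_depth}\n"
            )


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Read a VCF into VariantCalls, splitting multi-allelic records."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        sample = sample_id or (samples[0] if samples else Path(path).stem)
        for rec in vf:
            fmt = rec.samples[samples[0]] if samples else {}
            dp = fmt.get("DP")
            ad = fmt.get("AD")
            if dp is None or ad is None:
                continue
            annotations = {
                f: float(rec.info[f]) for f in _ANNOT_FIELDS if f in rec.info
            }
            gene = rec.info.get("GENE")
            csq = rec.info.get("CSQ", "other")
            pc = rec.info.get("PC")
            for i, alt in enumerate(rec.alts or ()):
                alt_depth = int(ad[i + 1]) if len(ad) > i + 1 else 0
                calls.append(
                    VariantCall(
                        sample_id=sample,
                        chrom=strip_chr(rec.chrom),
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=int(dp),
                        alt_depth=min(alt_depth, int(dp)),
                        rs_id=rec.id if rec.id and rec.id != "." else None,
                        hard_filter_annotations=annotations,
                        gene=gene,
                        consequence=csq if isinstance(csq, str) else "other",
                        protein_change=pc,
                    )
                )
    return calls


def write_pool(outdir: Path, pool: PooledEvidence) -> None:
    rows = [(c, p, r, a, n) for (c, p, r, a), n in sorted(pool.snv_pool_reads.items())]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "reads"]).to_csv(
        outdir / "pool_snv_reads.tsv", sep="\t", index=False
    )
    rows = [
        {"chrom": c, "pos": p, **{f"sample_{i + 1}": n for i, n in enumerate(counts)}}
        for (c, p), counts in sorted(pool.indel_window_support.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "pool_indel_support.tsv", sep="\t", index=False)


def read_pool(indir: Path) -> PooledEvidence:
    snv = pd.read_csv(indir / "pool_snv_reads.tsv", sep="\t", dtype={"chrom": str})
    snv_reads = {
        (strip_chr(r.chrom), int(r.pos), r.ref, r.alt): int(r.reads) for r in snv.itertuples()
    }
    ind = pd.read_csv(indir / "pool_indel_support.tsv", sep="\t", dtype={"chrom": str})
    count_cols = [c for c in ind.columns if c.startswith("sample_")]
    support = {
        (strip_chr(r["chrom"]), int(r["pos"])): tuple(int(r[c]) for c in count_cols)
        for _, r in ind.iterrows()
    }
    return PooledEvidence(snv_pool_reads=snv_reads, indel_window_support=support)


def write_truth(outdir: Path, truth: CohortTruth) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"sample_id": s, "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "somatic": flag}
        for (s, k), flag in sorted(truth.somatic_flags.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "somatic_flags.tsv", sep="\t", index=False)
    rows = [
        {"sample_id": s, "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3]}
        for s, k in sorted(truth.germline_keys)
    ]
    pd.DataFrame(rows).to_csv(outdir / "germline_keys.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": s, "mmr_class": c, "sex": truth.sample_sex[s]} for s, c in truth.mmr_class.items()]
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.true_exposures.to_csv(outdir / "true_exposures.tsv", sep="\t")
    rows = [
        {"sample_id": s, "chrom": c, "start": a, "end": b, "kind": k}
        for s, segs in truth.true_ai_segments.items()
        for c, a, b, k in segs
    ]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "kind"]).to_csv(
        outdir / "true_ai_segments.tsv", sep="\t", index=False
    )


def write_cohort(
    outdir: str | Path,
    config: CohortConfig,
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    pool: PooledEvidence,
    targets: TargetRegions,
    ms_loci: GenomicIntervals,
    truth: CohortTruth,
    resource: PopulationResource | None = None,
    write_fasta: bool = False,
) -> Path:
    """Write the full synthetic study to a directory tree."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    contigs = config.chrom_lengths()
    for sample, calls in calls_by_sample.items():
        write_vcf(outdir / "vcf" / f"{sample}.vcf", calls, sample, contigs)
    targets.intervals.to_bed(outdir / "targets.bed")
    ms_loci.to_bed(outdir / "microsatellites.bed")
    write_pool(outdir, pool)
    write_truth(outdir / "truth", truth)
    if resource is not None:
        resource.to_dir(outdir / "resource")
    if write_fasta:
        from sbaexome.synthetic import SyntheticGenome

        SyntheticGenome(config).write_fasta(outdir / "genome.fa")
    import yaml

    with open(outdir / "config.yaml", "w") as fh:
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        }
        yaml.safe_dump(cfg, fh)
    return outdir


def read_config(path: str | Path) -> CohortConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "n_ai_events_per_sample" in raw:
        raw["n_ai_events_per_sample"] = tuple(raw["n_ai_events_per_sample"])
    if "signature_mix" in raw:
        raw["signature_mix"] = {
            cls: dict(mix) for cls, mix in raw["signature_mix"].items()
        }
    return CohortConfig(**raw)
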