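"""Self-contained synthetic study generator.

Emulates a tumor-only exome cohort of small-bowel adenocarcinomas at desk
scale: per-sample call sets mixing germline heterozygous SNPs drawn from a
population allele-frequency resource, somatic mutations drawn from
class-specific mutational-signature mixtures at MSS (~4.3/Mb) and MSI
(~63.6/Mb) burdens over a declared 94 Mb capture target, microsatellite-indel
enrichment in MSI samples, ~40x negative-binomial coverage with
chromosome-specific depth effects, planted sequencing-artifact loci backed by
pooled-normal read evidence, and allelic-imbalance segments that jointly
shift BAF and coverage under a single tumor-purity scalar. Every emitted
variant is accounted for in a truth table, so downstream stages can be
scored without any external data.

Genomic coordinates live on a synthetic 22+X karyotype with real-genome
chromosome proportions scaled down 100-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sbaexome.baf import BafPoint
from sbaexome.intervals import GenomicIntervals
from sbaexome.signatures import CHANNELS, load_reference_catalog
from sbaexome.variants import (
    PooledEvidence,
    PopulationResource,
    TargetRegions,
    VariantCall,
    VariantKey,
)

# chromosome lengths in Mb before scaling (human-proportioned karyotype)
_KARYOTYPE_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 134, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51, "X": 155,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G on 0..3 codes
_BASE_STR = "ACGT"


def default_chrom_coefficients() -> dict[str, float]:
    """Fixed per-chromosome depth multipliers (platform property).

    Chromosome 1 sits at 1.0 and chromosome 16 at 30/38, mirroring typical
    exome capture unevenness; the rest vary mildly around 1.
    """
    rng = np.random.default_rng(999)
    coeff = {c: float(rng.uniform(0.88, 1.12)) for c in _KARYOTYPE_MB}
    coeff["1"] = 1.0
    coeff["16"] = 30.0 / 38.0
    return coeff


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the emulated study: 106 tumors of which ~14% MSI, a
    94 Mb capture target, 40x median depth, class burdens 4.3 (MSS) and
    63.6 (MSI) mut/Mb, and signature mixtures dominated by the MSI
    signature ("6") in MSI samples.
    """

    n_samples: int = 106
    msi_fraction: float = 15 / 106
    target_mb: float = 94.0
    mean_depth: float = 40.0
    mss_burden_per_mb: float = 4.3
    msi_burden_per_mb: float = 63.6
    signature_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "MSS": {"1A": 0.6, "17": 0.25, "U2": 0.15},
            "MSI": {"6": 0.8, "1A": 0.2},
        }
    )
    n_ai_events_per_sample: tuple[int, int] = (3, 12)
    germline_het_snps_per_sample: int = 6000
    seed: int = 0
    # secondary knobs
    purity: float = 0.7
    rare_fraction: float = 0.2
    invented_germline_rate: float = 0.02
    n_population_loci: int = 60000
    n_population_indels: int = 2000
    n_finnish_indels: int = 800
    n_inhouse: int = 1500
    inhouse_carrier_rate: float = 0.01
    n_artifact_loci: int = 150
    artifact_carrier_rate: float = 0.5
    n_ms_loci: int = 4000
    mss_indel_fraction: float = 0.06
    msi_indel_fraction: float = 0.25
    mss_ms_overlap: float = 0.10
    msi_ms_overlap: float = 0.80
    burden_dispersion: float = 0.15  # lognormal sigma on per-sample burden
    depth_dispersion: float = 8.0  # negative-binomial shape
    karyotype_scale: int = 100
    target_fraction: float = 0.30
    genome_seed: int = 1234

    def __post_init__(self) -> None:
        for name in ("target_mb", "mean_depth", "mss_burden_per_mb", "msi_burden_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.msi_fraction <= 1.0:
            raise ValueError("msi_fraction must be in [0,1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0,1]")
        for cls, mix in self.signature_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"signature mix for {cls!r} sums to {total}, not 1")

    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(mb * 1e6 / self.karyotype_scale) for c, mb in _KARYOTYPE_MB.items()}


@dataclass
class CohortTruth:
    """Ground truth for every emitted variant and every planted structure."""

    somatic_flags: dict[tuple[str, VariantKey], bool]
    mmr_class: dict[str, str]
    true_exposures: pd.DataFrame  # samples x signature names (counts)
    true_ai_segments: dict[str, list[tuple[str, int, int, str]]]
    germline_keys: set[tuple[str, VariantKey]]
    sample_sex: dict[str, str]

    def is_true_somatic(self, sample: str, key: VariantKey) -> bool:
        return self.somatic_flags.get((sample, key), False)


class SyntheticGenome:
    """Deterministic random reference sequence on the scaled karyotype."""

    def __init__(self, config: CohortConfig):
        self._lengths = config.chrom_lengths()
        self._seed = config.genome_seed
        self._cache: dict[str, np.ndarray] = {}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._cache:
            idx = list(self._lengths).index(chrom)
            rng = np.random.default_rng([self._seed, idx])
            self._cache[chrom] = rng.integers(0, 4, self._lengths[chrom], dtype=np.uint8)
        return self._cache[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Reference bases for a 1-based inclusive span."""
        if start < 1 or end > self._lengths[chrom]:
            raise IndexError(f"{chrom}:{start}-{end} outside contig")
        return _BASES[self.codes(chrom)[start - 1 : end]].tobytes().decode()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in self._lengths:
                fh.write(f">{chrom}\n")
                seq = _BASES[self.codes(chrom)].tobytes().decode()
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def make_target_regions(config: CohortConfig) -> TargetRegions:
    """Deterministic exon-like tiling covering ``target_fraction`` of the genome."""
    exon = 300
    period = max(exon + 1, round(exon / config.target_fraction))
    ivs = GenomicIntervals()
    for chrom, length in config.chrom_lengths().items():
        # keep one base of margin at both contig ends for trinucleotide flanks
        start = 2
        while start + exon - 1 < length - 1:
            ivs.add(chrom, start, start + exon - 1)
            start += period
    return TargetRegions(ivs.merge(), total_mb=config.target_mb)


def make_microsatellite_loci(config: CohortConfig, targets: TargetRegions) -> GenomicIntervals:
    """Synthetic microsatellite loci placed inside the capture target."""
    rng = np.random.default_rng([config.genome_seed, 77])
    target_ivs = list(targets.intervals)
    out = GenomicIntervals()
    picks = rng.integers(0, len(target_ivs), config.n_ms_loci)
    for i in picks:
        chrom, start, end = target_ivs[i]
        if end - start < 20:
            continue
        pos = int(rng.integers(start, end - 15))
        out.add(chrom, pos, pos + 14)
    return out.merge()


# --- context index ------------------------------------------------------------

_context_cache: dict[tuple, dict] = {}


def _collapsed_context_ids(genome: SyntheticGenome, targets: TargetRegions):
    """Index target positions by strand-collapsed trinucleotide context.

    Returns {context_id: (chrom_idx array, pos array)} where context_id
    encodes (central pyrimidine, 5' flank, 3' flank) in 0..31, plus the
    chromosome name list. Cached per (genome seed, karyotype, tiling).
    """
    key = (genome._seed, tuple(genome._lengths.items()), id(targets.intervals) and None,
           tuple((c, s, e) for c, s, e in targets.intervals)[:5], targets.intervals.total_bp())
    if key in _context_cache:
        return _context_cache[key]
    chroms = genome.chromosomes
    per_context_chrom: dict[int, list[np.ndarray]] = {i: [] for i in range(32)}
    per_context_pos: dict[int, list[np.ndarray]] = {i: [] for i in range(32)}
    ivs_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in targets.intervals:
        ivs_by_chrom.setdefault(chrom, []).append((s, e))
    for ci, chrom in enumerate(chroms):
        if chrom not in ivs_by_chrom:
            continue
        codes = genome.codes(chrom)
        pos_arrays = [np.arange(s, e + 1) for s, e in ivs_by_chrom[chrom]]
        pos = np.concatenate(pos_arrays)
        center = codes[pos - 1]
        five = codes[pos - 2]
        three = codes[pos]
        # collapse purine centers to the reverse-complement pyrimidine context
        purine = (center == 0) | (center == 2)  # A or G
        comp = np.array([3, 2, 1, 0], dtype=np.uint8)
        c_center = np.where(purine, comp[center], center)
        c_five = np.where(purine, comp[three], five)
        c_three = np.where(purine, comp[five], three)
        pyr_id = np.where(c_center == 1, 0, 1)  # C=0, T=1
        ctx_id = pyr_id * 16 + c_five * 4 + c_three
        order = np.argsort(ctx_id, kind="stable")
        ctx_sorted = ctx_id[order]
        pos_sorted = pos[order]
        bounds = np.searchsorted(ctx_sorted, np.arange(33))
        for i in range(32):
            lo, hi = bounds[i], bounds[i + 1]
            if hi > lo:
                per_context_chrom[i].append(np.full(hi - lo, ci, dtype=np.int16))
                per_context_pos[i].append(pos_sorted[lo:hi])
    index = {
        i: (
            np.concatenate(per_context_chrom[i]) if per_context_chrom[i] else np.empty(0, np.int16),
            np.concatenate(per_context_pos[i]) if per_context_pos[i] else np.empty(0, np.int64),
        )
        for i in range(32)
    }
    result = (chroms, index)
    _context_cache[key] = result
    return result


def _channel_context_id(channel: str) -> int:
    # "A[C>T]G" -> collapsed context id of ACG
    five, rest = channel[0], channel[2:]
    central = rest[0]
    three = channel[-1]
    pyr_id = 0 if central == "C" else 1
    return pyr_id * 16 + _BASE_STR.index(five) * 4 + _BASE_STR.index(three)


# --- population resource ------------------------------------------------------

def generate_population_resource(config: CohortConfig) -> PopulationResource:
    """Generate the population AF resource and exclusion panels.

    SNV allele frequencies span [1e-6, 0.5]; a ``rare_fraction`` of entries
    have AF <= 1e-4 (retained by the AF filter) and the rest AF > 1e-4
    (filterable). The Finnish key set covers most common entries and a
    minority of rare ones; the in-house panel holds platform-artifact keys
    at separate loci.
    """
    genome = SyntheticGenome(config)
    targets = make_target_regions(config)
    target_ivs = list(targets.intervals)
    lengths = config.chrom_lengths()

    rng_pos = np.random.default_rng([config.seed, 10])
    rng_rare = np.random.default_rng([config.seed, 11])
    rng_allele = np.random.default_rng([config.seed, 12])
    rng_af = np.random.default_rng([config.seed, 13])
    rng_panel = np.random.default_rng([config.seed, 14])

    n = config.n_population_loci
    keys: list[VariantKey] = []
    seen: set[VariantKey] = set()
    chrom_names = list(lengths)
    while len(keys) < n:
        if rng_pos.random() < 0.9:
            chrom, s, e = target_ivs[int(rng_pos.integers(0, len(target_ivs)))]
            pos = int(rng_pos.integers(s, e + 1))
        else:
            chrom = chrom_names[int(rng_pos.integers(0, len(chrom_names)))]
            pos = int(rng_pos.integers(2, lengths[chrom] - 1))
        ref = genome.base(chrom, pos)
        alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng_allele.integers(1, 4))) % 4]
        key = (chrom, pos, ref, alt)
        if key in seen:
            continue
        seen.add(key)
        keys.append(key)
    rare_mask = rng_rare.random(n) < config.rare_fraction
    afs = np.where(
        rare_mask,
        np.exp(rng_af.uniform(np.log(1e-6), np.log(1e-4), n)),
        np.exp(rng_af.uniform(np.log(2e-4), np.log(0.5), n)),
    )
    snv_af = {k: float(a) for k, a in zip(keys, afs)}

    finnish_pick = rng_panel.random(n) < np.where(rare_mask, 0.1, 0.6)
    finnish_keys = {k for k, f in zip(keys, finnish_pick) if f}

    def random_indel_sites(count: int, stream: np.random.Generator) -> GenomicIntervals:
        ivs = GenomicIntervals()
        picks = stream.integers(0, len(target_ivs), count)
        for i in picks:
            chrom, s, e = target_ivs[i]
            pos = int(stream.integers(s, e - 4))
            ivs.add(chrom, pos, pos + int(stream.integers(0, 5)))
        return ivs.merge()

    indel_sites = random_indel_sites(config.n_population_indels, rng_panel)
    finnish_indels = random_indel_sites(config.n_finnish_indels, rng_panel)

    inhouse: set[VariantKey] = set()
    while len(inhouse) < config.n_inhouse:
        chrom, s, e = target_ivs[int(rng_panel.integers(0, len(target_ivs)))]
        pos = int(rng_panel.integers(s, e + 1))
        ref = genome.base(chrom, pos)
        alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng_panel.integers(1, 4))) % 4]
        key = (chrom, pos, ref, alt)
        if key not in seen:
            inhouse.add(key)

    return PopulationResource(
        snv_af=snv_af,
        indel_sites=indel_sites,
        finnish_keys=finnish_keys,
        finnish_indel_sites=finnish_indels,
        inhouse_keys=inhouse,
    )


# --- cohort -------------------------------------------------------------------

def _ai_baf_shift(kind: str, purity: float) -> tuple[float, float]:
    """(major-allele fraction, coverage multiplier) for an AI event kind."""
    p = purity
    if kind == "loss":
        return (1.0 - ((1 - p) / (2 - p)), (2 - p) / 2.0)
    if kind == "gain":
        return ((1 + p) / (2 + p), (2 + p) / 2.0)
    if kind == "cnn-loh":
        return ((1 + p) / 2.0, 1.0)
    raise ValueError(f"unknown AI kind {kind!r}")


def _negbin_depth(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    mean = np.maximum(mean, 1.0)
    p = shape / (shape + mean)
    return np.maximum(rng.negative_binomial(shape, p), 1)


def generate_cohort(
    config: CohortConfig,
    resource: PopulationResource,
    reference_signatures: pd.DataFrame | None = None,
    require_msi: bool = False,
):
    """Generate the full synthetic cohort.

    Returns ``(calls_by_sample, pool, targets, ms_loci, truth)``. Somatic
    variants are guaranteed absent from the population resource; germline
    het SNPs are drawn from it with probability 1 - invented_germline_rate
    (AF-weighted, so common variants dominate as in a real genome) and
    invented rs-less otherwise, modeling residual rare germline variation.
    """
    if require_msi and config.msi_fraction * config.n_samples < 1:
        raise ValueError(
            "msi_fraction * n_samples < 1: cohort would contain no MSI sample"
        )
    reference = reference_signatures if reference_signatures is not None else load_reference_catalog()
    genome = SyntheticGenome(config)
    targets = make_target_regions(config)
    target_ivs = list(targets.intervals)
    ms_loci = make_microsatellite_loci(config, targets)
    ms_iv_list = list(ms_loci)
    chrom_coeff = default_chrom_coefficients()
    lengths = config.chrom_lengths()
    chroms, ctx_index = _collapsed_context_ids(genome, targets)

    resource_keys = sorted(resource.snv_af)
    afs = np.array([resource.snv_af[k] for k in resource_keys])
    af_weights = afs / afs.sum()
    rs_ids = {k: f"rs{1000000 + i}" for i, k in enumerate(resource_keys)}
    inhouse_list = sorted(resource.inhouse_keys)

    rng_assign = np.random.default_rng([config.seed, 3])
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    n_msi = int(round(config.msi_fraction * config.n_samples))
    msi_samples = set(rng_assign.choice(sample_ids, size=n_msi, replace=False)) if n_msi else set()
    sexes = {s: ("F" if rng_assign.random() < 0.5 else "M") for s in sample_ids}

    # cohort-level artifact loci (platform errors recurring across samples)
    rng_art = np.random.default_rng([config.seed, 4])
    artifact_snvs: list[VariantKey] = []
    while len(artifact_snvs) < config.n_artifact_loci:
        chrom, s, e = target_ivs[int(rng_art.integers(0, len(target_ivs)))]
        pos = int(rng_art.integers(s, e + 1))
        ref = genome.base(chrom, pos)
        alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng_art.integers(1, 4))) % 4]
        key = (chrom, pos, ref, alt)
        if key not in resource.snv_af:
            artifact_snvs.append(key)
    n_art_indels = max(2, config.n_artifact_loci // 10)
    artifact_indels: list[VariantKey] = []
    for _ in range(n_art_indels):
        chrom, s, e = target_ivs[int(rng_art.integers(0, len(target_ivs)))]
        pos = int(rng_art.integers(s, e - 1))
        ref = genome.fetch(chrom, pos, pos + 1)
        artifact_indels.append((chrom, pos, ref, ref[0]))
    pool_snv = {k: int(3 + rng_art.poisson(3)) for k in artifact_snvs}
    pool_indels = {}
    for chrom, pos, _, _ in artifact_indels:
        counts = np.zeros(10, dtype=int)
        supporters = rng_art.choice(10, size=int(rng_art.integers(2, 5)), replace=False)
        counts[supporters] = rng_art.integers(4, 9, len(supporters))
        pool_indels[(chrom, pos)] = tuple(int(c) for c in counts)
    pool = PooledEvidence(snv_pool_reads=pool_snv, indel_window_support=pool_indels)

    sig_names = list(reference.index)

    calls_by_sample: dict[str, list[VariantCall]] = {}
    somatic_flags: dict[tuple[str, VariantKey], bool] = {}
    germline_keys: set[tuple[str, VariantKey]] = set()
    mmr_class: dict[str, str] = {}
    true_ai: dict[str, list[tuple[str, int, int, str]]] = {}
    exposures = pd.DataFrame(0, index=sample_ids, columns=sig_names, dtype=int)

    for si, sample in enumerate(sample_ids):
        rng = np.random.default_rng([config.seed, 100 + si])
        is_msi = sample in msi_samples
        cls = "MSI" if is_msi else "MSS"
        mmr_class[sample] = cls
        calls: list[VariantCall] = []
        used_keys: set[VariantKey] = set()

        # --- allelic-imbalance segments (non-overlapping per chromosome)
        lo, hi = config.n_ai_events_per_sample
        n_events = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
        segments: list[tuple[str, int, int, str]] = []
        occupied: dict[str, list[tuple[int, int]]] = {}
        autosomes = [c for c in lengths if c != "X" or sexes[sample] == "F"]
        for _ in range(n_events):
            for _attempt in range(20):
                chrom = autosomes[int(rng.integers(0, len(autosomes)))]
                clen = lengths[chrom]
                span = int(clen * rng.uniform(0.2, 0.7))
                start = int(rng.integers(1, max(2, clen - span)))
                end = start + span
                if all(e < start or s > end for s, e in occupied.get(chrom, [])):
                    kind = str(rng.choice(["loss", "gain", "cnn-loh"], p=[0.55, 0.30, 0.15]))
                    occupied.setdefault(chrom, []).append((start, end))
                    segments.append((chrom, start, end, kind))
                    break
        true_ai[sample] = segments
        seg_ivs = GenomicIntervals((c, s, e) for c, s, e, _ in segments)
        seg_kind: dict[tuple[str, int, int], str] = {(c, s, e): k for c, s, e, k in segments}

        def ai_effect(chrom: str, pos: int) -> tuple[float | None, float]:
            for (c, s, e), kind in seg_kind.items():
                if c == chrom and s <= pos <= e:
                    return _ai_baf_shift(kind, config.purity)
            return None, 1.0

        # --- germline heterozygous SNPs
        n_germ = config.germline_het_snps_per_sample
        n_invented = int(rng.binomial(n_germ, config.invented_germline_rate))
        n_resource = n_germ - n_invented
        draw = rng.choice(
            len(resource_keys), size=min(n_resource, len(resource_keys)),
            replace=False, p=af_weights,
        )
        germ_records: list[tuple[VariantKey, str | None]] = [
            (resource_keys[i], rs_ids[resource_keys[i]]) for i in draw
        ]
        if sexes[sample] == "M":
            germ_records = [(k, r) for k, r in germ_records if k[0] != "X"]
        for _ in range(n_invented):
            chrom, s, e = target_ivs[int(rng.integers(0, len(target_ivs)))]
            if chrom == "X" and sexes[sample] == "M":
                continue
            pos = int(rng.integers(s, e + 1))
            ref = genome.base(chrom, pos)
            alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng.integers(1, 4))) % 4]
            key = (chrom, pos, ref, alt)
            if key in resource.snv_af:
                continue
            germ_records.append((key, None))

        positions = np.array([k[1] for k, _ in germ_records])
        chrom_mult = np.array([chrom_coeff[k[0]] for k, _ in germ_records])
        major_baf = np.full(len(germ_records), 0.5)
        cov_mult = np.ones(len(germ_records))
        for i, (k, _) in enumerate(germ_records):
            b, m = ai_effect(k[0], k[1])
            if b is not None:
                major_baf[i] = b
                cov_mult[i] = m
        depth = _negbin_depth(
            rng, config.mean_depth * chrom_mult * cov_mult, config.depth_dispersion
        )
        on_major = rng.random(len(germ_records)) < 0.5
        p_alt = np.where(on_major, major_baf, 1.0 - major_baf)
        alt_depth = rng.binomial(depth, p_alt)
        for i, (key, rs) in enumerate(germ_records):
            if key in used_keys:
                continue
            used_keys.add(key)
            ad = int(min(max(alt_depth[i], 1), depth[i] - 1)) if depth[i] > 1 else int(alt_depth[i])
            calls.append(
                VariantCall(
                    sample_id=sample, chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                    depth=int(depth[i]), alt_depth=ad, rs_id=rs,
                    gene=f"G{key[0]}_{key[1] // 10000}",
                    consequence="other",
                )
            )
            germline_keys.add((sample, key))

        # --- somatic mutations from the class signature mixture
        burden = config.msi_burden_per_mb if is_msi else config.mss_burden_per_mb
        if config.burden_dispersion > 0:
            sigma = config.burden_dispersion
            burden *= float(rng.lognormal(-sigma * sigma / 2.0, sigma))
        lam = burden * config.target_mb
        n_somatic = int(rng.poisson(lam))
        indel_frac = config.msi_indel_fraction if is_msi else config.mss_indel_fraction
        ms_overlap = config.msi_ms_overlap if is_msi else config.mss_ms_overlap
        n_indel = int(rng.binomial(n_somatic, indel_frac))
        n_snv = n_somatic - n_indel

        sig_weights = np.array([config.signature_mix[cls].get(s, 0.0) for s in sig_names])
        per_sig = rng.multinomial(n_snv, sig_weights / sig_weights.sum())
        for sig_i, count in enumerate(per_sig):
            exposures.iloc[si, sig_i] += int(count)
        snv_channels = []
        for sig_i, count in enumerate(per_sig):
            if count:
                sig_probs = reference.iloc[sig_i].to_numpy()
                sig_probs = sig_probs / sig_probs.sum()
                snv_channels.extend(rng.choice(96, size=count, p=sig_probs))
        somatic_keys_sample: list[tuple[VariantKey, str]] = []
        for ch in snv_channels:
            channel = CHANNELS[ch]
            ctx_id = _channel_context_id(channel)
            chrom_arr, pos_arr = ctx_index[ctx_id]
            if len(pos_arr) == 0:
                continue
            for _attempt in range(10):
                j = int(rng.integers(0, len(pos_arr)))
                chrom = chroms[chrom_arr[j]]
                pos = int(pos_arr[j])
                ref = genome.base(chrom, pos)
                sub = channel[2:5]  # e.g. "C>T"
                if ref in "CT":
                    alt = sub[2]
                else:
                    alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[sub[2]]
                key = (chrom, pos, ref, alt)
                if key not in resource.snv_af and key not in used_keys:
                    somatic_keys_sample.append((key, "SNV"))
                    break
        for _ in range(n_indel):
            at_ms = rng.random() < ms_overlap and ms_iv_list
            for _attempt in range(10):
                if at_ms:
                    chrom, s, e = ms_iv_list[int(rng.integers(0, len(ms_iv_list)))]
                    pos = int(rng.integers(s, e))
                else:
                    chrom, s, e = target_ivs[int(rng.integers(0, len(target_ivs)))]
                    pos = int(rng.integers(s, e - 1))
                if rng.random() < 0.5:  # deletion
                    ref = genome.fetch(chrom, pos, pos + 1)
                    alt = ref[0]
                else:  # insertion
                    ref = genome.base(chrom, pos)
                    alt = ref + _BASE_STR[int(rng.integers(0, 4))]
                key = (chrom, pos, ref, alt)
                if key not in used_keys:
                    somatic_keys_sample.append((key, "indel"))
                    break

        vaf = config.purity / 2.0
        consequences_snv = ["missense", "synonymous", "nonsense", "splice", "UTR"]
        probs_snv = [0.50, 0.25, 0.08, 0.05, 0.12]
        for key, kind in somatic_keys_sample:
            used_keys.add(key)
            chrom, pos = key[0], key[1]
            b, m = ai_effect(chrom, pos)
            dp = int(
                _negbin_depth(
                    rng,
                    np.array([config.mean_depth * chrom_coeff[chrom] * m]),
                    config.depth_dispersion,
                )[0]
            )
            ad = int(max(rng.binomial(dp, vaf), 1))
            if kind == "SNV":
                csq = str(rng.choice(consequences_snv, p=probs_snv))
            else:
                csq = "frameshift" if rng.random() < 0.8 else "other"
            pc = None
            if csq in ("missense", "nonsense"):
                aa = "ACDEFGHIKLMNPQRSTVWY"
                pc = (
                    f"{aa[int(rng.integers(0, 20))]}{pos % 500 + 1}"
                    f"{'*' if csq == 'nonsense' else aa[int(rng.integers(0, 20))]}"
                )
            calls.append(
                VariantCall(
                    sample_id=sample, chrom=chrom, pos=pos, ref=key[2], alt=key[3],
                    depth=dp, alt_depth=min(ad, dp), rs_id=None,
                    gene=f"G{chrom}_{pos // 10000}", consequence=csq, protein_change=pc,
                )
            )
            somatic_flags[(sample, key)] = True

        # --- planted artifacts (in-house panel carriers and pool-supported)
        for key in inhouse_list:
            if rng.random() < config.inhouse_carrier_rate and key not in used_keys:
                used_keys.add(key)
                dp = int(
                    _negbin_depth(
                        rng, np.array([config.mean_depth * chrom_coeff[key[0]]]),
                        config.depth_dispersion,
                    )[0]
                )
                calls.append(
                    VariantCall(
                        sample_id=sample, chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                        depth=dp, alt_depth=max(1, int(rng.binomial(dp, 0.15))),
                        gene=f"G{key[0]}_{key[1] // 10000}", consequence="other",
                    )
                )
                somatic_flags[(sample, key)] = False
        for key in artifact_snvs + artifact_indels:
            if rng.random() < config.artifact_carrier_rate and key not in used_keys:
                used_keys.add(key)
                dp = int(
                    _negbin_depth(
                        rng, np.array([config.mean_depth * chrom_coeff[key[0]]]),
                        config.depth_dispersion,
                    )[0]
                )
                calls.append(
                    VariantCall(
                        sample_id=sample, chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                        depth=dp, alt_depth=max(1, int(rng.binomial(dp, 0.1))),
                        gene=f"G{key[0]}_{key[1] // 10000}", consequence="other",
                    )
                )
                somatic_flags[(sample, key)] = False

        calls.sort(key=lambda c: ((0, int(c.chrom)) if c.chrom.isdigit() else (1, c.chrom), c.pos))
        calls_by_sample[sample] = calls

    truth = CohortTruth(
        somatic_flags=somatic_flags,
        mmr_class=mmr_class,
        true_exposures=exposures,
        true_ai_segments=true_ai,
        germline_keys=germline_keys,
        sample_sex=sexes,
    )
    return calls_by_sample, pool, targets, ms_loci, truth


def generate_normal_panel(
    config: CohortConfig,
    n_normals: int = 40,
    snps_per_normal: int | None = None,
    artifact_regions: Sequence[tuple[str, int, int]] = (),
    artifact_rate: float = 1.0,
) -> tuple[dict[str, list[BafPoint]], dict[str, str]]:
    """Generate BAF points for a panel of normal exomes.

    Normals have balanced BAF everywhere except in ``artifact_regions``
    (technical AI-artifact loci, shifted in a random ``artifact_rate``
    subset of normals) — the input to chromosome normalization and
    blacklist derivation. Coverage carries the same chromosome-specific
    multipliers as the tumor cohort.
    """
    chrom_coeff = default_chrom_coefficients()
    targets = make_target_regions(config)
    target_ivs = list(targets.intervals)
    n_snps = snps_per_normal or config.germline_het_snps_per_sample
    points: dict[str, list[BafPoint]] = {}
    sexes: dict[str, str] = {}
    for i in range(n_normals):
        rng = np.random.default_rng([config.seed, 5000 + i])
        sample = f"N{i + 1:03d}"
        sexes[sample] = "F" if rng.random() < 0.5 else "M"
        affected = rng.random() < artifact_rate
        iv_picks = rng.integers(0, len(target_ivs), n_snps)
        pts = []
        for j in iv_picks:
            chrom, s, e = target_ivs[j]
            if chrom == "X" and sexes[sample] == "M":
                continue
            pos = int(rng.integers(s, e + 1))
            p_alt = 0.5
            if affected:
                for ac, a_s, a_e in artifact_regions:
                    if chrom == ac and a_s <= pos <= a_e:
                        p_alt = 0.85 if rng.random() < 0.5 else 0.15
                        break
            dp = int(
                _negbin_depth(
                    rng, np.array([config.mean_depth * chrom_coeff[chrom]]),
                    config.depth_dispersion,
                )[0]
            )
            if dp < 10:
                continue
            pts.append(BafPoint(chrom, pos, float(rng.binomial(dp, p_alt)) / dp, dp))
        pts.sort(key=lambda p: ((0, int(p.chrom)) if p.chrom.isdigit() else (1, p.chrom), p.pos))
        points[sample] = pts
    return points, sexes
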