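"""BAF segmentation, log-R normalization, and two-pass AI calling."""

import itertools

import numpy as np
import pytest

from conftest import make_call

from sbaexome.baf import (
    AISegment,
    BafPoint,
    NormalizationModel,
    SegmentationParams,
    call_ai,
    compute_chrom_normalization,
    compute_logr,
    derive_blacklist,
    optimal_partition,
    segment_baf,
    select_informative_snps,
    summarize_ai,
)
from sbaexome.intervals import GenomicIntervals
from sbaexome.variants import TargetRegions


def _points(mbafs, chrom="1", start=1000, spacing=100, coverage=40):
    """BafPoints with the requested mirrored-BAF values."""
    return [
        BafPoint(chrom, start + i * spacing, float(m), coverage)
        for i, m in enumerate(mbafs)
    ]


class TestSnpSelection:
    def setup_method(self):
        self.targets = TargetRegions(GenomicIntervals([("1", 1000, 2000)]), 0.001)
        self.blacklist = GenomicIntervals()

    def test_qualifying_het_snp_becomes_point(self):
        call = make_call(rs_id="rs1", depth=40, alt_depth=20)
        points, _ = select_informative_snps([call], set(), self.targets, self.blacklist)
        assert len(points) == 1 and points[0].baf == pytest.approx(0.5)

    def test_low_coverage_excluded(self):
        call = make_call(rs_id="rs1", depth=9, alt_depth=4)
        points, _ = select_informative_snps([call], set(), self.targets, self.blacklist)
        assert points == []

    def test_somatic_flagged_excluded(self):
        call = make_call(rs_id="rs1")
        points, _ = select_informative_snps([call], {call.key}, self.targets, self.blacklist)
        assert points == []

    def test_rs_less_and_blacklisted_excluded(self):
        no_rs = make_call()
        self.blacklist.add("1", 1600, 1700)
        blacklisted = make_call(pos=1650, rs_id="rs2")
        points, _ = select_informative_snps(
            [no_rs, blacklisted], set(), self.targets, self.blacklist
        )
        assert points == []


class TestChromNormalization:
    def test_printed_median_example(self):
        # chr1 median 38 = global median -> 1.0; chr16 median 30 -> 30/38
        normals = {
            "N1": _points([0.5] * 10, chrom="1", coverage=38)
            + _points([0.5] * 8, chrom="16", coverage=30),
        }
        model = compute_chrom_normalization(normals)
        assert model.chrom_coeff["1"] == pytest.approx(1.0)
        assert model.chrom_coeff["16"] == pytest.approx(30 / 38)

    def test_uniform_coverage_gives_unit_coefficients(self):
        normals = {"N1": _points([0.5] * 5, chrom="1") + _points([0.5] * 5, chrom="2")}
        model = compute_chrom_normalization(normals)
        assert all(v == pytest.approx(1.0) for v in model.chrom_coeff.values())

    def test_x_requires_female_samples(self):
        normals = {"N1": _points([0.5] * 5, chrom="X") + _points([0.5] * 5, chrom="1")}
        model = compute_chrom_normalization(normals, sex={"N1": "M"})
        assert "X" not in model.chrom_coeff and "X" in model.undefined_chroms


class TestLogR:
    def test_identity_doubling_and_chrom_correction(self):
        model = NormalizationModel(
            chrom_coeff={"1": 1.0, "16": 30 / 38}, sample_median={"S": 40.0}
        )
        p0 = BafPoint("1", 1, 0.5, 40)
        p1 = BafPoint("1", 2, 0.5, 80)
        out = compute_logr([p0, p1], model, "S")
        assert out[0].logr == pytest.approx(0.0)
        assert out[1].logr == pytest.approx(1.0)
        model.sample_median["S"] = 38.0
        (p16,) = compute_logr([BafPoint("16", 3, 0.5, 30)], model, "S")
        assert p16.logr == pytest.approx(0.0)

    def test_missing_median_raises(self):
        model = NormalizationModel(chrom_coeff={"1": 1.0})
        with pytest.raises(ValueError):
            compute_logr([BafPoint("1", 1, 0.5, 40)], model, "S")


def brute_force_partition(x, penalty):
    """Exhaustive minimum of SSE + penalty * n_breakpoints (ties: fewer segments)."""
    n = len(x)
    best_key, best_bounds = None, None
    for mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(mask) if b] + [n]
        cost = sum(
            float(((x[a:b] - x[a:b].mean()) ** 2).sum()) for a, b in zip(bounds, bounds[1:])
        ) + penalty * (len(bounds) - 2)
        key = (round(cost, 10), len(bounds) - 1)
        if best_key is None or key < best_key:
            best_key, best_bounds = key, bounds
    return best_key, best_bounds


class TestSegmentation:
    def test_shifted_block_recovered(self):
        rng = np.random.default_rng(0)
        mbafs = [0.5] * 10 + [0.9] * 10 + [0.5] * 10
        noisy = np.clip(np.array(mbafs) + rng.normal(0, 0.01, 30), 0.5, 1.0)
        segs = segment_baf(_points(noisy))
        assert len(segs) == 1
        assert segs[0].n_snps == 10
        assert segs[0].start == 1000 + 10 * 100 and segs[0].end == 1000 + 19 * 100

    def test_minimum_size_rule(self):
        mbafs = [0.5] * 10 + [0.9] * 3 + [0.5] * 10
        assert segment_baf(_points(mbafs)) == []

    def test_non_informative_point_dropped(self):
        mbafs = [0.5] * 10 + [0.99] + [0.5] * 10
        assert segment_baf(_points(mbafs)) == []

    def test_isolated_high_point_removed_by_triplet_filter(self):
        # 0.85 < non_informative but > triplet_threshold, with balanced neighbors
        mbafs = [0.5] * 10 + [0.85] + [0.5] * 10
        assert segment_baf(_points(mbafs)) == []

    def test_adjacent_high_points_survive_triplet_filter(self):
        rng = np.random.default_rng(1)
        mbafs = np.array([0.55] * 8 + [0.85] * 6 + [0.55] * 8)
        noisy = np.clip(mbafs + rng.normal(0, 0.01, len(mbafs)), 0.5, 0.96)
        segs = segment_baf(_points(noisy))
        assert len(segs) == 1 and segs[0].n_snps == 6

    @pytest.mark.parametrize("n,seed", [(8, 0), (10, 1), (12, 2), (14, 3)])
    def test_equals_exhaustive_partition(self, n, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0.55, 0.03, n // 2), rng.normal(0.8, 0.03, n - n // 2)])
        penalty = 0.05
        spans = optimal_partition(x, penalty)
        cost = sum(float(((x[a:b] - x[a:b].mean()) ** 2).sum()) for a, b in spans)
        cost += penalty * (len(spans) - 1)
        (brute_cost, brute_nseg), brute_bounds = brute_force_partition(x, penalty)
        assert cost == pytest.approx(brute_cost, abs=1e-9)
        assert [a for a, _ in spans] == brute_bounds[:-1]

    def test_equals_independent_dp_on_30_points(self):
        rng = np.random.default_rng(7)
        x = np.concatenate(
            [rng.normal(0.55, 0.04, 12), rng.normal(0.85, 0.04, 8), rng.normal(0.55, 0.04, 10)]
        )
        penalty = 0.08
        # independent scalar-loop dynamic program
        n = len(x)
        inf = float("inf")
        best = [inf] * (n + 1)
        back = [0] * (n + 1)
        best[0] = -penalty
        for j in range(1, n + 1):
            for i in range(j):
                seg = x[i:j]
                c = best[i] + float(((seg - seg.mean()) ** 2).sum()) + penalty
                if c < best[j] - 1e-12:
                    best[j], back[j] = c, i
        bounds = []
        j = n
        while j > 0:
            bounds.append((back[j], j))
            j = back[j]
        spans = optimal_partition(x, penalty)
        assert spans == bounds[::-1]


class TestTwoPassCalling:
    def _model(self):
        return NormalizationModel(chrom_coeff={"1": 1.0, "2": 1.0, "X": 1.0})

    def _sample_points(self, rng, kind=None, seg_range=(80, 160), n=240, base_cov=40):
        """One chromosome of binomial BAF points with an optional planted event."""
        shift = {"gain": (0.63, 1.35), "loss": (0.77, 0.65), "cnn-loh": (0.85, 1.0)}
        pts = []
        for i in range(n):
            p_alt, mult = 0.5, 1.0
            if kind and seg_range[0] <= i < seg_range[1]:
                b, mult = shift[kind]
                p_alt = b if rng.random() < 0.5 else 1 - b
            cov = max(10, rng.poisson(base_cov * mult))
            pts.append(BafPoint("1", 1000 + i * 50, rng.binomial(cov, p_alt) / cov, cov))
        return pts

    def test_planted_gain_called_gain(self):
        rng = np.random.default_rng(5)
        pts = self._sample_points(rng, "gain")
        segs = call_ai("S", pts, self._model())
        assert len(segs) == 1 and segs[0].call == "gain"
        assert segs[0].median_logr > 0.1

    def test_copy_neutral_loh_called_loss(self):
        rng = np.random.default_rng(6)
        # long segment so the median log-R (expected 0) is estimated tightly
        pts = self._sample_points(rng, "cnn-loh", seg_range=(100, 250), n=360)
        segs = call_ai("S", pts, self._model())
        assert len(segs) == 1 and segs[0].call == "loss"
        assert abs(segs[0].median_logr) < 0.25  # coverage unchanged

    def test_no_events_no_segments(self):
        rng = np.random.default_rng(8)
        pts = self._sample_points(rng, None)
        assert call_ai("S", pts, self._model()) == []

    def test_male_x_excluded(self):
        rng = np.random.default_rng(9)
        pts = [BafPoint("X", 1000 + i * 50, 0.9, 40) for i in range(20)]
        assert call_ai("S", pts, self._model(), sex="M") == []
        assert len(call_ai("S", pts, self._model(), sex="F")) == 1

    def test_pass2_median_excludes_ai_territory(self):
        # large loss region drags the naive median down; pass 2 recovers it
        rng = np.random.default_rng(10)
        pts = self._sample_points(rng, "loss", seg_range=(0, 150), n=240)
        model = self._model()
        call_ai("S", pts, model)
        diploid_cov = np.median([p.coverage for p in pts[150:]])
        assert model.sample_median["S"] == pytest.approx(diploid_cov, rel=0.06)


class TestBlacklist:
    def test_recurrent_artifact_region_recovered(self):
        rng = np.random.default_rng(3)
        normals = {}
        for i in range(10):
            pts = []
            for j in range(100):
                p_alt = 0.5
                if i < 5 and 40 <= j < 60:  # artifact in half the normals
                    p_alt = 0.9 if rng.random() < 0.5 else 0.1
                cov = max(10, rng.poisson(40))
                pts.append(BafPoint("1", 1000 + j * 100, rng.binomial(cov, p_alt) / cov, cov))
            normals[f"N{i}"] = pts
        blk = derive_blacklist(normals, recurrence_fraction=0.10)
        assert blk.contains("1", 1000 + 50 * 100)
        assert not blk.contains("1", 1000 + 10 * 100)

    def test_single_normal_call_not_blacklisted(self):
        rng = np.random.default_rng(4)
        normals = {}
        for i in range(20):
            pts = []
            for j in range(60):
                p_alt = 0.85 if (i == 0 and 20 <= j < 40) else 0.5
                cov = max(10, rng.poisson(40))
                pts.append(BafPoint("1", 1000 + j * 100, rng.binomial(cov, p_alt) / cov, cov))
            normals[f"N{i}"] = pts
        blk = derive_blacklist(normals, recurrence_fraction=0.10)
        assert not blk.contains("1", 1000 + 30 * 100)


class TestSummary:
    def test_counting(self):
        segs = {
            "A": [
                AISegment("A", "1", 1, 100, 10, 0.8, 0.5, "gain"),
                AISegment("A", "2", 1, 100, 10, 0.8, -0.5, "loss"),
                AISegment("A", "3", 1, 100, 10, 0.8, -0.5, "loss"),
            ],
            "B": [
                AISegment("B", "1", 1, 100, 10, 0.8, 0.5, "gain"),
                AISegment("B", "2", 1, 100, 10, 0.8, -0.5, "loss"),
                AISegment("B", "17", 1, 100, 10, 0.8, -0.5, "loss"),
            ],
        }
        out = summarize_ai(segs, gene_annotations={"TP53": ("17", 40, 60)})
        assert out["totals"]["gains"].iloc[0] == 2
        assert out["totals"]["losses"].iloc[0] == 4
        gene_row = out["per_gene"].set_index("gene").loc["TP53"]
        assert gene_row["samples_with_loss"] == 1 and gene_row["samples_with_gain"] == 0

    def test_empty_input(self):
        out = summarize_ai({})
        assert out["totals"]["gains"].iloc[0] == 0 and out["totals"]["losses"].iloc[0] == 0


def test_segment_invariants_on_synthetic_sample():
    """Called segments never overlap and always satisfy their type invariants."""
    rng = np.random.default_rng(12)
    pts = []
    for chrom in ["1", "2"]:
        for i in range(150):
            p_alt = 0.77 if 30 <= i < 70 else 0.5
            if rng.random() < 0.5:
                p_alt = 1 - p_alt
            cov = max(10, rng.poisson(40))
            pts.append(BafPoint(chrom, 1000 + i * 50, rng.binomial(cov, p_alt) / cov, cov))
    params = SegmentationParams()
    model = NormalizationModel(chrom_coeff={"1": 1.0, "2": 1.0})
    segs = call_ai("S", pts, model, params)
    assert segs, "planted losses should be detected"
    for seg in segs:
        assert seg.n_snps >= params.ai_size
        assert seg.mean_mbaf >= params.ai_threshold
        assert seg.call == ("gain" if seg.median_logr > 0.1 else "loss")
    for chrom in ["1", "2"]:
        spans = sorted((s.start, s.end) for s in segs if s.chrom == chrom)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
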