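"""Per-position coverage, outlier masking, bootstrap sampling, SJ round trip."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lsvkit.coverage import (
    EdgeCoverage,
    SJFile,
    SJFormatError,
    bootstrap_rates,
    junction_coverage,
    intron_raw_coverage,
    mask_outliers,
    read_sj,
    reduce_intron,
    write_sj,
)


class FakeRead:
    """Minimal stand-in for a pysam AlignedSegment (synthetic)."""

    def __init__(self, start, cigartuples):
        self.reference_start = start
        self.cigartuples = cigartuples
        ref = sum(l for op, l in cigartuples if op in (0, 2, 3, 7, 8))
        self.reference_end = start + ref
        self.is_unmapped = False


def split_read(junction, offset, L=100):
    s, e = junction
    return FakeRead(s - offset, [(0, offset), (3, e - s), (0, L - offset)])


class TestJunctionCoverage:
    def test_single_read_at_offset(self):
        cov = junction_coverage([split_read((100, 400), 50)], (100, 400))
        assert cov.num_positions == 99
        assert cov.position_counts[49] == 1
        assert cov.total_reads == 1

    def test_multiple_reads_accumulate(self):
        reads = [split_read((100, 400), o) for o in (10, 10, 20)]
        cov = junction_coverage(reads, (100, 400))
        assert cov.position_counts[9] == 2
        assert cov.position_counts[19] == 1
        assert cov.total_reads == 3

    def test_other_junctions_ignored(self):
        cov = junction_coverage([split_read((100, 800), 30)], (100, 400))
        assert cov.total_reads == 0


class TestIntronCoverage:
    def test_boundary_read_counts_like_junction(self):
        # contiguous read covering the intron start at offset 40
        read = FakeRead(460, [(0, 100)])
        cov = intron_raw_coverage([read], (500, 800))
        assert cov.position_counts[39] == 1

    def test_internal_read_position_by_genomic_offset(self):
        read = FakeRead(520, [(0, 100)])  # starts 20 bp inside the intron
        cov = intron_raw_coverage([read], (500, 800), read_length=100)
        # genomic offset o = 21 (1-based from the intron start) follows the
        # 99 junction-like placements: index 98 + o
        assert cov.position_counts[98 + 21] == 1

    def test_spliced_read_excluded(self):
        cov = intron_raw_coverage([split_read((500, 800), 50)], (500, 800))
        assert cov.total_reads == 0

    def test_reduction_preserves_constant_counts(self):
        raw = EdgeCoverage(("I", "c", ".", 0, 300), np.full(399, 3.0))
        red = reduce_intron(raw, 100)
        assert red.num_positions == 99
        assert np.allclose(red.position_counts, 3.0)

    def test_reduction_mean_matches_bruteforce(self, rng):
        raw_counts = rng.poisson(2.0, size=99 + 250).astype(float)
        red = reduce_intron(EdgeCoverage(("I", "c", ".", 0, 250), raw_counts), 100)
        chunks = np.array_split(raw_counts, 99)
        assert np.allclose(red.position_counts, [c.mean() for c in chunks])
        # mean over reduced bins equals mean over raw positions
        assert math.isclose(red.position_counts.mean(), raw_counts.mean(),
                            rel_tol=0, abs_tol=1.0)

    def test_short_vector_returned_raw(self):
        raw = EdgeCoverage(("I", "c", ".", 0, 5), np.arange(50, dtype=float))
        assert reduce_intron(raw, 100).num_positions == 50


class TestMaskOutliers:
    def test_equal_counts_unmasked(self):
        cov = mask_outliers(EdgeCoverage(("J", "c", ".", 0, 1), [2, 2, 2, 2, 2]))
        assert not cov.mask.any()

    def test_spike_masked_at_poisson_tail(self):
        counts = [2.0, 2.0, 2.0, 2.0, 500.0]
        cov = mask_outliers(EdgeCoverage(("J", "c", ".", 0, 1), counts), 1e-7)
        # independent check: Poisson tail at lambda=2 for 500 is tiny
        assert stats.poisson.sf(499, 2.0) < 1e-7
        assert cov.mask[4]
        assert not cov.mask[:4].any()

    def test_zero_positions_always_masked(self):
        cov = mask_outliers(EdgeCoverage(("J", "c", ".", 0, 1), [0, 3, 0, 3]))
        assert list(cov.mask) == [True, False, True, False]

    def test_alpha_zero_masks_only_zeros(self):
        counts = [2.0, 2.0, 2.0, 2.0, 5000.0, 0.0]
        cov = mask_outliers(EdgeCoverage(("J", "c", ".", 0, 1), counts), 0.0)
        assert list(cov.mask) == [False] * 5 + [True]

    @given(st.floats(min_value=1e-12, max_value=1e-2))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_masking_antimonotone_in_alpha(self, alpha):
        counts = [1.0, 2.0, 3.0, 2.0, 40.0, 0.0]
        small = mask_outliers(EdgeCoverage(("J", "c", ".", 0, 1), counts), alpha)
        large = mask_outliers(EdgeCoverage(("J", "c", ".", 0, 1), counts),
                              min(alpha * 100, 0.5))
        assert np.all(large.mask[small.mask])


class TestBootstrap:
    def test_underdispersed_uses_poisson_branch(self):
        cov = EdgeCoverage(("J", "c", ".", 0, 1), np.full(20, 3.0))
        boot = bootstrap_rates(cov, M=10_000, seed=5)
        total = 60.0
        se = math.sqrt(total / 10_000)
        assert abs(boot.replicates.mean() - total) < 3 * se

    def test_overdispersed_resampling_preserves_mean(self, rng):
        counts = rng.negative_binomial(2, 0.2, size=30).astype(float)
        counts[counts == 0] = 1.0
        assert counts.var(ddof=1) > counts.mean()
        cov = EdgeCoverage(("J", "c", ".", 0, 1), counts)
        boot = bootstrap_rates(cov, M=10_000, seed=6)
        total = counts.sum()
        se = math.sqrt(len(counts) * counts.var() / 10_000) * math.sqrt(len(counts))
        assert abs(boot.replicates.mean() - total) < 3 * se + 1e-9

    def test_deterministic_under_seed(self):
        cov = EdgeCoverage(("J", "c", ".", 0, 1), [1.0, 5.0, 2.0, 9.0])
        a = bootstrap_rates(cov, M=1, seed=7).replicates
        b = bootstrap_rates(cov, M=1, seed=7).replicates
        assert np.array_equal(a, b)

    def test_all_masked_gives_zero_replicates(self):
        cov = EdgeCoverage(("J", "c", ".", 0, 1), [0.0, 0.0])
        cov = mask_outliers(cov)
        assert np.all(bootstrap_rates(cov, M=10, seed=1).replicates == 0)


class TestSJRoundTrip:
    def make_sj(self):
        sj = SJFile(experiment="e1", read_length=100)
        sj.records[("J", "chr1", ".", 100, 400)] = np.arange(99, dtype=float)
        sj.records[("I", "chr1", ".", 500, 800)] = np.linspace(0, 2.5, 399)
        return sj

    def test_lossless_roundtrip(self, tmp_path):
        sj = self.make_sj()
        p = tmp_path / "e1.sj"
        write_sj(sj, str(p))
        back = read_sj(str(p))
        assert back.experiment == "e1" and back.read_length == 100
        assert set(back.records) == set(sj.records)
        for k in sj.records:
            assert np.array_equal(back.records[k], sj.records[k])

    def test_truncated_file_raises(self, tmp_path):
        p = tmp_path / "e1.sj"
        write_sj(self.make_sj(), str(p))
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")  # drop the #end record
        with pytest.raises(SJFormatError, match="truncated"):
            read_sj(str(p))

    def test_version_mismatch_names_versions(self, tmp_path):
        p = tmp_path / "e1.sj"
        p.write_text("#lsvkit-sj\t99\n#end\t0\n")
        with pytest.raises(SJFormatError, match="99"):
            read_sj(str(p))
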