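"""Tile byte sizes, baseline scaling, and quantization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tilecov import (
    BaiIndex,
    CraiRecord,
    FaiTable,
    ReferenceInfo,
    compute_baseline,
    crai_tile_sizes,
    quantize_scaled,
    read_bai,
    read_bam_references,
    scale_profile,
    tile_byte_sizes,
)
from tilecov.coverage import TILE_SIZE, build_cohort_matrix, dequantize
from tilecov.fixtures import depth_oracle


def bai_from_offsets(*per_ref_offsets):
    return BaiIndex(
        linear=[np.asarray(o, dtype=np.uint64) for o in per_ref_offsets],
        counts=[None] * len(per_ref_offsets),
    )


def refs_for(*lengths, prefix="r"):
    return [ReferenceInfo(f"{prefix}{i}", ln) for i, ln in enumerate(lengths)]


class TestTileByteSizes:
    def test_identical_offsets_zero_size(self):
        idx = bai_from_offsets([100 << 16, 100 << 16])
        sizes = tile_byte_sizes(idx, refs_for(2 * TILE_SIZE))
        assert sizes["r0"][0] == 0.0

    def test_constant_compressed_step(self):
        offsets = [(i * 32768) << 16 for i in range(10)]
        sizes = tile_byte_sizes(bai_from_offsets(offsets), refs_for(10 * TILE_SIZE))
        assert np.allclose(sizes["r0"][:8], 32768.0)
        assert sizes["r0"][9] == 0.0  # last indexed tile has no successor

    def test_zero_entries_filled_forward(self):
        # tile 1 has no alignment start: its offset is 0 in the raw index
        offsets = [(10_000 << 16), 0, (20_000 << 16)]
        sizes = tile_byte_sizes(bai_from_offsets(offsets), refs_for(3 * TILE_SIZE))
        # the zero entry becomes a copy of its predecessor, so tile 0 spans
        # no bytes and the 10-kB step lands on tile 1
        assert sizes["r0"][0] == 0.0
        assert sizes["r0"][1] == pytest.approx(10_000)

    def test_negative_steps_clamped(self, caplog):
        offsets = [(20_000 << 16), (10_000 << 16), (30_000 << 16)]
        with caplog.at_level("WARNING"):
            sizes = tile_byte_sizes(bai_from_offsets(offsets), refs_for(3 * TILE_SIZE))
        assert (sizes["r0"] >= 0).all()
        assert "clamp" in caplog.text

    def test_array_length_fixed_by_reference(self):
        # linear index shorter than the tile grid: remaining tiles are 0
        sizes = tile_byte_sizes(
            bai_from_offsets([0, 1 << 16]), refs_for(10 * TILE_SIZE)
        )
        assert len(sizes["r0"]) == 10

    def test_truncated_index_all_zero(self):
        idx = bai_from_offsets([(i * 32768) << 16 for i in range(5)])
        idx.truncated = True
        sizes = tile_byte_sizes(idx, refs_for(5 * TILE_SIZE))
        assert (sizes["r0"] == 0).all()

    def test_invariant_to_prepended_empty_reference(self):
        offsets = [(i * 30_000) << 16 for i in range(6)]
        base = tile_byte_sizes(bai_from_offsets(offsets), refs_for(6 * TILE_SIZE))
        shifted = tile_byte_sizes(
            bai_from_offsets([], offsets),
            [ReferenceInfo("pre", 3 * TILE_SIZE), *refs_for(6 * TILE_SIZE)],
        )
        np.testing.assert_allclose(shifted["r0"], base["r0"])

    def test_agrees_with_per_base_depth_oracle(self, small_bam):
        """Index-derived scaled coverage tracks true per-base depth."""
        refs = read_bam_references(small_bam["path"])
        idx = read_bai(small_bam["path"] + ".bai", len(refs))
        sizes = tile_byte_sizes(idx, refs)
        prof = scale_profile(sizes, compute_baseline(sizes, refs), "s1")
        oracle = depth_oracle(small_bam["path"], refs)
        est = np.concatenate([prof[r.name] for r in refs])
        tru = np.concatenate([oracle[r.name] for r in refs])
        m = (est > 0) & (tru > 0)
        r = np.corrcoef(est[m], tru[m])[0, 1]
        assert r > 0.9
        # and the simulated hemizygous segment shows up at ~0.5
        lo, hi = 500_000 // TILE_SIZE + 1, 800_000 // TILE_SIZE - 1
        assert 0.35 < prof["chr1"][lo:hi].mean() < 0.65


class TestCraiTileSizes:
    fai = FaiTable(entries=(("c0", 10 * TILE_SIZE),))

    def test_full_containment(self):
        rec = CraiRecord(0, 3 * TILE_SIZE + 1, TILE_SIZE, 0, 0, 7000)
        sizes = crai_tile_sizes([rec], self.fai)
        assert sizes["c0"][3] == 7000
        assert sizes["c0"].sum() == 7000

    def test_even_split_across_two_tiles(self):
        rec = CraiRecord(0, TILE_SIZE // 2 + 1, TILE_SIZE, 0, 0, 8000)
        sizes = crai_tile_sizes([rec], self.fai)
        assert sizes["c0"][0] == pytest.approx(4000)
        assert sizes["c0"][1] == pytest.approx(4000)

    def test_matches_per_base_accumulation_oracle(self):
        rng = np.random.default_rng(5)
        length = 10 * TILE_SIZE
        records = []
        for _ in range(200):
            start = int(rng.integers(0, length - 1))
            span = int(rng.integers(1, 3 * TILE_SIZE))
            span = min(span, length - start)
            records.append(CraiRecord(0, start + 1, span, 0, 0, int(rng.integers(1, 20_000))))
        sizes = crai_tile_sizes(records, self.fai)
        # brute force: spread size/span bytes over every covered base
        per_base = np.zeros(length)
        for r in records:
            s = r.start - 1
            per_base[s : s + r.span] += r.slice_size / r.span
        oracle = per_base.reshape(10, TILE_SIZE).sum(axis=1)
        np.testing.assert_allclose(sizes["c0"], oracle, rtol=1e-9)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=10 * TILE_SIZE - 1),
                st.integers(min_value=1, max_value=4 * TILE_SIZE),
                st.integers(min_value=0, max_value=10**6),
            ),
            max_size=30,
        )
    )
    def test_bytes_conserved(self, raw):
        records = [
            CraiRecord(0, s + 1, min(sp, 10 * TILE_SIZE - s), 0, 0, sz) for s, sp, sz in raw
        ]
        sizes = crai_tile_sizes(records, self.fai)
        total = sum(r.slice_size for r in records)
        assert sizes["c0"].sum() == pytest.approx(total, rel=1e-6, abs=1e-6)

    def test_seq_id_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            crai_tile_sizes([CraiRecord(5, 1, 100, 0, 0, 10)], self.fai)


class TestBaselineAndScaling:
    def test_constant_median(self):
        from tilecov.coverage import TileSizes

        sizes = TileSizes(by_ref={"chr1": np.full(20, 32768.0)})
        assert compute_baseline(sizes, [ReferenceInfo("chr1", 20 * TILE_SIZE)]) == 32768

    def test_median_of_mixed_sizes(self):
        from tilecov.coverage import TileSizes

        vals = np.array([16384.0] * 10 + [32768.0] * 11)
        sizes = TileSizes(by_ref={"chr1": vals})
        assert compute_baseline(sizes, [ReferenceInfo("chr1", len(vals) * TILE_SIZE)]) == 32768

    def test_zero_tiles_excluded_from_median(self):
        from tilecov.coverage import TileSizes

        vals = np.array([0.0] * 50 + [1000.0] * 5)
        sizes = TileSizes(by_ref={"chr1": vals})
        assert compute_baseline(sizes, [ReferenceInfo("chr1", len(vals) * TILE_SIZE)]) == 1000

    def test_sex_and_excluded_refs_skipped(self):
        from tilecov.coverage import TileSizes

        sizes = TileSizes(
            by_ref={
                "chr1": np.full(5, 100.0),
                "chrX": np.full(5, 999.0),
                "chr1_random": np.full(5, 999.0),
            }
        )
        refs = [
            ReferenceInfo("chr1", 5 * TILE_SIZE),
            ReferenceInfo("chrX", 5 * TILE_SIZE),
            ReferenceInfo("chr1_random", 5 * TILE_SIZE, excluded=True),
        ]
        assert compute_baseline(sizes, refs, ("X", "Y")) == 100

    def test_all_zero_flagged(self):
        from tilecov.coverage import TileSizes

        sizes = TileSizes(by_ref={"chr1": np.zeros(10)})
        baseline = compute_baseline(sizes, [ReferenceInfo("chr1", 10 * TILE_SIZE)])
        assert baseline == 0
        prof = scale_profile(sizes, baseline, "s", truncated=True)
        assert prof.flagged
        assert (prof["chr1"] == 0).all()

    @pytest.mark.parametrize("size, expected", [(1.0, 1.0), (0.5, 0.5), (0.0, 0.0)])
    def test_scaling_definition(self, size, expected):
        from tilecov.coverage import TileSizes

        sizes = TileSizes(by_ref={"c": np.array([size, 1.0])})
        prof = scale_profile(sizes, 1.0, "s")
        assert prof["c"][0] == expected

    def test_median_of_scaled_baseline_tiles_is_one(self, small_bam):
        refs = read_bam_references(small_bam["path"])
        idx = read_bai(small_bam["path"] + ".bai", len(refs))
        sizes = tile_byte_sizes(idx, refs)
        baseline = compute_baseline(sizes, refs, ("X", "Y"))
        prof = scale_profile(sizes, baseline, "s1")
        vals = prof["chr1"]  # chrX is a sex chromosome, not baseline-defining
        assert np.median(vals[vals > 0]) == pytest.approx(1.0)


class TestQuantization:
    @pytest.mark.parametrize("value, code", [(0.0, 0), (1.0, 64), (10.0, 255)])
    def test_examples(self, value, code):
        assert quantize_scaled(value) == code

    @given(st.floats(min_value=0, max_value=3.9))
    def test_roundtrip_error_bounded(self, v):
        assert abs(dequantize(np.array(quantize_scaled(v))) - v) <= 1 / 128 + 1e-12

    def test_matrix_layout(self):
        from tilecov.coverage import CoverageProfile

        refs = [ReferenceInfo("chr1", TILE_SIZE + 5), ReferenceInfo("chrX", TILE_SIZE)]
        profs = [
            CoverageProfile("a", {"chr1": np.array([1.0, 0.5]), "chrX": np.array([1.0])}, 1.0),
            CoverageProfile("b", {"chr1": np.array([2.0, 1.0]), "chrX": np.array([0.0])}, 1.0),
        ]
        cm = build_cohort_matrix(profs, refs, ("X", "Y"))
        assert cm.matrix.shape == (2, 2)  # chrX left out of the PCA matrix
        assert cm.matrix.dtype == np.uint8
        assert list(cm.tiles["chrom"]) == ["chr1", "chr1"]
        assert list(cm.tiles["end"]) == [TILE_SIZE, TILE_SIZE + 5]
        np.testing.assert_array_equal(cm.matrix[:, 0], [64, 128])
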