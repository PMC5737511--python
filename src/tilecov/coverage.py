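"""From index structures to median-scaled relative coverage.

The estimator never looks at alignment records.  For BAM, consecutive
linear-index virtual offsets bound the compressed bytes spent on each
16 384-bp tile; because alignment records are of roughly constant
compressed size within a sample, bytes per tile is proportional to reads
per tile and hence to depth.  For CRAM, each CRAI slice's byte size is
spread over the tiles its genomic span overlaps.

Per-tile byte masses are then divided by the genome-wide median of
nonzero tiles over non-excluded autosomes, so that 1.0 corresponds to the
sample's baseline (diploid) depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .index_io import BaiIndex, CraiRecord, FaiTable, ReferenceInfo

log = logging.getLogger(__name__)

#: Width in bases of one linear-index interval (BAI tile).
TILE_SIZE = 16384

#: Scaled-coverage units per quantization step: codes are round(64 * value),
#: so one byte spans [0, ~3.98] at 1/64 resolution.
QUANT_SCALE = 64


def n_tiles(ref_length: int) -> int:
    return math.ceil(ref_length / TILE_SIZE)


def _norm_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def is_sex_chrom(name: str, sex_chrom_names: tuple[str, ...]) -> bool:
    """Match a reference against the configured sex chromosomes, tolerating
    a 'chr' prefix on either side."""
    norm = _norm_chrom(name).lower()
    return any(norm == _norm_chrom(s).lower() for s in sex_chrom_names)


@dataclass
class TileSizes:
    """Estimated compressed bytes per 16 384-bp tile, per reference.

    Array lengths are fixed by the reference length (ceil(len/TILE_SIZE)),
    never by how far the index happened to reach.
    """

    by_ref: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.by_ref[name]


@dataclass
class CoverageProfile:
    """Per-reference median-scaled relative coverage for one sample."""

    sample_id: str
    by_ref: dict[str, np.ndarray] = field(default_factory=dict)
    baseline: float = 0.0
    truncated: bool = False

    @property
    def flagged(self) -> bool:
        """True when no usable coverage signal exists (zero baseline)."""
        return self.truncated or self.baseline <= 0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.by_ref[name]


@dataclass
class CohortMatrix:
    """samples x tiles matrix of 1-byte quantized scaled coverage.

    ``tiles`` gives each column's genomic coordinates (chrom, start, end;
    0-based half-open).  Column order follows reference order, then tile
    order within each reference.
    """

    matrix: np.ndarray  # uint8, shape (n_samples, n_tiles)
    tiles: pd.DataFrame
    sample_ids: list[str]


def _positive_steps(index: BaiIndex) -> np.ndarray:
    steps = []
    for raw in index.linear:
        if len(raw) < 2:
            continue
        raw = _fill_forward(np.asarray(raw, dtype=np.uint64))
        dc = np.diff((raw >> np.uint64(16)).astype(np.float64))
        steps.append(dc[dc > 0])
    return np.concatenate(steps) if steps else np.empty(0)


def _sampled_block_sizes(bam_path: str, index: BaiIndex, max_samples: int = 300) -> np.ndarray:
    """Exact compressed sizes of BGZF blocks whose starts appear in the
    linear index, read from each block's 18-byte container header.

    Only container headers are touched — never alignment records — so the
    cost is a few hundred tiny reads regardless of BAM size.
    """
    coffs = sorted(
        {
            int(c)
            for raw in index.linear
            for c in (np.asarray(raw, dtype=np.uint64) >> np.uint64(16)).tolist()
            if c > 0
        }
    )
    if not coffs:
        return np.empty(0)
    stride = max(1, len(coffs) // max_samples)
    sizes = []
    with open(bam_path, "rb") as fh:
        for c in coffs[::stride]:
            fh.seek(c)
            hdr = fh.read(18)
            # standard BGZF header: gzip magic, FEXTRA with the 6-byte
            # 'BC' subfield carrying (total block size - 1)
            if (
                len(hdr) == 18
                and hdr[:2] == b"\x1f\x8b"
                and hdr[10:12] == b"\x06\x00"
                and hdr[12:14] == b"BC"
            ):
                sizes.append(int.from_bytes(hdr[16:18], "little") + 1)
    return np.asarray(sizes, dtype=np.float64)


def _block_size_by_periodicity(steps: np.ndarray) -> float:
    """Infer the compressed block size from the linear index alone.

    Positive compressed-offset steps are integer multiples of the block
    size (plus jitter from block-to-block compression variation), so the
    true size maximizes their phase coherence; among near-maximal
    candidates the largest is taken, since any divisor of the block size
    scores equally well.
    """
    if steps.size == 0:
        return 65536.0
    cands = np.exp(np.linspace(np.log(512.0), np.log(65536.0), 500))
    phases = 2 * np.pi * steps[None, :] / cands[:, None]
    scores = np.cos(phases).mean(axis=1)
    best = scores.max()
    return float(cands[np.flatnonzero(scores >= best - 0.02)[-1]])


def estimate_block_size(index: BaiIndex, bam_path: str | None = None) -> float:
    """Mean compressed BGZF block size for one sample.

    When the BAM file is available its block headers are sampled for
    exact sizes; otherwise the size is inferred from the periodic
    structure of the index's compressed-offset steps.  Either way the
    estimate is refined so that block counts reproduce the observed
    steps on average.
    """
    steps = _positive_steps(index)
    b = 0.0
    if bam_path is not None:
        try:
            sizes = _sampled_block_sizes(bam_path, index)
        except OSError:
            sizes = np.empty(0)
        if sizes.size:
            b = float(sizes.mean())
    if b <= 0:
        b = _block_size_by_periodicity(steps)
    if steps.size:
        k = np.maximum(1, np.rint(steps / b))
        b = float(steps.sum() / k.sum())
    return b


def tile_byte_sizes(
    index: BaiIndex, refs: list[ReferenceInfo], bam_path: str | None = None
) -> TileSizes:
    """Turn a BAI linear index into per-tile compressed byte estimates.

    Linear-index entries of zero after the first populated one mean "no
    alignment starts here" and are filled forward so differences stay
    meaningful.  The bytes charged to tile *i* come from the step between
    its virtual offset and the next one: the compressed-offset difference
    is resolved into a whole number of BGZF blocks (using the block size
    estimated from the index itself) and the within-block offsets add the
    sub-block remainder, converted from uncompressed to compressed units
    by the block-level compression ratio.  This keeps tile estimates
    accurate well below one compressed block, which a raw
    ``coffset + uoffset/65536`` file-position difference cannot do.  The
    last indexed tile (no successor offset) and tiles beyond the linear
    index get size 0; negative steps (corrupt index) clamp to 0 with a
    warning.

    A truncated index yields all-zero sizes so the sample surfaces in QC
    near the origin of the sex plot rather than crashing the run.
    """
    out = TileSizes()
    block = estimate_block_size(index, bam_path) if not index.truncated else 65536.0
    ratio = block / 65536.0  # compressed bytes per uncompressed byte
    for i, ref in enumerate(refs):
        nt = n_tiles(ref.length)
        sizes = np.zeros(nt, dtype=np.float64)
        out.by_ref[ref.name] = sizes
        if index.truncated:
            continue
        raw = index.linear[i] if i < len(index.linear) else np.empty(0, dtype="<u8")
        if len(raw) < 2:
            continue
        raw = _fill_forward(np.asarray(raw, dtype=np.uint64))
        dc = np.diff((raw >> np.uint64(16)).astype(np.float64))
        du = np.diff((raw & np.uint64(0xFFFF)).astype(np.float64))
        if (dc < 0).any():
            log.warning(
                "%s: %d negative linear-index steps clamped to 0 (corrupt index?)",
                ref.name,
                int((dc < 0).sum()),
            )
        k = np.where(dc > 0, np.maximum(1.0, np.rint(dc / block)), 0.0)
        est = k * block + du * ratio
        neg = est < 0
        if (neg & (dc >= 0)).any() and not (dc < 0).any():
            log.warning(
                "%s: %d negative tile byte estimates clamped to 0",
                ref.name,
                int(neg.sum()),
            )
        est[neg | (dc < 0)] = 0.0
        m = min(len(est), nt)
        sizes[:m] = est[:m]
    return out


def _fill_forward(raw: np.ndarray) -> np.ndarray:
    """Replace zero entries after the first nonzero entry with the previous
    entry (a zero there means "nothing starts in this tile")."""
    nz = np.flatnonzero(raw)
    if len(nz) == 0:
        return raw
    first = nz[0]
    seg = raw[first:]
    idx = np.arange(len(seg))
    last_valid = np.maximum.accumulate(np.where(seg != 0, idx, 0))
    filled = raw.copy()
    filled[first:] = seg[last_valid]
    return filled


def crai_tile_sizes(records: list[CraiRecord], fai: FaiTable) -> TileSizes:
    """Distribute CRAI slice byte sizes onto the fixed 16 384-bp tile grid.

    CRAM slices have sample-specific genomic spans, so each slice's bytes
    are apportioned to the tiles it overlaps in proportion to overlap
    length; total bytes are conserved.
    """
    out = TileSizes()
    for name, length in fai.entries:
        out.by_ref[name] = np.zeros(n_tiles(length), dtype=np.float64)
    for rec in records:
        if rec.seq_id < 0 or rec.seq_id >= len(fai):
            raise ValueError(
                f"CRAI seq_id {rec.seq_id} outside FAI range (0..{len(fai) - 1})"
            )
        name, length = fai[rec.seq_id]
        arr = out.by_ref[name]
        start = rec.start - 1  # CRAI stores 1-based starts
        if rec.span <= 0:
            t = min(start // TILE_SIZE, len(arr) - 1)
            arr[t] += rec.slice_size
            continue
        end = start + rec.span
        t0 = start // TILE_SIZE
        t1 = min((end - 1) // TILE_SIZE, len(arr) - 1)
        per_base = rec.slice_size / rec.span
        for t in range(t0, t1 + 1):
            ov = min(end, (t + 1) * TILE_SIZE) - max(start, t * TILE_SIZE)
            arr[t] += per_base * ov
    return out


def compute_baseline(
    sizes: TileSizes,
    refs: list[ReferenceInfo],
    sex_chrom_names: tuple[str, ...] = ("X", "Y"),
) -> float:
    """Median byte size of nonzero tiles over non-excluded autosomes.

    Sex chromosomes are left out so the baseline reflects the diploid
    autosomal state regardless of karyotype; zero tiles are left out so
    N-masked gaps (centromeres, acrocentric arms) do not drag the median
    down.  Returns 0.0 when no tile qualifies (e.g. truncated index) —
    the caller flags the sample.
    """
    vals: list[np.ndarray] = []
    for ref in refs:
        if ref.excluded or is_sex_chrom(ref.name, sex_chrom_names):
            continue
        arr = sizes.by_ref.get(ref.name)
        if arr is not None:
            vals.append(arr[arr > 0])
    if not vals:
        return 0.0
    allvals = np.concatenate(vals)
    if len(allvals) == 0:
        return 0.0
    return float(np.median(allvals))


def scale_profile(
    sizes: TileSizes,
    baseline: float,
    sample_id: str = "",
    truncated: bool = False,
) -> CoverageProfile:
    """Divide tile byte sizes by the baseline; 1.0 = baseline depth.

    With a zero baseline (flagged sample) every value is 0.  No clipping
    is applied: large amplifications stay visible.
    """
    prof = CoverageProfile(sample_id=sample_id, baseline=baseline, truncated=truncated)
    for name, arr in sizes.by_ref.items():
        if baseline > 0:
            prof.by_ref[name] = arr / baseline
        else:
            prof.by_ref[name] = np.zeros_like(arr)
    return prof


def quantize_scaled(value):
    """Quantize scaled coverage to one byte: round(64*v), clamped to 255.

    Resolution is 1/64 of the baseline; saturation at 255/64 ≈ 3.98 covers
    copy numbers up to ~8, beyond which precision is irrelevant for QC.
    """
    codes = np.clip(np.rint(np.asarray(value, dtype=np.float64) * QUANT_SCALE), 0, 255)
    out = codes.astype(np.uint8)
    return out if out.ndim else int(out)


def dequantize(codes: np.ndarray) -> np.ndarray:
    return np.asarray(codes, dtype=np.float64) / QUANT_SCALE


def build_cohort_matrix(
    profiles: list[CoverageProfile],
    refs: list[ReferenceInfo],
    sex_chrom_names: tuple[str, ...] = ("X", "Y"),
    include_sex: bool = False,
) -> CohortMatrix:
    """Stack quantized scaled profiles into the samples x tiles matrix.

    By default only non-excluded autosomes enter: sex-chromosome columns
    would let karyotype dominate the principal components and mask batch
    structure.
    """
    chroms: list[str] = []
    starts: list[int] = []
    use = [
        r
        for r in refs
        if not r.excluded and (include_sex or not is_sex_chrom(r.name, sex_chrom_names))
    ]
    blocks = []
    for ref in use:
        nt = n_tiles(ref.length)
        chroms.extend([ref.name] * nt)
        starts.extend(range(0, nt * TILE_SIZE, TILE_SIZE))
        blocks.append(
            np.stack([quantize_scaled(p.by_ref[ref.name]) for p in profiles], axis=0)
        )
    if blocks:
        matrix = np.concatenate(blocks, axis=1)
    else:
        matrix = np.zeros((len(profiles), 0), dtype=np.uint8)
    start_arr = np.asarray(starts, dtype=np.int64)
    lengths = {r.name: r.length for r in use}
    end_arr = np.minimum(
        start_arr + TILE_SIZE,
        np.asarray([lengths[c] for c in chroms], dtype=np.int64) if chroms else start_arr,
    )
    tiles = pd.DataFrame({"chrom": chroms, "start": start_arr, "end": end_arr})
    return CohortMatrix(matrix=matrix, tiles=tiles, sample_ids=[p.sample_id for p in profiles])
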