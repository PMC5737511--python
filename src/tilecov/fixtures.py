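"""Synthetic sequencing data for testing every stage without downloads.

``make_synthetic_bam`` simulates a coordinate-sorted BAM: fixed-length
reads placed as a Poisson process along each reference, with per-segment
depth multipliers (deletions, duplications, sex-chromosome dosage).  The
SAM text is streamed through ``samtools view``/``samtools index`` so the
resulting BAI is produced by the standard indexer, exercising real index
dialects rather than a bespoke writer.

``depth_oracle`` computes exact per-base depth from the alignment
records — the independent ground truth the index-based estimator is
judged against.
"""

from __future__ import annotations

import gzip
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pysam

from .coverage import TILE_SIZE, n_tiles
from .index_io import CraiRecord, FaiTable, ReferenceInfo

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHUNK = 200_000


@dataclass(frozen=True)
class Segment:
    """Half-open interval [start, end) with a depth multiplier relative to
    the genome-wide base depth (0 = deletion, 0.5 = hemizygous, 2 = dup)."""

    start: int
    end: int
    multiplier: float


@dataclass
class GenomeSpec:
    """Recipe for one synthetic sample.

    ``depth`` is the expected per-base depth (x coverage) where the
    multiplier is 1.  Reads are ``read_length`` bases, placed uniformly
    (Poisson counts per constant-rate interval), so per-tile read counts
    have relative sampling error ~1/sqrt(depth*TILE/read_length).
    """

    references: list[tuple[str, int]]
    segments: dict[str, list[Segment]] = field(default_factory=dict)
    depth: float = 10.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.references)
        for name, segs in self.segments.items():
            for seg in segs:
                if not (0 <= seg.start < seg.end <= lengths[name]):
                    raise ValueError(f"segment {seg} outside {name}:{lengths[name]}")
                if seg.multiplier < 0:
                    raise ValueError("multiplier must be >= 0")


def _intervals(length: int, segs: list[Segment]) -> list[tuple[int, int, float]]:
    """Partition [0, length) into constant-multiplier intervals."""
    cuts = sorted({0, length, *(s.start for s in segs), *(s.end for s in segs)})
    out = []
    for a, b in zip(cuts, cuts[1:]):
        mult = 1.0
        for s in segs:
            if s.start <= a and b <= s.end:
                mult = s.multiplier
        out.append((a, b, mult))
    return out


def make_synthetic_bam(spec: GenomeSpec, path: str, sample_name: str | None = None) -> int:
    """Write a coordinate-sorted, BAI-indexed BAM; returns the record count.

    Reads carry random sequence (so per-record compressed size is stable),
    constant quality, a single full-match CIGAR, and a read group whose SM
    tag is *sample_name* (default: the file stem).  Deterministic for a
    fixed spec: the RNG is seeded and samtools is invoked with --no-PG.
    """
    path = str(path)
    if sample_name is None:
        sample_name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    hdr_lines = ["@HD\tVN:1.6\tSO:coordinate"]
    hdr_lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in spec.references]
    hdr_lines.append(f"@RG\tID:{sample_name}\tSM:{sample_name}")
    qual = "I" * L
    total = 0
    proc = subprocess.Popen(
        ["samtools", "view", "-b", "-1", "--no-PG", "-o", path, "-"],
        stdin=subprocess.PIPE,
    )
    assert proc.stdin is not None
    proc.stdin.write(("\n".join(hdr_lines) + "\n").encode())
    for name, length in spec.references:
        starts = _poisson_starts(rng, length, spec, name)
        for off in range(0, len(starts), _CHUNK):
            chunk = starts[off : off + _CHUNK]
            seqs = _BASES[rng.integers(0, 4, size=(len(chunk), L), dtype=np.uint8)]
            seqs = seqs.view(f"S{L}").ravel()
            lines = [
                f"r{name}.{total + i}\t0\t{name}\t{p + 1}\t60\t{L}M\t*\t0\t0\t"
                f"{seqs[i].decode()}\t{qual}\tRG:Z:{sample_name}"
                for i, p in enumerate(chunk)
            ]
            proc.stdin.write(("\n".join(lines) + "\n").encode())
            total += len(chunk)
    proc.stdin.close()
    if proc.wait() != 0:
        raise RuntimeError("samtools view failed while writing synthetic BAM")
    subprocess.run(["samtools", "index", path], check=True)
    return total


def _poisson_starts(
    rng: np.random.Generator, length: int, spec: GenomeSpec, name: str
) -> np.ndarray:
    rate = spec.depth / spec.read_length  # read starts per base at multiplier 1
    segs = spec.segments.get(name, [])
    parts = []
    for a, b, mult in _intervals(length, segs):
        hi = min(b, length - spec.read_length)
        if hi <= a or mult == 0:
            continue
        n = rng.poisson(rate * mult * (hi - a))
        parts.append(rng.integers(a, hi, size=n, dtype=np.int64))
    starts = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    starts.sort()
    return starts


def expected_read_count(spec: GenomeSpec) -> float:
    """Closed-form Poisson mean of the total record count for a spec."""
    rate = spec.depth / spec.read_length
    mean = 0.0
    for name, length in spec.references:
        for a, b, mult in _intervals(length, spec.segments.get(name, [])):
            hi = min(b, length - spec.read_length)
            if hi > a:
                mean += rate * mult * (hi - a)
    return mean


def depth_oracle(
    bam_path: str, refs: list[ReferenceInfo], scale: bool = True
) -> dict[str, np.ndarray]:
    """Exact per-base depth from alignment records, averaged per tile.

    Accumulates coverage of every aligned block via a difference array,
    means it within each 16 384-bp tile, and (by default) divides by the
    genome-wide median of nonzero tile means — mirroring how empirical
    per-base depth is normalized when validating the index-based proxy.
    """
    out: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for ref in refs:
            diff = np.zeros(ref.length + 1, dtype=np.int64)
            for read in bam.fetch(ref.name):
                for bstart, bend in read.get_blocks():
                    diff[bstart] += 1
                    diff[min(bend, ref.length)] -= 1
            depth = np.cumsum(diff[:-1])
            nt = n_tiles(ref.length)
            padded = np.zeros(nt * TILE_SIZE, dtype=np.float64)
            padded[: ref.length] = depth
            sums = padded.reshape(nt, TILE_SIZE).sum(axis=1)
            widths = np.full(nt, TILE_SIZE, dtype=np.float64)
            if ref.length % TILE_SIZE:
                widths[-1] = ref.length % TILE_SIZE
            out[ref.name] = sums / widths
    if scale:
        allvals = np.concatenate([v[v > 0] for v in out.values()]) if out else np.empty(0)
        med = float(np.median(allvals)) if allvals.size else 0.0
        if med > 0:
            out = {k: v / med for k, v in out.items()}
    return out


def make_truncated_index(bai_path: str, out_path: str, fraction: float) -> str:
    """Byte-truncate a copy of an index file to the given fraction."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    with open(bai_path, "rb") as fh:
        data = fh.read()
    keep = max(1, int(len(data) * fraction))
    with open(out_path, "wb") as fh:
        fh.write(data[:keep])
    return str(out_path)


def write_fai(entries: list[tuple[str, int]], path: str) -> FaiTable:
    """Write a minimal FASTA index (name, length + placeholder columns)."""
    with open(path, "w") as fh:
        for name, length in entries:
            line_bases = 60
            fh.write(f"{name}\t{length}\t{len(name) + 2}\t{line_bases}\t{line_bases + 1}\n")
    return FaiTable(entries=tuple(entries))


def write_crai(records: list[CraiRecord], path: str) -> None:
    """Write CRAI records as gzip-compressed tab-separated text."""
    with gzip.open(path, "wt") as fh:
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.start}\t{r.span}\t{r.container_offset}\t"
                f"{r.slice_offset}\t{r.slice_size}\n"
            )


def make_synthetic_crai(
    spec: GenomeSpec,
    path: str,
    slice_span: int = 8192,
    bytes_per_read: float = 80.0,
) -> list[CraiRecord]:
    """Synthesize a CRAI whose slice byte sizes follow a GenomeSpec.

    Slices tile each reference in fixed genomic spans; each slice's byte
    size is Poisson in the expected read count of its span times
    *bytes_per_read*.  CRAM containers themselves are never written — the
    index alone drives the estimator.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.depth / spec.read_length
    records: list[CraiRecord] = []
    offset = 0
    for seq_id, (name, length) in enumerate(spec.references):
        segs = spec.segments.get(name, [])
        for s0 in range(0, length, slice_span):
            s1 = min(s0 + slice_span, length)
            mean_reads = 0.0
            for a, b, mult in _intervals(length, segs):
                ov = min(b, s1) - max(a, s0)
                if ov > 0:
                    mean_reads += rate * mult * ov
            size = int(rng.poisson(mean_reads) * bytes_per_read)
            if size > 0:
                records.append(CraiRecord(seq_id, s0 + 1, s1 - s0, offset, 0, size))
                offset += size
    write_crai(records, path)
    return records


def make_batch_matrix(
    n_per_batch: tuple[int, int] = (10, 10),
    n_columns: int = 500,
    bias_sd: float = 0.0707,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Quantized cohort matrix with one well-behaved and one biased batch.

    Emulates a library-preparation batch effect: samples in the second
    batch share a fixed per-tile bias pattern (as PCR amplification shares
    GC-correlated depth distortions across samples) on top of independent
    noise.  With bias_sd ~= noise_sd * sqrt(2) the biased batch has ~3x
    the per-sample tile-level variance of the clean batch.

    Returns (CohortMatrix, labels) where labels is 0/1 per sample.
    """
    from .coverage import CohortMatrix, quantize_scaled
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_batch
    bias = rng.normal(0.0, bias_sd, size=n_columns)
    rows = [1.0 + rng.normal(0.0, noise_sd, size=n_columns) for _ in range(n_a)]
    rows += [1.0 + bias + rng.normal(0.0, noise_sd, size=n_columns) for _ in range(n_b)]
    matrix = np.stack([quantize_scaled(r) for r in rows])
    tiles = pd.DataFrame(
        {
            "chrom": ["chrS"] * n_columns,
            "start": np.arange(n_columns) * TILE_SIZE,
            "end": (np.arange(n_columns) + 1) * TILE_SIZE,
        }
    )
    ids = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    labels = np.array([0] * n_a + [1] * n_b)
    return CohortMatrix(matrix=matrix, tiles=tiles, sample_ids=ids), labels
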