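"""Readers for BAM-adjacent index formats: BAI, CRAI, FAI, and BAM headers.

The BAI linear index is the raw material for index-derived coverage: for
each consecutive 16 384-bp tile of a reference it stores the BGZF virtual
offset of the first alignment starting in that tile.  Nothing here decodes
alignment records; only index structures and the BAM header are read.

Truncated BAI files (e.g. from an interrupted copy) are not fatal: the
index is returned with ``truncated=True`` so that downstream QC can flag
the sample instead of dropping it.
"""

from __future__ import annotations

import gzip
import logging
import re
import struct
from dataclasses import dataclass, field

import numpy as np
import pysam

log = logging.getLogger(__name__)

BAI_MAGIC = b"BAI\x01"

#: Special BAI bin carrying per-reference mapped/unmapped record counts.
PSEUDO_BIN = 37450

#: Decoy/alt/unplaced contigs that would distort the genome-wide median.
DEFAULT_EXCLUDE_PATTERN = (
    r"_random$|_alt$|^chrUn|^GL|^NC_|^hs37d5$|^HLA-|hap\d+$|^chrEBV$"
)


class FatalInputError(Exception):
    """An input file is unreadable or structurally invalid."""


@dataclass(frozen=True)
class VirtualOffset:
    """A 64-bit BGZF file pointer.

    The upper 48 bits address the start of a compressed BGZF block in the
    file (``coffset``); the lower 16 bits are the byte offset within the
    uncompressed content of that block (``uoffset``).
    """

    raw: int
    coffset: int
    uoffset: int

    def __post_init__(self) -> None:
        assert self.raw == self.coffset * 65536 + self.uoffset


def split_virtual_offset(raw: int) -> VirtualOffset:
    """Split a raw 64-bit virtual offset into its block/within-block parts."""
    if not 0 <= raw < 1 << 64:
        raise ValueError(f"virtual offset out of 64-bit range: {raw}")
    return VirtualOffset(raw=raw, coffset=raw >> 16, uoffset=raw & 0xFFFF)


@dataclass(frozen=True)
class ReferenceInfo:
    """One reference sequence: name, length in bases, and whether it is
    excluded from genome-wide statistics by the contig-exclusion pattern."""

    name: str
    length: int
    excluded: bool = False


@dataclass
class BaiIndex:
    """Parsed contents of a .bai file.

    ``linear`` holds, per reference, the raw virtual offsets of the linear
    index (one per 16 384-bp interval the indexer emitted).  ``counts``
    holds per-reference (mapped, unmapped) record counts when the metadata
    pseudo-bin was present, else ``None``.
    """

    linear: list[np.ndarray] = field(default_factory=list)
    counts: list[tuple[int, int] | None] = field(default_factory=list)
    truncated: bool = False
    n_no_coor: int | None = None


@dataclass(frozen=True)
class CraiRecord:
    """One CRAI line: a CRAM slice's genomic span and its size in bytes."""

    seq_id: int
    start: int  # 1-based, as stored in the file
    span: int
    container_offset: int
    slice_offset: int
    slice_size: int


@dataclass(frozen=True)
class FaiTable:
    """Ordered (name, length) pairs from a FASTA index.

    The order defines the ``seq_id`` mapping used by CRAI records.
    """

    entries: tuple[tuple[str, int], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> tuple[str, int]:
        return self.entries[i]

    def references(self, exclude_pattern: str = DEFAULT_EXCLUDE_PATTERN) -> list[ReferenceInfo]:
        pat = re.compile(exclude_pattern) if exclude_pattern else None
        return [
            ReferenceInfo(name, length, excluded=bool(pat.search(name)) if pat else False)
            for name, length in self.entries
        ]


def read_bam_references(
    bam_path: str, exclude_pattern: str = DEFAULT_EXCLUDE_PATTERN
) -> list[ReferenceInfo]:
    """Read reference names/lengths from a BAM header, in header order.

    Only the header is decoded; no alignment records are touched.  Contigs
    matching *exclude_pattern* are marked ``excluded`` (they still occupy
    their slot so BAI reference ordinals line up).
    """
    try:
        with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
            names = bam.references
            lengths = bam.lengths
    except (OSError, ValueError) as exc:
        raise FatalInputError(f"cannot read BAM header from {bam_path}: {exc}") from exc
    pat = re.compile(exclude_pattern) if exclude_pattern else None
    refs = [
        ReferenceInfo(name, length, excluded=bool(pat.search(name)) if pat else False)
        for name, length in zip(names, lengths)
    ]
    if not refs:
        log.warning("%s: BAM header declares no reference sequences", bam_path)
    return refs


def read_bam_sample_name(bam_path: str) -> str | None:
    """Return the sample (SM) tag shared by all read groups, if unique."""
    with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
        rgs = bam.header.to_dict().get("RG", [])
    sms = {rg["SM"] for rg in rgs if "SM" in rg}
    return sms.pop() if len(sms) == 1 else None


class _Cursor:
    """Byte cursor over an in-memory buffer; raises on premature end."""

    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise EOFError
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def skip(self, n: int) -> None:
        if self.pos + n > len(self.data):
            raise EOFError
        self.pos += n

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]

    def i32(self) -> int:
        return struct.unpack("<i", self.take(4))[0]

    def u64(self) -> int:
        return struct.unpack("<Q", self.take(8))[0]


def read_bai(bai_path: str, n_expected_refs: int) -> BaiIndex:
    """Parse a .bai file, keeping only linear indexes and record counts.

    Distinguishable bins are skipped by seeking; the metadata pseudo-bin
    (37450) is captured for its mapped/unmapped counts.  If the stream ends
    before *n_expected_refs* references are fully read, the index is
    returned with ``truncated=True`` and empty linear indexes padded in —
    a broken index must surface in QC output, not abort the run.
    """
    try:
        with open(bai_path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise FatalInputError(f"cannot read index {bai_path}: {exc}") from exc
    if data[:4] != BAI_MAGIC:
        raise FatalInputError(f"{bai_path}: not a BAI file (bad magic)")

    cur = _Cursor(data)
    cur.skip(4)
    idx = BaiIndex()
    try:
        n_ref = cur.i32()
    except EOFError:
        idx.truncated = True
        n_ref = 0

    for _ in range(n_ref):
        try:
            counts: tuple[int, int] | None = None
            n_bin = cur.i32()
            for _ in range(n_bin):
                bin_no = cur.u32()
                n_chunk = cur.i32()
                if bin_no == PSEUDO_BIN and n_chunk == 2:
                    cur.u64()  # unmapped-region begin voffset
                    cur.u64()  # unmapped-region end voffset
                    counts = (cur.u64(), cur.u64())
                else:
                    cur.skip(16 * n_chunk)
            n_intv = cur.i32()
            linear = np.frombuffer(cur.take(8 * n_intv), dtype="<u8")
        except EOFError:
            idx.truncated = True
            break
        idx.linear.append(linear)
        idx.counts.append(counts)

    if cur.pos + 8 <= len(data):
        idx.n_no_coor = struct.unpack("<Q", data[cur.pos : cur.pos + 8])[0]

    if n_ref != n_expected_refs:
        log.warning(
            "%s: index declares %d references, expected %d", bai_path, n_ref, n_expected_refs
        )
        if n_ref < n_expected_refs:
            idx.truncated = True
    if idx.truncated:
        log.warning("%s: truncated BAM index; sample will be flagged", bai_path)
    while len(idx.linear) < n_expected_refs:
        idx.linear.append(np.empty(0, dtype="<u8"))
        idx.counts.append(None)
    return idx


def read_crai(crai_path: str) -> list[CraiRecord]:
    """Parse a gzip-compressed CRAI into records, dropping unmapped lines.

    Each line holds six tab-separated integers: seq_id, 1-based alignment
    start, span in bases, container byte offset, slice offset within the
    container, and slice size in bytes.  Records with seq_id == -1
    (unmapped reads) carry no positional information and are dropped.
    """
    records: list[CraiRecord] = []
    try:
        with gzip.open(crai_path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 6:
                    raise FatalInputError(
                        f"{crai_path}:{lineno}: expected 6 columns, got {len(fields)}"
                    )
                try:
                    seq_id, start, span, c_off, s_off, s_size = (int(x) for x in fields)
                except ValueError as exc:
                    raise FatalInputError(f"{crai_path}:{lineno}: non-integer field") from exc
                if seq_id == -1:
                    continue
                records.append(CraiRecord(seq_id, start, span, c_off, s_off, s_size))
    except (OSError, gzip.BadGzipFile) as exc:
        raise FatalInputError(f"cannot read CRAI {crai_path}: {exc}") from exc
    if not records:
        log.warning("%s: CRAI contains no mapped records", crai_path)
    return records


def read_fai(fai_path: str) -> FaiTable:
    """Parse a FASTA .fai index; the first two columns (name, length) are
    kept and their order defines the CRAI seq_id mapping."""
    entries: list[tuple[str, int]] = []
    try:
        with open(fai_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise FatalInputError(
                        f"{fai_path}:{lineno}: expected >=2 tab-separated columns"
                    )
                try:
                    entries.append((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise FatalInputError(f"{fai_path}:{lineno}: bad length field") from exc
    except OSError as exc:
        raise FatalInputError(f"cannot read FAI {fai_path}: {exc}") from exc
    if not entries:
        raise FatalInputError(f"{fai_path}: empty FASTA index")
    return FaiTable(entries=tuple(entries))
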