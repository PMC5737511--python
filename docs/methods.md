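# Methods

## Coverage from index byte layout

A coordinate-sorted BAM is stored as BGZF: a chain of independently
deflated blocks, each holding up to 65 536 bytes of uncompressed data. The
`.bai` linear index records, for every consecutive 16 384-bp tile of each
reference, the 64-bit virtual offset of the first alignment starting in the
tile — compressed block offset in the upper 48 bits (`coffset`),
uncompressed within-block offset in the lower 16 (`uoffset`). Under the
assumption that alignment records of one sample occupy a near-constant
number of bytes each, the file distance between consecutive linear-index
entries is proportional to the number of reads starting in the tile, hence
to local depth.

Zero entries after the first populated one mean "no alignment starts in
this tile" and are filled forward before differencing. The last indexed
tile has no successor offset and is assigned 0 bytes; at 16-kb resolution
this one-tile edge loss is negligible, and such tiles are excluded from the
median anyway (zero tiles never define the baseline).

### Sub-block resolution

A naive scalar position `coffset + uoffset/65536` differences to roughly
±half a compressed block of error per tile boundary. At ~10× short-read
depth a tile spans only ~3–6 compressed blocks, so that error is 5–10% per
tile — enough to visibly bias copy-number ratios (measured: a simulated
male's CN_X drifts from 1.0 toward 0.75) and to cap the correlation with
true per-base depth near 0.86–0.91 on clean data. `tilecov` therefore
resolves each step exactly into blocks:

```
k(t)     = round(Δcoffset / b̂)          # whole blocks crossed
bytes(t) = k(t)·b̂ + Δuoffset · (b̂/65536)
```

`b̂`, the sample's mean compressed block size, is measured by reading the
18-byte BGZF container header (which stores the block's total size) at up
to 300 block starts listed in the index — container metadata only, never
record data, so cost is independent of BAM size. When no BAM file is
available (e.g. unit tests operating on a bare index) `b̂` is inferred from
the index alone: positive `Δcoffset` steps are integer multiples of the
block size, so the true size maximizes their phase coherence
(`mean cos(2π·Δc/b)` over a log-spaced candidate grid); among near-maximal
candidates the largest is taken because every divisor of the block size
scores equally. A plain alternating fit of `k` and `b̂` was rejected: its
fixed point is not unique (on test data it converged to 16.5 kB against a
true 12.0 kB).

Block-count rounding is reliable while `k · sd(block)/b̂ < 0.5`; for
homogeneous short-read data `sd(block)/b̂` is a few percent and `k ≤ ~10`,
comfortably inside that bound.

### CRAM

`.crai` lines record each slice's reference span and compressed byte size.
Spans are sample-specific, so each slice's bytes are spread over the
16 384-bp tiles it overlaps, proportionally to overlap length; total bytes
are conserved exactly. Each index line is treated as an independent byte
mass. The CRAM file itself is never opened.

## Scaling and the baseline

Scaled coverage is `bytes(t) / baseline`, with the baseline the single
genome-wide median of nonzero tile byte sizes over non-excluded autosomes.
Design choices folded into that sentence:

- **Genome-wide, not per-chromosome.** Sex-chromosome copy number is only
  interpretable against an autosomal baseline; per-chromosome scaling would
  force every chromosome to 1.
- **Sex chromosomes excluded** so the baseline is karyotype-independent.
- **Zero tiles excluded** so N-masked centromeres and acrocentric arms do
  not drag the median down.
- **Decoy/alt/unplaced contigs excluded** via a configurable regex
  (default `_random$|_alt$|^chrUn|^GL|^NC_|^hs37d5$|^HLA-|hap\d+$|^chrEBV$`).

A sample with no qualifying tile (typically a truncated index) gets
baseline 0, an all-zero profile, and a flag; it is carried through every
output rather than dropped, because surfacing broken inputs is the point of
a QC tool. Byte-truncated `.bai` files are detected during parsing (stream
ends before the declared reference count is consumed) and are never fatal.

## Cohort statistics

**Gap mask.** Tiles zero in every usable cohort sample are reference gaps
and are excluded from copy-number estimation, tile statistics, and PCA.
With a single usable sample there is no cross-sample evidence, so runs of
≥3 consecutive zero tiles are treated as gaps while isolated zeros (1–2
tiles) count as genuinely missing coverage.

**Copy number and sex.** `CN(chrom) = 2 · median(scaled coverage)` over
masked-in tiles; the median resists segmental CNVs. Tiles that males prove
mappable but that are empty in a female count as zeros for her, which is
what drives CN_Y to 0. The sex call uses CN_X only, with thresholds 0.4
and 1.5 — midpoints between the integer CN clusters observed in real
cohorts, with a dead zone near 0 so flagged samples come out "unknown"
(PED code 0).

**Tile statistics.** Proportion of masked autosomal tiles with scaled
coverage < 0.15 (`bins.lo`, missing data) and outside the closed interval
[0.85, 1.15] (`bins.out`, variability). These cutoffs separate aberrant
from uniformly covered samples and are insensitive to moderate changes.

**Reverse CDF.** Proportion of tiles at or above each threshold on the
fixed grid 0.00, 0.02, …, 2.50; the slope through 1.0 summarizes how
tightly a sample concentrates around its baseline.

**PCA.** The cohort matrix stores one byte per scaled value
(`round(64·v)`, saturating at 255/64 ≈ 3.98 — copy number ~8 — at 1/64
resolution; the constant is this package's choice and only needs to
preserve large-scale structure). The matrix covers non-excluded autosomes:
sex-chromosome columns would let karyotype dominate PC1 and mask batch
structure. Columns are dequantized, all-zero columns dropped, remaining
columns centered (not variance-scaled), and the top
`min(5, n_samples−1, n_columns)` components taken by SVD. Signs are fixed
so each component's largest-magnitude loading is positive, making output
deterministic.

## Synthetic data generator

`fixtures.GenomeSpec` describes references, per-segment depth multipliers,
a base depth (default 10×, the depth regime the estimator is designed to
work at and the scale used throughout the tests), and a read length
(default 150 bp, standard short-read). Reads are placed as a Poisson
process (counts Poisson in `depth/read_length × interval length`, starts
uniform), carry random sequence so per-record compressed size is stable,
and are streamed as SAM through `samtools view`/`samtools index`, so the
BAI under test comes from the standard indexer. Fixed seeds give
byte-identical BAMs.

What it emulates: uniform short-read WGS with megabase-scale dosage events
(deletions, duplications, sex-chromosome counts). What it does not: GC
bias, mapping artifacts, split-read/tag byte inflation, duplicate stacks,
low-complexity pileups. Passing tests therefore demonstrate correctness of
the estimator under its core proportional-bytes assumption, not robustness
to every real-data distortion; on real data the correlation with per-base
depth is expected to be lower than on these fixtures.

The batch-effect generator models a library-preparation effect the way it
manifests in practice: samples of the affected batch share a fixed
per-tile bias pattern (as PCR amplification shares GC-correlated depth
distortions) on top of independent noise, giving the affected batch ~3×
the tile-level variance and a common direction that PCA can find.

The per-base depth oracle accumulates exact depth from alignment records
via difference arrays over aligned blocks, averages within tiles, and
scales by the genome-wide median of nonzero tiles — an independent path
used only in tests.

## Problem sizes

Tests and the acceptance script run scaled-down simulations chosen to keep
tile counts statistically meaningful: a 50-Mb genome (~3 050 tiles) for
oracle agreement and deletion recovery, a 7-Mb three-chromosome genome for
the karyotype cohort (123 X tiles, 62 Y tiles; at 10× the median-based CN
estimates have sampling error well under the ±0.2 assertions), and
20 × 500 matrices for PCA checks.

## Known limitations

- Resolution is one tile (16 384 bp); events much smaller than a tile are
  invisible.
- Byte counts conflate depth with per-record size: split-read- or tag-rich
  regions read as high coverage.
- The last indexed tile of each reference is assigned 0 bytes.
- CSI indexes and long-read data are unsupported; with few alignments per
  tile, byte counts are dominated by sampling error.
- This is a screening tool: it flags candidates for per-base follow-up, it
  does not call CNVs.
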