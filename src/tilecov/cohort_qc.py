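"""Cohort-level QC from scaled coverage profiles.

Covers sex-chromosome copy-number estimation and sex calls, the
tile-proportion statistics used to spot aberrant samples, reverse-CDF
coverage summaries, and a PCA of the quantized cohort matrix for batch
detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coverage import CohortMatrix, CoverageProfile, dequantize, is_sex_chrom
from .index_io import ReferenceInfo

log = logging.getLogger(__name__)

# Copy-number boundaries for the sex call: midpoints between the integer
# CN states seen as clusters in real cohorts, with a dead zone near zero
# so broken (e.g. truncated-index) samples come out "unknown".
CN_X_UNKNOWN_BELOW = 0.4
CN_X_FEMALE_AT = 1.5

# Tile-proportion cutoffs: tiles below 0.15 are effectively missing;
# tiles outside [0.85, 1.15] deviate from the diploid baseline.
LOW_CUTOFF = 0.15
IN_RANGE = (0.85, 1.15)

#: Reverse-CDF evaluation grid for scaled coverage.
CDF_GRID = np.round(np.arange(0, 126) * 0.02, 2)


@dataclass(frozen=True)
class SexCall:
    cn_by_chrom: dict[str, float]
    sex_label: str  # "male" | "female" | "unknown"
    ped_sex_code: int  # 1 male, 2 female, 0 unknown


@dataclass(frozen=True)
class TileStats:
    p_low: float
    p_out: float
    p_in: float
    n_evaluated: int


@dataclass
class PcaResult:
    """Sample coordinates on the top principal components (at most 5)."""

    coords: np.ndarray  # shape (n_samples, k)
    explained_variance_ratio: np.ndarray  # shape (k,)
    components: np.ndarray  # shape (k, n_used_columns)
    used_columns: np.ndarray  # indices into the cohort-matrix columns

    @property
    def k(self) -> int:
        return self.coords.shape[1] if self.coords.size else 0

    def coords_padded(self, width: int = 5) -> np.ndarray:
        """Coordinates right-padded with zeros to a fixed column count."""
        n = self.coords.shape[0]
        out = np.zeros((n, width))
        k = min(width, self.coords.shape[1]) if self.coords.size else 0
        if k:
            out[:, :k] = self.coords[:, :k]
        return out


@dataclass
class SampleQC:
    sample_id: str
    sex: SexCall
    tiles: TileStats
    pcs: np.ndarray = field(default_factory=lambda: np.zeros(5))
    truncated: bool = False


def cohort_nonzero_mask(
    profiles: list[CoverageProfile], refs: list[ReferenceInfo]
) -> dict[str, np.ndarray]:
    """Per-reference mask of tiles carrying signal in the cohort.

    Tiles that are zero in *every* sample are reference gaps (N-masked
    centromeres, unassembled arms) and carry no sample information; they
    are excluded from copy-number estimation, tile statistics, and PCA.
    Flagged (zero-baseline) samples contribute nothing to the mask.

    With a single usable sample there is no cross-sample evidence, so a
    run of >=3 consecutive zero tiles is treated as a gap while isolated
    zero tiles (1-2 long) still count as missing coverage.
    """
    usable = [p for p in profiles if not p.flagged]
    masks: dict[str, np.ndarray] = {}
    for ref in refs:
        arrs = [p.by_ref[ref.name] for p in usable if ref.name in p.by_ref]
        if not arrs:
            some = next((p.by_ref[ref.name] for p in profiles if ref.name in p.by_ref), None)
            masks[ref.name] = (
                np.zeros(len(some), dtype=bool) if some is not None else np.zeros(0, dtype=bool)
            )
        elif len(arrs) == 1:
            masks[ref.name] = _single_sample_mask(arrs[0])
        else:
            masks[ref.name] = np.any(np.stack(arrs) > 0, axis=0)
    return masks


def _single_sample_mask(values: np.ndarray, min_gap_run: int = 3) -> np.ndarray:
    mask = values > 0
    if mask.all() or not mask.size:
        return mask
    # flip short zero runs back to True
    padded = np.concatenate([[True], mask, [True]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):  # zero runs in `mask` coords
        if e - s < min_gap_run:
            mask[s:e] = True
    return mask


def estimate_copy_number(
    profile: CoverageProfile,
    chrom_name: str,
    cohort_nonzero: np.ndarray | None = None,
) -> float:
    """Estimated copy number of one chromosome: 2 x median scaled coverage.

    The median is taken over tiles with cross-cohort signal so reference
    gaps do not pull the estimate down, while genuine absence (e.g. no Y
    reads in a female, where males prove the tiles are mappable) still
    counts as zero.  The median (not mean) keeps the estimate robust to
    segmental CNVs.  Flagged samples return 0.
    """
    if chrom_name not in profile.by_ref:
        raise KeyError(
            f"unknown chromosome {chrom_name!r}; available: {sorted(profile.by_ref)}"
        )
    if profile.flagged:
        return 0.0
    vals = profile.by_ref[chrom_name]
    if cohort_nonzero is not None:
        vals = vals[cohort_nonzero[: len(vals)]]
    if len(vals) == 0:
        return 0.0
    return float(2.0 * np.median(vals))


def infer_sex(cn_x: float) -> tuple[str, int]:
    """Sex call from the X copy number alone (Y does not enter the rule)."""
    if cn_x < CN_X_UNKNOWN_BELOW:
        return "unknown", 0
    if cn_x < CN_X_FEMALE_AT:
        return "male", 1
    return "female", 2


def call_sex(
    profile: CoverageProfile,
    sex_chrom_names: tuple[str, ...],
    masks: dict[str, np.ndarray] | None = None,
) -> SexCall:
    cn = {}
    for name in sex_chrom_names:
        resolved = _resolve_chrom(profile, name)
        if resolved is None:
            cn[name] = 0.0
            continue
        m = masks.get(resolved) if masks else None
        cn[name] = estimate_copy_number(profile, resolved, m)
    first = sex_chrom_names[0] if sex_chrom_names else None
    label, code = infer_sex(cn.get(first, 0.0)) if first else ("unknown", 0)
    return SexCall(cn_by_chrom=cn, sex_label=label, ped_sex_code=code)


def _resolve_chrom(profile: CoverageProfile, name: str) -> str | None:
    """Find `name` in the profile, tolerating a 'chr' prefix mismatch."""
    if name in profile.by_ref:
        return name
    for cand in profile.by_ref:
        if is_sex_chrom(cand, (name,)):
            return cand
    return None


def tile_proportions(
    profile: CoverageProfile, evaluation_mask: dict[str, np.ndarray]
) -> TileStats:
    """Proportions of evaluated tiles in/out of [0.85, 1.15] and below 0.15.

    *evaluation_mask* selects non-excluded autosomal tiles with
    cross-cohort signal.  The in-range interval is closed; p_in + p_out
    = 1 by construction and p_low <= p_out (anything below 0.15 is also
    outside the band).
    """
    chunks = [
        profile.by_ref[name][mask[: len(profile.by_ref[name])]]
        for name, mask in evaluation_mask.items()
        if name in profile.by_ref
    ]
    vals = np.concatenate(chunks) if chunks else np.empty(0)
    n = len(vals)
    if n == 0:
        log.warning("%s: empty evaluation mask; tile statistics undefined", profile.sample_id)
        return TileStats(p_low=0.0, p_out=0.0, p_in=0.0, n_evaluated=0)
    inside = (vals >= IN_RANGE[0]) & (vals <= IN_RANGE[1])
    p_in = float(inside.mean())
    return TileStats(
        p_low=float((vals < LOW_CUTOFF).mean()),
        p_out=1.0 - p_in,
        p_in=p_in,
        n_evaluated=n,
    )


def coverage_cdf(values: np.ndarray) -> list[tuple[float, float]]:
    """Reverse CDF of scaled coverage on the fixed grid 0.00, 0.02, ... 2.50.

    Each point is (threshold, proportion of tiles with coverage >= it);
    the curve is non-increasing and its slope at 1.0 reflects how tightly
    the sample concentrates around the baseline.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return []
    sorted_vals = np.sort(values)
    n = len(sorted_vals)
    ge = n - np.searchsorted(sorted_vals, CDF_GRID, side="left")
    return [(float(t), float(g) / n) for t, g in zip(CDF_GRID, ge)]


def pca_project(matrix: CohortMatrix) -> PcaResult:
    """Project samples onto the top-5 principal components of the cohort.

    Works on the 1-byte quantized matrix (dequantized to code/64): the
    coarse precision costs little because batch effects are large-scale.
    Columns zero across every sample are removed, remaining columns are
    centered by their cohort mean (no variance scaling), and components
    come from an SVD.  Signs are fixed so each component's
    largest-magnitude loading is positive, making output deterministic.
    """
    n = matrix.matrix.shape[0]
    if n < 2:
        log.warning("PCA skipped: need >=2 samples, got %d", n)
        return PcaResult(
            coords=np.zeros((n, 0)),
            explained_variance_ratio=np.zeros(0),
            components=np.zeros((0, 0)),
            used_columns=np.zeros(0, dtype=np.int64),
        )
    X = dequantize(matrix.matrix)
    used = np.flatnonzero(X.any(axis=0))
    X = X[:, used]
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(5, n - 1, X.shape[1])
    total = float((s**2).sum())
    coords = u[:, :k] * s[:k]
    comps = vt[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] = -comps[j]
            coords[:, j] = -coords[:, j]
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaResult(
        coords=coords,
        explained_variance_ratio=evr,
        components=comps,
        used_columns=used,
    )
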