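"""Output writers: BGZF BED coverage matrix, extended PED QC table, and a
self-contained HTML report.

The overview page puts the two highest-information plots first — the sex
plot (CN_X vs CN_Y) and the tile plot (proportion of low tiles vs
proportion outside the expected band) — followed by PCA plots, download
links, and per-chromosome thumbnails.  Each thumbnail links to an
interactive per-chromosome page where hovering a line identifies the
sample (native SVG tooltips; no external JS)."""

from __future__ import annotations

import base64
import html
import logging
import os
from dataclasses import dataclass

import numpy as np
import pysam

from .cohort_qc import PcaResult, SampleQC, coverage_cdf
from .coverage import TILE_SIZE, CoverageProfile, n_tiles
from .index_io import FatalInputError, ReferenceInfo

log = logging.getLogger(__name__)

# 1x1 transparent PNG, used when rendering a chromosome fails.
_PLACEHOLDER_PNG = base64.b64decode(
    "iVBORw0KGgoAAAANSUhEUgAAAAEAAAABCAYAAAAfFcSJAAAADUlEQVR42mNkYPhf"
    "DwAChwGA60e6kgAAAABJRU5ErkJggg=="
)


@dataclass(frozen=True)
class OutputPaths:
    """Derived file locations inside one output directory."""

    directory: str
    prefix: str

    @property
    def bed(self) -> str:
        return os.path.join(self.directory, f"{self.prefix}-tilecov.bed.gz")

    @property
    def ped(self) -> str:
        return os.path.join(self.directory, f"{self.prefix}-tilecov.ped")

    @property
    def index_html(self) -> str:
        return os.path.join(self.directory, "index.html")

    def chrom_html(self, chrom: str) -> str:
        return os.path.join(self.directory, f"{self.prefix}-{chrom}.html")

    def chrom_png(self, chrom: str, kind: str) -> str:
        return os.path.join(self.directory, f"{self.prefix}-{kind}-{chrom}.png")


def output_paths(directory: str, prefix: str | None = None) -> OutputPaths:
    os.makedirs(directory, exist_ok=True)
    if prefix is None:
        prefix = os.path.basename(os.path.normpath(directory)) or "tilecov"
    return OutputPaths(directory=directory, prefix=prefix)


def included_refs(refs: list[ReferenceInfo]) -> list[ReferenceInfo]:
    return [r for r in refs if not r.excluded]


def write_bed(profiles: list[CoverageProfile], refs: list[ReferenceInfo], path: str) -> None:
    """Write the scaled-coverage matrix as a BGZF-compressed BED file.

    One row per 16 384-bp tile of every non-excluded reference (0-based
    half-open; the final tile is truncated to the reference length), one
    column per sample, values at 3 decimal places.
    """
    try:
        with pysam.BGZFile(path, "wb") as out:
            names = "\t".join(p.sample_id for p in profiles)
            out.write(f"#chrom\tstart\tend\t{names}\n".encode())
            for ref in included_refs(refs):
                nt = n_tiles(ref.length)
                cols = [p.by_ref[ref.name] for p in profiles]
                for t in range(nt):
                    start = t * TILE_SIZE
                    end = min(start + TILE_SIZE, ref.length)
                    vals = "\t".join(f"{c[t]:.3f}" for c in cols)
                    out.write(f"{ref.name}\t{start}\t{end}\t{vals}\n".encode())
    except OSError as exc:
        raise FatalInputError(f"cannot write BED {path}: {exc}") from exc


PED_COLUMNS = (
    "#family_id sample_id paternal_id maternal_id sex phenotype "
    "CNX CNY bins.in bins.out bins.lo PC1 PC2 PC3 PC4 PC5"
).split()


def write_ped(qc: list[SampleQC], sex_chrom_names: tuple[str, ...], path: str) -> None:
    """Write the extended PED table: the 6 standard pedigree columns plus
    sex-chromosome copy numbers, tile statistics, and top-5 PCs.

    Sex codes follow PED convention (1 male, 2 female, 0 unknown);
    parents and phenotype are -9 (unknown); reals at 4 decimals.
    """
    try:
        with open(path, "w") as out:
            out.write("\t".join(PED_COLUMNS) + "\n")
            for q in qc:
                cns = [q.sex.cn_by_chrom.get(n, 0.0) for n in sex_chrom_names[:2]]
                while len(cns) < 2:
                    cns.append(0.0)
                row = [
                    q.sample_id,
                    q.sample_id,
                    "-9",
                    "-9",
                    str(q.sex.ped_sex_code),
                    "-9",
                    f"{cns[0]:.4f}",
                    f"{cns[1]:.4f}",
                    f"{q.tiles.p_in:.4f}",
                    f"{q.tiles.p_out:.4f}",
                    f"{q.tiles.p_low:.4f}",
                    *(f"{v:.4f}" for v in q.pcs[:5]),
                ]
                out.write("\t".join(row) + "\n")
    except OSError as exc:
        raise FatalInputError(f"cannot write PED {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# HTML report


def _svg_scatter(
    points: list[tuple[float, float, str]],
    xlabel: str,
    ylabel: str,
    width: int = 420,
    height: int = 340,
) -> str:
    """Scatter plot as inline SVG; each marker's <title> names the sample,
    so hovering identifies it in any browser without scripting."""
    pad = 45
    xs = [p[0] for p in points] or [0.0]
    ys = [p[1] for p in points] or [0.0]
    x0, x1 = min(0.0, min(xs)), max(max(xs), 1e-9)
    y0, y1 = min(0.0, min(ys)), max(max(ys), 1e-9)
    x1 += 0.05 * (x1 - x0) or 1.0
    y1 += 0.05 * (y1 - y0) or 1.0

    def sx(v: float) -> float:
        return pad + (v - x0) / (x1 - x0) * (width - 2 * pad)

    def sy(v: float) -> float:
        return height - pad - (v - y0) / (y1 - y0) * (height - 2 * pad)

    parts = [
        f'<svg class="scatter" width="{width}" height="{height}" '
        f'xmlns="http://www.w3.org/2000/svg">',
        f'<rect x="{pad}" y="{pad}" width="{width - 2 * pad}" '
        f'height="{height - 2 * pad}" fill="none" stroke="#ccc"/>',
        f'<text x="{width / 2:.0f}" y="{height - 8}" text-anchor="middle" '
        f'font-size="12">{html.escape(xlabel)}</text>',
        f'<text x="12" y="{height / 2:.0f}" text-anchor="middle" font-size="12" '
        f'transform="rotate(-90 12 {height / 2:.0f})">{html.escape(ylabel)}</text>',
        f'<text x="{pad}" y="{height - pad + 14}" font-size="10">{x0:.2g}</text>',
        f'<text x="{width - pad}" y="{height - pad + 14}" text-anchor="end" '
        f'font-size="10">{x1:.2g}</text>',
        f'<text x="{pad - 4}" y="{height - pad}" text-anchor="end" font-size="10">{y0:.2g}</text>',
        f'<text x="{pad - 4}" y="{pad + 4}" text-anchor="end" font-size="10">{y1:.2g}</text>',
    ]
    for x, y, name in points:
        parts.append(
            f'<circle cx="{sx(x):.1f}" cy="{sy(y):.1f}" r="4" fill="steelblue" '
            f'fill-opacity="0.6" stroke="navy"><title>{html.escape(name)}</title></circle>'
        )
    parts.append("</svg>")
    return "".join(parts)


def _svg_lines(
    series: list[tuple[str, np.ndarray, np.ndarray]],
    xlabel: str,
    ylabel: str,
    width: int = 900,
    height: int = 300,
    max_points: int = 1200,
    ymax: float = 2.5,
) -> str:
    """Multi-sample line plot as inline SVG with per-line hover titles."""
    pad = 45
    xmax = max((float(x[-1]) for _, x, _ in series if len(x)), default=1.0)
    parts = [
        f'<svg class="lines" width="{width}" height="{height}" '
        f'xmlns="http://www.w3.org/2000/svg">',
        f'<rect x="{pad}" y="{pad}" width="{width - 2 * pad}" '
        f'height="{height - 2 * pad}" fill="none" stroke="#ccc"/>',
        f'<text x="{width / 2:.0f}" y="{height - 8}" text-anchor="middle" '
        f'font-size="12">{html.escape(xlabel)}</text>',
        f'<text x="12" y="{height / 2:.0f}" text-anchor="middle" font-size="12" '
        f'transform="rotate(-90 12 {height / 2:.0f})">{html.escape(ylabel)}</text>',
    ]
    palette = ["#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3", "#937860", "#da8bc3"]
    for si, (name, x, y) in enumerate(series):
        if len(x) == 0:
            continue
        step = max(1, len(x) // max_points)
        xi, yi = x[::step], np.clip(y[::step], 0, ymax)
        px = pad + xi / max(xmax, 1e-9) * (width - 2 * pad)
        py = height - pad - yi / ymax * (height - 2 * pad)
        pts = " ".join(f"{a:.1f},{b:.1f}" for a, b in zip(px, py))
        color = palette[si % len(palette)]
        parts.append(
            f'<polyline fill="none" stroke="{color}" stroke-opacity="0.75" '
            f'stroke-width="1.5" points="{pts}">'
            f"<title>{html.escape(name)}</title></polyline>"
        )
    parts.append("</svg>")
    return "".join(parts)


_HELP = {
    "sex": "Each point is one sample at its estimated X and Y copy number; "
    "males cluster at (1, 1), females at (2, 0). Points near the origin "
    "indicate missing or truncated indexes; off-cluster points suggest sex "
    "chromosome aneuploidies.",
    "tiles": "Proportion of autosomal tiles with scaled coverage below 0.15 "
    "(x) versus outside 0.85-1.15 (y). High x means missing data; high y "
    "means high coverage variability.",
    "pca": "Samples projected onto the top principal components of the "
    "scaled-coverage matrix. Separated clusters usually indicate batch "
    "effects such as differing library preparation.",
    "chrom": "Per-chromosome scaled coverage along the chromosome and as a "
    "reverse CDF (proportion of tiles covered at or above each depth). "
    "Click a thumbnail for the interactive version; hover a line to "
    "identify the sample.",
}


def _try_png(path: str, draw) -> None:
    """Render one thumbnail; on failure leave a placeholder and continue."""
    try:
        draw(path)
    except Exception as exc:  # noqa: BLE001 - report must survive plot errors
        log.warning("thumbnail %s failed (%s); placeholder written", path, exc)
        with open(path, "wb") as fh:
            fh.write(_PLACEHOLDER_PNG)


def render_html(
    profiles: list[CoverageProfile],
    qc: list[SampleQC],
    pca: PcaResult,
    cdfs: dict[str, list[tuple[str, list[tuple[float, float]]]]],
    paths: OutputPaths,
) -> None:
    """Write index.html plus per-chromosome interactive pages and PNGs.

    *cdfs* maps chromosome -> [(sample_id, reverse-CDF points)].  Output
    is deterministic for fixed inputs: no timestamps are embedded.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    refs_in_order = list(profiles[0].by_ref) if profiles else []
    sections: list[str] = []

    sex_pts = []
    for q in qc:
        cns = list(q.sex.cn_by_chrom.values())
        sex_pts.append((cns[0] if cns else 0.0, cns[1] if len(cns) > 1 else 0.0, q.sample_id))
    sections.append(
        '<section id="sex"><h2>Sex plot <a class="help" href="#help-sex">?</a></h2>'
        + _svg_scatter(sex_pts, "copy number (X)", "copy number (Y)")
        + "</section>"
    )
    tile_pts = [(q.tiles.p_low, q.tiles.p_out, q.sample_id) for q in qc]
    sections.append(
        '<section id="tiles"><h2>Tile plot <a class="help" href="#help-tiles">?</a></h2>'
        + _svg_scatter(tile_pts, "proportion of tiles < 0.15", "proportion outside 0.85-1.15")
        + "</section>"
    )
    coords = pca.coords_padded(5) if pca.coords.size else np.zeros((len(qc), 5))
    pca_12 = [(coords[i, 0], coords[i, 1], q.sample_id) for i, q in enumerate(qc)]
    pca_13 = [(coords[i, 0], coords[i, 2], q.sample_id) for i, q in enumerate(qc)]
    sections.append(
        '<section id="pca"><h2>PCA <a class="help" href="#help-pca">?</a></h2>'
        + _svg_scatter(pca_12, "PC1", "PC2")
        + _svg_scatter(pca_13, "PC1", "PC3")
        + "</section>"
    )
    sections.append(
        '<section id="downloads"><h2>Downloads</h2><ul>'
        f'<li><a href="{os.path.basename(paths.bed)}">scaled coverage BED</a></li>'
        f'<li><a href="{os.path.basename(paths.ped)}">sample QC PED</a></li>'
        "</ul></section>"
    )

    thumb_parts = [
        '<section id="chroms"><h2>Chromosomes <a class="help" href="#help-chrom">?</a></h2>'
    ]
    for chrom in refs_in_order:
        if chrom not in cdfs:
            continue
        _render_chrom(profiles, cdfs[chrom], chrom, paths, plt)
        page = os.path.basename(paths.chrom_html(chrom))
        depth_png = os.path.basename(paths.chrom_png(chrom, "depth"))
        cdf_png = os.path.basename(paths.chrom_png(chrom, "cdf"))
        thumb_parts.append(
            f'<div class="chrom"><h3>{html.escape(chrom)}</h3>'
            f'<a href="{page}"><img src="{depth_png}" alt="{html.escape(chrom)} depth"/></a>'
            f'<a href="{page}"><img src="{cdf_png}" alt="{html.escape(chrom)} CDF"/></a></div>'
        )
    thumb_parts.append("</section>")
    sections.append("".join(thumb_parts))

    help_html = "".join(
        f'<p id="help-{key}"><b>{key}</b>: {html.escape(text)}</p>' for key, text in _HELP.items()
    )
    sections.append(f'<section id="help"><h2>Help</h2>{help_html}</section>')

    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>tilecov coverage QC</title>"
        "<style>body{font-family:sans-serif;margin:2em} img{height:140px;margin:4px;"
        "border:1px solid #ddd} section{margin-bottom:2em} .help{font-size:0.7em}"
        "</style></head><body><h1>tilecov coverage QC</h1>"
        + "".join(sections)
        + "</body></html>"
    )
    with open(paths.index_html, "w") as fh:
        fh.write(doc)


def _render_chrom(
    profiles: list[CoverageProfile],
    chrom_cdfs: list[tuple[str, list[tuple[float, float]]]],
    chrom: str,
    paths: OutputPaths,
    plt,
) -> None:
    mb = 1.0 / 1_000_000

    def draw_depth(png_path: str) -> None:
        fig, ax = plt.subplots(figsize=(4, 1.6), dpi=72)
        for p in profiles:
            y = p.by_ref[chrom]
            x = (np.arange(len(y)) * TILE_SIZE + TILE_SIZE / 2) * mb
            ax.plot(x, np.clip(y, 0, 2.5), lw=0.5, alpha=0.7)
        ax.set_ylim(0, 2.5)
        ax.set_xlabel("Mb", fontsize=7)
        ax.set_ylabel("scaled cov", fontsize=7)
        ax.tick_params(labelsize=6)
        fig.tight_layout()
        fig.savefig(png_path, metadata={"Software": "tilecov"})
        plt.close(fig)

    def draw_cdf(png_path: str) -> None:
        fig, ax = plt.subplots(figsize=(4, 1.6), dpi=72)
        for _, pts in chrom_cdfs:
            if pts:
                t, pr = zip(*pts)
                ax.plot(t, pr, lw=0.7, alpha=0.7)
        ax.set_xlabel("scaled coverage", fontsize=7)
        ax.set_ylabel("prop ≥ x", fontsize=7)
        ax.tick_params(labelsize=6)
        fig.tight_layout()
        fig.savefig(png_path, metadata={"Software": "tilecov"})
        plt.close(fig)

    _try_png(paths.chrom_png(chrom, "depth"), draw_depth)
    _try_png(paths.chrom_png(chrom, "cdf"), draw_cdf)

    depth_series = []
    for p in profiles:
        y = p.by_ref[chrom]
        x = (np.arange(len(y), dtype=np.float64) * TILE_SIZE + TILE_SIZE / 2) * mb
        depth_series.append((p.sample_id, x, y))
    cdf_series = []
    for sid, pts in chrom_cdfs:
        if pts:
            t, pr = zip(*pts)
            cdf_series.append((sid, np.asarray(t), np.asarray(pr)))
    page = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(chrom)} coverage</title></head><body>"
        f"<h1>{html.escape(chrom)}</h1><p><a href='index.html'>back to overview</a>"
        " &mdash; hover a line to identify the sample</p>"
        "<h2>Scaled coverage along the chromosome</h2>"
        + _svg_lines(depth_series, "position (Mb)", "scaled coverage")
        + "<h2>Reverse CDF</h2>"
        + _svg_lines(cdf_series, "scaled coverage", "proportion ≥ x", ymax=1.05)
        + "</body></html>"
    )
    with open(paths.chrom_html(chrom), "w") as fh:
        fh.write(page)


def compute_cdfs(
    profiles: list[CoverageProfile], refs: list[ReferenceInfo]
) -> dict[str, list[tuple[str, list[tuple[float, float]]]]]:
    """Reverse CDF per non-excluded chromosome per sample."""
    out: dict[str, list[tuple[str, list[tuple[float, float]]]]] = {}
    for ref in included_refs(refs):
        out[ref.name] = [
            (p.sample_id, coverage_cdf(p.by_ref[ref.name])) for p in profiles
        ]
    return out
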