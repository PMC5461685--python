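"""Static report: TSV artifacts plus linked HTML pages.

``write_pipeline_outputs`` materializes every computed artifact of a
call (SE table, rank curve, closeness, enrichment, summary statistics,
chromosomal SVGs, per-SE profile snapshots) into an output directory;
``assemble_report`` then builds self-contained HTML pages over those
files. Both are pure functions of their inputs: rerunning on unchanged
inputs reproduces identical bytes.
"""

from __future__ import annotations

import html
import os

import pandas as pd

from .algebra import SignalTrack
from .annotation import genecards_url, ucsc_url
from .calling import RankCurve
from .chromstats import closeness_all, enrichment_table, summary_statistics
from .errors import AssemblyError
from .intervals import GenomicInterval, StitchedEnhancer
from .io import write_se_table
from .pipeline import subpeak_table
from .plots import profile_svg, render_chromosomal_plot, snapshot_windows

MAX_SNAPSHOTS = 50  # profile images for the top-ranked SEs only


def write_pipeline_outputs(
    outdir: str,
    table: pd.DataFrame,
    regions: list[StitchedEnhancer],
    curve: RankCurve | None,
    chrom_sizes: dict[str, int],
    track: SignalTrack | None = None,
    genes_per_chrom: dict[str, int] | None = None,
    max_snapshots: int = MAX_SNAPSHOTS,
) -> None:
    """Write every TSV/SVG artifact of one pipeline run under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "stats"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "snapshots"), exist_ok=True)

    write_se_table(table, os.path.join(outdir, "se_table.tsv"))

    if curve is not None:
        pd.DataFrame(
            {"scaled_rank": curve.scaled_rank, "scaled_count": curve.scaled_count}
        ).to_csv(os.path.join(outdir, "rank_curve.tsv"), sep="\t", index=False)

    se_only = [r for r in regions if r.is_se]
    records = closeness_all(se_only)
    pd.DataFrame(
        [{"rank": r.se_id, "chrom": r.chrom, "closeness": r.closeness} for r in records]
    ).to_csv(os.path.join(outdir, "closeness.tsv"), sep="\t", index=False, na_rep="NA")

    marks: dict[str, str] = {}
    if genes_per_chrom:
        enr = enrichment_table(regions, genes_per_chrom)
        enr.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
        marks = dict(zip(enr["chrom"], enr["mark"]))

    if not table.empty:
        stats = summary_statistics(table, subpeak_table(regions))
        for name, frame in stats.items():
            frame.to_csv(os.path.join(outdir, "stats", f"{name}.tsv"), sep="\t", index=False)

    for mode in ("enrichment", "rank", "closeness"):
        svg = render_chromosomal_plot(
            regions, mode, chrom_sizes, enrichment_marks=marks, closeness_records=records
        )
        with open(os.path.join(outdir, f"chrom_plot_{mode}.svg"), "w") as fh:
            fh.write(svg)

    if track is not None:
        for region in sorted(se_only, key=lambda r: r.rank)[:max_snapshots]:
            near, far = snapshot_windows(region.interval, chrom_sizes.get(region.chrom))
            for label, window in (("near", near), ("far", far)):
                svg = profile_svg(region, track, window)
                path = os.path.join(outdir, "snapshots", f"se_{region.rank}_{label}.svg")
                with open(path, "w") as fh:
                    fh.write(svg)


def _page(title: str, body: str, nav_links: list[tuple[str, str]]) -> str:
    nav = " | ".join(f'<a href="{href}">{html.escape(label)}</a>' for href, label in nav_links)
    return (
        "<!DOCTYPE html>\n"
        f"<html><head><meta charset='utf-8'><title>{html.escape(title)}</title>"
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #ccc;padding:3px 8px;font-size:13px}</style>"
        f"</head><body><nav>{nav}</nav><h1>{html.escape(title)}</h1>\n{body}\n</body></html>\n"
    )


def assemble_report(outdir: str) -> list[str]:
    """Build the HTML pages over the artifacts in ``outdir``.

    Returns the written page paths. The evaluation page is produced
    only when ``goodness.tsv`` is present; any other missing artifact
    raises :class:`AssemblyError` naming the stage.
    """
    table_path = os.path.join(outdir, "se_table.tsv")
    if not os.path.exists(table_path):
        raise AssemblyError("missing SE table (stage: call)")
    for mode in ("enrichment", "rank", "closeness"):
        if not os.path.exists(os.path.join(outdir, f"chrom_plot_{mode}.svg")):
            raise AssemblyError(f"missing chromosomal plot '{mode}' (stage: plots)")
    stats_dir = os.path.join(outdir, "stats")
    if not os.path.isdir(stats_dir):
        raise AssemblyError("missing summary statistics (stage: statistics)")

    table = pd.read_csv(table_path, sep="\t", na_values=["NA"], keep_default_na=False)
    has_eval = os.path.exists(os.path.join(outdir, "goodness.tsv"))
    nav = [("index.html", "Main"), ("se_table.html", "SE table"),
           ("statistics.html", "Statistics")]
    if has_eval:
        nav.append(("evaluation.html", "Evaluation"))

    pages = []

    plots_html = "".join(
        f"<h2>{mode.capitalize()} plot</h2>"
        f'<object type="image/svg+xml" data="chrom_plot_{mode}.svg" width="920"></object>'
        for mode in ("enrichment", "rank", "closeness")
    )
    n_se = int(table["is_SE"].astype(bool).sum()) if not table.empty else 0
    summary = (
        f"<p>{len(table)} stitched enhancers; {n_se} called superenhancers.</p>"
    )
    pages.append(("index.html", _page("Superenhancer report", summary + plots_html, nav)))

    rows = []
    head = (
        "<tr><th>rank</th><th>locus</th><th>gene</th><th>count</th><th>subpeaks</th>"
        "<th>type</th><th>% OUTS</th><th>SE</th><th>profile</th></tr>"
    )
    for _, r in table.iterrows():
        locus = GenomicInterval(str(r["chrom"]), int(r["start"]), int(r["end"]))
        gene = str(r["closest_gene"])
        gene_cell = (
            f'<a href="{genecards_url(gene)}">{html.escape(gene)}</a>' if gene != "NA" else "NA"
        )
        snap = os.path.join(outdir, "snapshots", f"se_{int(r['rank'])}_near.svg")
        snap_cell = (
            f'<a href="snapshots/se_{int(r["rank"])}_near.svg">near</a> '
            f'<a href="snapshots/se_{int(r["rank"])}_far.svg">far</a>'
            if os.path.exists(snap)
            else ""
        )
        rows.append(
            f'<tr id="se-{int(r["rank"])}"><td>{int(r["rank"])}</td>'
            f'<td><a href="{ucsc_url(locus)}">{locus.chrom}:{locus.start}-{locus.end}</a></td>'
            f"<td>{gene_cell}</td><td>{r['count']}</td><td>{int(r['n_subpeaks'])}</td>"
            f"<td>{html.escape(str(r['enhancer_type']))}</td><td>{r['percentage_outs']}</td>"
            f"<td>{'yes' if bool(r['is_SE']) else 'no'}</td><td>{snap_cell}</td></tr>"
        )
    pages.append(
        ("se_table.html", _page("SE table", "<table>" + head + "\n".join(rows) + "</table>", nav))
    )

    stat_parts = []
    for name in sorted(os.listdir(stats_dir)):
        if not name.endswith(".tsv"):
            continue
        frame = pd.read_csv(os.path.join(stats_dir, name), sep="\t")
        stat_parts.append(f"<h2>{html.escape(name[:-4])}</h2>" + frame.to_html(index=False))
    pages.append(("statistics.html", _page("SE vs TE statistics", "\n".join(stat_parts), nav)))

    if has_eval:
        goodness = pd.read_csv(os.path.join(outdir, "goodness.tsv"), sep="\t")
        body = goodness.to_html(index=False)
        matrix_path = os.path.join(outdir, "marker_matrix.tsv")
        if os.path.exists(matrix_path):
            body += "<h2>Per-marker scaled ranks</h2>"
            body += pd.read_csv(matrix_path, sep="\t").to_html(index=False)
        pages.append(("evaluation.html", _page("Predictor evaluation", body, nav)))

    written = []
    for name, content in pages:
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            fh.write(content)
        written.append(path)
    return written
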