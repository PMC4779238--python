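"""Summary-table (TSV + HTML), per-target GTF custom tracks, and UCSC
genome-browser / In-Silico-PCR hyperlink generation.

The TSV is the canonical machine artifact: a frozen column order, UTF-8,
one header line whose column names are exactly the identifiers accepted by
quality-matrix rules. The HTML view renders the same rows with clickable
links and carries no scripts. URLs are emitted as strings only — nothing is
fetched.
"""

from __future__ import annotations

import html
from pathlib import Path
from typing import Mapping, Optional, Sequence
from urllib.parse import urlencode

from .annotator import AnnotatedPair

__all__ = [
    "SUMMARY_COLUMNS",
    "summary_row",
    "write_summary",
    "write_gtf_track",
    "browser_url",
    "insilico_pcr_url",
]

# Frozen output schema: any of these names may be used as a quality-rule column.
SUMMARY_COLUMNS: tuple[str, ...] = (
    "target_id",
    "pair_id",
    "forward_primer",
    "reverse_primer",
    "oligo",
    "forward_tm",
    "reverse_tm",
    "forward_gc",
    "reverse_gc",
    "forward_penalty",
    "reverse_penalty",
    "pair_penalty",
    "amplicon_coordinates",
    "product_size",
    "n_cutsites_fwd",
    "n_cutsites_rev",
    "n_cutsites_oligo",
    "n_cutsites_amplicon",
    "n_snps_fwd",
    "n_snps_rev",
    "n_snps_amplicon",
    "n_snps_oligo",
    "n_cpg_islands",
    "n_repeats",
    "repeat_in_primer",
    "upstream_gene",
    "upstream_gene_strand",
    "upstream_gene_distance",
    "downstream_gene",
    "downstream_gene_strand",
    "downstream_gene_distance",
    "target_distance",
    "quality_level",
    "browser_url",
    "insilico_url",
)

UCSC_BROWSER_BASE = "https://genome.ucsc.edu/cgi-bin/hgTracks"
UCSC_INSILICO_BASE = "https://genome.ucsc.edu/cgi-bin/hgPcr"


def browser_url(chrom: str, start: int, end: int, assembly: str) -> str:
    """UCSC genome-browser URL for a 0-based half-open genomic interval.

    The position string uses the browser's 1-based inclusive display
    convention: ``chrom:start+1-end``.
    """
    query = urlencode({"db": assembly, "position": f"{chrom}:{start + 1}-{end}"})
    return f"{UCSC_BROWSER_BASE}?{query}"


def insilico_pcr_url(forward: str, reverse: str, assembly: str) -> str:
    """UCSC In-Silico PCR URL carrying both primer sequences."""
    query = urlencode({
        "db": assembly,
        "wp_target": "genome",
        "wp_f": forward.upper(),
        "wp_r": reverse.upper(),
    })
    return f"{UCSC_INSILICO_BASE}?{query}"


def summary_row(
    apair: AnnotatedPair,
    assembly: str = "hg19",
    quality_level: Optional[int] = None,
) -> dict:
    """Assemble one summary-table row (dict keyed by :data:`SUMMARY_COLUMNS`)."""
    pair = apair.pair
    g = apair.genomic
    cs = apair.cut_summary
    return {
        "target_id": apair.target_id,
        "pair_id": pair.pair_id,
        "forward_primer": pair.forward.sequence,
        "reverse_primer": pair.reverse.sequence,
        "oligo": pair.oligo.sequence if pair.oligo else "",
        "forward_tm": round(pair.forward.tm, 2),
        "reverse_tm": round(pair.reverse.tm, 2),
        "forward_gc": round(pair.forward.gc, 2),
        "reverse_gc": round(pair.reverse.gc, 2),
        "forward_penalty": round(pair.forward.penalty, 4),
        "reverse_penalty": round(pair.reverse.penalty, 4),
        "pair_penalty": round(pair.pair_penalty, 4),
        "amplicon_coordinates": f"{g.chrom}:{g.amplicon[0]}-{g.amplicon[1]}",
        "product_size": pair.product_size,
        "n_cutsites_fwd": cs.n_fwd,
        "n_cutsites_rev": cs.n_rev,
        "n_cutsites_oligo": cs.n_oligo,
        "n_cutsites_amplicon": cs.n_amplicon,
        "n_snps_fwd": apair.n_snps_fwd,
        "n_snps_rev": apair.n_snps_rev,
        "n_snps_amplicon": apair.n_snps_amplicon,
        "n_snps_oligo": apair.n_snps_oligo,
        "n_cpg_islands": apair.n_cpg_islands,
        "n_repeats": apair.n_repeats,
        "repeat_in_primer": int(apair.repeat_in_primer),
        "upstream_gene": apair.upstream_gene or "",
        "upstream_gene_strand": apair.upstream_strand or "",
        "upstream_gene_distance": (
            apair.dist_upstream if apair.dist_upstream is not None else ""
        ),
        "downstream_gene": apair.downstream_gene or "",
        "downstream_gene_strand": apair.downstream_strand or "",
        "downstream_gene_distance": (
            apair.dist_downstream if apair.dist_downstream is not None else ""
        ),
        "target_distance": apair.target_distance,
        "quality_level": quality_level if quality_level is not None else "",
        "browser_url": browser_url(g.chrom, g.amplicon[0], g.amplicon[1], assembly),
        "insilico_url": insilico_pcr_url(
            pair.forward.sequence, pair.reverse.sequence, assembly
        ),
    }


_HTML_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Primer design summary</title>
<style>
table {{ border-collapse: collapse; font: 13px sans-serif; }}
th, td {{ border: 1px solid #999; padding: 3px 6px; white-space: nowrap; }}
th {{ background: #eee; }}
</style>
</head>
<body>
<h1>Primer design summary</h1>
<table>
<thead><tr>{header}</tr></thead>
<tbody>
{body}
</tbody>
</table>
</body>
</html>
"""


def write_summary(
    rows: Sequence[Mapping],
    out_dir: str | Path,
    *,
    basename: str = "summary",
) -> tuple[Path, Path]:
    """Write the summary table as TSV and HTML; returns (tsv_path, html_path).

    The TSV always carries the full frozen header, even with zero rows, so
    an empty result is explicit. URL columns are rendered as hyperlinks in
    the HTML view; every TSV data row corresponds to exactly one HTML row.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv_path = out / f"{basename}.tsv"
    html_path = out / f"{basename}.html"

    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in SUMMARY_COLUMNS) + "\n")

    header = "".join(f"<th>{html.escape(c)}</th>" for c in SUMMARY_COLUMNS)
    body_rows = []
    for row in rows:
        cells = []
        for c in SUMMARY_COLUMNS:
            value = str(row[c])
            if c.endswith("_url") and value:
                label = "browser" if c == "browser_url" else "in-silico PCR"
                cells.append(
                    f'<td><a href="{html.escape(value, quote=True)}">{label}</a></td>'
                )
            else:
                cells.append(f"<td>{html.escape(value)}</td>")
        body_rows.append("<tr>" + "".join(cells) + "</tr>")
    with open(html_path, "w", encoding="utf-8") as fh:
        fh.write(_HTML_PAGE.format(header=header, body="\n".join(body_rows)))
    return tsv_path, html_path


def write_gtf_track(
    pairs: Sequence[AnnotatedPair],
    path: str | Path,
    *,
    track_name: Optional[str] = None,
) -> Path:
    """Write one target's selected pairs as a UCSC custom track in GTF.

    Per pair, three features are emitted — amplicon, forward primer, reverse
    primer — with GTF 1-based inclusive coordinates (start = BED start + 1,
    end = BED end), score = pair penalty, and attributes carrying target and
    pair IDs.
    """
    path = Path(path)
    lines = []
    if pairs:
        name = track_name or f"msreprime_{pairs[0].target_id}"
        lines.append(
            f'track name="{name}" description="primer pairs for '
            f'{pairs[0].target_id}" visibility=2'
        )
    for apair in pairs:
        g = apair.genomic
        attrs = (
            f'target_id "{apair.target_id}"; pair_id "{apair.pair.pair_id}";'
        )
        score = f"{apair.pair.pair_penalty:.4f}"
        for feature, (lo, hi) in (
            ("amplicon", g.amplicon),
            ("forward_primer", g.forward),
            ("reverse_primer", g.reverse),
        ):
            lines.append(
                "\t".join([
                    g.chrom, "msreprime", feature,
                    str(lo + 1), str(hi), score, "+", ".", attrs,
                ])
            )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
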