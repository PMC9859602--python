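"""Table rendering and landscape output.

The satellitome table is laid out like the field's published tables: one
row per family (name, genome proportion, repeat unit length, A+T content,
mean K2P divergence, TSI, DivPeak, RSP), a Total row for the proportion
column, and Mean / SD / Median summary rows. Proportions are printed with
5 decimals, everything else with 2; values stay unrounded internally.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .satstats import SUMMARY_COLUMNS, Landscape, SatellitomeTable, FamilyStats, summarize_table

__all__ = ["render_table", "write_table_tsv", "read_table_tsv", "write_landscape_csv"]

_COLUMNS = [
    "name",
    "genome_proportion",
    "monomer_length",
    "at_percent",
    "mean_k2p",
    "tsi",
    "divpeak",
    "rsp",
]

_HEADER = [
    "Name",
    "GenomeProportion",
    "RepeatUnitLength(bp)",
    "A+TPercentage",
    "KimuraDivergence",
    "TSI",
    "DivP",
    "RSP",
]


def _fmt(value, col: str) -> str:
    if value is None or (isinstance(value, float) and value != value):
        return ""
    if col == "name":
        return str(value)
    if col == "genome_proportion":
        return f"{value:.5f}"
    if col in ("monomer_length", "divpeak"):
        return f"{value:.0f}" if isinstance(value, float) else str(value)
    return f"{value:.2f}"


def _render_rows(table: SatellitomeTable) -> list[list[str]]:
    df = table.to_dataframe()
    lines = [list(_HEADER)]
    for _, row in df.iterrows():
        lines.append([_fmt(row[c], c) for c in _COLUMNS])
    if len(df):
        lines.append(["Total", f"{table.total_proportion:.5f}"] + [""] * 6)
        summ = summarize_table(df)
        for stat, label in (("mean", "Mean"), ("sd", "SD"), ("median", "Median")):
            cells = [label, ""]
            for col in _COLUMNS[2:]:
                cells.append(
                    f"{summ[col][stat]:.2f}" if col in summ else ""
                )
            lines.append(cells)
    return lines


def render_table(table: SatellitomeTable) -> tuple[str, str]:
    """Render a satellitome table as (TSV text, Markdown text)."""
    rows = _render_rows(table)
    tsv = "\n".join("\t".join(r) for r in rows) + "\n"
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    md_lines = ["| " + " | ".join(c.ljust(w) for c, w in zip(rows[0], widths)) + " |"]
    md_lines.append("|" + "|".join("-" * (w + 2) for w in widths) + "|")
    for r in rows[1:]:
        md_lines.append("| " + " | ".join(c.ljust(w) for c, w in zip(r, widths)) + " |")
    return tsv, "\n".join(md_lines) + "\n"


def write_table_tsv(table: SatellitomeTable, path: str | Path) -> None:
    tsv, _ = render_table(table)
    Path(path).write_text(tsv)


def read_table_tsv(path: str | Path) -> SatellitomeTable:
    """Read back a rendered table (footer rows are recomputed, not parsed)."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("Total", "Mean", "SD", "Median", ""):
                continue
            rows.append(
                FamilyStats(
                    name=parts[0],
                    genome_proportion=float(parts[1]),
                    monomer_length=int(float(parts[2])),
                    at_percent=float(parts[3]),
                    mean_k2p=float(parts[4]) if parts[4] else None,
                    tsi=float(parts[5]) if parts[5] else None,
                    divpeak=int(float(parts[6])) if parts[6] else None,
                    rsp=float(parts[7]) if parts[7] else None,
                )
            )
    return SatellitomeTable(rows=rows)


def write_landscape_csv(ls: Landscape, path: str | Path) -> None:
    """Landscape as a two-column CSV (divergence bin, abundance %)."""
    with open(path, "w") as fh:
        fh.write("divergence_bin,abundance_pct\n")
        for b in sorted(ls.bins):
            fh.write(f"{b},{ls.bins[b]:.8f}\n")
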