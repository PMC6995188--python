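"""Design reports in markdown and HTML.

The report echoes the inputs verbatim (so it is reproducible from the
config alone), summarises the solved design, and tabulates the operating
characteristics under H_G, H_A and every LFC_k.  Numbers are written at
full precision in the accompanying CSVs; the tables round for display
only.
"""

from __future__ import annotations

import datetime as _dt
import html as _html
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import spec_to_dict

__all__ = ["ReportBundle", "build_report", "markdown_to_html"]


@dataclass
class ReportBundle:
    markdown: str
    tables: dict
    plot_files: list
    config: dict


def _df_to_markdown(df: pd.DataFrame, ndp: int = 4) -> str:
    df = df.round(ndp)
    cols = [str(df.index.name or "")] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [("" if pd.isna(v) else f"{v:g}" if isinstance(v, float) else str(v))
                              for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def build_report(spec, result, opchar_df, curves=None,
                 plot_files=None) -> ReportBundle:
    """Assemble the design report."""
    cfg = spec_to_dict(spec)
    design = result.final_design
    thr = result.thresholds
    lines = [
        "# Multi-arm trial design report", "",
        f"Generated by polyarm {__version__} on "
        f"{_dt.date.today().isoformat()}.", "",
        "## Inputs", "",
    ]
    for k, v in cfg.items():
        lines.append(f"- `{k}`: {v}")
    lines += ["", "## Identified design", ""]
    lines.append(f"- control-arm size n0 = {design.n0:.4f}")
    for k, nk in enumerate(design.n, 1):
        lines.append(f"- n{k} = {nk:.4f} (ratio r{k} = {design.ratios[k-1]:.4f})")
    lines.append(f"- total sample size N = {design.total:.4f}")
    lines.append(f"- correction: {thr.mcc} ({thr.family}); "
                 "significance thresholds gamma = "
                 + ", ".join(f"{g:.6f}" for g in thr.gammas))
    lines.append(f"- controlled power: {result.power_type} >= {result.target}"
                 f"; achieved (continuous) = {result.achieved_power:.6f}")
    if result.integer_design is not None:
        lines.append("- integer design achieved power = "
                     f"{result.achieved_power_integer:.6f}")
    lines += ["", "## Operating characteristics", "",
              _df_to_markdown(opchar_df), ""]
    tables = {"opchar": opchar_df}
    if curves:
        for name, df in curves.items():
            tables[name] = df
    if plot_files:
        lines.append("## Plots")
        lines.append("")
        for p in plot_files:
            lines.append(f"![{Path(p).stem}]({Path(p).name})")
        lines.append("")
    return ReportBundle(markdown="\n".join(lines), tables=tables,
                        plot_files=list(plot_files or []), config=cfg)


def markdown_to_html(md: str) -> str:
    """Minimal markdown renderer covering the report's own constructs
    (headings, bullet lists, tables, inline code and images)."""
    out = ["<!DOCTYPE html><html><head><meta charset='utf-8'>",
           "<style>body{font-family:sans-serif;margin:2em}"
           "table{border-collapse:collapse}td,th{border:1px solid #999;"
           "padding:2px 6px;font-size:90%}</style></head><body>"]
    lines = md.split("\n")
    i = 0
    in_list = False
    while i < len(lines):
        line = lines[i]
        if line.startswith("|"):
            rows = []
            while i < len(lines) and lines[i].startswith("|"):
                cells = [c.strip() for c in lines[i].strip("|").split("|")]
                rows.append(cells)
                i += 1
            out.append("<table>")
            for r, cells in enumerate(rows):
                if r == 1:
                    continue  # separator row
                tag = "th" if r == 0 else "td"
                out.append("<tr>" + "".join(
                    f"<{tag}>{_inline(c)}</{tag}>" for c in cells) + "</tr>")
            out.append("</table>")
            continue
        if line.startswith("- "):
            if not in_list:
                out.append("<ul>")
                in_list = True
            out.append(f"<li>{_inline(line[2:])}</li>")
        else:
            if in_list:
                out.append("</ul>")
                in_list = False
            m = re.match(r"^(#{1,6})\s+(.*)$", line)
            if m:
                lvl = len(m.group(1))
                out.append(f"<h{lvl}>{_inline(m.group(2))}</h{lvl}>")
            elif line.strip():
                out.append(f"<p>{_inline(line)}</p>")
        i += 1
    if in_list:
        out.append("</ul>")
    out.append("</body></html>")
    return "\n".join(out)


def _inline(text: str) -> str:
    text = _html.escape(text)
    text = re.sub(r"!\[([^\]]*)\]\(([^)]+)\)",
                  r"<img src='\2' alt='\1' style='max-width:100%'>", text)
    text = re.sub(r"`([^`]+)`", r"<code>\1</code>", text)
    return text
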