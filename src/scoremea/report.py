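"""Static HTML report for enrichment results.

A self-contained document (no network assets): a click-to-sort table of
per-motif coefficients and p-values plus the run log.  Motif names and log
lines are HTML-escaped.
"""
from __future__ import annotations

import html
from typing import Iterable, Sequence

import pandas as pd

_SORT_JS = """
function sortTable(col) {
  var table = document.getElementById('results');
  var rows = Array.from(table.tBodies[0].rows);
  var dir = table.dataset['dir' + col] === 'asc' ? -1 : 1;
  table.dataset['dir' + col] = dir === 1 ? 'asc' : 'desc';
  rows.sort(function(a, b) {
    var x = a.cells[col].innerText, y = b.cells[col].innerText;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return dir * (nx - ny);
    return dir * x.localeCompare(y);
  });
  rows.forEach(function(r) { table.tBodies[0].appendChild(r); });
}
"""

_STYLE = """
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 4px 8px; }
th { cursor: pointer; background: #eee; }
"""


def render_html(results: pd.DataFrame, run_log: Iterable[str] | None = None) -> str:
    """Render enrichment results (a frame with motif/coefficient/p columns)
    and the run log as a standalone sortable HTML page.  Empty results give
    a placeholder page carrying only the log."""
    log_lines = list(run_log or [])
    log_html = "".join(f"<li>{html.escape(str(line))}</li>" for line in log_lines)
    if results is None or len(results) == 0:
        body = "<p>No enrichment results.</p>"
    else:
        header = "".join(
            f'<th onclick="sortTable({i})">{html.escape(str(c))}</th>'
            for i, c in enumerate(results.columns)
        )
        rows = []
        for _, row in results.iterrows():
            cells = "".join(f"<td>{html.escape(str(v))}</td>" for v in row)
            rows.append(f"<tr>{cells}</tr>")
        body = (
            f'<table id="results"><thead><tr>{header}</tr></thead>'
            f"<tbody>{''.join(rows)}</tbody></table>"
        )
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Motif enrichment report</title>"
        f"<style>{_STYLE}</style><script>{_SORT_JS}</script></head><body>"
        "<h1>Motif enrichment report</h1>"
        f"{body}"
        f"<h2>Run log</h2><ul>{log_html}</ul>"
        "</body></html>"
    )
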