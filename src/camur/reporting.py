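"""Static markdown reports mirroring a run's results page."""

from __future__ import annotations

from pathlib import Path
from typing import Union

from camur.kb import KnowledgeBase, QUERY_NAMES


def _table(columns, rows) -> str:
    head = "| " + " | ".join(str(c) for c in columns) + " |"
    sep = "|" + "|".join(" --- " for _ in columns) + "|"
    body = ["| " + " | ".join(str(v) for v in row) + " |" for row in rows]
    return "\n".join([head, sep, *body]) if rows else "\n".join([head, sep, "| (empty) " + "| " * (len(columns) - 1) + "|"])


def render_report(kb: KnowledgeBase, run_id: int,
                  dest: Union[str, Path, None] = None) -> str:
    """Render one run as a self-contained markdown document.

    Every number in the report comes from the stored run row or a
    knowledge-base query, so the report can be cross-checked against them.
    """
    info = kb.run_info(run_id)  # raises KeyError for unknown run ids
    lines: list[str] = []
    lines.append(f"# Run {run_id} report")
    lines.append("")
    lines.append("## Dataset")
    lines.append("")
    lines.append(_table(
        ["samples", "features", "fingerprint"],
        [(info["n_samples"], info["n_genes"], info["dataset_fingerprint"][:16])],
    ))
    lines.append("")
    lines.append("### Classes")
    lines.append("")
    lines.append(_table(
        ["class", "count", "percentage"],
        [(label, count, f"{pct:.2f}%") for label, count, pct in info["class_summary"]],
    ))
    lines.append("")
    lines.append("## Run")
    lines.append("")
    totals = info["manifest"]["totals"]
    lines.append(_table(
        ["mode", "iterations", "extracted rules", "extracted genes", "stop reason"],
        [(info["mode"], totals["iterations"], kb.query_rules(run_id).rows.__len__(),
          len(totals["distinct_genes"]), info["stop_reason"])],
    ))
    lines.append("")
    titles = {
        "features": "Features list",
        "conjunctions": "Literals and conjunctions list",
        "rules": "Rules list",
        "literal-stats": "Literals statistics",
        "pairs": "Feature pairs",
    }
    for name in QUERY_NAMES:
        result = kb.query(name, run_id)
        lines.append(f"## {titles[name]}")
        lines.append("")
        lines.append(_table(result.columns, result.rows))
        lines.append("")
    if not kb.query_rules(run_id).rows:
        lines.append("_0 extracted rules._")
        lines.append("")
    text = "\n".join(lines)
    if dest is not None:
        Path(dest).write_text(text, encoding="utf-8")
    return text
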