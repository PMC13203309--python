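"""Record formats and reviewable exports.

JSONL (one object per line) is the canonical record format — free-text
answers embed commas and newlines, which CSV handles only lossily. CSV
is offered as a convenience export. Scored records add a ``cenhov``
field (the exact 6-character case-coded tag) and a ``provenance`` field
(JSON text). The HTML grid export carries a text-equivalent description
of every cell's slot states, so the grid remains reviewable through a
screen reader or a plain-text diff.

Every malformed input is reported with its file and line number.
"""

from __future__ import annotations

import dataclasses
import html as _html
import json
import pathlib
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .audit_stats import ConditionSummary, DeltaResult, round_half_up
from .grid_view import AuditGrid, ClusterReport
from .rule_scoring import (
    GoldItem,
    NumericFact,
    ResponseRecord,
    ScoredRecord,
)
from .tag_model import SLOTS, TagError, format_tag, parse_tag

PathLike = Union[str, pathlib.Path]

_SLOT_MEANING = {
    "C": "clinically correct",
    "E": "evidence-supported",
    "N": "numerically concordant",
    "H": "hedged",
    "O": "ornamented",
    "V": "supported-error veneer",
}


class RecordFormatError(ValueError):
    """Malformed record file; message names the file and line."""


def _fail(path: PathLike, lineno: int, message: str) -> None:
    raise RecordFormatError(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# gold items

def _fact_to_dict(f: NumericFact) -> Dict[str, object]:
    d: Dict[str, object] = {"value": f.value, "unit": f.unit, "kind": f.kind}
    if f.high is not None:
        d["high"] = f.high
    return d


def _fact_from_dict(d: Mapping[str, object]) -> NumericFact:
    return NumericFact(
        value=float(d["value"]),  # type: ignore[arg-type]
        unit=str(d.get("unit", "")),
        kind=str(d.get("kind", "other")),
        high=float(d["high"]) if d.get("high") is not None else None,  # type: ignore[arg-type]
    )


def write_gold_items(items: Sequence[GoldItem], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as f:
        for it in items:
            d = dataclasses.asdict(it)
            d["required_numbers"] = [_fact_to_dict(x) for x in it.required_numbers]
            d["required_qualifiers"] = list(it.required_qualifiers)
            d["caveat_allowlist"] = list(it.caveat_allowlist)
            f.write(json.dumps(d, ensure_ascii=False) + "\n")


def read_gold_items(path: PathLike) -> List[GoldItem]:
    items: List[GoldItem] = []
    seen: set = set()
    for lineno, d in _read_jsonl(path):
        try:
            item = GoldItem(
                item_id=d["item_id"],
                doc_id=d["doc_id"],
                source_date=d["source_date"],
                question=d["question"],
                gold_answer=d["gold_answer"],
                evidence_sentence=d["evidence_sentence"],
                required_qualifiers=tuple(d.get("required_qualifiers", ())),
                required_numbers=tuple(
                    _fact_from_dict(x) for x in d.get("required_numbers", ())
                ),
                caveat_allowlist=tuple(d.get("caveat_allowlist", ())),
            )
        except (KeyError, ValueError, TypeError) as exc:
            _fail(path, lineno, f"invalid gold item: {exc}")
        if item.item_id in seen:
            _fail(path, lineno, f"duplicate item_id {item.item_id!r}")
        seen.add(item.item_id)
        items.append(item)
    return items


# ---------------------------------------------------------------------------
# responses and scored records

_CORE_RESPONSE_FIELDS = {"item_id", "regime", "answer_text", "cited_doc_id"}


def _read_jsonl(path: PathLike):
    with open(path, "r", encoding="utf-8") as f:
        for lineno, line in enumerate(f, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                _fail(path, lineno, f"malformed JSON: {exc}")
            if not isinstance(d, dict):
                _fail(path, lineno, "record must be a JSON object")
            yield lineno, d


def _response_from_dict(d: Mapping[str, object], path: PathLike, lineno: int) -> ResponseRecord:
    try:
        meta = dict(d.get("metadata", {}))  # type: ignore[arg-type]
        # unknown top-level fields are preserved in metadata
        for k, v in d.items():
            if k not in _CORE_RESPONSE_FIELDS | {"metadata", "cenhov", "provenance"}:
                meta[k] = v
        return ResponseRecord(
            item_id=str(d["item_id"]),
            regime=str(d.get("regime", "")),
            answer_text=str(d["answer_text"]),
            cited_doc_id=(None if d.get("cited_doc_id") in (None, "") else str(d["cited_doc_id"])),
            metadata=meta,
        )
    except KeyError as exc:
        _fail(path, lineno, f"missing field {exc}")
        raise  # unreachable


def write_responses(records: Sequence[ResponseRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as f:
        for r in records:
            f.write(json.dumps(_response_dict(r), ensure_ascii=False) + "\n")


def _response_dict(r: ResponseRecord) -> Dict[str, object]:
    return {
        "item_id": r.item_id,
        "regime": r.regime,
        "answer_text": r.answer_text,
        "cited_doc_id": r.cited_doc_id,
        "metadata": dict(r.metadata),
    }


def read_responses(path: PathLike, format: str = "jsonl") -> List[ResponseRecord]:
    if format == "csv":
        frame = pd.read_csv(path, dtype=str).fillna("")
        out = []
        for i, row in frame.iterrows():
            d = row.to_dict()
            out.append(_response_from_dict(d, path, int(i) + 2))
        return out
    if format != "jsonl":
        raise ValueError(f"unknown format {format!r}; expected jsonl or csv")
    return [_response_from_dict(d, path, lineno) for lineno, d in _read_jsonl(path)]


def write_scored(records: Sequence[ScoredRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as f:
        for r in records:
            d = _response_dict(r.response)
            d["cenhov"] = format_tag(r.tag)
            d["provenance"] = json.dumps(r.provenance, ensure_ascii=False)
            f.write(json.dumps(d, ensure_ascii=False) + "\n")


def read_scored(path: PathLike) -> List[ScoredRecord]:
    out: List[ScoredRecord] = []
    for lineno, d in _read_jsonl(path):
        if "cenhov" not in d:
            _fail(path, lineno, "scored record is missing the 'cenhov' field")
        try:
            tag = parse_tag(str(d["cenhov"]), strict=True)
        except TagError as exc:
            _fail(path, lineno, f"invalid tag text {d['cenhov']!r}: {exc}")
        prov = d.get("provenance", "{}")
        provenance = json.loads(prov) if isinstance(prov, str) else prov
        out.append(
            ScoredRecord(
                response=_response_from_dict(d, path, lineno),
                tag=tag,
                provenance=provenance,
            )
        )
    return out


def scored_to_csv(records: Sequence[ScoredRecord], path: PathLike) -> None:
    """Lossy convenience export (answer text is CSV-quoted)."""
    rows = []
    for r in records:
        d = _response_dict(r.response)
        d["metadata"] = json.dumps(d["metadata"], ensure_ascii=False)
        d["cenhov"] = format_tag(r.tag)
        d["provenance"] = json.dumps(r.provenance, ensure_ascii=False)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid and table exports

def grid_to_text(grid: AuditGrid) -> str:
    """One 6-character tag per cell, space-separated, one row per line."""
    return "\n".join(
        " ".join(format_tag(cell.tag) for cell in row) for row in grid.rows()
    ) + "\n"


def grid_to_frame(grid: AuditGrid) -> pd.DataFrame:
    rows = []
    for k, cell in enumerate(grid.cells):
        r, c = grid.position(k)
        rows.append(
            {"row": r, "col": c, "item_id": cell.response.item_id,
             "cenhov": format_tag(cell.tag)}
        )
    return pd.DataFrame(rows)


def describe_tag_states(tag) -> str:
    """Text-equivalent slot description, e.g. for screen readers."""
    parts = [
        f"{_SLOT_MEANING[s]}: {'yes' if tag.slot(s) else 'no'}" for s in SLOTS
    ]
    return "; ".join(parts)


def grid_to_html(grid: AuditGrid, title: str = "CEAG audit grid") -> str:
    """HTML table; each cell carries a text-equivalent slot description."""
    out = [
        "<table>",
        f"<caption>{_html.escape(title)} "
        f"(ordering {_html.escape(grid.ordering)}, width {grid.width})</caption>",
        "<thead><tr><th scope=\"col\">row</th>"
        + "".join(f"<th scope=\"col\">c{c}</th>" for c in range(grid.width))
        + "</tr></thead>",
        "<tbody>",
    ]
    for r, row in enumerate(grid.rows()):
        cells = []
        for cell in row:
            text = format_tag(cell.tag)
            desc = (
                f"{cell.response.item_id}: {describe_tag_states(cell.tag)}"
            )
            cells.append(
                f"<td><span title=\"{_html.escape(desc)}\" "
                f"aria-label=\"{_html.escape(desc)}\">{text}</span></td>"
            )
        out.append(f"<tr><th scope=\"row\">r{r}</th>" + "".join(cells) + "</tr>")
    out += ["</tbody>", "</table>"]
    return "\n".join(out) + "\n"


SUMMARY_COLUMNS = [
    "condition", "n", "correct_pct", "correct_ci", "support_pct", "support_ci",
    "numeric_pct", "numeric_ci", "veneer_pct", "veneer_ci",
]


def summary_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Condition-by-condition rate table with Wilson CIs, one row per regime."""
    frame = pd.DataFrame([s.row() for s in summaries])
    return frame[SUMMARY_COLUMNS]


def delta_frame(result: DeltaResult) -> pd.DataFrame:
    rows = [
        {"item_id": item, "differing_slots": "".join(sorted(slots, key=SLOTS.index))}
        for item, slots in sorted(result.per_item.items())
    ]
    return pd.DataFrame(rows)


def cluster_frame(report: ClusterReport) -> pd.DataFrame:
    rows = []
    for r in report.rows:
        rows.append(
            {
                "doc_id": r.doc_id,
                "items_in_block": r.items_in_block,
                "predicate_hits": r.predicate_hits,
                "block_rate_pct": round_half_up(100.0 * r.block_rate),
                "share_of_all_hits_pct": (
                    round_half_up(100.0 * r.share_of_all_hits)
                    if report.total_hits else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
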