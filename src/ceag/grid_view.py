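"""Audit grids: ordering, adjacency continuity, and per-source clustering.

A scored dataset becomes a rectangular, row-major grid of tags. Ordering
changes only the arrangement of cells — never any rate computed from
them — but determines what local structure a reviewer can see:
``STRIPES_BY_DOC`` keeps each source passage's items contiguous so
source-linked clusters stand out; ``TIME_SERIES`` sorts by source date.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

from .rule_scoring import GoldItem, ScoredRecord
from .tag_model import CenhovTag

ORDERINGS = ("STRIPES_BY_DOC", "TIME_SERIES", "AS_GIVEN")


def _doc_sort_key(doc_id: str) -> Tuple:
    # numeric-aware: D4 sorts before D10
    import re

    parts = re.split(r"(\d+)", doc_id)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def order_records(
    records: Sequence[ScoredRecord],
    rule: str,
    gold_catalog: Mapping[str, GoldItem],
) -> List[ScoredRecord]:
    """Stable-sort scored records under an ordering rule.

    STRIPES_BY_DOC: (doc_id ascending, item_id ascending).
    TIME_SERIES: (source_date ascending, doc_id, item_id).
    AS_GIVEN: input order preserved. Output is always a permutation of
    the input.
    """
    if rule not in ORDERINGS:
        raise ValueError(f"unknown ordering rule {rule!r}; expected one of {ORDERINGS}")
    for r in records:
        if r.response.item_id not in gold_catalog:
            raise KeyError(f"unresolvable item_id {r.response.item_id!r}")
    if rule == "AS_GIVEN":
        return list(records)

    def gold(r: ScoredRecord) -> GoldItem:
        return gold_catalog[r.response.item_id]

    if rule == "STRIPES_BY_DOC":
        key: Callable[[ScoredRecord], Tuple] = lambda r: (
            _doc_sort_key(gold(r).doc_id),
            _doc_sort_key(r.response.item_id),
        )
    else:  # TIME_SERIES — ISO dates compare lexicographically
        key = lambda r: (
            gold(r).source_date,
            _doc_sort_key(gold(r).doc_id),
            _doc_sort_key(r.response.item_id),
        )
    return sorted(records, key=key)


@dataclass(frozen=True)
class AuditGrid:
    """Row-major grid of scored records; cell k sits at (k // width, k % width)."""

    cells: Tuple[ScoredRecord, ...]
    width: int
    ordering: str = "AS_GIVEN"

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("grid width must be >= 1")

    @property
    def n_rows(self) -> int:
        return (len(self.cells) + self.width - 1) // self.width

    def position(self, k: int) -> Tuple[int, int]:
        return divmod(k, self.width)[0], k % self.width

    def index(self, row: int, col: int) -> int:
        k = row * self.width + col
        if col >= self.width or k >= len(self.cells):
            raise IndexError(f"no cell at ({row}, {col})")
        return k

    def rows(self) -> List[List[ScoredRecord]]:
        return [
            list(self.cells[i : i + self.width])
            for i in range(0, len(self.cells), self.width)
        ]


def build_grid(
    ordered: Sequence[ScoredRecord], width: int, ordering: str = "AS_GIVEN"
) -> AuditGrid:
    """Lay out already-ordered records row-major; last row may be partial."""
    return AuditGrid(cells=tuple(ordered), width=width, ordering=ordering)


def adjacency_match(grid: AuditGrid) -> float:
    """Percentage of horizontally/vertically adjacent cells sharing a full tag.

    No diagonals, no wraparound; pairs exist only between occupied
    cells. A descriptive continuity measure, not a clinical endpoint.
    """
    n = len(grid.cells)
    w = grid.width
    total = 0
    same = 0
    for k in range(n):
        row, col = divmod(k, w)
        # right neighbor
        if col + 1 < w and k + 1 < n:
            total += 1
            same += grid.cells[k].tag == grid.cells[k + 1].tag
        # down neighbor
        if k + w < n:
            total += 1
            same += grid.cells[k].tag == grid.cells[k + w].tag
    if total == 0:
        raise ValueError("adjacency match undefined: grid has no adjacent pair")
    return 100.0 * same / total


@dataclass(frozen=True)
class BlockRow:
    doc_id: str
    items_in_block: int
    predicate_hits: int
    block_rate: float  # hits / items_in_block
    share_of_all_hits: float  # hits / total hits across blocks; nan when no hits


@dataclass(frozen=True)
class ClusterReport:
    """Per-source-passage concentration of a tag predicate."""

    rows: Tuple[BlockRow, ...]
    total_hits: int
    total_items: int

    def row_for(self, doc_id: str) -> BlockRow:
        for r in self.rows:
            if r.doc_id == doc_id:
                return r
        raise KeyError(f"no block {doc_id!r} in report")


def block_report(
    records: Sequence[ScoredRecord],
    predicate: Callable[[CenhovTag], bool],
    gold_catalog: Mapping[str, GoldItem],
) -> ClusterReport:
    """Count predicate hits per source passage and each block's share of hits.

    ``predicate`` is any condition over a tag, e.g. ``lambda t: t.v == 1``.
    """
    if not records:
        raise ValueError("block report requires at least one record")
    per_doc: Dict[str, List[ScoredRecord]] = {}
    for r in records:
        item = r.response.item_id
        if item not in gold_catalog:
            raise KeyError(f"unresolvable item_id {item!r}")
        per_doc.setdefault(gold_catalog[item].doc_id, []).append(r)
    total_hits = sum(
        1 for r in records if predicate(r.tag)
    )
    rows = []
    for doc_id in sorted(per_doc, key=_doc_sort_key):
        block = per_doc[doc_id]
        hits = sum(1 for r in block if predicate(r.tag))
        rows.append(
            BlockRow(
                doc_id=doc_id,
                items_in_block=len(block),
                predicate_hits=hits,
                block_rate=hits / len(block),
                share_of_all_hits=(hits / total_hits) if total_hits else float("nan"),
            )
        )
    return ClusterReport(rows=tuple(rows), total_hits=total_hits, total_items=len(records))
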