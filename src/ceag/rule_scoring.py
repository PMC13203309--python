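"""Rule-based assignment of the C, E, N, H, O slots against a gold item.

Every scorer is deterministic, auditable and purely lexical: the goal is
a reproducible audit surface, not semantic entailment. Each slot scorer
returns a bit plus a list of human-readable reasons (provenance); a 0 on
C, E or N always carries at least one reason.

Conventions:

* Correctness (C) checks that every required qualifier phrase appears in
  the normalized answer and that no number the answer asserts for a
  required slot contradicts the gold value. Omitting a required number
  is not a C failure (that is N's job); omitting a required *qualifier*
  is. C flags the presence of an error, never its severity.
* Evidential support (E) is assessed at topic level: the cited document
  must be the gold document and the item's topic anchor phrase (the
  first required qualifier) must appear in both the answer and the gold
  evidence sentence. E is deliberately independent of the answer's
  numbers being right — otherwise the supported-error veneer state
  (E=1, C=0) could never arise from a numeric error. Records whose E=1
  rests only on this topic-anchor check are flagged in provenance so a
  human reviewer can override.
* Numeric concordance (N) requires every gold-required number to appear
  in the answer with equal value and compatible unit, and every number
  the answer states to be present in the gold evidence sentence (no
  unsupported extras).
* Hedging (H) fires on lexicon words at word boundaries, outside
  allowlisted caveat spans. Ornamentation (O) fires on caps runs,
  exclamation marks, decorative glyph clusters or configured
  promotional phrases, and never alters C, E or N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .tag_model import CenhovTag

# ---------------------------------------------------------------------------
# numeric facts

FactKind = str  # dose | threshold | age_range | date | interval | count | other

_UNIT_KINDS: Dict[str, FactKind] = {
    "mg": "dose", "mcg": "dose", "g": "dose", "ml": "dose", "l": "dose",
    "mmhg": "threshold", "mmol/l": "threshold", "mg/dl": "threshold",
    "%": "threshold",
    "hour": "interval", "day": "interval", "week": "interval",
    "month": "interval", "year": "interval", "minute": "interval",
    "dose": "count", "time": "count", "visit": "count", "case": "count",
}

_TIME_UNITS = {"hour", "day", "week", "month", "year", "minute"}
_AGE_CUE = re.compile(r"\bage[ds]?\b", re.IGNORECASE)
_NUM = r"\d+(?:\.\d+)?"
_RANGE_RE = re.compile(rf"({_NUM})\s*(?:[–—−-]|\bto\b)\s*({_NUM})")
_NUMBER_RE = re.compile(rf"({_NUM})\s*(%)|({_NUM})(?:\s+([A-Za-z][A-Za-z/]*))?")


def _normalize_unit(unit: str) -> str:
    u = unit.strip().lower().rstrip(".")
    if u.endswith("s") and u[:-1] in _UNIT_KINDS:
        u = u[:-1]
    return u if u in _UNIT_KINDS else ("" if not u else u)


@dataclass(frozen=True)
class NumericFact:
    """One number (or range) with its unit and inferred kind."""

    value: float
    unit: str = ""
    kind: FactKind = "other"
    high: Optional[float] = None  # upper bound for range facts

    def __post_init__(self) -> None:
        if not (self.value == self.value and abs(self.value) != float("inf")):
            raise ValueError("fact value must be finite")
        if self.high is not None and self.high < self.value:
            raise ValueError("range bounds must be ordered low <= high")

    @property
    def is_range(self) -> bool:
        return self.high is not None

    def describe(self) -> str:
        span = f"{self.value:g}" if self.high is None else f"{self.value:g}-{self.high:g}"
        return f"{span} {self.unit}".strip() + f" ({self.kind})"


def _values_equal(a: float, b: float) -> bool:
    # exact for integers, tight relative tolerance for decimals
    if float(a).is_integer() and float(b).is_integer():
        return a == b
    return abs(a - b) <= 1e-9 * max(1.0, abs(a), abs(b))


def facts_match(a: NumericFact, b: NumericFact) -> bool:
    """Value/unit/range-shape equality; ``kind`` is informational only."""
    if a.is_range != b.is_range:
        return False
    if not _values_equal(a.value, b.value):
        return False
    if a.is_range and not _values_equal(a.high, b.high):  # type: ignore[arg-type]
        return False
    return _normalize_unit(a.unit) == _normalize_unit(b.unit)


def _infer_kind(unit: str, context_before: str, is_range: bool) -> FactKind:
    u = _normalize_unit(unit)
    if is_range:
        if _AGE_CUE.search(context_before[-40:]):
            return "age_range"
        if u in _TIME_UNITS:
            return "interval"
        return "other"
    if re.search(r"\bevery\b|\beach\b", context_before[-16:], re.IGNORECASE) and u in _TIME_UNITS:
        return "interval"
    return _UNIT_KINDS.get(u, "other")


def extract_numeric_facts(text: str) -> List[NumericFact]:
    """Extract every numeric token with its attached unit and inferred kind.

    Recognized: integers and decimals, percentages, simple ranges
    ("45-75", "45 to 75"), numbers followed by a known unit word, and
    bare 4-digit years (1900-2099, scored as dates). Hedge words and
    ornament markers never suppress extraction.
    """
    if not text:
        return []
    located: List[Tuple[int, NumericFact]] = []
    consumed = [False] * len(text)

    for m in _RANGE_RE.finditer(text):
        lo, hi = float(m.group(1)), float(m.group(2))
        if hi < lo:
            continue  # not a plausible range; leave for scalar pass
        unit = ""
        after = text[m.end():]
        unit_m = re.match(r"\s+([A-Za-z][A-Za-z/]*)", after)
        if unit_m and _normalize_unit(unit_m.group(1)) in _UNIT_KINDS:
            unit = _normalize_unit(unit_m.group(1))
        kind = _infer_kind(unit, text[: m.start()], is_range=True)
        located.append((m.start(), NumericFact(lo, unit, kind, high=hi)))
        for i in range(m.start(), m.end()):
            consumed[i] = True

    for m in re.finditer(rf"({_NUM})", text):
        if any(consumed[i] for i in range(m.start(), m.end())):
            continue
        raw = m.group(1)
        value = float(raw)
        after = text[m.end():]
        unit = ""
        if re.match(r"\s?%", after):
            unit = "%"
        else:
            unit_m = re.match(r"\s+([A-Za-z][A-Za-z/]*)", after)
            if unit_m and _normalize_unit(unit_m.group(1)) in _UNIT_KINDS:
                unit = _normalize_unit(unit_m.group(1))
        if not unit and re.fullmatch(r"(19|20)\d\d", raw):
            located.append((m.start(), NumericFact(value, "", "date")))
            continue
        located.append(
            (m.start(), NumericFact(value, unit, _infer_kind(unit, text[: m.start()], False)))
        )
    located.sort(key=lambda pair: pair[0])
    return [fact for _, fact in located]


# ---------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class GoldItem:
    """One grounded QA item: question, gold answer, evidence sentence.

    The corpus is self-grounding: every required number is textually
    present in ``evidence_sentence``. The first required qualifier acts
    as the item's topic anchor phrase for the E scorer.
    """

    item_id: str
    doc_id: str
    source_date: str  # ISO-8601 calendar date
    question: str
    gold_answer: str
    evidence_sentence: str
    required_qualifiers: Tuple[str, ...] = ()
    required_numbers: Tuple[NumericFact, ...] = ()
    caveat_allowlist: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        evid = extract_numeric_facts(self.evidence_sentence)
        for req in self.required_numbers:
            if not any(facts_match(req, f) for f in evid):
                raise ValueError(
                    f"{self.item_id}: required number {req.describe()} not "
                    f"present in evidence sentence (corpus must self-ground)"
                )

    @property
    def topic_anchor(self) -> Optional[str]:
        return self.required_qualifiers[0] if self.required_qualifiers else None


@dataclass(frozen=True)
class ResponseRecord:
    """One response to be audited, keyed to a gold item."""

    item_id: str
    regime: str
    answer_text: str
    cited_doc_id: Optional[str] = None
    metadata: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoredRecord:
    """A response joined to its tag and per-slot rule provenance."""

    response: ResponseRecord
    tag: CenhovTag
    provenance: Mapping[str, Mapping[str, object]]


DEFAULT_HEDGE_LEXICON: Tuple[str, ...] = ("may", "might", "possibly", "uncertain", "likely")
DEFAULT_GLYPHS = "★✦●▶■◆✧☆"  # ★ ✦ ● ▶ ■ ◆ ✧ ☆


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable lexicons and marker rules for the H and O scorers.

    The hedge lexicon defaults to the five canonical uncertainty markers
    and is extended only through configuration, never in code.
    """

    hedge_lexicon: Tuple[str, ...] = DEFAULT_HEDGE_LEXICON
    ornament_glyphs: str = DEFAULT_GLYPHS
    min_glyphs: int = 3
    caps_run_min_words: int = 2
    caps_word_min_len: int = 4
    promo_phrases: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.hedge_lexicon:
            raise ValueError("hedge lexicon must be non-empty")


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)


def normalize_text(text: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace (no stemming)."""
    return " ".join(_PUNCT_RE.sub(" ", text.casefold()).split())


# ---------------------------------------------------------------------------
# slot scorers

def score_correct(response: ResponseRecord, gold: GoldItem) -> Tuple[int, List[str]]:
    """C: gold-answer match — qualifiers all present, no contradicted number."""
    reasons: List[str] = []
    norm_answer = normalize_text(response.answer_text)
    for q in gold.required_qualifiers:
        if normalize_text(q) not in norm_answer:
            reasons.append(f"missing required qualifier: {q!r}")
    answer_facts = extract_numeric_facts(response.answer_text)
    for req in gold.required_numbers:
        slot_candidates = [
            f for f in answer_facts
            if f.is_range == req.is_range
            and _normalize_unit(f.unit) == _normalize_unit(req.unit)
        ]
        if slot_candidates and not any(facts_match(req, f) for f in slot_candidates):
            stated = ", ".join(f.describe() for f in slot_candidates)
            reasons.append(
                f"contradicted required number: gold {req.describe()}, answer states {stated}"
            )
    if reasons:
        return 0, reasons
    return 1, ["all required qualifiers present; no contradicted required number"]


def score_cite(response: ResponseRecord, gold: GoldItem) -> Tuple[int, List[str]]:
    """E: cited document matches and topic anchor is present (topic-level)."""
    if response.cited_doc_id is None:
        return 0, ["no citation given"]
    if response.cited_doc_id != gold.doc_id:
        return 0, [
            f"cited {response.cited_doc_id!r} but gold source is {gold.doc_id!r}"
        ]
    anchor = gold.topic_anchor
    if anchor is not None:
        norm_anchor = normalize_text(anchor)
        if norm_anchor not in normalize_text(response.answer_text):
            return 0, [f"topic anchor {anchor!r} absent from answer"]
        if norm_anchor not in normalize_text(gold.evidence_sentence):
            return 0, [f"topic anchor {anchor!r} absent from evidence sentence"]
    return 1, [
        "cited doc matches gold source; topic anchor present in answer and "
        "evidence (topic-anchor-only support check — reviewer may override)"
    ]


def score_numeric(response: ResponseRecord, gold: GoldItem) -> Tuple[int, List[str]]:
    """N: all required numbers present and concordant, no unsupported extras."""
    answer_facts = extract_numeric_facts(response.answer_text)
    evidence_facts = extract_numeric_facts(gold.evidence_sentence)
    for req in gold.required_numbers:
        if not any(facts_match(req, f) for f in answer_facts):
            return 0, [f"required number omitted or wrong: {req.describe()}"]
    for f in answer_facts:
        if not any(facts_match(f, ev) for ev in evidence_facts):
            return 0, [f"unsupported number in answer: {f.describe()}"]
    matched = ", ".join(r.describe() for r in gold.required_numbers) or "none required"
    return 1, [f"all required numbers concordant ({matched}); no unsupported extras"]


def score_hedge(
    answer_text: str,
    allowlist: Sequence[str] = (),
    lexicon: Sequence[str] = DEFAULT_HEDGE_LEXICON,
) -> Tuple[int, List[str]]:
    """H: lexicon word at a word boundary, outside allowlisted caveats."""
    if not lexicon:
        raise ValueError("hedge lexicon must be non-empty")
    masked = answer_text
    for phrase in allowlist:
        if phrase:
            masked = re.sub(re.escape(phrase), " " * len(phrase), masked, flags=re.IGNORECASE)
    hits: List[str] = []
    for word in lexicon:
        if re.search(rf"\b{re.escape(word)}\b", masked, re.IGNORECASE):
            hits.append(word)
    if hits:
        return 1, [f"hedge lexicon hit: {', '.join(hits)}"]
    return 0, ["no hedge lexicon word outside allowlisted caveats"]


def score_ornament(
    answer_text: str, config: ScoringConfig = ScoringConfig()
) -> Tuple[int, List[str]]:
    """O: caps runs, exclamation marks, glyph clusters or promo phrases."""
    reasons: List[str] = []
    w = config.caps_word_min_len
    caps_run = re.compile(
        rf"\b[A-Z]{{{w},}}(?:\s+[A-Z]{{{w},}}){{{config.caps_run_min_words - 1},}}\b"
    )
    m = caps_run.search(answer_text)
    if m:
        reasons.append(f"capitalized run: {m.group(0)!r}")
    if "!" in answer_text:
        reasons.append("exclamation mark present")
    glyph_count = sum(answer_text.count(g) for g in config.ornament_glyphs)
    if glyph_count >= config.min_glyphs:
        reasons.append(f"{glyph_count} decorative glyphs")
    for phrase in config.promo_phrases:
        if phrase.casefold() in answer_text.casefold():
            reasons.append(f"promotional phrase: {phrase!r}")
    if reasons:
        return 1, reasons
    return 0, ["no ornament marker fired"]


def score_record(
    response: ResponseRecord,
    gold: GoldItem,
    config: ScoringConfig = ScoringConfig(),
) -> ScoredRecord:
    """Compose the five slot scorers and derive V."""
    if response.item_id != gold.item_id:
        raise KeyError(
            f"response item_id {response.item_id!r} does not resolve to gold "
            f"item {gold.item_id!r}"
        )
    c, c_why = score_correct(response, gold)
    e, e_why = score_cite(response, gold)
    n, n_why = score_numeric(response, gold)
    h, h_why = score_hedge(response.answer_text, gold.caveat_allowlist, config.hedge_lexicon)
    o, o_why = score_ornament(response.answer_text, config)
    tag = CenhovTag.from_flags(c, e, n, h, o)
    provenance = {
        "C": {"value": c, "reasons": c_why},
        "E": {"value": e, "reasons": e_why},
        "N": {"value": n, "reasons": n_why},
        "H": {"value": h, "reasons": h_why},
        "O": {"value": o, "reasons": o_why},
        "V": {"value": tag.v, "reasons": [f"derived from E={e}, C={c}"]},
    }
    return ScoredRecord(response=response, tag=tag, provenance=provenance)


def score_all(
    responses: Sequence[ResponseRecord],
    catalog: Mapping[str, GoldItem],
    config: ScoringConfig = ScoringConfig(),
) -> List[ScoredRecord]:
    """Score a batch of responses against a gold catalog keyed by item_id."""
    out = []
    for r in responses:
        if r.item_id not in catalog:
            raise KeyError(f"unresolvable item_id {r.item_id!r}")
        out.append(score_record(r, catalog[r.item_id], config))
    return out
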