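"""Synthetic stress-test benchmark: corpus, gold items, scripted regimes.

The controlled benchmark is entirely fictional: 30 guideline-style
source passages (dosing, screening-interval, threshold, update-date and
count topics) carrying 120 grounded QA items, each with one gold answer
and one evidence sentence, so correctness, citation support and numeric
concordance are controlled exactly. Four scripted response regimes
(RUSH, VERIFY, POETIC, POSTER) emulate presentation styles a monitoring
team might compare; no live model is queried.

Responses are built by *inverting* the rule scorers: an intended
(C, E, N, H, O) flag vector is realized as text perturbations —
wrong-number substitution for C=0, omitted or mis-pointed citation for
E=0, an unsupported extra number for N=0, a lexicon hedge for H=1,
ornament markers for O=1 — and every generated record is re-scored to
assert it round-trips to its intended flags exactly.

Flag allocation is count-exact (every marginal is hit exactly, not in
expectation). The default layout — including which items err in which
regime, which drives paired masked-delta percentages — ships as a
fixture-pinned plan in ``data/regime_flag_plan.json``; per-item overlap
across regimes is a design artifact, not derivable from marginal rates.
``allocate_flags`` provides seeded count-exact allocation for custom
profiles.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .rule_scoring import (
    GoldItem,
    NumericFact,
    ResponseRecord,
    ScoringConfig,
    extract_numeric_facts,
    facts_match,
    score_record,
)

REGIMES = ("RUSH", "VERIFY", "POETIC", "POSTER")


# ---------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class RegimeJointProfile:
    """Exact joint (C, E) cell counts plus N, H, O marginals for one regime."""

    regime: str
    n: int
    k11: int  # C=1, E=1
    k10: int  # C=1, E=0
    k01: int  # C=0, E=1  (the veneer cell: V count)
    k00: int  # C=0, E=0
    n_count: int
    h_count: int
    o_count: int

    def __post_init__(self) -> None:
        if self.k11 + self.k10 + self.k01 + self.k00 != self.n:
            raise ValueError(f"{self.regime}: joint cells must sum to n")
        if self.n_count > self.k11 + self.k10:
            raise ValueError(
                f"{self.regime}: N=1 count exceeds C=1 count — numeric "
                f"concordance cannot coexist with a wrong-number error"
            )
        for name in ("k11", "k10", "k01", "k00", "n_count", "h_count", "o_count"):
            if getattr(self, name) < 0 or getattr(self, name) > self.n:
                raise ValueError(f"{self.regime}: {name} out of range")

    @property
    def c_count(self) -> int:
        return self.k11 + self.k10

    @property
    def e_count(self) -> int:
        return self.k11 + self.k01

    @property
    def v_count(self) -> int:
        return self.k01


DEFAULT_SYNTH_PROFILES: Dict[str, RegimeJointProfile] = {
    "RUSH": RegimeJointProfile("RUSH", 120, 81, 7, 31, 1, 25, 13, 0),
    "VERIFY": RegimeJointProfile("VERIFY", 120, 116, 0, 4, 0, 38, 0, 0),
    "POETIC": RegimeJointProfile("POETIC", 120, 72, 26, 18, 4, 25, 60, 6),
    "POSTER": RegimeJointProfile("POSTER", 120, 106, 3, 11, 0, 26, 0, 120),
}

DEFAULT_PUBLIC_PROFILES: Dict[str, RegimeJointProfile] = {
    "RUSH": RegimeJointProfile("RUSH", 12, 4, 0, 8, 0, 3, 1, 0),
    "VERIFY": RegimeJointProfile("VERIFY", 12, 12, 0, 0, 0, 6, 0, 0),
    "POETIC": RegimeJointProfile("POETIC", 12, 10, 0, 2, 0, 5, 8, 1),
    "POSTER": RegimeJointProfile("POSTER", 12, 12, 0, 0, 0, 6, 0, 12),
}


@dataclass(frozen=True)
class Flags:
    """Intended slot values for one rendered response (V always derived)."""

    c: int
    e: int
    n: int
    h: int
    o: int

    def __post_init__(self) -> None:
        if self.n == 1 and self.c == 0:
            raise ValueError(
                "infeasible flags: N=1 with C=0 — the wrong-number "
                "perturbation that realizes C=0 always breaks concordance"
            )


@dataclass(frozen=True)
class PassageSpec:
    """One fictional source passage; items share its evidence sentence."""

    doc_id: str
    topic: str
    evidence_sentence: str
    source_date: str
    items_per_passage: int


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration for the generated benchmark. All randomness flows
    from ``seed``; counts never depend on it (surface text does)."""

    seed: int = 20260
    n_passages: int = 30
    n_items: int = 120
    cluster_doc_index: int = 3  # D4 carries the 9-item block
    cluster_items: int = 9
    profiles: Mapping[str, RegimeJointProfile] = field(
        default_factory=lambda: dict(DEFAULT_SYNTH_PROFILES)
    )
    public_profiles: Mapping[str, RegimeJointProfile] = field(
        default_factory=lambda: dict(DEFAULT_PUBLIC_PROFILES)
    )
    use_packaged_plan: bool = True
    grid_width: int = 12
    public_grid_width: int = 4


def load_flag_plan() -> Mapping[str, object]:
    """The packaged fixture-pinned per-item flag layout."""
    with resources.files("ceag.data").joinpath("regime_flag_plan.json").open() as f:
        return json.load(f)


def _plan_flags(plan_section: Mapping[str, object], regime: str, n: int) -> List[Flags]:
    g = plan_section["regimes"][regime]  # type: ignore[index]
    ce01, ce10, ce00 = set(g["ce01"]), set(g["ce10"]), set(g["ce00"])
    n1, h1, o1 = set(g["n1"]), set(g["h1"]), set(g["o1"])
    out = []
    for i in range(n):
        c = 0 if (i in ce01 or i in ce00) else 1
        e = 0 if (i in ce10 or i in ce00) else 1
        out.append(Flags(c, e, int(i in n1), int(i in h1), int(i in o1)))
    return out


# ---------------------------------------------------------------------------
# fictional corpus

_DRUG_STEMS = ("vel", "dor", "mex", "lan", "tre", "sor", "pal", "nev", "qui", "bar")
_DRUG_SUFFIXES = ("prazole", "amide", "ipril", "idine", "oxib", "ustat")
_SURNAMES = (
    "Arlen", "Borel", "Calden", "Darrow", "Elvas", "Farrin", "Gorse",
    "Halden", "Imbre", "Jorvik", "Kestrel", "Lorn", "Marrow", "Norrel",
    "Ostin", "Pellar",
)
_POPULATIONS = ("adults", "older adults", "adolescents", "pregnant patients")
_TOPICS = ("dosing", "screening", "threshold", "update_date", "count")


def _items_plan(config: BenchmarkConfig) -> List[int]:
    """Items per passage: one cluster block, remainder split as evenly as
    possible with earlier passages taking the extras (default plan:
    D4 carries 9, 24 passages carry 4, the last 5 carry 3; 9+96+15=120)."""
    n_p, total = config.n_passages, config.n_items
    if n_p < 1 or not (1 <= config.cluster_items <= total):
        raise ValueError("item plan inconsistent with passage count")
    rest_n = n_p - 1
    rest_total = total - config.cluster_items
    if rest_n == 0:
        if rest_total != 0:
            raise ValueError("item plan inconsistent with passage count")
        return [config.cluster_items]
    base, extra = divmod(rest_total, rest_n)
    if base < 1:
        raise ValueError(
            f"item plan inconsistent: {n_p} passages cannot carry "
            f"{total} items with a {config.cluster_items}-item cluster block"
        )
    counts = []
    given = 0
    for i in range(n_p):
        if i == config.cluster_doc_index:
            counts.append(config.cluster_items)
        else:
            counts.append(base + (1 if given < extra else 0))
            given += 1
    return counts


_QUESTION_FORMS = (
    "What does the guidance state about {subject}?",
    "Restate the current recommendation on {subject}.",
    "According to the source passage, what applies to {subject}?",
    "Summarize the guidance for {subject}.",
    "What is recommended regarding {subject}?",
    "For review: what does the passage say about {subject}?",
    "State the recommendation covering {subject}.",
    "What rule does the guidance give for {subject}?",
    "Which recommendation applies to {subject}?",
)

CAVEAT_PHRASE = "dosing may vary with kidney function"


def _passage_content(
    topic: str, rng: random.Random, drug: str, condition: str, population: str
) -> Tuple[str, Tuple[NumericFact, ...], Tuple[str, ...], str]:
    """Returns (evidence sentence, required numbers, qualifiers, subject)."""
    if topic == "dosing":
        dose = rng.choice((100, 150, 200, 250, 300, 400, 500, 600, 750))
        hours = rng.choice((6, 8, 12, 24))
        evidence = (
            f"For {population} with {condition}, {drug} is given at "
            f"{dose} mg every {hours} hours."
        )
        numbers = (
            NumericFact(dose, "mg", "dose"),
            NumericFact(hours, "hour", "interval"),
        )
        return evidence, numbers, (drug, condition, population), f"{drug} dosing in {condition}"
    if topic == "screening":
        lo = rng.choice((40, 45, 50, 55))
        hi = lo + rng.choice((20, 25, 30))
        every = rng.choice((2, 3, 5))
        evidence = (
            f"Screening for {condition} is advised for {population} aged "
            f"{lo} to {hi} years, repeated every {every} years."
        )
        numbers = (
            NumericFact(every, "year", "interval"),
            NumericFact(lo, "year", "age_range", high=hi),
        )
        return evidence, numbers, (condition, population), f"{condition} screening"
    if topic == "threshold":
        t = rng.choice((130, 140, 150, 160))
        evidence = (
            f"In {condition}, treatment with {drug} is considered once "
            f"systolic pressure exceeds {t} mmHg."
        )
        numbers = (NumericFact(t, "mmhg", "threshold"),)
        return evidence, numbers, (condition, drug), f"the {condition} treatment threshold"
    if topic == "update_date":
        year = rng.choice((2017, 2018, 2019, 2020, 2021, 2022, 2023))
        evidence = (
            f"The {condition} guidance on {drug} use was last revised in {year}."
        )
        numbers = (NumericFact(year, "", "date"),)
        return evidence, numbers, (condition, drug), f"the {condition} guidance revision"
    # count
    doses = rng.choice((2, 3, 4, 5))
    evidence = (
        f"The {condition} schedule for {population} includes {doses} doses of {drug}."
    )
    numbers = (NumericFact(doses, "dose", "count"),)
    return evidence, numbers, (condition, population), f"the {condition} schedule"


def build_corpus(
    config: BenchmarkConfig = BenchmarkConfig(),
    doc_prefix: str = "D",
) -> Tuple[List[PassageSpec], List[GoldItem]]:
    """Emit the fictional passage catalog and its grounded gold items.

    Deterministic for a fixed seed; the passage/item counts are fixed by
    the plan and never depend on the seed.
    """
    rng = random.Random(config.seed)
    counts = _items_plan(config)
    start = _dt.date(2019, 1, 15)
    passages: List[PassageSpec] = []
    items: List[GoldItem] = []
    used_names: set = set()
    for i in range(config.n_passages):
        doc_id = f"{doc_prefix}{i + 1}"
        topic = _TOPICS[i % len(_TOPICS)]
        while True:
            drug = rng.choice(_DRUG_STEMS) + rng.choice(_DRUG_SUFFIXES)
            condition = rng.choice(_SURNAMES) + " " + rng.choice(("syndrome", "disease"))
            if (drug, condition) not in used_names:
                used_names.add((drug, condition))
                break
        population = rng.choice(_POPULATIONS)
        evidence, numbers, qualifiers, subject = _passage_content(
            topic, rng, drug, condition, population
        )
        caveat: Tuple[str, ...] = ()
        if i % 7 == 3:
            evidence = evidence[:-1] + f"; {CAVEAT_PHRASE}."
            caveat = (CAVEAT_PHRASE,)
        # source dates evenly spaced; fictional
        source_date = (start + _dt.timedelta(days=31 * i)).isoformat()
        passages.append(
            PassageSpec(doc_id, topic, evidence, source_date, counts[i])
        )
        gold_answer = evidence  # gold restates the evidence sentence
        for j in range(counts[i]):
            items.append(
                GoldItem(
                    item_id=f"{doc_id}-Q{j + 1}",
                    doc_id=doc_id,
                    source_date=source_date,
                    question=_QUESTION_FORMS[j % len(_QUESTION_FORMS)].format(subject=subject),
                    gold_answer=gold_answer,
                    evidence_sentence=evidence,
                    required_qualifiers=qualifiers,
                    required_numbers=numbers,
                    caveat_allowlist=caveat,
                )
            )
    return passages, items


# ---------------------------------------------------------------------------
# flag allocation and response rendering

def allocate_flags(
    profile: RegimeJointProfile,
    items: Sequence[GoldItem],
    seed: int,
    pin_doc: Optional[str] = None,
    pin_veneer: int = 0,
) -> List[Flags]:
    """Seeded count-exact assignment of joint (C, E) cells and N/H/O.

    Every profile count is hit exactly, never in expectation. When
    ``pin_doc`` is given, ``pin_veneer`` of the k01 veneer items are
    placed inside that source block (the worked-example cluster).
    """
    n = len(items)
    if n != profile.n:
        raise ValueError(f"profile n={profile.n} but {n} items supplied")
    rng = random.Random(seed)
    positions = list(range(n))
    rng.shuffle(positions)
    cells = ["11"] * n
    pinned: List[int] = []
    if pin_doc is not None and pin_veneer > 0:
        block = [i for i, it in enumerate(items) if it.doc_id == pin_doc]
        if pin_veneer > min(len(block), profile.k01):
            raise ValueError(
                f"infeasible pin: {pin_veneer} veneer items requested in "
                f"block {pin_doc} of size {len(block)} (k01={profile.k01})"
            )
        pinned = rng.sample(block, pin_veneer)
        for i in pinned:
            cells[i] = "01"
    remaining = [i for i in positions if i not in set(pinned)]
    quota = [("01", profile.k01 - len(pinned)), ("00", profile.k00), ("10", profile.k10)]
    cursor = 0
    for cell, count in quota:
        for i in remaining[cursor : cursor + count]:
            cells[i] = cell
        cursor += count
    c_one = [i for i in range(n) if cells[i][0] == "1"]
    n_ones = set(rng.sample(c_one, profile.n_count))
    h_ones = set(rng.sample(range(n), profile.h_count))
    o_ones = set(rng.sample(range(n), profile.o_count))
    return [
        Flags(int(cells[i][0]), int(cells[i][1]), int(i in n_ones),
              int(i in h_ones), int(i in o_ones))
        for i in range(n)
    ]


_REGIME_PREFIX = {
    "RUSH": "Quick answer: ",
    "VERIFY": "Checked against the source: ",
    "POETIC": "As the guidance sets it out, ",
    "POSTER": "",
}

_HEDGE_SENTENCES = {
    "RUSH": " It is likely fine to follow this as written.",
    "POETIC": " Like weather, outcomes may shift from person to person.",
    "VERIFY": " Residual effects are possibly smaller in practice.",
    "POSTER": " Individual responses may differ.",
}

_ORNAMENT_SUFFIX = {
    "POSTER": " ★ ★ ★ KEY GUIDANCE UPDATE! SHARE WIDELY!",
    "RUSH": " Read the full update now!",
    "VERIFY": " Read the full update now!",
    "POETIC": " A banner day for guidance — read it now!",
}

_EXTRA_PERCENTS = (12, 18, 23, 27, 34, 41)


def _perturb_value(req: NumericFact, gold: GoldItem) -> float:
    evidence_vals = {
        (f.value, f.unit)
        for f in extract_numeric_facts(gold.evidence_sentence)
        if not f.is_range
    }
    if req.kind == "date":
        candidates = [req.value + 1, req.value + 2]
    else:
        candidates = [req.value * 2, req.value + 50, req.value + 1, req.value + 3]
    for cand in candidates:
        if cand != req.value and (cand, req.unit) not in evidence_vals:
            return cand
    raise ValueError(f"no perturbable value for {req.describe()} in {gold.item_id}")


def render_response(
    gold: GoldItem,
    flags: Flags,
    regime: str,
    rng: random.Random,
    doc_pool: Sequence[str] = (),
) -> ResponseRecord:
    """Construct answer text realizing the intended flags by inversion of
    the rule scorers. The caller is expected to re-score the record; the
    generator asserts the round trip.
    """
    answer = gold.gold_answer
    if flags.c == 0:
        # substitute a wrong value for the first scalar required number
        scalars = [f for f in gold.required_numbers if not f.is_range]
        if not scalars:
            raise ValueError(f"{gold.item_id}: no perturbable scalar number for C=0")
        req = scalars[0]
        wrong = _perturb_value(req, gold)
        pattern = rf"\b{re.escape(f'{req.value:g}')}\b"
        answer, n_subs = re.subn(pattern, f"{wrong:g}", answer, count=1)
        if n_subs != 1:
            raise ValueError(f"{gold.item_id}: required number not found in gold answer")
    elif flags.n == 0:
        pct = rng.choice(_EXTRA_PERCENTS)
        answer = answer[:-1] + f", a point raised in about {pct}% of reviews."
    if flags.h == 1:
        answer += _HEDGE_SENTENCES.get(regime, _HEDGE_SENTENCES["VERIFY"])
    answer = _REGIME_PREFIX.get(regime, "") + answer
    if flags.o == 1:
        answer += _ORNAMENT_SUFFIX.get(regime, _ORNAMENT_SUFFIX["RUSH"])
    if flags.e == 1:
        cited: Optional[str] = gold.doc_id
    else:
        others = [d for d in doc_pool if d != gold.doc_id]
        cited = rng.choice(others) if (others and rng.random() < 0.5) else None
    return ResponseRecord(
        item_id=gold.item_id,
        regime=regime,
        answer_text=answer,
        cited_doc_id=cited,
        metadata={"generator": "synthetic-regime-script"},
    )


def _render_regime(
    regime: str,
    items: Sequence[GoldItem],
    flag_list: Sequence[Flags],
    seed: int,
    config: ScoringConfig,
    catalog: Mapping[str, GoldItem],
    doc_pool: Sequence[str],
) -> List[ResponseRecord]:
    rng = random.Random(f"{seed}:{regime}")  # hashed stably by Random itself
    records = []
    for gold, flags in zip(items, flag_list):
        rec = render_response(gold, flags, regime, rng, doc_pool)
        scored = score_record(rec, catalog[gold.item_id], config)
        got = (scored.tag.c, scored.tag.e, scored.tag.n, scored.tag.h, scored.tag.o)
        want = (flags.c, flags.e, flags.n, flags.h, flags.o)
        if got != want:
            raise AssertionError(
                f"round-trip failure on {gold.item_id} [{regime}]: intended "
                f"{want}, scored {got}: {rec.answer_text!r}"
            )
        records.append(rec)
    return records


def generate_benchmark(
    config: BenchmarkConfig = BenchmarkConfig(),
    scoring: ScoringConfig = ScoringConfig(),
) -> Tuple[List[PassageSpec], List[GoldItem], Dict[str, List[ResponseRecord]]]:
    """The full controlled benchmark: corpus + four regimes x 120 records.

    Scoring the returned records reproduces each regime's profile counts
    exactly (guaranteed by a per-record round-trip assertion).
    """
    passages, items = build_corpus(config)
    catalog = {it.item_id: it for it in items}
    doc_pool = [p.doc_id for p in passages]
    cluster_doc = f"D{config.cluster_doc_index + 1}"
    plan = load_flag_plan() if config.use_packaged_plan else None
    responses: Dict[str, List[ResponseRecord]] = {}
    for regime, profile in config.profiles.items():
        if plan is not None and regime in plan["synthetic"]["regimes"]:  # type: ignore[index]
            flag_list = _plan_flags(plan["synthetic"], regime, profile.n)
            _check_plan_against_profile(regime, flag_list, profile)
        else:
            flag_list = allocate_flags(
                profile, items, seed=config.seed,
                pin_doc=cluster_doc if regime == "RUSH" else None,
                pin_veneer=min(6, profile.k01) if regime == "RUSH" else 0,
            )
        responses[regime] = _render_regime(
            regime, items, flag_list, config.seed, scoring, catalog, doc_pool
        )
    return passages, items, responses


def generate_public_fixture(
    config: BenchmarkConfig = BenchmarkConfig(),
    scoring: ScoringConfig = ScoringConfig(),
) -> Tuple[List[PassageSpec], List[GoldItem], Dict[str, List[ResponseRecord]]]:
    """The 12-case public-check-style fixture (fictional claim-style items)."""
    pub_config = replace(
        config, n_passages=12, n_items=12, cluster_doc_index=0, cluster_items=1,
        seed=config.seed + 1,
    )
    passages, items = build_corpus(pub_config, doc_prefix="P")
    # claim-style phrasing for the public check
    items = [
        replace(
            it,
            question=f"Is this claim consistent with the source: "
            f"\"{it.evidence_sentence}\"?",
        )
        for it in items
    ]
    catalog = {it.item_id: it for it in items}
    doc_pool = [p.doc_id for p in passages]
    plan = load_flag_plan() if config.use_packaged_plan else None
    responses: Dict[str, List[ResponseRecord]] = {}
    for regime, profile in config.public_profiles.items():
        if plan is not None and regime in plan["public"]["regimes"]:  # type: ignore[index]
            flag_list = _plan_flags(plan["public"], regime, profile.n)
            _check_plan_against_profile(regime, flag_list, profile)
        else:
            flag_list = allocate_flags(profile, items, seed=pub_config.seed)
        responses[regime] = _render_regime(
            regime, items, flag_list, pub_config.seed, scoring, catalog, doc_pool
        )
    return passages, items, responses


def _check_plan_against_profile(
    regime: str, flag_list: Sequence[Flags], profile: RegimeJointProfile
) -> None:
    counts = {
        "k11": sum(1 for f in flag_list if f.c == 1 and f.e == 1),
        "k10": sum(1 for f in flag_list if f.c == 1 and f.e == 0),
        "k01": sum(1 for f in flag_list if f.c == 0 and f.e == 1),
        "k00": sum(1 for f in flag_list if f.c == 0 and f.e == 0),
        "n_count": sum(f.n for f in flag_list),
        "h_count": sum(f.h for f in flag_list),
        "o_count": sum(f.o for f in flag_list),
    }
    for name, got in counts.items():
        want = getattr(profile, name)
        if got != want:
            raise ValueError(
                f"packaged flag plan disagrees with {regime} profile on "
                f"{name}: plan {got}, profile {want}"
            )
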