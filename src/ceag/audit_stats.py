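"""Descriptive statistics for audit summaries.

All rates are reported as percentages with 95% Wilson score intervals.
The Wilson interval for k successes in n trials with normal quantile z is

    (p + z^2/2n  ±  z * sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n),  p = k/n.

For the canonical 95% level the conventional two-decimal quantile
z = 1.96 is used (the exact quantile is used for any other confidence
level); display values are rounded half-up to one decimal. No
continuity correction and no multiple-testing adjustment are applied:
these are descriptive intervals, not hypothesis tests.

``masked_delta`` compares two regimes answering the same items: each
pair of tags is XOR-ed and restricted to a slot mask (content/trust =
C,E,N,V; style = H,O), and the percentage of pairs with any retained
difference is reported. Pairing is strictly by item_id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy.stats import norm

from .rule_scoring import ScoredRecord
from .tag_model import FULL, CenhovTag, MaskSpec, tag_delta


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for percentages)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def z_for_confidence(confidence: float) -> float:
    """Normal quantile for a two-sided confidence level.

    Returns the conventional 1.96 at 95%; the exact quantile otherwise.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if abs(confidence - 0.95) < 1e-12:
        return 1.96
    return float(norm.ppf(0.5 + confidence / 2.0))


def wilson_bounds(
    k: Union[int, np.ndarray], n: int, z: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized Wilson score bounds on the probability scale (0..1)."""
    k = np.asarray(k, dtype=float)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    halfwidth = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - halfwidth, center + halfwidth


@dataclass(frozen=True)
class ProportionSummary:
    """k/n with its Wilson interval, on the percentage scale."""

    k: int
    n: int
    rate: float  # exact percentage, full precision
    ci_low: float
    ci_high: float
    z: float = 1.96

    @property
    def display(self) -> str:
        return (
            f"{round_half_up(self.rate):.1f} "
            f"({round_half_up(self.ci_low):.1f}-{round_half_up(self.ci_high):.1f})"
        )


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> ProportionSummary:
    """Wilson score interval for k successes in n trials.

    Full precision is retained internally; use ``round_half_up`` (or the
    summary's ``display``) for one-decimal presentation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    z = z_for_confidence(confidence)
    lo, hi = wilson_bounds(k, n, z)
    return ProportionSummary(
        k=k, n=n, rate=100.0 * k / n,
        ci_low=100.0 * float(lo), ci_high=100.0 * float(hi), z=z,
    )


SUMMARY_SLOTS = ("C", "E", "N", "V")


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition rates for C, E, N and the derived veneer V."""

    condition: str
    n: int
    slots: Mapping[str, ProportionSummary]

    def row(self) -> Dict[str, object]:
        out: Dict[str, object] = {"condition": self.condition, "n": self.n}
        names = {"C": "correct", "E": "support", "N": "numeric", "V": "veneer"}
        for slot, name in names.items():
            s = self.slots[slot]
            out[f"{name}_pct"] = round_half_up(s.rate)
            out[f"{name}_ci"] = (
                f"{round_half_up(s.ci_low):.1f}-{round_half_up(s.ci_high):.1f}"
            )
        return out


def summarize_condition(
    records: Sequence[ScoredRecord],
    condition: Optional[str] = None,
    confidence: float = 0.95,
) -> ConditionSummary:
    """Count slot positives for C, E, N, V and attach Wilson intervals.

    All records must share one condition (regime) label; pass
    ``condition`` explicitly to assert which one.
    """
    if not records:
        raise ValueError("cannot summarize an empty record set")
    labels = {r.response.regime for r in records}
    if condition is None:
        if len(labels) != 1:
            raise ValueError(f"records mix conditions {sorted(labels)}; pass one")
        condition = labels.pop()
    elif labels != {condition}:
        raise ValueError(f"records carry conditions {sorted(labels)}, not {condition!r}")
    n = len(records)
    slots = {
        slot: wilson_interval(sum(r.tag.slot(slot) for r in records), n, confidence)
        for slot in SUMMARY_SLOTS
    }
    return ConditionSummary(condition=condition, n=n, slots=slots)


@dataclass(frozen=True)
class DeltaResult:
    """Masked XOR comparison between two regimes on paired items."""

    mask: MaskSpec
    n: int
    differing: int
    percent_nonzero: float
    per_item: Mapping[str, Set[str]]  # item_id -> differing retained slots


def masked_delta(
    records_a: Sequence[ScoredRecord],
    records_b: Sequence[ScoredRecord],
    mask: MaskSpec = FULL,
) -> DeltaResult:
    """Pair records by item_id, XOR their tags, retain masked slots.

    Every item must appear exactly once on each side; there is no
    positional fallback.
    """
    def index(records: Sequence[ScoredRecord], side: str) -> Dict[str, CenhovTag]:
        out: Dict[str, CenhovTag] = {}
        for r in records:
            item = r.response.item_id
            if item in out:
                raise ValueError(f"duplicate item_id {item!r} in {side} records")
            out[item] = r.tag
        return out

    tags_a = index(records_a, "first")
    tags_b = index(records_b, "second")
    if tags_a.keys() != tags_b.keys():
        only_a = sorted(tags_a.keys() - tags_b.keys())
        only_b = sorted(tags_b.keys() - tags_a.keys())
        raise ValueError(
            f"records do not pair one-to-one by item_id: "
            f"only in first {only_a[:5]}, only in second {only_b[:5]}"
        )
    per_item = {item: tag_delta(tags_a[item], tags_b[item], mask) for item in tags_a}
    differing = sum(1 for d in per_item.values() if d)
    n = len(per_item)
    return DeltaResult(
        mask=mask, n=n, differing=differing,
        percent_nonzero=100.0 * differing / n, per_item=per_item,
    )


KAPPA_UNDEFINED = float("nan")


def cohen_kappa(
    labels_a: Sequence[int], labels_b: Sequence[int]
) -> float:
    """Cohen's kappa for two binary label sequences.

    (observed agreement - chance agreement) / (1 - chance agreement).
    Returns NaN (undefined marker) when chance agreement is 1, i.e. when
    either rater is constant in a way that makes the denominator vanish.
    Intended for future multi-rater C/E/N reliability data.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("label sequences must be equal-length, non-empty 1-D")
    n = len(a)
    po = float(np.mean(a == b))
    pe = 0.0
    for cls in (0, 1):
        pe += float(np.mean(a == cls)) * float(np.mean(b == cls))
    if abs(1.0 - pe) < 1e-12:
        return KAPPA_UNDEFINED
    return (po - pe) / (1.0 - pe)
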