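"""The CENHOV audit tag: a six-slot binary code for one LLM response.

A response is summarized by six binary signals in fixed order:

======  ===========================================================
slot    signal
======  ===========================================================
C       clinical correctness
E       evidential support (cited source materially supports answer)
N       numeric concordance (all required numbers present, grounded)
H       hedging (explicit uncertainty markers)
O       ornamentation (poster-like / promotional styling)
V       supported-error citation veneer, *derived* as E=1 and C=0
======  ===========================================================

The text form is case-coded: uppercase letter = signal present (1),
lowercase = absent (0). ``CENhov`` is a correct, supported, numerically
grounded answer with no hedging, no ornament and no veneer; ``cEnhoV``
is the veneer state — cited as if supported, substantively wrong.

V is never an independent judgement: it is forced by (C, E). Parsing is
strict by default and rejects text whose V letter contradicts its C and
E letters; lenient parsing recomputes V and reports a warning instead,
for ingesting legacy hand-typed labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Iterable, Optional, Set, Tuple

SLOTS: Tuple[str, ...] = ("C", "E", "N", "H", "O", "V")
"""Canonical slot order. Tags are positional codes and are never reordered."""

_SLOT_INDEX = {s: i for i, s in enumerate(SLOTS)}


class TagError(ValueError):
    """Invalid tag text or invalid slot combination.

    Attributes
    ----------
    position : int or None
        Zero-based offending character position in the text form, when
        the error is positional.
    """

    def __init__(self, message: str, position: Optional[int] = None):
        super().__init__(message)
        self.position = position


def derive_veneer(c: int, e: int) -> int:
    """Supported-error citation veneer bit: 1 iff E=1 and C=0.

    Unsupported errors (E=0, C=0) and unsupported truths (E=0, C=1) are
    visible through the C and E slots but are deliberately not counted
    as veneer.
    """
    if c not in (0, 1) or e not in (0, 1):
        raise TagError(f"slot bits must be 0 or 1, got c={c!r}, e={e!r}")
    return 1 if (e == 1 and c == 0) else 0


@dataclass(frozen=True, order=True)
class CenhovTag:
    """One six-slot audit tag. ``v`` must equal ``derive_veneer(c, e)``."""

    c: int
    e: int
    n: int
    h: int
    o: int
    v: int

    def __post_init__(self) -> None:
        for name in ("c", "e", "n", "h", "o", "v"):
            if getattr(self, name) not in (0, 1):
                raise TagError(f"slot {name.upper()} must be 0 or 1")
        if self.v != derive_veneer(self.c, self.e):
            raise TagError(
                f"invalid V={self.v}: V must equal 1 exactly when E=1 and C=0 "
                f"(here C={self.c}, E={self.e})",
                position=_SLOT_INDEX["V"],
            )

    @classmethod
    def from_flags(cls, c: int, e: int, n: int, h: int, o: int) -> "CenhovTag":
        """Build a tag from the five scored slots, deriving V."""
        return cls(c, e, n, h, o, derive_veneer(c, e))

    @property
    def bits(self) -> Tuple[int, int, int, int, int, int]:
        return (self.c, self.e, self.n, self.h, self.o, self.v)

    def slot(self, name: str) -> int:
        """Bit for a slot letter (``"C"`` ... ``"V"``)."""
        try:
            return self.bits[_SLOT_INDEX[name.upper()]]
        except KeyError:
            raise TagError(f"unknown slot {name!r}") from None

    def __str__(self) -> str:
        return format_tag(self)


def format_tag(tag: CenhovTag) -> str:
    """Case-coded six-character text form (uppercase = 1)."""
    return "".join(
        letter if bit else letter.lower() for letter, bit in zip(SLOTS, tag.bits)
    )


def parse_tag(text: str, strict: bool = True) -> CenhovTag:
    """Parse a case-coded CENHOV tag.

    Parameters
    ----------
    text : str
        Exactly six characters; character *i* must be the *i*-th letter
        of ``CENHOV`` in upper or lower case.
    strict : bool
        When True (default), text whose V letter contradicts C and E is
        rejected. When False, V is recomputed from C and E and the
        inconsistency is recorded on the returned tag's ``warnings``
        attribute (see :func:`parse_tag_lenient`).

    Raises
    ------
    TagError
        Wrong length, wrong letter at a position, or (strict mode) a
        V-inconsistent tag; ``position`` names the offending character.
    """
    tag, warning = _parse(text, strict=strict)
    return tag


def parse_tag_lenient(text: str) -> Tuple[CenhovTag, Optional[str]]:
    """Lenient parse: returns ``(tag, warning)``.

    ``warning`` is None for consistent text and a human-readable message
    when the V letter was recomputed.
    """
    return _parse(text, strict=False)


def _parse(text: str, strict: bool) -> Tuple[CenhovTag, Optional[str]]:
    if not isinstance(text, str) or len(text) != 6:
        raise TagError(
            f"tag text must be exactly 6 characters, got {text!r}",
            position=None,
        )
    bits = []
    for i, (ch, letter) in enumerate(zip(text, SLOTS)):
        if ch.upper() != letter:
            raise TagError(
                f"position {i}: expected letter {letter!r} (upper or lower), "
                f"got {ch!r} in {text!r}",
                position=i,
            )
        bits.append(1 if ch.isupper() else 0)
    c, e, n, h, o, v = bits
    expected_v = derive_veneer(c, e)
    warning: Optional[str] = None
    if v != expected_v:
        msg = (
            f"position 5: V letter is {'upper' if v else 'lower'}case but "
            f"C={c}, E={e} forces V={expected_v} in {text!r}"
        )
        if strict:
            raise TagError(msg, position=5)
        warning = msg
    return CenhovTag(c, e, n, h, o, expected_v), warning


def all_valid_tags() -> Iterable[CenhovTag]:
    """All 32 representable tags (C,E,N,H,O free, V forced)."""
    for code in range(32):
        c, e, n, h, o = ((code >> k) & 1 for k in range(4, -1, -1))
        yield CenhovTag.from_flags(c, e, n, h, o)


class TrustState(Enum):
    """The four (C, E) trust states. ``supported_error`` coincides with V=1."""

    SUPPORTED_TRUTH = "supported_truth"
    SUPPORTED_ERROR = "supported_error"
    UNSUPPORTED_TRUTH = "unsupported_truth"
    UNSUPPORTED_ERROR = "unsupported_error"


def classify_trust_state(tag: CenhovTag) -> TrustState:
    """Map a tag's (C, E) pair to its trust state."""
    if tag.e == 1:
        return TrustState.SUPPORTED_TRUTH if tag.c == 1 else TrustState.SUPPORTED_ERROR
    return TrustState.UNSUPPORTED_TRUTH if tag.c == 1 else TrustState.UNSUPPORTED_ERROR


@dataclass(frozen=True)
class MaskSpec:
    """A non-empty subset of slots retained in a masked tag comparison."""

    retained: FrozenSet[str]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        retained = frozenset(s.upper() for s in self.retained)
        unknown = retained - set(SLOTS)
        if unknown:
            raise TagError(f"unknown slots in mask: {sorted(unknown)}")
        if not retained:
            raise TagError("mask must retain at least one slot")
        object.__setattr__(self, "retained", retained)


CONTENT_TRUST = MaskSpec(frozenset("CENV"), name="content_trust")
"""Mask retaining the substantive trust slots C, E, N and V."""

STYLE = MaskSpec(frozenset("HO"), name="style")
"""Mask retaining the stylistic slots H and O."""

FULL = MaskSpec(frozenset(SLOTS), name="full")
"""All six slots (raw, unmasked comparison)."""

MASK_PRESETS = {"content_trust": CONTENT_TRUST, "style": STYLE, "full": FULL}


def tag_delta(a: CenhovTag, b: CenhovTag, mask: MaskSpec = FULL) -> Set[str]:
    """Slots retained by ``mask`` whose bits differ between two tags.

    The XOR of the two six-bit vectors, restricted to the mask. An empty
    set means the pair matches under the mask.
    """
    if not isinstance(mask, MaskSpec):
        raise TagError("mask must be a MaskSpec")
    return {
        s for s in SLOTS if s in mask.retained and a.slot(s) != b.slot(s)
    }
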