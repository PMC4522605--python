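"""Prosite PA-line pattern parsing and scanning.

Supported grammar (elements separated by ``-``):

* a single residue letter, e.g. ``G``
* ``x`` — any residue
* ``[ABC]`` — a residue class
* ``{ABC}`` — an exclusion class (any residue not listed)
* a repeat suffix ``(n)`` or ``(n,m)`` on any element
* ``<`` / ``>`` anchors at the pattern boundaries
* an optional trailing ``.``

The family signature used to recognise bona fide P5CR sequences is exposed
as :data:`P5CR_SIGNATURE`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_core import ProteinRecord

#: PA-line signature recognising P5CR family members.
P5CR_SIGNATURE = (
    "[PALF]-x(2,3)-[LIV]-x(3)-[LIVM]-[STAC]-[STV]-x-[GANK]-G-x-T-x(2)-"
    "[AG]-[LIV]-x(2)-[LMF]-[DENQK]"
)

_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: a residue class (or ANY / NOT-class) with
    repeat bounds."""

    allowed: frozenset[str] | None  # None = ANY ("x")
    negated: bool = False
    repeat_min: int = 1
    repeat_max: int = 1

    def matches(self, residue: str) -> bool:
        if self.allowed is None:
            return True
        # Conservative treatment of the ambiguity residue: X satisfies only
        # the wildcard, never a residue class or exclusion.
        if residue == "X":
            return False
        if self.negated:
            return residue not in self.allowed
        return residue in self.allowed


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple[PatternElement, ...]
    source_text: str
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_span(self) -> int:
        return sum(e.repeat_min for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.repeat_max for e in self.elements)


@dataclass(frozen=True)
class PatternHit:
    """A match of a pattern in a sequence (1-based inclusive coordinates)."""

    start: int
    end: int
    matched: str


class PrositeParseError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


def _parse_repeat(token: str, base_offset: int) -> tuple[int, int, str]:
    """Parse a trailing (n) or (n,m) repeat from ``token``; returns
    (rmin, rmax, remaining token)."""
    if not token.endswith(")"):
        return 1, 1, token
    lp = token.rfind("(")
    if lp < 0:
        raise PrositeParseError("unbalanced parenthesis", base_offset + len(token) - 1)
    inner = token[lp + 1 : -1]
    parts = inner.split(",")
    if not 1 <= len(parts) <= 2 or not all(p.strip().isdigit() for p in parts):
        raise PrositeParseError(f"non-numeric repeat {inner!r}", base_offset + lp)
    rmin = int(parts[0])
    rmax = int(parts[-1])
    if rmin < 1 or rmax < rmin:
        raise PrositeParseError(f"invalid repeat bounds {inner!r}", base_offset + lp)
    return rmin, rmax, token[:lp]


def _parse_class(token: str, offset: int) -> tuple[frozenset[str], bool]:
    if token.startswith("[") and token.endswith("]"):
        body, negated = token[1:-1], False
    elif token.startswith("{") and token.endswith("}"):
        body, negated = token[1:-1], True
    else:
        raise PrositeParseError(f"unbalanced brackets in {token!r}", offset)
    if not body:
        raise PrositeParseError("empty residue class", offset + 1)
    for k, ch in enumerate(body):
        if ch not in _RESIDUES:
            raise PrositeParseError(
                f"invalid residue {ch!r} in class", offset + 1 + k
            )
    return frozenset(body), negated


def parse_prosite(pattern: str) -> PrositePattern:
    """Compile a PA-line string into a :class:`PrositePattern`.

    Raises :class:`PrositeParseError` (with a 0-based character offset)
    on unbalanced brackets, empty classes or malformed repeats.
    """
    text = pattern.strip()
    work = text[:-1] if text.endswith(".") else text
    anchored_start = work.startswith("<")
    if anchored_start:
        work = work[1:]
    anchored_end = work.endswith(">")
    if anchored_end:
        work = work[:-1]
    if not work:
        raise PrositeParseError("empty pattern", 0)

    elements: list[PatternElement] = []
    offset = len(text) - len(text.lstrip())  # 0 after strip; kept for clarity
    pos = (1 if anchored_start else 0)
    for token in work.split("-"):
        if not token:
            raise PrositeParseError("empty element", pos)
        rmin, rmax, core = _parse_repeat(token, pos)
        if not core:
            raise PrositeParseError("repeat without element", pos)
        if core in ("x", "X"):
            elem = PatternElement(None, False, rmin, rmax)
        elif len(core) == 1:
            if core not in _RESIDUES:
                raise PrositeParseError(f"invalid residue {core!r}", pos)
            elem = PatternElement(frozenset(core), False, rmin, rmax)
        else:
            allowed, negated = _parse_class(core, pos)
            elem = PatternElement(allowed, negated, rmin, rmax)
        elements.append(elem)
        pos += len(token) + 1
    return PrositePattern(
        elements=tuple(elements),
        source_text=text,
        anchored_start=anchored_start,
        anchored_end=anchored_end,
    )


def _shortest_match_end(seq: str, pos: int, elements: tuple[PatternElement, ...],
                        k: int, require_end: int | None) -> int | None:
    """Smallest end index (exclusive) of a match of elements[k:] starting at
    ``pos``, or None. ``require_end`` pins the match end (for '>' anchors)."""
    if k == len(elements):
        if require_end is not None and pos != require_end:
            return None
        return pos
    elem = elements[k]
    best: int | None = None
    # All residues of a repeated element must individually satisfy it, so a
    # failure at repeat i rules out every longer expansion.
    for n in range(1, elem.repeat_max + 1):
        if pos + n > len(seq) or not elem.matches(seq[pos + n - 1]):
            break
        if n < elem.repeat_min:
            continue
        sub = _shortest_match_end(seq, pos + n, elements, k + 1, require_end)
        if sub is not None and (best is None or sub < best):
            best = sub
    return best


def scan(pattern: PrositePattern, seq: ProteinRecord | str) -> list[PatternHit]:
    """Report every start position admitting a match, once each, using the
    shortest admissible expansion at that start; sorted by start."""
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    # Pre-check repeat_min feasibility to skip impossible tails quickly.
    hits: list[PatternHit] = []
    starts = [0] if pattern.anchored_start else range(len(residues))
    require_end = len(residues) if pattern.anchored_end else None
    for start in starts:
        if start + pattern.min_span > len(residues):
            break
        end = _shortest_match_end(residues, start, pattern.elements, 0, require_end)
        if end is not None:
            hits.append(
                PatternHit(start=start + 1, end=end, matched=residues[start:end])
            )
    return hits
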