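"""Fingerprint motifs A-E, the dimer-dimer determinant, and the rule-based
cofactor-preference and oligomeric-state classifiers.

Motif coordinates are expressed in the rice (OsP5CR) numbering. A query is
placed in that frame either through an :class:`AnchorMap` built from a
global alignment against the reference, or (unanchored) by scanning for the
motif consensus patterns in their canonical N-to-C order.

The oligomeric-state call follows the sequence-determinant hypothesis for
the family: decamer-forming P5CRs carry the A-D-G-G-V-A-A-G-L-P-R-[DR]-L
determinant window (rice 202-214, with the critical G204/G205/P211) plus a
conserved network of inter-dimer salt bridges (D203-K241*, R212-D242*,
H236-D242*) and a stacking arginine, while dimer-only members carry
divergent windows such as Q-N-A-A-I-R-Q-G-F-D-M-A-E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._scoring import SIMILARITY_GROUPS, same_class
from .prosite import P5CR_SIGNATURE, PatternElement, parse_prosite, scan
from .seq_core import PairwiseAlignment, ProteinRecord, global_align

#: Canonical N-to-C order of the fingerprint motifs along the sequence.
MOTIF_ORDER = ("B", "A", "B_ext", "C", "D", "E")

#: Decamer-type determinant window consensus (rice 202-214); position 12
#: admits Asp or Arg. Indices 2, 3 and 9 are the critical Gly/Pro sites.
DD_CONSENSUS: tuple[frozenset[str], ...] = tuple(
    frozenset(ch) for ch in "ADGGVAAGLPR"
) + (frozenset("DR"), frozenset("L"))
DD_CRITICAL_IDX = (2, 3, 9)  # G204, G205, P211 (0-based within the window)

#: Rice positions of the individually scored determinant features.
FEATURE_POSITIONS: dict[str, tuple[int, str]] = {
    "D203": (203, "D"),
    "G204": (204, "G"),
    "G205": (205, "G"),
    "P211": (211, "P"),
    "R212": (212, "R"),
    "H236": (236, "H"),
    "K241": (241, "K"),
    "D242": (242, "D"),
    "R251": (251, "R"),
}

#: Default feature weights. R251 is advisory (weight 0): the stacking Arg is
#: absent from at least one confirmed decamer, so it never drives a call.
DEFAULT_FEATURE_WEIGHTS: dict[str, float] = {
    "D203": 1.0,
    "G204": 1.0,
    "G205": 1.0,
    "P211": 1.0,
    "R212": 1.0,
    "H236": 1.0,
    "K241": 1.0,
    "D242": 1.0,
    "R251": 0.0,
    "DD_similarity": 1.0,
}


@dataclass(frozen=True)
class MotifDefinition:
    """A named consensus motif with its rice reference span."""

    name: str
    consensus: str  # mini PA-line pattern, one element per position
    ref_span: tuple[int, int]
    role: str

    @property
    def elements(self) -> tuple[PatternElement, ...]:
        return parse_prosite(self.consensus).elements

    def __len__(self) -> int:
        return self.ref_span[1] - self.ref_span[0] + 1


_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("B", "G-x-x-G-x-G-x-[ML]", (9, 16),
                    "Gly-rich Rossmann loop binding the pyrophosphate"),
    MotifDefinition("A", "H-x-[RN]-x-x-R", (53, 58),
                    "adenine / 2'-phosphate region (union of the H-R-R-x-x-R "
                    "and H-x-N-x-N-R variants)"),
    MotifDefinition("B_ext", "V-K-P", (76, 78),
                    "pyrophosphate-anchoring Lys loop"),
    MotifDefinition("C", "R-x-M-x-N", (132, 136),
                    "nicotinamide-proximal active-site loop"),
    MotifDefinition("D", "G-S-x-P-A", (188, 192),
                    "inter-domain hinge loop"),
    MotifDefinition("DD", "A-D-G-G-V-A-A-G-L-P-R-[DR]-L", (202, 214),
                    "dimer-dimer determinant region (decamer consensus)"),
    MotifDefinition("E", "S-P-[AG]-G-T-T", (246, 251),
                    "proline-carboxylate pocket"),
)


def builtin_motifs() -> tuple[MotifDefinition, ...]:
    """The seven built-in motif definitions (immutable)."""
    return _MOTIFS


def motif(name: str) -> MotifDefinition:
    for m in _MOTIFS:
        if m.name == name:
            return m
    raise KeyError(name)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based query coordinates, inclusive
    end: int
    matched: str
    exact: bool
    anchored_ref_span: tuple[int, int] | None = None


@dataclass(frozen=True)
class AnchorMap:
    """Query <-> reference residue correspondence from one global alignment.

    Pairs are 1-based and strictly increasing in both coordinates (only
    both-non-gap alignment columns are kept), hence injective both ways.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_q = prev_r = 0
        for q, r in self.pairs:
            if q <= prev_q or r <= prev_r:
                raise ValueError("anchor pairs must be strictly increasing")
            prev_q, prev_r = q, r

    @property
    def query_by_ref(self) -> dict[int, int]:
        return {r: q for q, r in self.pairs}

    def query_position(self, ref_pos: int) -> int | None:
        return self.query_by_ref.get(ref_pos)


def anchor_to_reference(query: ProteinRecord, reference: ProteinRecord,
                        **align_kwargs) -> AnchorMap:
    """Build an :class:`AnchorMap` from a global alignment of query against
    the reference."""
    aln: PairwiseAlignment = global_align(query, reference, **align_kwargs)
    row_q, row_r = aln.rows
    pairs: list[tuple[int, int]] = []
    qi = ri = 0
    for cq, cr in zip(row_q, row_r):
        if cq != "-":
            qi += 1
        if cr != "-":
            ri += 1
        if cq != "-" and cr != "-":
            pairs.append((qi, ri))
    return AnchorMap(pairs=tuple(pairs))


def _mismatches(elements: Sequence[PatternElement], residues: str,
                start0: int) -> int | None:
    """Mismatch count of a fixed-length consensus at 0-based ``start0``, or
    None if it would run past the end of the sequence."""
    if start0 < 0 or start0 + len(elements) > len(residues):
        return None
    return sum(
        0 if el.matches(residues[start0 + k]) else 1
        for k, el in enumerate(elements)
    )


def _anchored_expected_start(m: MotifDefinition, anchors: AnchorMap) -> int | None:
    """Expected 0-based query start of a motif under the anchor map."""
    lookup = anchors.query_by_ref
    for offset in range(len(m)):
        q = lookup.get(m.ref_span[0] + offset)
        if q is not None:
            return q - 1 - offset
    return None


def scan_fingerprint(
    query: ProteinRecord,
    anchors: AnchorMap | None = None,
    max_mismatch: int = 1,
    exact: bool = False,
    slack: int = 10,
) -> list[MotifHit]:
    """Locate the fingerprint motifs in a query sequence.

    With ``anchors`` each motif is sought near its mapped rice span and one
    consensus mismatch is tolerated (``exact=True`` disables the tolerance);
    among admissible placements the one nearest the mapped span wins. The
    determinant window (DD) is placed strictly by the anchors and always
    reported when mappable, with ``exact`` recording whether the decamer
    consensus is satisfied.

    Without anchors, motifs are located by their first exact consensus match
    scanning left to right in the canonical order B < A < B_ext < C < D < E;
    DD is then placed at its fixed offset from motif D.

    Missing motifs are simply absent from the result.
    """
    residues = query.residues
    hits: dict[str, MotifHit] = {}
    tol = 0 if exact else max_mismatch

    if anchors is not None:
        for m in _MOTIFS:
            expected = _anchored_expected_start(m, anchors)
            if expected is None:
                continue
            if m.name == "DD":
                mm = _mismatches(m.elements, residues, expected)
                if mm is None:
                    continue
                hits[m.name] = MotifHit(
                    motif=m.name,
                    start=expected + 1,
                    end=expected + len(m),
                    matched=residues[expected : expected + len(m)],
                    exact=(mm == 0),
                    anchored_ref_span=m.ref_span,
                )
                continue
            best: tuple[int, int, int] | None = None  # (|delta|, mm, start0)
            for start0 in range(max(0, expected - slack), expected + slack + 1):
                mm = _mismatches(m.elements, residues, start0)
                if mm is None or mm > tol:
                    continue
                key = (abs(start0 - expected), mm, start0)
                if best is None or key < best:
                    best = key
            if best is not None:
                start0 = best[2]
                hits[m.name] = MotifHit(
                    motif=m.name,
                    start=start0 + 1,
                    end=start0 + len(m),
                    matched=residues[start0 : start0 + len(m)],
                    exact=(best[1] == 0),
                    anchored_ref_span=m.ref_span,
                )
    else:
        prev_end0 = 0
        for name in MOTIF_ORDER:
            m = motif(name)
            found = None
            for start0 in range(prev_end0, len(residues) - len(m) + 1):
                if _mismatches(m.elements, residues, start0) == 0:
                    found = start0
                    break
            if found is None:
                continue
            hits[name] = MotifHit(
                motif=name,
                start=found + 1,
                end=found + len(m),
                matched=residues[found : found + len(m)],
                exact=True,
            )
            prev_end0 = found + len(m)
        if "D" in hits:
            m = motif("DD")
            d_def = motif("D")
            start0 = hits["D"].start - 1 + (m.ref_span[0] - d_def.ref_span[0])
            mm = _mismatches(m.elements, residues, start0)
            if mm is not None:
                hits["DD"] = MotifHit(
                    motif="DD",
                    start=start0 + 1,
                    end=start0 + len(m),
                    matched=residues[start0 : start0 + len(m)],
                    exact=(mm == 0),
                )
    order = {name: k for k, name in enumerate(("B", "A", "B_ext", "C", "D", "DD", "E"))}
    return sorted(hits.values(), key=lambda h: order[h.motif])


@dataclass(frozen=True)
class CofactorCall:
    """NADPH-preference call from the motif-A window."""

    preference: str  # NADPH-preferring | NADPH-capable | indeterminate
    mode: int | str  # 1 | 2 | 3 | "unassigned"
    evidence: tuple[tuple[str, int, str], ...]  # (residue, query pos, rule)


def classify_cofactor(hits: Iterable[MotifHit],
                      query: ProteinRecord) -> CofactorCall:
    """Call cofactor preference from the motif-A (adenine/2'-phosphate)
    window.

    Arg/Lys in the window anchor the 2'-phosphate: two or more predict an
    NADPH-preferring enzyme, exactly one an NADPH-capable one. His residues
    (adenine stacking) are reported as evidence but do not count toward the
    preference. The phosphate-interaction mode is 1 when both Ser and Arg
    are present, else 2 for Lys, else 3 for Asn, else unassigned.
    """
    a_hit = next((h for h in hits if h.motif == "A"), None)
    if a_hit is None:
        return CofactorCall("indeterminate", "unassigned", ())
    window = a_hit.matched
    evidence: list[tuple[str, int, str]] = []
    n_anchor = 0
    for k, res in enumerate(window):
        pos = a_hit.start + k
        if res in "RK":
            n_anchor += 1
            evidence.append((res, pos, "basic 2'-phosphate anchor"))
        elif res == "H":
            evidence.append((res, pos, "adenine-stacking histidine"))
    if n_anchor >= 2:
        preference = "NADPH-preferring"
    elif n_anchor == 1:
        preference = "NADPH-capable"
    else:
        preference = "indeterminate"
    if "S" in window and "R" in window:
        mode: int | str = 1
        evidence.append(("S", a_hit.start + window.index("S"), "mode-1 serine"))
    elif "K" in window:
        mode = 2
    elif "N" in window:
        mode = 3
        evidence.append(("N", a_hit.start + window.index("N"), "mode-3 asparagine"))
    else:
        mode = "unassigned"
    return CofactorCall(preference, mode, tuple(evidence))


@dataclass(frozen=True)
class OligomerCall:
    """Decamer/dimer call with per-feature evidence.

    ``features`` maps feature name to 1.0/0.0 (present/absent), a fraction
    for the DD-consensus similarity, or None when the feature could not be
    evaluated (unmapped position).
    """

    state: str  # decamer | dimer | unknown
    score: float
    features: Mapping[str, float | None]


def dd_similarity(window: str) -> float:
    """Per-position class agreement of a 13-residue window with the decamer
    determinant consensus; the critical Gly/Pro positions weigh double."""
    if len(window) != len(DD_CONSENSUS):
        raise ValueError(
            f"determinant window must have {len(DD_CONSENSUS)} residues"
        )
    total = got = 0.0
    for idx, (res, allowed) in enumerate(zip(window, DD_CONSENSUS)):
        w = 2.0 if idx in DD_CRITICAL_IDX else 1.0
        total += w
        if any(res == a or same_class(res, a) for a in allowed):
            got += w
    return got / total


def _score_features(features: Mapping[str, float | None],
                    weights: Mapping[str, float],
                    decamer_threshold: float,
                    dimer_threshold: float) -> OligomerCall:
    num = den = 0.0
    for name, value in features.items():
        w = weights.get(name, 1.0)
        if value is None or w == 0.0:
            continue
        num += w * value
        den += w
    if den == 0.0:
        return OligomerCall("unknown", 0.0, dict(features))
    score = num / den
    if score >= decamer_threshold:
        state = "decamer"
    elif score <= dimer_threshold:
        state = "dimer"
    else:
        state = "unknown"
    return OligomerCall(state, score, dict(features))


def classify_dd_window(
    window: str,
    weights: Mapping[str, float] = DEFAULT_FEATURE_WEIGHTS,
    decamer_threshold: float = 0.5,
    dimer_threshold: float = 0.3,
) -> OligomerCall:
    """Classify a bare 13-residue determinant window (rice 202-214).

    Only the window-internal features (D203, G204, G205, P211, R212 and the
    consensus similarity) are evaluated; bridge residues outside the window
    are reported as unavailable.
    """
    features: dict[str, float | None] = {}
    for name, (ref_pos, expected) in FEATURE_POSITIONS.items():
        offset = ref_pos - 202
        if 0 <= offset < len(window):
            features[name] = 1.0 if window[offset] == expected else 0.0
        else:
            features[name] = None
    features["DD_similarity"] = dd_similarity(window)
    return _score_features(features, weights, decamer_threshold, dimer_threshold)


def classify_oligomer(
    query: ProteinRecord,
    anchors: AnchorMap | None = None,
    weights: Mapping[str, float] = DEFAULT_FEATURE_WEIGHTS,
    decamer_threshold: float = 0.5,
    dimer_threshold: float = 0.3,
) -> OligomerCall:
    """Call the oligomeric state (decamer / dimer / unknown) of a query.

    Every determinant feature is evaluated at its rice position, resolved
    through ``anchors`` when given, otherwise by fixed offsets from the
    unanchored motif-D hit. Queries whose C-terminal determinant region
    cannot be placed are called unknown.
    """
    residues = query.residues

    def resolve(ref_pos: int) -> int | None:  # -> 0-based query index
        if anchors is not None:
            q = anchors.query_position(ref_pos)
            return None if q is None else q - 1
        return None

    if anchors is None:
        hits = scan_fingerprint(query, anchors=None)
        d_hit = next((h for h in hits if h.motif == "D"), None)
        if d_hit is None:
            return OligomerCall("unknown", 0.0, {})
        d_ref_start = motif("D").ref_span[0]

        def resolve(ref_pos: int) -> int | None:  # noqa: F811
            idx = d_hit.start - 1 + (ref_pos - d_ref_start)
            return idx if 0 <= idx < len(residues) else None

    features: dict[str, float | None] = {}
    for name, (ref_pos, expected) in FEATURE_POSITIONS.items():
        idx = resolve(ref_pos)
        features[name] = None if idx is None else float(residues[idx] == expected)

    window_idx = [resolve(p) for p in range(202, 215)]
    if all(i is not None for i in window_idx):
        window = "".join(residues[i] for i in window_idx)  # type: ignore[index]
        features["DD_similarity"] = dd_similarity(window)
    else:
        features["DD_similarity"] = None

    if all(v is None for v in features.values()):
        return OligomerCall("unknown", 0.0, features)
    return _score_features(features, weights, decamer_threshold, dimer_threshold)


def conservation_fraction(alignment, region: tuple[int, int],
                          similarity_groups: Sequence[str] = SIMILARITY_GROUPS,
                          ) -> float:
    """Fraction of columns in ``region`` (1-based inclusive) that are
    identical or within one similarity group across all rows.

    Columns containing a gap in any row count as not conserved.
    """
    lo, hi = region
    width = len(alignment.rows[0])
    if not (1 <= lo <= hi <= width):
        raise ValueError(f"region {region} outside alignment width {width}")
    group_of = {res: g for g in similarity_groups for res in g}
    conserved = 0
    for col in range(lo - 1, hi):
        column = [row[col] for row in alignment.rows]
        if any(c in "-." for c in column):
            continue
        if len(set(column)) == 1:
            conserved += 1
            continue
        groups = {group_of.get(c) for c in column}
        if len(groups) == 1 and None not in groups:
            conserved += 1
    return conserved / (hi - lo + 1)


@dataclass(frozen=True)
class FingerprintReport:
    """Full per-sequence report: motif hits, cofactor and oligomer calls,
    and whether the family PA-line signature is present."""

    record_id: str
    hits: tuple[MotifHit, ...]
    cofactor: CofactorCall
    oligomer: OligomerCall
    is_p5cr_signature: bool

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "is_p5cr_signature": self.is_p5cr_signature,
            "hits": [
                {
                    "motif": h.motif,
                    "start": h.start,
                    "end": h.end,
                    "matched": h.matched,
                    "exact": h.exact,
                    "anchored_ref_span": list(h.anchored_ref_span)
                    if h.anchored_ref_span
                    else None,
                }
                for h in self.hits
            ],
            "cofactor": {
                "preference": self.cofactor.preference,
                "mode": self.cofactor.mode,
                "evidence": [list(e) for e in self.cofactor.evidence],
            },
            "oligomer": {
                "state": self.oligomer.state,
                "score": self.oligomer.score,
                "features": dict(self.oligomer.features),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def tsv_rows(self) -> list[tuple]:
        """One row per motif hit: (record, motif, start, end, matched, exact,
        oligomer state, cofactor preference)."""
        return [
            (
                self.record_id,
                h.motif,
                h.start,
                h.end,
                h.matched,
                h.exact,
                self.oligomer.state,
                self.cofactor.preference,
            )
            for h in self.hits
        ]


def fingerprint_report(
    query: ProteinRecord,
    reference: ProteinRecord | None = None,
    signature: str = P5CR_SIGNATURE,
    **classify_kwargs,
) -> FingerprintReport:
    """Run the full fingerprint pipeline on one sequence."""
    anchors = (
        anchor_to_reference(query, reference) if reference is not None else None
    )
    hits = scan_fingerprint(query, anchors)
    return FingerprintReport(
        record_id=query.id,
        hits=tuple(hits),
        cofactor=classify_cofactor(hits, query),
        oligomer=classify_oligomer(query, anchors, **classify_kwargs),
        is_p5cr_signature=bool(scan(parse_prosite(signature), query)),
    )
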