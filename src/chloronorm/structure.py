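"""Inference of the quadripartite LSC/IRb/SSC/IRa partition.

The primary route reads the two ``repeat_region`` annotations that plastome
annotators emit for the inverted repeats.  Records without such annotations
cannot be placed relative to the standard form and raise :class:`NoIRError`;
batch callers classify them as ``no_ir`` and omit them from standardization.
A de novo finder for bare sequences locates the longest pair of disjoint
arcs that are exact reverse complements of each other.
"""

from __future__ import annotations

import logging

from .errors import AmbiguousStructureError, NoIRError
from .genome_model import (
    AnnotatedSequence,
    Arc,
    RegionPartition,
    circular_slice,
    revcomp,
)

logger = logging.getLogger(__name__)

#: maximum allowed length difference between annotated IR copies (bp).
#: The two copies are identical in the idealized model; annotators may
#: disagree slightly at the boundaries.
DEFAULT_IR_LENGTH_TOLERANCE = 100

#: repeat annotations closer end-to-start than this are merged before
#: pairing: short-read assemblies misassign roughly 10 bp at IR boundaries.
DEFAULT_MERGE_GAP = 10

DEFAULT_MIN_IR_LEN = 10_000


def _feature_arc(feature, L: int) -> Arc:
    spans = feature.spans(L)
    start = spans[0][0]
    total = sum(s for _, s, _ in spans)
    return Arc(start, total)


def _merge_bookended(arcs: list[Arc], L: int, merge_gap: int) -> list[Arc]:
    """Merge arcs separated by at most ``merge_gap`` bp, circularly."""
    if len(arcs) <= 1:
        return arcs
    arcs = sorted(arcs, key=lambda a: a.start)
    merged = [arcs[0]]
    for arc in arcs[1:]:
        prev = merged[-1]
        gap = (arc.start - (prev.start + prev.length)) % L
        if gap <= merge_gap:
            merged[-1] = Arc(prev.start, prev.length + gap + arc.length)
        else:
            merged.append(arc)
    # wrap-around pair: last arc may abut the first across the origin
    if len(merged) > 1:
        first, last = merged[0], merged[-1]
        gap = (first.start - (last.start + last.length)) % L
        if gap <= merge_gap:
            merged[0] = Arc(last.start, last.length + gap + first.length)
            merged.pop()
    return merged


def partition_from_annotations(
    seq: AnnotatedSequence,
    ir_length_tolerance: int = DEFAULT_IR_LENGTH_TOLERANCE,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> RegionPartition:
    """Quadripartite partition from the record's repeat_region annotations.

    Exactly two non-overlapping repeat arcs of near-equal length (within
    ``ir_length_tolerance``) must remain after merging book-ended intervals.
    The two gaps between them are the single-copy regions; the longer gap is
    the LSC.  IRb/IRa labels are positional (IRb follows the LSC walking
    forward); ``standardize.assign_ir_labels`` makes them definitive.

    Raises
    ------
    NoIRError
        if fewer than two repeat annotations are present.
    AmbiguousStructureError
        if the repeats overlap, cannot be reduced to two arcs, differ in
        length beyond tolerance, or the single-copy gaps have equal length.
    """
    L = len(seq)
    repeats = seq.repeat_regions()
    arcs = _merge_bookended([_feature_arc(f, L) for f in repeats], L, merge_gap)
    if len(arcs) < 2:
        raise NoIRError(
            f"record {seq.id!r}: {len(arcs)} annotated inverted repeat(s); "
            "cannot determine the quadripartite structure"
        )
    if len(arcs) > 2:
        raise AmbiguousStructureError(
            f"record {seq.id!r}: {len(arcs)} repeat arcs remain after merging"
        )
    a, b = arcs
    if abs(a.length - b.length) > ir_length_tolerance:
        raise AmbiguousStructureError(
            f"record {seq.id!r}: IR copies differ in length by "
            f"{abs(a.length - b.length)} bp (> {ir_length_tolerance})"
        )
    gap_ab = (b.start - (a.start + a.length)) % L  # gap after a, before b
    gap_ba = (a.start - (b.start + b.length)) % L
    if gap_ab == 0 or gap_ba == 0:
        raise AmbiguousStructureError(
            f"record {seq.id!r}: IR arcs overlap or leave no single-copy region"
        )
    if gap_ab + gap_ba + a.length + b.length != L:
        raise AmbiguousStructureError(f"record {seq.id!r}: IR arcs overlap")
    if gap_ab == gap_ba:
        raise AmbiguousStructureError(
            f"record {seq.id!r}: single-copy regions have equal length"
        )
    sc_after_a = Arc((a.start + a.length) % L, gap_ab)
    sc_after_b = Arc((b.start + b.length) % L, gap_ba)
    if gap_ab > gap_ba:
        lsc, ssc = sc_after_a, sc_after_b
        irb, ira = b, a  # the copy following the LSC is positional IRb
    else:
        lsc, ssc = sc_after_b, sc_after_a
        irb, ira = a, b
    return RegionPartition(lsc, irb, ssc, ira, L)


# ---------------------------------------------------------------------------
# De novo inverted-repeat detection


def _maximal_inverted_matches(residues: str, min_len: int, seed_len: int):
    """Maximal exact matches between the sequence and its reverse complement,
    with circular wrap, as (a_start, b_start, length) arc pairs in original
    coordinates.  Seed-and-extend on doubled strings; per-diagonal coverage
    bookkeeping keeps repeated seeds inside one long match cheap."""
    L = len(residues)
    S2 = residues + residues
    T = revcomp(residues)
    T2 = T + T
    k = min(seed_len, min_len)
    index: dict[str, list[int]] = {}
    for j in range(len(T2) - k + 1):
        index.setdefault(T2[j : j + k], []).append(j)
    covered: dict[int, int] = {}  # diagonal (i - j) -> furthest i extended
    out = set()
    for i in range(len(S2) - k + 1):
        hits = index.get(S2[i : i + k])
        if not hits:
            continue
        for j in hits:
            d = i - j
            if covered.get(d, -1) >= i:
                continue
            # extend left and right within the doubled strings
            li, lj = i, j
            while li > 0 and lj > 0 and S2[li - 1] == T2[lj - 1]:
                li -= 1
                lj -= 1
            ri, rj = i + k, j + k
            while ri < len(S2) and rj < len(T2) and S2[ri] == T2[rj]:
                ri += 1
                rj += 1
            covered[d] = ri
            m = ri - li
            if m < min_len:
                continue
            m = min(m, L)  # a circular arc cannot exceed the sequence
            a_start = li % L
            # T2 position lj corresponds to the arc ending at L - lj in S
            b_start = (L - (lj % L) - m) % L
            pair = (a_start, b_start, m) if a_start <= b_start else (b_start, a_start, m)
            out.add(pair)
    return out


def _arcs_disjoint(a: Arc, b: Arc, L: int) -> bool:
    return (
        not a.contains_pos(b.start, L)
        and not b.contains_pos(a.start, L)
    )


def find_inverted_repeats(
    seq: AnnotatedSequence, min_len: int = DEFAULT_MIN_IR_LEN, seed_len: int = 32
) -> tuple[Arc, Arc]:
    """Longest pair of disjoint arcs that are exact reverse complements.

    Matching is exact (no mismatches) and wraps the origin.  Ties are broken
    by the smallest start coordinate of the first arc.  Raises
    :class:`NoIRError` when no pair of length >= ``min_len`` exists.
    """
    if min_len < 1:
        raise ValueError("min_len must be positive")
    L = len(seq)
    candidates = []
    for a_start, b_start, m in _maximal_inverted_matches(seq.residues, min_len, seed_len):
        a, b = Arc(a_start, m), Arc(b_start, m)
        if _arcs_disjoint(a, b, L):
            candidates.append((a, b))
    if not candidates:
        raise NoIRError(
            f"record {seq.id!r}: no inverted repeat of length >= {min_len} bp"
        )
    best = max(candidates, key=lambda ab: (ab[0].length, -ab[0].start))
    a, b = best
    assert circular_slice(seq.residues, a.start, a.length) == revcomp(
        circular_slice(seq.residues, b.start, b.length)
    )
    return a, b
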