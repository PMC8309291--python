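"""The standard-form engine: orientation tests, deviation classification,
and rewriting sequence + annotations into the standard form.

Standard form
-------------
The linearization of the circular plastome with its origin at the boundary
between IRa and LSC, reading forward into the LSC, region order
LSC, IRb, SSC, IRa, and each region oriented so that its characteristic
genes lie mostly on the negative strand: *rpl*/*rps* genes for the LSC,
all genes for the SSC, and *rrn* genes for IRb.

Two edit primitives suffice to reach standard form from any stored form:
a cyclic shift of the whole sequence, and in-place replacement of one or
more regions by their inverse complement.  Rotations whose circular
distance from zero is below ``MIN_OFFSET_BP`` (10 bp) are regarded as
IR-boundary misassignment noise, reported but not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ChloronormError, NoIRError, UndeterminedOrientationError
from .genome_model import (
    AnnotatedSequence,
    Arc,
    Feature,
    FormClassification,
    RegionPartition,
    Transformation,
    circular_distance,
    circular_slice,
    replace_circular_slice,
    revcomp,
)
from .structure import partition_from_annotations

logger = logging.getLogger(__name__)

#: minimum cyclic-shift offset (bp) that counts as a real shift; smaller
#: offsets are attributed to ~10 bp IR boundary misassignment in assemblies.
MIN_OFFSET_BP = 10


@dataclass(frozen=True)
class OrientationRule:
    """Gene-strand majority rule for one region's orientation.

    ``gene_filter`` is a set of case-insensitive gene-name prefixes
    (None = all genes).  In standard orientation more of the matching genes
    lie on the negative strand than on the positive strand.
    """

    region: str
    gene_filter: frozenset[str] | None


#: the three fixed rules; configuration constants, not user data.
ORIENTATION_RULES = {
    "LSC": OrientationRule("LSC", frozenset({"rpl", "rps"})),
    "SSC": OrientationRule("SSC", None),
    "IRb": OrientationRule("IRb", frozenset({"rrn"})),
}


def _name_matches(name: str | None, gene_filter: frozenset[str] | None) -> bool:
    if gene_filter is None:
        return True
    if name is None:
        return False
    low = name.lower()
    return any(low.startswith(p) for p in gene_filter)


def strand_counts(
    seq: AnnotatedSequence, arc: Arc, gene_filter: frozenset[str] | None
) -> tuple[int, int]:
    """(n_plus, n_minus) over gene features wholly inside ``arc``.

    Gene names are matched against the prefix filter case-insensitively.
    Features straddling an arc boundary are excluded (and logged); zero
    counts are legal output.
    """
    L = len(seq)
    n_plus = n_minus = 0
    for f in seq.genes():
        if not _name_matches(f.name, gene_filter):
            continue
        spans = f.spans(L)
        if not all(arc.contains_span(s, span, L) for s, span, _ in spans):
            if any(arc.contains_pos(s, L) for s, _, _ in spans):
                logger.debug("gene %s straddles arc %s; excluded", f.name, arc)
            continue
        if f.strand == "+":
            n_plus += 1
        elif f.strand == "-":
            n_minus += 1
    return n_plus, n_minus


def region_needs_flip(seq: AnnotatedSequence, arc: Arc, rule: OrientationRule) -> bool:
    """True iff the region is reversed relative to standard orientation.

    The primary gene filter decides by strand majority; a tie (including
    0 = 0) falls back to counting all genes in the arc; a persistent tie
    raises :class:`UndeterminedOrientationError` rather than guessing.
    """
    n_plus, n_minus = strand_counts(seq, arc, rule.gene_filter)
    if n_plus == n_minus:
        if rule.gene_filter is None:
            raise UndeterminedOrientationError(
                f"{rule.region} orientation tied at {n_plus}+/{n_minus}-"
            )
        n_plus, n_minus = strand_counts(seq, arc, None)
        if n_plus == n_minus:
            raise UndeterminedOrientationError(
                f"{rule.region} orientation tied even over all genes "
                f"({n_plus}+/{n_minus}-)"
            )
    return n_plus > n_minus


def assign_ir_labels(
    seq: AnnotatedSequence, partition: RegionPartition
) -> RegionPartition:
    """Definitive IRb/IRa labels from rRNA gene orientation.

    The copy whose *rrn* genes are majority-negative in its current reading
    is IRb.  When the labels so assigned disagree with the positional order
    (walking the circle from the LSC forward reads IRa, SSC, IRb), the
    orientation-based labels stand and the discrepancy is logged; it
    manifests as an inverted-IR cause downstream.
    """
    rrn = frozenset({"rrn"})
    pb, mb = strand_counts(seq, partition.irb, rrn)
    pa, ma = strand_counts(seq, partition.ira, rrn)
    if pb + mb + pa + ma == 0:
        raise UndeterminedOrientationError(
            f"record {seq.id!r}: no rrn genes in either IR copy"
        )
    neg_copies = [mb > pb, ma > pa]
    pos_copies = [pb > mb, pa > ma]
    if sum(neg_copies) == 1:
        b_is_first = neg_copies[0]
    elif sum(pos_copies) == 1:
        b_is_first = not pos_copies[0]
    else:
        raise UndeterminedOrientationError(
            f"record {seq.id!r}: rrn orientation does not single out one IR copy "
            f"({pb}+/{mb}- vs {pa}+/{ma}-)"
        )
    if b_is_first:
        return partition
    logger.info(
        "record %s: orientation labels IRs in the order IRa, SSC, IRb; "
        "the molecule deviates from standard form",
        seq.id,
    )
    return RegionPartition(
        partition.lsc,
        partition.ira,
        partition.ssc,
        partition.irb,
        partition.genome_length,
    )


def compute_offset(partition: RegionPartition, genome_length: int) -> int:
    """Raw cyclic-shift offset in [0, L): the circular position of the LSC
    start boundary, i.e. the rotation that would move it to position 0."""
    return partition.lsc.start % genome_length


def _flip_tests(seq: AnnotatedSequence, partition: RegionPartition) -> frozenset[str]:
    """Set of region labels whose orientation tests fail (LSC/SSC/IR).

    The IR test runs on the positional IRb copy (the one following the LSC):
    its *rrn* genes must be majority-negative."""
    flipped = set()
    if region_needs_flip(seq, partition.lsc, ORIENTATION_RULES["LSC"]):
        flipped.add("LSC")
    if region_needs_flip(seq, partition.ssc, ORIENTATION_RULES["SSC"]):
        flipped.add("SSC")
    if region_needs_flip(seq, partition.irb, ORIENTATION_RULES["IRb"]):
        flipped.add("IR")
    return frozenset(flipped)


def classify_form(
    seq: AnnotatedSequence, min_offset: int = MIN_OFFSET_BP
) -> FormClassification:
    """Diagnose how the stored sequence deviates from the standard form.

    Causes gathered: a cyclic shift whenever the circular distance of the
    offset reaches ``min_offset``, plus each failing orientation test.
    Exactly one cause names its category; two or more give ``combination``;
    none is ``standard``.  Records without a usable IR pair are ``no_ir``
    with offset and flips undefined.
    """
    try:
        partition = partition_from_annotations(seq)
    except NoIRError:
        return FormClassification("no_ir", None, None)
    L = len(seq)
    try:
        flipped = _flip_tests(seq, partition)
    except UndeterminedOrientationError as exc:
        raise UndeterminedOrientationError(f"record {seq.id!r}: {exc}") from exc
    offset = compute_offset(partition, L)
    shifted = circular_distance(offset, L) >= min_offset
    n_causes = len(flipped) + int(shifted)
    if n_causes == 0:
        category = "standard"
    elif n_causes > 1:
        category = "combination"
    elif shifted:
        category = "cyclic_shift"
    else:
        category = {"LSC": "inverted_lsc", "SSC": "inverted_ssc", "IR": "inverted_ir"}[
            next(iter(flipped))
        ]
    return FormClassification(category, offset, flipped)


# ---------------------------------------------------------------------------
# Edit primitives shared with the synthetic-corruption machinery


def rotate_record(seq: AnnotatedSequence, rotate_by: int) -> AnnotatedSequence:
    """New record starting at source position ``rotate_by`` (p -> (p - r) mod L)."""
    L = len(seq)
    r = rotate_by % L
    if r == 0:
        return AnnotatedSequence(seq.id, seq.residues, seq.circular, list(seq.features))
    residues = seq.residues[r:] + seq.residues[:r]
    features = []
    for f in seq.features:
        spans = [((s - r) % L, span, st) for s, span, st in f.spans(L)]
        features.append(Feature.from_spans(f.kind, f.name, spans, L))
    return AnnotatedSequence(seq.id, residues, seq.circular, features)


def _mirror_span(
    span: tuple[int, int, str | None], arc: Arc, L: int
) -> tuple[int, int, str | None]:
    s, length, st = span
    offset = arc.offset_of(s, L)
    new_offset = arc.length - (offset + length)
    new_strand = {"+": "-", "-": "+", None: None}[st]
    return ((arc.start + new_offset) % L, length, new_strand)


def invert_arc_record(seq: AnnotatedSequence, arc: Arc) -> AnnotatedSequence:
    """Replace the arc's content by its inverse complement, in place.

    Features wholly inside the arc are mirrored (coordinates reflected,
    strand flipped); features wholly outside are untouched; features
    straddling the arc boundary are dropped with a warning.
    """
    L = len(seq)
    residues = replace_circular_slice(
        seq.residues, arc.start, revcomp(circular_slice(seq.residues, arc.start, arc.length))
    )
    features = []
    dropped = []
    for f in seq.features:
        spans = f.spans(L)
        new_spans = []
        for sp in spans:
            s, length, st = sp
            span_arc = Arc(s, length)
            if arc.contains_span(s, length, L):
                new_spans.append(_mirror_span(sp, arc, L))
            elif (
                arc.contains_pos(s, L)
                or arc.contains_pos((s + length - 1) % L, L)
                or span_arc.contains_pos(arc.start, L)
            ):
                dropped.append(f.name or f.kind)
                new_spans = None
                break
            else:
                new_spans.append(sp)
        if new_spans is not None:
            features.append(Feature.from_spans(f.kind, f.name, new_spans, L))
    if dropped:
        logger.warning(
            "inverting arc %s dropped %d boundary-straddling feature(s): %s",
            arc,
            len(dropped),
            ", ".join(dropped),
        )
    return AnnotatedSequence(seq.id, residues, seq.circular, features)


def revcomp_record(seq: AnnotatedSequence) -> AnnotatedSequence:
    """Reverse complement of the whole molecule, features remapped."""
    L = len(seq)
    residues = revcomp(seq.residues)
    features = []
    for f in seq.features:
        spans = [
            ((L - s - length) % L, length, {"+": "-", "-": "+", None: None}[st])
            for s, length, st in f.spans(L)
        ]
        features.append(Feature.from_spans(f.kind, f.name, spans, L))
    return AnnotatedSequence(seq.id, residues, seq.circular, features)


# ---------------------------------------------------------------------------
# Standardization


def _expand_invert_labels(invert: tuple[str, ...]) -> set[str]:
    arcs = set()
    for label in invert:
        arcs.update({"IR": {"IRb", "IRa"}}.get(label, {label}))
    return arcs


def remap_features(
    features: list[Feature],
    transformation: Transformation,
    partition: RegionPartition,
    genome_length: int,
) -> list[Feature]:
    """Map features through a standardizing transformation.

    ``partition`` is the region partition *after* rotation (standard-form
    coordinates).  Rotation shifts coordinates mod L; a span inside an
    inverted region arc is reflected within the arc with its strand flipped.
    Features with a span straddling a region boundary are dropped with one
    warning listing their names.
    """
    L = genome_length
    r = transformation.rotate_by
    inverted = _expand_invert_labels(transformation.invert)
    arcs = partition.arcs()
    out = []
    dropped = []
    for f in features:
        new_spans = []
        for s, length, st in f.spans(L):
            s = (s - r) % L
            region = partition.region_of_span(s, length)
            if region is None:
                dropped.append(f.name or f.kind)
                new_spans = None
                break
            if region in inverted:
                new_spans.append(_mirror_span((s, length, st), arcs[region], L))
            else:
                new_spans.append((s, length, st))
        if new_spans is not None:
            out.append(Feature.from_spans(f.kind, f.name, new_spans, L))
    if dropped:
        logger.warning(
            "standardization dropped %d feature(s) straddling region boundaries: %s",
            len(dropped),
            ", ".join(dropped),
        )
    return out


def to_standard_form(
    seq: AnnotatedSequence, min_offset: int = MIN_OFFSET_BP
) -> tuple[AnnotatedSequence, Transformation]:
    """Rewrite sequence + annotations into standard form.

    Returns the standardized record and the :class:`Transformation` that
    produced it.  Offsets below the circular-distance threshold are left in
    place (``rotate_by`` stays 0); region inversions then operate on the
    record's actual arcs.  Standard input comes back unchanged with the
    identity transformation.
    """
    partition = partition_from_annotations(seq)
    L = len(seq)
    try:
        flipped = _flip_tests(seq, partition)
    except UndeterminedOrientationError as exc:
        raise UndeterminedOrientationError(f"record {seq.id!r}: {exc}") from exc
    offset = compute_offset(partition, L)
    rotate_by = offset if circular_distance(offset, L) >= min_offset else 0
    invert = tuple(label for label in ("LSC", "SSC", "IR") if label in flipped)
    transformation = Transformation(rotate_by=rotate_by, invert=invert)
    if transformation.is_identity:
        copy = AnnotatedSequence(seq.id, seq.residues, seq.circular, list(seq.features))
        return copy, transformation
    std = apply_transformation(seq, transformation, partition=partition)
    return std, transformation


def apply_transformation(
    seq: AnnotatedSequence,
    transformation: Transformation,
    partition: RegionPartition | None = None,
) -> AnnotatedSequence:
    """Replay a recorded transformation on its source record.

    Deterministic: recording with :func:`to_standard_form` and replaying
    here yields the standardized record exactly.
    """
    if partition is None:
        partition = partition_from_annotations(seq)
    L = len(seq)
    rotated_partition = partition.rotated(transformation.rotate_by)
    r = transformation.rotate_by % L
    residues = seq.residues[r:] + seq.residues[:r] if r else seq.residues
    arcs = rotated_partition.arcs()
    for label in _expand_invert_labels(transformation.invert):
        arc = arcs[label]
        residues = replace_circular_slice(
            residues, arc.start, revcomp(circular_slice(residues, arc.start, arc.length))
        )
    features = remap_features(seq.features, transformation, rotated_partition, L)
    return AnnotatedSequence(seq.id, residues, seq.circular, features)


# ---------------------------------------------------------------------------
# Batch census


@dataclass
class BatchReport:
    """Machine-readable census of stored-form deviations in a batch."""

    records: pd.DataFrame  # one row per record: id, category, offset, flips
    census: pd.DataFrame  # one row per category: count, percent

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.census.to_string(index=False)


_CENSUS_ORDER = (
    "standard",
    "cyclic_shift",
    "inverted_lsc",
    "inverted_ssc",
    "inverted_ir",
    "combination",
    "no_ir",
    "undetermined",
)


def batch_report(records: list[AnnotatedSequence]) -> BatchReport:
    """Classify every record and tabulate per-category counts/percentages.

    Per-record orientation failures are tallied as ``undetermined`` rather
    than aborting the batch.  Record ids must be unique.
    """
    if not records:
        raise ValueError("empty batch")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in batch")
    rows = []
    for seq in records:
        try:
            c = classify_form(seq)
            flips = ",".join(sorted(c.flipped_regions)) if c.flipped_regions else ""
            rows.append((seq.id, c.category, c.offset_bp, flips))
        except ChloronormError as exc:
            logger.warning("record %s: %s", seq.id, exc)
            rows.append((seq.id, "undetermined", None, None))
    records_df = pd.DataFrame(
        rows, columns=["id", "category", "offset_bp", "flipped_regions"]
    )
    counts = records_df["category"].value_counts()
    census_rows = [
        (cat, int(counts.get(cat, 0)), 100.0 * counts.get(cat, 0) / len(records))
        for cat in _CENSUS_ORDER
        if counts.get(cat, 0) > 0
    ]
    census_df = pd.DataFrame(census_rows, columns=["category", "count", "percent"])
    return BatchReport(records=records_df, census=census_df)
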