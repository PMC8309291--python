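"""Domain types for circular annotated genomes and their file formats.

Coordinate convention
---------------------
Internal coordinates are **0-based half-open** throughout the package.
GenBank and GFF3 both use 1-based inclusive coordinates; the conversion
happens only inside :func:`read_record` / :func:`write_record`.

All position arithmetic treats the molecule as circular.  A feature whose
location crosses the origin (a GenBank ``join(a..L,1..b)``) is stored as a
single :class:`Feature` with ``wraps_origin=True`` and two intervals, the
first ending at the sequence length and the second starting at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, MissingAnnotationError

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "repeat_region", "other")
#: kinds for which a strand is mandatory
STRANDED_KINDS = frozenset({"gene", "CDS", "tRNA", "rRNA"})
REGION_LABELS = ("LSC", "IRb", "SSC", "IRa")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return s.translate(_COMPLEMENT)[::-1]


def circular_distance(offset: int, length: int) -> int:
    """Distance of a rotation offset from 0 on a circle of ``length`` bp.

    A rotation of ``length - 7`` is only 7 bp away from no rotation at all,
    so ``circular_distance(length - 7, length) == 7``.
    """
    o = offset % length
    return min(o, length - o)


def circular_slice(residues: str, start: int, span: int) -> str:
    """``span`` bp of ``residues`` starting at ``start``, wrapping the origin."""
    length = len(residues)
    start %= length
    if span > length:
        raise ValueError("slice longer than the sequence")
    end = start + span
    if end <= length:
        return residues[start:end]
    return residues[start:] + residues[: end - length]


def replace_circular_slice(residues: str, start: int, content: str) -> str:
    """Return ``residues`` with ``content`` written at ``start``, wrapping."""
    length = len(residues)
    start %= length
    end = start + len(content)
    if end <= length:
        return residues[:start] + content + residues[end:]
    tail = end - length
    return content[length - start:] + residues[tail:start] + content[: length - start]


@dataclass(frozen=True)
class Arc:
    """A directed arc on the circle: ``length`` bp starting at ``start``.

    Stored as (start, length) rather than (start, end) so that arcs which
    wrap the origin need no special casing.
    """

    start: int
    length: int

    def end(self, genome_length: int) -> int:
        """Exclusive end position, modulo the genome length."""
        return (self.start + self.length) % genome_length

    def contains_pos(self, pos: int, genome_length: int) -> bool:
        return (pos - self.start) % genome_length < self.length

    def contains_span(self, start: int, span: int, genome_length: int) -> bool:
        """True iff the ``span`` bp beginning at ``start`` lie wholly inside."""
        offset = (start - self.start) % genome_length
        return offset + span <= self.length

    def offset_of(self, pos: int, genome_length: int) -> int:
        return (pos - self.start) % genome_length

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.start},+{self.length})"


@dataclass
class Feature:
    """A typed, stranded annotation on a circular sequence.

    ``intervals`` is a tuple of ``(start, end, strand)`` with 0-based
    half-open coordinates, ``0 <= start < end <= L`` for each interval and
    strand in ``{"+", "-", None}``.  When ``wraps_origin`` is true the
    feature has exactly two intervals, ``(a, L)`` followed by ``(0, b)``,
    which form one contiguous span across the origin.
    """

    kind: str
    name: str | None
    intervals: tuple[tuple[int, int, str | None], ...]
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        self.intervals = tuple((int(s), int(e), st) for s, e, st in self.intervals)
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.intervals:
            raise ValueError("feature with no intervals")
        for s, e, st in self.intervals:
            if not s < e:
                raise ValueError(f"empty or inverted interval ({s}, {e})")
            if st not in ("+", "-", None):
                raise ValueError(f"bad strand {st!r}")
            if st is None and self.kind in STRANDED_KINDS:
                raise ValueError(f"{self.kind} feature requires a strand")
        if self.wraps_origin:
            if len(self.intervals) != 2 or self.intervals[1][0] != 0:
                raise ValueError("origin-wrapping feature must be (a,L)+(0,b)")

    @property
    def strand(self) -> str | None:
        return self.intervals[0][2]

    def spans(self, genome_length: int) -> list[tuple[int, int, str | None]]:
        """Logical circular spans as ``(start, span_length, strand)``.

        An origin-wrapping pair of intervals collapses into one span whose
        length exceeds the distance to the sequence end.
        """
        if self.wraps_origin:
            (s1, e1, st), (_, e2, _) = self.intervals
            if e1 != genome_length:
                raise ValueError("wrapping feature does not touch sequence end")
            return [(s1, (e1 - s1) + e2, st)]
        return [(s, e - s, st) for s, e, st in self.intervals]

    @classmethod
    def from_spans(
        cls,
        kind: str,
        name: str | None,
        spans: list[tuple[int, int, str | None]],
        genome_length: int,
    ) -> "Feature":
        """Build a feature from circular spans, splitting any span that
        crosses the origin into the canonical two-interval form."""
        intervals: list[tuple[int, int, str | None]] = []
        wraps = False
        for start, span, st in spans:
            start %= genome_length
            end = start + span
            if end <= genome_length:
                intervals.append((start, end, st))
            else:
                if len(spans) != 1:
                    raise ValueError("only single-span features may wrap the origin")
                wraps = True
                intervals.append((start, genome_length, st))
                intervals.append((0, end - genome_length, st))
        return cls(kind, name, tuple(intervals), wraps_origin=wraps)

    def total_length(self, genome_length: int) -> int:
        return sum(span for _, span, _ in self.spans(genome_length))


@dataclass
class AnnotatedSequence:
    """A circular DNA record with typed, stranded features.

    Residues are uppercased on construction; characters outside A/C/G/T/N
    are rejected so that reverse complementation is deterministic.  The
    ``circular`` flag records what the source file claimed; the package's
    arithmetic treats every record as circular regardless (a warning is
    logged at read time when the flag was absent).
    """

    id: str
    residues: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in record {self.id!r}")
        L = len(self.residues)
        for f in self.features:
            for s, e, _ in f.intervals:
                if not (0 <= s < e <= L):
                    raise ValueError(
                        f"feature {f.name!r} interval ({s},{e}) outside [0,{L})"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    def repeat_regions(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "repeat_region"]


@dataclass(frozen=True)
class RegionPartition:
    """The four arcs of the quadripartite structure on the circle.

    Invariants: the arcs are pairwise disjoint, jointly cover the circle,
    and ``len(LSC) >= len(SSC)``.  IRb/IRa labels are positional here
    (IRb is the copy encountered walking forward from the LSC); definitive
    orientation-based labels are assigned by ``standardize.assign_ir_labels``.
    """

    lsc: Arc
    irb: Arc
    ssc: Arc
    ira: Arc
    genome_length: int

    def __post_init__(self) -> None:
        L = self.genome_length
        arcs = [self.lsc, self.irb, self.ssc, self.ira]
        if sum(a.length for a in arcs) != L:
            raise ValueError("partition arcs do not cover the circle")
        if any(a.length <= 0 for a in arcs):
            raise ValueError("empty partition arc")
        ordered = sorted(arcs, key=lambda a: a.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.start + a.length != b.start:
                raise ValueError("partition arcs overlap or leave a gap")
        last = ordered[-1]
        if (last.start + last.length) % L != ordered[0].start:
            raise ValueError("partition arcs do not close the circle")
        if self.lsc.length < self.ssc.length:
            raise ValueError("LSC shorter than SSC")

    def arcs(self) -> dict[str, Arc]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def rotated(self, rotate_by: int) -> "RegionPartition":
        """The same partition after rotating the sequence by ``rotate_by``
        (position p moves to ``(p - rotate_by) mod L``)."""
        L = self.genome_length

        def rot(a: Arc) -> Arc:
            return Arc((a.start - rotate_by) % L, a.length)

        return RegionPartition(
            rot(self.lsc), rot(self.irb), rot(self.ssc), rot(self.ira), L
        )

    def region_of_span(self, start: int, span: int) -> str | None:
        """Label of the region wholly containing the span, else None."""
        for label, arc in self.arcs().items():
            if arc.contains_span(start, span, self.genome_length):
                return label
        return None


FORM_CATEGORIES = (
    "standard",
    "cyclic_shift",
    "inverted_lsc",
    "inverted_ssc",
    "inverted_ir",
    "combination",
    "no_ir",
)


@dataclass(frozen=True)
class FormClassification:
    """Diagnosis of how a stored sequence deviates from the standard form.

    ``offset_bp`` is the raw rotation of the LSC start away from position 0,
    in ``[0, L)``; it counts as a cyclic-shift cause only when its circular
    distance from 0 reaches the configured minimum (default 10 bp).  Both
    ``offset_bp`` and ``flipped_regions`` are None for ``no_ir`` records,
    where the partition is undeterminable.
    """

    category: str
    offset_bp: int | None
    flipped_regions: frozenset[str] | None

    def __post_init__(self) -> None:
        if self.category not in FORM_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class Transformation:
    """An auditable edit script converting a record to standard form.

    ``rotate_by`` is applied first: position ``p`` of the source moves to
    ``(p - rotate_by) mod L`` (i.e. the new sequence starts at source
    position ``rotate_by``).  ``invert`` then lists the region labels
    (``LSC``, ``SSC``, ``IR``) whose content is replaced by its inverse
    complement in standard-form coordinates; ``IR`` means both copies.
    """

    rotate_by: int = 0
    invert: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for label in self.invert:
            if label not in ("LSC", "SSC", "IR"):
                raise ValueError(f"unknown invert label {label!r}")

    @property
    def is_identity(self) -> bool:
        return self.rotate_by == 0 and not self.invert


# ---------------------------------------------------------------------------
# File I/O


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbf", ".genbank"):
        return "genbank"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta+gff"
    raise FormatError(f"cannot infer format from suffix of {path}")


def _strand_to_int(st: str | None) -> int | None:
    return {"+": 1, "-": -1, None: None}[st]


def _strand_from_int(st: int | None) -> str | None:
    if st is None or st == 0:
        return None
    return "+" if st > 0 else "-"


_NAME_QUALIFIERS = ("gene", "standard_name", "note", "product", "locus_tag")


def _feature_from_biopython(f: SeqFeature, L: int) -> Feature:
    kind = f.type if f.type in FEATURE_KINDS else "other"
    name = None
    for q in _NAME_QUALIFIERS:
        if q in f.qualifiers and f.qualifiers[q]:
            name = str(f.qualifiers[q][0])
            break
    parts = [(int(p.start), int(p.end), _strand_from_int(p.strand)) for p in f.location.parts]
    if kind not in STRANDED_KINDS:
        # GenBank cannot express strandlessness: a plain (non-complement)
        # location on a strand-free kind reads back as strandless
        parts = [(s, e, None if st == "+" else st) for s, e, st in parts]
    # a minus-strand join is listed in biological join order either way;
    # normalize an origin-crossing pair to (a, L) then (0, b)
    wraps = False
    if len(parts) == 2:
        ends_at_L = [p for p in parts if p[1] == L]
        starts_at_0 = [p for p in parts if p[0] == 0 and p[1] < L]
        if len(ends_at_L) == 1 and len(starts_at_0) == 1:
            parts = [ends_at_L[0], starts_at_0[0]]
            wraps = True
    return Feature(kind, name, tuple(parts), wraps_origin=wraps)


def _feature_to_biopython(f: Feature) -> SeqFeature:
    locs = [
        SimpleLocation(s, e, _strand_to_int(st) if st else 1) for s, e, st in f.intervals
    ]
    location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    ftype = f.kind if f.kind != "other" else "misc_feature"
    qualifiers: dict[str, list[str]] = {}
    if f.name is not None:
        key = "note" if f.kind == "repeat_region" else "gene"
        qualifiers[key] = [f.name]
    return SeqFeature(location, type=ftype, qualifiers=qualifiers)


def read_record(
    path: str | Path, format: str | None = None, gff_path: str | Path | None = None
) -> AnnotatedSequence:
    """Read a GenBank flat file or a FASTA + GFF3 pair into the model.

    ``format`` is ``"genbank"`` or ``"fasta+gff"`` (inferred from the suffix
    when omitted).  For FASTA input the companion GFF3 defaults to the FASTA
    path with a ``.gff3`` suffix and must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "genbank":
        return _read_genbank(path)
    if fmt == "fasta+gff":
        gff = Path(gff_path) if gff_path is not None else path.with_suffix(".gff3")
        return _read_fasta_gff(path, gff)
    raise FormatError(f"unknown format {fmt!r}")


def _read_genbank(path: Path) -> AnnotatedSequence:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"failed to parse GenBank file {path}: {exc}") from exc
    circular = rec.annotations.get("topology") == "circular"
    if not circular:
        logger.warning(
            "record %s lacks a circular topology flag; treating it as circular",
            rec.id,
        )
    L = len(rec.seq)
    features = [
        _feature_from_biopython(f, L) for f in rec.features if f.type != "source"
    ]
    return AnnotatedSequence(rec.id, str(rec.seq), circular=True, features=features)


def _read_fasta_gff(fasta_path: Path, gff_path: Path) -> AnnotatedSequence:
    if not gff_path.exists():
        raise MissingAnnotationError(
            f"FASTA record {fasta_path} has no companion annotation {gff_path}"
        )
    try:
        rec = SeqIO.read(str(fasta_path), "fasta")
    except ValueError as exc:
        raise FormatError(f"failed to parse FASTA file {fasta_path}: {exc}") from exc
    L = len(rec.seq)
    # group GFF lines by ID attribute so origin-wrapping two-line features
    # come back as a single Feature
    groups: dict[str, list] = {}
    order: list[str] = []
    for n, line in enumerate(gffutils.DataIterator(str(gff_path))):
        key = line.attributes["ID"][0] if "ID" in line.attributes else f"__line{n}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(line)
    features = []
    for key in order:
        lines = groups[key]
        kind = lines[0].featuretype if lines[0].featuretype in FEATURE_KINDS else "other"
        name = lines[0].attributes["Name"][0] if "Name" in lines[0].attributes else None
        strand = lines[0].strand if lines[0].strand in ("+", "-") else None
        parts = [(line.start - 1, line.end, strand) for line in lines]
        wraps = False
        if len(parts) == 2:
            ends_at_L = [p for p in parts if p[1] == L]
            starts_at_0 = [p for p in parts if p[0] == 0 and p[1] < L]
            if len(ends_at_L) == 1 and len(starts_at_0) == 1:
                parts = [ends_at_L[0], starts_at_0[0]]
                wraps = True
        features.append(Feature(kind, name, tuple(parts), wraps_origin=wraps))
    return AnnotatedSequence(rec.id, str(rec.seq), circular=True, features=features)


def write_record(
    seq: AnnotatedSequence,
    path: str | Path,
    format: str | None = None,
    gff_path: str | Path | None = None,
) -> None:
    """Write the record as GenBank or FASTA + GFF3.

    The emitted file re-reads to an equal record.  Zero-length intervals
    cannot be encoded and raise :class:`FormatError` (they are already
    rejected at :class:`Feature` construction).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "genbank":
        _write_genbank(seq, path)
    elif fmt == "fasta+gff":
        gff = Path(gff_path) if gff_path is not None else path.with_suffix(".gff3")
        _write_fasta_gff(seq, path, gff)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def _write_genbank(seq: AnnotatedSequence, path: Path) -> None:
    rec = SeqRecord(Seq(seq.residues), id=seq.id, name=seq.id[:16], description="")
    rec.annotations = {
        "molecule_type": "DNA",
        "topology": "circular",
        "data_file_division": "PLN",
    }
    rec.features = [_feature_to_biopython(f) for f in seq.features]
    SeqIO.write(rec, str(path), "genbank")


def _write_fasta_gff(seq: AnnotatedSequence, fasta_path: Path, gff_path: Path) -> None:
    rec = SeqRecord(Seq(seq.residues), id=seq.id, description="")
    SeqIO.write(rec, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seq.id} 1 {len(seq)}\n")
        for i, f in enumerate(seq.features):
            attrs = f"ID={seq.id}.f{i}"
            if f.name is not None:
                attrs += f";Name={f.name}"
            ftype = f.kind if f.kind != "other" else "misc_feature"
            for s, e, st in f.intervals:
                cols = [
                    seq.id,
                    "chloronorm",
                    ftype,
                    str(s + 1),
                    str(e),
                    ".",
                    st if st else ".",
                    ".",
                    attrs,
                ]
                fh.write("\t".join(cols) + "\n")
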