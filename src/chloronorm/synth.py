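"""Synthetic plastomes with ground-truth structure, corruption operators,
and random trees — the fixture factory for the whole package.

The generator emits a standard-form plastome: exact inverted repeats
(IRa bit-exactly the reverse complement of IRb), gene features planted
wholly inside regions with names from the real plastid vocabularies, and
strands assigned by exact quota so the orientation majorities can never
tie by chance.  Default region sizes (84 kb LSC, 25 kb IRs, 18 kb SSC,
152 kb total) sit inside the 120-160 kb envelope typical of land-plant
chloroplast genomes.

Corruption operators apply the inverse of standardization — cyclic shifts,
in-place region inverse-complements, whole-molecule reverse complement —
so round-trip tests can assert bit-exact recovery.  A small state algebra
(:func:`expected_classification`) predicts, independently of the
gene-counting classifier, which deviation causes a corruption recipe
produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genome_model import (
    AnnotatedSequence,
    Arc,
    Feature,
    FormClassification,
    RegionPartition,
    circular_distance,
    revcomp,
)
from .standardize import (
    MIN_OFFSET_BP,
    invert_arc_record,
    revcomp_record,
    rotate_record,
)
from .structure import partition_from_annotations
from .treedist import PhyloTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_VOCAB = {
    "rpl": ["rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32", "rpl33", "rpl36"],
    "rps": ["rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14", "rps15",
            "rps16", "rps18", "rps19"],
    "rrn": ["rrn16", "rrn23", "rrn4.5", "rrn5"],
    "psb": ["psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI"],
    "ndh": ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH", "ndhI",
            "ndhJ", "ndhK"],
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic plastome generator.

    ``neg_strand_fraction`` applies to each orientation-bearing gene class
    (rpl/rps in the LSC, all genes in the SSC, rrn in each IR copy); it
    must exceed 0.5 so strand majorities are well defined, and the rounded
    quota must not tie.
    """

    lsc_len: int = 84_000
    ir_len: int = 25_000
    ssc_len: int = 18_000
    lsc_rplrps_genes: int = 20
    lsc_other_genes: int = 6
    ssc_genes: int = 12
    ir_rrn_genes: int = 4
    neg_strand_fraction: float = 0.75
    gene_len_range: tuple[int, int] = (300, 1500)
    seed: int = 0

    @property
    def total_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    def validate(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise ValueError("region lengths must be positive")
        if self.lsc_len <= self.ssc_len:
            raise ValueError("LSC must be longer than SSC")
        if self.ssc_genes < 1:
            raise ValueError(
                "SSC must host at least one gene or its orientation is undeterminable"
            )
        if self.lsc_rplrps_genes < 1 or self.ir_rrn_genes < 1:
            raise ValueError("LSC rpl/rps and IR rrn gene counts must be positive")
        if not 0.5 < self.neg_strand_fraction <= 1.0:
            raise ValueError("neg_strand_fraction must be in (0.5, 1]")
        for n in (self.lsc_rplrps_genes, self.ssc_genes, self.ir_rrn_genes):
            if round(self.neg_strand_fraction * n) * 2 == n:
                raise ValueError(
                    f"strand quota ties for {n} genes at fraction "
                    f"{self.neg_strand_fraction}"
                )


def _quota_strands(n: int, neg_fraction: float, rng: np.random.Generator) -> list[str]:
    """Exactly round(neg_fraction*n) minus-strand genes, shuffled."""
    n_neg = round(neg_fraction * n)
    strands = ["-"] * n_neg + ["+"] * (n - n_neg)
    rng.shuffle(strands)
    return strands


def _gene_names(prefixes: list[str], n: int) -> list[str]:
    pool = [name for p in prefixes for name in GENE_VOCAB[p]]
    names = []
    round_no = 0
    while len(names) < n:
        for name in pool:
            suffix = "" if round_no == 0 else f"_{round_no}"
            names.append(name + suffix)
            if len(names) == n:
                break
        round_no += 1
    return names


def _place_genes(
    arc: Arc,
    names: list[str],
    strands: list[str],
    spec: SynthSpec,
    rng: np.random.Generator,
    L: int,
) -> list[Feature]:
    """Non-overlapping placement inside the arc.

    Gene lengths are drawn first; the remaining slack is then split into
    random inter-gene gaps, so placement succeeds whenever the genes fit
    at all (a rejection loop would stall on densely packed regions)."""
    lo, hi = spec.gene_len_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in names]
    slack = arc.length - sum(lengths)
    if slack < 0:
        raise ValueError(
            f"region {arc} too small to host {len(names)} genes of "
            f"{lo}-{hi} bp without overlap"
        )
    cuts = sorted(int(c) for c in rng.integers(0, slack + 1, size=len(names)))
    features = []
    cursor = 0
    prev_cut = 0
    for name, strand, glen, cut in zip(names, strands, lengths, cuts):
        cursor += cut - prev_cut
        prev_cut = cut
        start = (arc.start + cursor) % L
        features.append(Feature.from_spans("gene", name, [(start, glen, strand)], L))
        cursor += glen
    return features


def generate_genome(spec: SynthSpec | None = None) -> tuple[AnnotatedSequence, RegionPartition]:
    """A standard-form plastome plus its ground-truth partition.

    Deterministic in ``spec.seed``; IRa is set bit-exactly to the reverse
    complement of IRb, and every orientation quota is met exactly, so the
    output always classifies as standard.
    """
    spec = spec or SynthSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.total_len
    lsc = Arc(0, spec.lsc_len)
    irb = Arc(spec.lsc_len, spec.ir_len)
    ssc = Arc(spec.lsc_len + spec.ir_len, spec.ssc_len)
    ira = Arc(spec.lsc_len + spec.ir_len + spec.ssc_len, spec.ir_len)

    head_len = spec.lsc_len + spec.ir_len + spec.ssc_len
    head = bytearray(_BASES[rng.integers(0, 4, head_len)].tobytes())
    # force mismatches at the IR boundaries so the exact repeat is maximal
    # at precisely the planted arcs: a chance complementary base just outside
    # either boundary would let de novo detection extend past them
    comp = dict(zip(b"ACGT", b"TGCA"))
    for inside, outside in ((lsc.length - 1, 0), (ssc.start, ssc.end(L) - 1)):
        if head[inside] == comp[head[outside]]:
            head[inside] = next(b for b in b"ACGT" if b != comp[head[outside]])
    head = head.decode()
    irb_seq = head[irb.start : irb.start + irb.length]
    residues = head + revcomp(irb_seq)

    features: list[Feature] = []
    # LSC: rpl/rps genes carry the orientation signal; a few psb genes are
    # balanced so they can never overturn an all-genes fallback count.
    n = spec.lsc_rplrps_genes
    features += _place_genes(
        Arc(lsc.start, lsc.length // 2),
        _gene_names(["rpl", "rps"], n),
        _quota_strands(n, spec.neg_strand_fraction, rng),
        spec,
        rng,
        L,
    )
    if spec.lsc_other_genes:
        m = spec.lsc_other_genes
        strands = ["+"] * (m // 2) + ["-"] * (m - m // 2)
        features += _place_genes(
            Arc(lsc.start + lsc.length // 2, lsc.length - lsc.length // 2),
            _gene_names(["psb"], m),
            strands,
            spec,
            rng,
            L,
        )
    # SSC: all genes count toward its orientation.
    features += _place_genes(
        ssc,
        _gene_names(["ndh"], spec.ssc_genes),
        _quota_strands(spec.ssc_genes, spec.neg_strand_fraction, rng),
        spec,
        rng,
        L,
    )
    # IRb rrn genes, mirrored into IRa with opposite strands so that the
    # features of both copies describe the same underlying repeat.
    irb_genes = _place_genes(
        irb,
        _gene_names(["rrn"], spec.ir_rrn_genes),
        _quota_strands(spec.ir_rrn_genes, spec.neg_strand_fraction, rng),
        spec,
        rng,
        L,
    )
    features += irb_genes
    flip = {"+": "-", "-": "+"}
    for g in irb_genes:
        (s, glen, st) = g.spans(L)[0]
        off = irb.offset_of(s, L)
        mirrored = (ira.start + (ira.length - off - glen)) % L
        features.append(
            Feature.from_spans("gene", g.name, [(mirrored, glen, flip[st])], L)
        )
    # both copies carry the same name: they are the same repeat, and the
    # label must not encode a position (a whole-molecule reverse complement
    # exchanges the copies' contents)
    for arc in (irb, ira):
        features.append(
            Feature.from_spans(
                "repeat_region", "inverted repeat", [(arc.start, arc.length, None)], L
            )
        )
    seq = AnnotatedSequence(f"synth-{spec.seed}", residues, True, features)
    return seq, RegionPartition(lsc, irb, ssc, ira, L)


# ---------------------------------------------------------------------------
# Corruption operators

RotateOp = tuple[str, int]  # ("rotate", k)
InvertOp = tuple[str, str]  # ("invert", "LSC"|"SSC"|"IR")
RevcompOp = tuple[str]  # ("revcomp",)
CorruptionOp = RotateOp | InvertOp | RevcompOp


def corrupt(seq: AnnotatedSequence, op: CorruptionOp) -> AnnotatedSequence:
    """Apply one deviation-manufacturing operator.

    ``("rotate", k)`` moves the stored origin so the classifier will report
    an offset of ``k`` (sub-threshold ``k`` is still applied; the expected
    classification is then standard).  ``("invert", region)`` replaces the
    region (both copies for ``IR``) by its inverse complement in place.
    ``("revcomp",)`` reverse-complements the whole molecule.
    """
    L = len(seq)
    kind = op[0]
    if kind == "rotate":
        # sub-threshold k is applied too; such fixtures are expected to
        # classify as standard downstream
        return rotate_record(seq, (L - op[1]) % L)
    if kind == "invert":
        partition = partition_from_annotations(seq)
        region = op[1]
        if region == "LSC":
            return invert_arc_record(seq, partition.lsc)
        if region == "SSC":
            return invert_arc_record(seq, partition.ssc)
        if region == "IR":
            return invert_arc_record(invert_arc_record(seq, partition.irb), partition.ira)
        raise ValueError(f"unknown region {region!r}")
    if kind == "revcomp":
        return revcomp_record(seq)
    raise ValueError(f"unknown corruption op {op!r}")


def apply_recipe(seq: AnnotatedSequence, recipe: list[CorruptionOp]) -> AnnotatedSequence:
    """Compose corruption operators left to right."""
    for op in recipe:
        seq = corrupt(seq, op)
    return seq


def expected_classification(
    recipe: list[CorruptionOp],
    genome_length: int,
    lsc_len: int,
    min_offset: int = MIN_OFFSET_BP,
) -> FormClassification:
    """Predict the deviation diagnosis for a corruption recipe.

    Pure state algebra over (offset, LSC flip, SSC flip, IR flip), with no
    reference to the gene-counting classifier: rotations add offsets,
    in-place inversions toggle their flag, and a whole-molecule reverse
    complement toggles the LSC and SSC flags while sending the offset r to
    -(r + len(LSC)) mod L (the IR flag is unchanged because the reflection
    also swaps the two copies' contents, which cancels for an exact repeat).
    """
    L = genome_length
    r = 0
    flags = {"LSC": False, "SSC": False, "IR": False}
    for op in recipe:
        if op[0] == "rotate":
            r = (r + op[1]) % L
        elif op[0] == "invert":
            flags[op[1]] = not flags[op[1]]
        elif op[0] == "revcomp":
            r = (-(r + lsc_len)) % L
            flags["LSC"] = not flags["LSC"]
            flags["SSC"] = not flags["SSC"]
        else:
            raise ValueError(f"unknown corruption op {op!r}")
    flipped = frozenset(k for k, v in flags.items() if v)
    shifted = circular_distance(r, L) >= min_offset
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
    return FormClassification(category, r, flipped)


# ---------------------------------------------------------------------------
# Random trees


def random_tree(n: int, seed: int, mean_branch_length: float = 0.1) -> PhyloTree:
    """Random binary topology on leaves T1..Tn with exponential branch lengths.

    Built by repeated random edge attachment; the unrooted tree has the
    full 2n-3 branches of a resolved topology.
    """
    if n < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    labels = [f"T{i}" for i in range(1, n + 1)]
    for label in labels[:2]:
        child = tree.seed_node.new_child()
        child.taxon = ns.require_taxon(label)
    for label in labels[2:]:
        nodes = [nd for nd in tree if nd.parent_node is not None]
        target = nodes[int(rng.integers(0, len(nodes)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = mid.new_child()
        leaf.taxon = ns.require_taxon(label)
    for nd in tree:
        if nd.parent_node is not None:
            nd.edge.length = float(rng.exponential(mean_branch_length))
    return PhyloTree(tree=tree, rooted=False)


def _nni_candidates(tree: dendropy.Tree):
    """Internal unrooted edges as (v, partner) node pairs whose child
    subtrees can be swapped."""
    seed = tree.seed_node
    seed_children = seed.child_nodes()
    out = []
    for v in tree.preorder_node_iter():
        if v.parent_node is None or not v.child_nodes():
            continue
        p = v.parent_node
        if p is seed and len(seed_children) == 2:
            partner = next(c for c in seed_children if c is not v)
            if partner.child_nodes() and id(v) < id(partner):
                out.append((v, partner))
        else:
            out.append((v, p))
    return out


def perturb_tree(
    t: PhyloTree, n_nni: int, length_jitter: float, seed: int
) -> PhyloTree:
    """Apply nearest-neighbor interchanges and multiplicative log-normal
    branch-length jitter.  ``n_nni=0, length_jitter=0`` is the identity."""
    rng = np.random.default_rng(seed)
    tree = t.tree.clone(depth=1)
    for _ in range(n_nni):
        candidates = _nni_candidates(tree)
        if not candidates:
            break
        v, partner = candidates[int(rng.integers(0, len(candidates)))]
        x_pool = v.child_nodes()
        y_pool = [c for c in partner.child_nodes() if c is not v]
        x = x_pool[int(rng.integers(0, len(x_pool)))]
        y = y_pool[int(rng.integers(0, len(y_pool)))]
        v.remove_child(x)
        partner.remove_child(y)
        v.add_child(y)
        partner.add_child(x)
    if length_jitter:
        for nd in tree:
            if nd.parent_node is not None and nd.edge.length is not None:
                nd.edge.length *= float(math.exp(rng.normal(0.0, length_jitter)))
    return PhyloTree(tree=tree, rooted=t.rooted)
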