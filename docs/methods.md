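# Methods

## The stored-form problem

A land-plant chloroplast genome is a circular molecule of roughly
120–160 kb with a quadripartite architecture: a large and a small
single-copy region (LSC, SSC) separated by two identical inverted repeats
(IRb, IRa), with IRa the exact reverse complement of IRb.  Because the
molecule is circular, and because flip-flop recombination between the IRs
means both SSC orientations coexist in every cell, the same genome can be
deposited in a database under many different linearizations: rotated to an
arbitrary origin, with the LSC or SSC stored as its reverse complement,
with the IR pair exchanged, or any combination.  Whole-genome alignments
and the phylogenies built on them are sensitive to these storage artifacts,
so sequences should be normalized to one canonical form first.

## The standard form and its orientation tests

The canonical linearization places the origin at the IRa/LSC boundary,
reads forward into the LSC, and orders the regions LSC, IRb, SSC, IRa.
Region orientation is decided by gene-strand majorities: in standard
orientation, more of the LSC's *rpl*/*rps* genes, more of all the SSC's
genes, and more of IRb's *rrn* genes lie on the negative strand than on
the positive strand.  Gene names are matched case-insensitively on the
prefix before the numeral (`rpl2`, `rps12`, `rrn16` → `rpl`, `rps`,
`rrn`).

Each test can tie (equal counts, including 0–0).  A tie under the primary
filter falls back to a majority over all genes wholly inside the region;
a persistent tie raises `UndeterminedOrientationError` rather than
guessing.  Genes straddling a region boundary are excluded from counts.

## Partition inference

The quadripartite partition is read from the record's two `repeat_region`
annotations.  Repeat intervals closer than 10 bp end-to-start are merged
first (assemblies misassign about 10 bp at IR boundaries); exactly two
non-overlapping arcs of near-equal length (default tolerance 100 bp,
configurable) must remain.  The two gaps between them are the single-copy
regions, the longer being the LSC; equal gap lengths are refused as
ambiguous rather than guessed.  Records with fewer than two annotated
repeats raise `NoIRError` and are classified `no_ir`: without the IRs the
record's relation to the standard form is undeterminable, and batch
processing omits such records from standardization.

A de novo finder serves bare sequences: it returns the longest pair of
disjoint circular arcs whose residues are exact reverse complements
(seed-and-extend over the doubled sequence, 32-mer seeds, per-diagonal
coverage bookkeeping; ties broken by the smaller start coordinate).  It
requires exact identity — degraded IRs are out of scope — and is checked
against an O(L²) exhaustive diagonal-scan oracle on small inputs.

## Classification and rewriting

Deviation causes are gathered independently:

* **cyclic shift** — the raw offset of the LSC start is reported in
  [0, L); it counts as a shift only when its *circular* distance from zero,
  min(offset, L − offset), is at least 10 bp.  Smaller offsets are treated
  as IR-boundary misassignment noise: reported, classified `standard`, and
  deliberately left unrotated.
* **inverted LSC / SSC / IRs** — the three orientation tests above; the IR
  test runs on the copy that follows the LSC along the circle.

Exactly one cause names its category; two or more give `combination`.
Rewriting applies a rotation (moving the LSC start to position 0) followed
by in-place reverse complementation of each flipped region (both copies
for the IR pair), recorded as an auditable `Transformation` that can be
replayed deterministically.  Feature coordinates are remapped: rotation
shifts them modulo L, inversion mirrors them within the region arc and
flips the strand; features straddling a region boundary are dropped with a
warning (standardized sequences are expected to be re-annotated anyway,
and a split policy could be added later).

A whole-molecule reverse complement deserves a note: because IRa is the
reverse complement of IRb, reflecting the circle also swaps the two
copies' contents, and the two effects cancel.  The reflection is therefore
exactly equivalent to a cyclic shift of L − len(LSC) plus inversions of
LSC and SSC — the IR test still passes — and is diagnosed and repaired as
that combination.  This is forced by the algebra and is confirmed
bit-exactly by the round-trip tests.

## Tree comparison

Four distances, each with a scaling denominator that removes the
dependence on dataset size n:

| distance | definition | denominator |
|---|---|---|
| RF | symmetric difference of nontrivial bipartition sets (unrooted) | 2n − 3 |
| KC_T | Kendall–Colijn at λ = 0 | C(n, 2) |
| KC | Kendall–Colijn at λ = 0.5 | C(n, 2) + n |
| BS | branch score (Kuhner–Felsenstein), square-root form | Σ branch lengths of both trees |

The Kendall–Colijn vector holds, for every leaf pair (lexicographic), the
blend (1 − λ)·(edge count from root to the pair's MRCA) + λ·(path length
root → MRCA), followed by one pendant entry per leaf,
(1 − λ) + λ·(pendant length).  λ = 0 depends on rooted topology alone;
the distance is the Euclidean norm of the vector difference.  KC requires
rooted trees; the comparison suite roots both trees at a user-supplied
outgroup, splitting its pendant edge at the midpoint (the rooting
procedure is a package choice; nothing downstream depends on where along
the pendant edge the root sits).

Conventions chosen where the literature varies: BS includes pendant
bipartitions and takes the square root (the distance form, commensurate
with KC); RF excludes pendants; the RF denominator is the formula 2n − 3
even for multifurcating inputs (it reproduces the printed 109 for n = 56);
a stored basal bifurcation is collapsed for unrooted comparisons by
summing its two edge lengths into one branch.  For n = 56 the denominators
are 109, 1540 and 1596.  Scaled RF is bounded by 2(n−2)/(2n−3) < 1 and
scaled BS by 1, since √Σ(a−b)² ≤ Σa + Σb for nonnegative lengths.

## Synthetic data

The generator emits standard-form plastomes with ground truth: default
geometry 84 kb LSC + 25 kb IRs + 18 kb SSC (152 kb total, inside the
120–160 kb envelope); uniform random residues with IRa set bit-exactly to
revcomp(IRb); 20 *rpl*/*rps* genes in the LSC, 12 *ndh* genes in the SSC,
4 *rrn* genes per IR copy (mirrored between copies with opposite strands,
as in real plastomes), plus 6 strand-balanced *psb* genes that cannot
overturn a fallback count.  Strands are assigned by exact quota at a 0.75
negative-strand fraction — never by independent coin flips — so orientation
majorities cannot tie by chance; specs whose rounded quota would tie are
refused, as is an SSC with no genes (its orientation would be
undeterminable).  Gene lengths are uniform on 300–1500 bp; placement draws
the lengths first and splits the remaining slack into random inter-gene
gaps, which yields a uniform non-overlapping layout and cannot stall on
densely packed regions.  The base at each IR boundary is adjusted when
needed so the planted repeat is maximal at exactly its arcs, keeping de
novo detection byte-identical to the ground truth.

Corruption operators (rotate by k, invert LSC/SSC/IR pair in place,
reverse complement the whole molecule) are the inverses of
standardization, compose freely, and edit features alongside residues.  A
small state algebra over (offset, LSC flip, SSC flip, IR flip) predicts
the expected diagnosis of any recipe independently of the gene-counting
classifier: rotations add, inversions toggle, and whole-molecule
reflection maps offset r to −(r + len LSC) mod L while toggling LSC and
SSC only.

Random trees are grown by repeated random edge attachment (binary, 2n − 3
branches) with exponential branch lengths (mean 0.1); perturbation applies
nearest-neighbor interchanges — one NNI changes exactly one split, giving
RF = 2 — and multiplicative log-normal length jitter.

What the generator does **not** emulate: AT-rich base composition, gene
content realism beyond name vocabularies, introns/trans-splicing, degraded
or shifted IR boundaries, annotation errors, or sequence evolution.
Passing tests therefore demonstrate the correctness of the structural
algebra (partition, classification, rewriting, distances) on idealized
records, not robustness to noisy real-world annotation.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open; GenBank/GFF3 conversion
  happens only at the I/O boundary.  Origin-crossing features are one
  feature with `wraps_origin` set.
* All arithmetic treats records as circular; a missing topology flag is
  logged, not fatal.
* Residues are uppercased on read; characters outside A/C/G/T/N are
  rejected so reverse complementation is total and deterministic.
* Distance assertions in tests use 1e−9 relative tolerance; the distances
  themselves are plain floating-point sums (n is small).
* Problem sizes used by the acceptance checks: 500 round-trip pairs
  (25 genomes × 20 recipes at default 152 kb geometry), all 105 six-leaf
  topologies for RF, all 105 rooted five-leaf topologies for KC_T, 1000
  random perturbed tree pairs for the scaled bounds, 100 planted-repeat
  sequences of 1–2 kb for the IR-finder oracle.  These sizes exercise
  every code path while keeping the whole suite around a minute.

## Known limitations

* Only exact IR pairs are detected de novo; annotated IR copies may differ
  by up to the configurable length tolerance, but single-copy/IR boundary
  refinement is out of scope.
* Boundary-straddling features are dropped during rewriting, not split.
* `no_ir` records are reported but never rewritten — without IRs the
  relation to the standard form is undefined, not merely unknown.
* Tree distances assume identical leaf label sets; no name fuzzying.
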