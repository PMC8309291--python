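"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chloronorm import SynthSpec, generate_genome
from chloronorm.genome_model import revcomp


@pytest.fixture(scope="session")
def default_genome():
    """One default-sized (152 kb) synthetic standard-form plastome."""
    return generate_genome(SynthSpec(seed=42))


@pytest.fixture(scope="session")
def small_genome():
    """A reduced plastome for tests where geometry, not scale, matters."""
    spec = SynthSpec(
        lsc_len=8000, ir_len=2500, ssc_len=1800,
        lsc_rplrps_genes=8, lsc_other_genes=2, ssc_genes=5, ir_rrn_genes=3,
        gene_len_range=(60, 200), seed=7,
    )
    return generate_genome(spec)


def brute_force_inverted_repeat(residues: str, min_len: int):
    """O(L^2) oracle: the longest pair of disjoint circular arcs that are
    exact reverse complements, by exhaustive diagonal run-length scanning
    of the doubled sequence against its doubled reverse complement.

    Returns a list of (a_start, b_start, length) maximal matches with
    disjoint arcs and length >= min_len (deduplicated, arcs ordered by
    start), or an empty list.
    """
    L = len(residues)
    S2 = np.frombuffer((residues + residues).encode(), dtype=np.uint8)
    T = revcomp(residues)
    T2 = np.frombuffer((T + T).encode(), dtype=np.uint8)
    n2 = 2 * L
    pairs = set()
    for d in range(-n2 + 1, n2):
        if d >= 0:
            i0, j0 = d, 0
        else:
            i0, j0 = 0, -d
        diag = S2[i0 : n2] if d >= 0 else S2[0 : n2 + d]
        other = T2[j0 : j0 + len(diag)]
        eq = diag == other
        if not eq.any():
            continue
        # maximal runs of True
        padded = np.concatenate(([False], eq, [False])).astype(np.int8)
        delta = np.diff(padded)
        starts = np.nonzero(delta == 1)[0]
        ends = np.nonzero(delta == -1)[0]
        for s, e in zip(starts, ends):
            m = int(e - s)
            if m < min_len:
                continue
            m = min(m, L)
            i, j = i0 + int(s), j0 + int(s)
            a_start = i % L
            b_start = (L - (j % L) - m) % L
            pair = (min(a_start, b_start), max(a_start, b_start), m)
            # keep only disjoint arc pairs
            a, b = pair[0], pair[1]
            if (b - a) % L >= m and (a - b) % L >= m and a != b:
                pairs.add(pair)
    return sorted(pairs, key=lambda p: (-p[2], p[0]))
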