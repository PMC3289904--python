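"""Independent oracles and small generators shared across the test suite.

Everything here is deliberately written as the dumbest correct thing —
exhaustive enumeration and per-window loops — so it shares no code path with
the implementations it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from amelio.tree import Clade, PhyloTree, unroot

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# exhaustive global alignment
# ---------------------------------------------------------------------------

def brute_force_align_score(a: str, b: str, matrix: str = "BLOSUM62",
                            gap_open: float = 10.0,
                            gap_extend: float = 0.5) -> float:
    """Max global alignment score by enumerating every alignment.

    A gap run of length L costs gap_open + gap_extend * L; exponential in
    the sequence lengths, usable up to ~8 residues.
    """
    m = substitution_matrices.load(matrix)
    best = [-np.inf]

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + m[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend + (gap_open if last != "D" else 0.0)
            rec(i + 1, j, score - cost, "D")
        if j < len(b):
            cost = gap_extend + (gap_open if last != "I" else 0.0)
            rec(i, j + 1, score - cost, "I")

    rec(0, 0, 0.0, None)
    return best[0]


# ---------------------------------------------------------------------------
# per-window composition recomputation
# ---------------------------------------------------------------------------

def loop_gc(seq: str) -> float:
    gc = sum(1 for c in seq if c in "GC")
    acgt = sum(1 for c in seq if c in "ACGT")
    return gc / acgt


def loop_windowed_gc(seq: str, window: int, step: int) -> list[tuple[float, float]]:
    points = []
    for start in range(0, len(seq) - window + 1, step):
        points.append((start + window / 2.0, loop_gc(seq[start:start + window])))
    return points


def loop_codon_gc(cds: str, drop_stop: bool = True) -> tuple[float, float, float]:
    if drop_stop and len(cds) >= 6 and cds[-3:] in ("TAA", "TAG", "TGA"):
        cds = cds[:-3]
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    out = []
    for k in range(3):
        col = [c[k] for c in codons if c[k] != "N"]
        out.append(sum(1 for x in col if x in "GC") / len(col))
    return tuple(out)


def loop_sliding_codon_gc(cds: str, window: int, step: int
                          ) -> list[tuple[float, tuple[float, float, float]]]:
    if len(cds) >= 6 and cds[-3:] in ("TAA", "TAG", "TGA"):
        cds = cds[:-3]
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    points = []
    for start in range(0, len(codons) - window + 1, step):
        sub = "".join(codons[start:start + window])
        points.append((start + window / 2.0, loop_codon_gc(sub, drop_stop=False)))
    return points


# ---------------------------------------------------------------------------
# random additive trees
# ---------------------------------------------------------------------------

def random_unrooted_tree(rng: np.random.Generator, n_taxa: int,
                         min_bl: float = 0.1, max_bl: float = 1.0) -> PhyloTree:
    """Random binary unrooted tree with positive branch lengths."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    active = [Clade(name=l) for l in labels]
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(int(j))
        a = active.pop(int(i))
        active.append(Clade(children=[a, b]))
    root = Clade(children=active)
    for node in root.walk():
        if node is not root:
            node.branch_length = float(rng.uniform(min_bl, max_bl))
    return unroot(PhyloTree(root, rooted=True))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def random_dna(rng: np.random.Generator, length: int, p_gc: float = 0.5) -> str:
    out = []
    for _ in range(length):
        if rng.random() < p_gc:
            out.append("G" if rng.random() < 0.5 else "C")
        else:
            out.append("A" if rng.random() < 0.5 else "T")
    return "".join(out)


def random_cds(rng: np.random.Generator, n_codons: int, p_gc: float = 0.5) -> str:
    """A random in-frame CDS with no internal stops, ATG start, TGA stop."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_dna(rng, 3, p_gc)
        if c not in stops:
            codons.append(c)
    codons.append("TGA")
    return "".join(codons)
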