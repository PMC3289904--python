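"""Distance-based protein phylogenetics: pairwise global alignment, Kimura's
protein distance correction, Saitou–Nei neighbor joining, column-resampling
bootstrap support, and outgroup rooting.

The chain mirrors classic ClustalX-style tree building: align each pair of
proteins globally (BLOSUM62, affine gaps), take the mismatch fraction D over
gap-free columns, correct for multiple hits with Kimura's
``d = -ln(1 - D - D^2/5)``, then join neighbors on the distance matrix.
Supports come from resampling alignment columns of a user-supplied multiple
alignment and rebuilding the tree per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import SequenceRecord
from .tree import Clade, PhyloTree, root_with_outgroup  # noqa: F401

KIMURA_DOMAIN_MAX = 0.85


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal global alignment of two proteins under affine gap costs."""

    seqA: str
    seqB: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seqA) != len(self.seqB):
            raise ValueError("aligned rows must have equal length")

    @property
    def fraction_mismatch(self) -> float:
        """Mismatch fraction D over columns with no gap in either row."""
        pairs = [(a, b) for a, b in zip(self.seqA, self.seqB)
                 if a != "-" and b != "-"]
        if not pairs:
            raise ValueError("no gap-free columns to compare")
        return sum(a != b for a, b in pairs) / len(pairs)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float
                  ) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap run of length L costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(protA: str | SequenceRecord, protB: str | SequenceRecord,
               matrix: str = "BLOSUM62", gap_open: float = 10.0,
               gap_extend: float = 0.5) -> PairwiseAlignment:
    """Optimal global alignment (Needleman–Wunsch/Gotoh, affine gaps).

    A gap run of length L costs ``gap_open + gap_extend * L``; defaults are
    the classic ClustalX protein settings.  The traceback is deterministic.
    """
    a, b = str(protA).upper(), str(protB).upper()
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(seqA=str(aln[0]), seqB=str(aln[1]),
                             score=float(aln.score))


def self_score(prot: str | SequenceRecord, matrix: str = "BLOSUM62") -> float:
    """Alignment score of a protein against itself (no gaps): the diagonal sum."""
    m = substitution_matrices.load(matrix)
    return float(sum(m[c, c] for c in str(prot).upper()))


def kimura_distance(D: float, *, fallback_raw: bool = False) -> float:
    """Kimura's correction of an observed protein mismatch fraction D.

    ``d = -ln(1 - D - D^2/5)``, valid for D < 0.85.  Beyond the domain an
    error is raised unless ``fallback_raw`` returns the uncorrected D.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"mismatch fraction {D} outside [0, 1]")
    if D >= KIMURA_DOMAIN_MAX:
        if fallback_raw:
            return D
        raise ValueError(f"D={D:.3f} beyond correction domain (>= 0.85)")
    return -np.log(1.0 - D - D * D / 5.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise evolutionary distances."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)


def _as_protein_map(proteins) -> dict[str, str]:
    if isinstance(proteins, Mapping):
        return {k: str(v).upper() for k, v in proteins.items()}
    out = {}
    for rec in proteins:
        if rec.id in out:
            raise ValueError(f"duplicate label {rec.id!r}")
        out[rec.id] = str(rec).upper()
    return out


def distance_matrix(proteins: Sequence[SequenceRecord] | Mapping[str, str], *,
                    matrix: str = "BLOSUM62", gap_open: float = 10.0,
                    gap_extend: float = 0.5, correction: str = "kimura",
                    fallback_raw: bool = True) -> DistanceMatrix:
    """All-pairs Kimura-corrected distances from pairwise global alignments.

    ``correction="raw"`` keeps the uncorrected mismatch fractions.  Requires
    at least 3 uniquely labelled proteins (the minimum for neighbor joining).
    """
    prot = _as_protein_map(proteins)
    labels = tuple(sorted(prot))
    if len(labels) < 3:
        raise ValueError("distance matrix requires at least 3 proteins")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_pair(prot[labels[i]], prot[labels[j]], matrix=matrix,
                             gap_open=gap_open, gap_extend=gap_extend)
            D = aln.fraction_mismatch
            if correction == "kimura":
                dist = kimura_distance(D, fallback_raw=fallback_raw)
            elif correction == "raw":
                dist = D
            else:
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d)


def alignment_distance_matrix(msa: Mapping[str, str], *,
                              correction: str = "kimura",
                              fallback_raw: bool = True,
                              columns: np.ndarray | None = None
                              ) -> DistanceMatrix:
    """Pairwise distances read off a multiple alignment.

    D for a pair is the mismatch fraction over columns where neither row has
    a gap; ``columns`` restricts/reorders columns (used by the bootstrap).
    """
    labels = tuple(sorted(msa))
    if len(labels) < 3:
        raise ValueError("distance matrix requires at least 3 sequences")
    rows = [np.frombuffer(msa[l].upper().encode(), dtype=np.uint8) for l in labels]
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows differ in length")
    mat = np.vstack(rows)
    if columns is not None:
        mat = mat[:, columns]
    nongap = mat != ord("-")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = nongap[i] & nongap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no shared gap-free columns for {labels[i]}/{labels[j]}")
            D = float(np.sum(mat[i, ok] != mat[j, ok])) / m
            if correction == "kimura":
                d[i, j] = d[j, i] = kimura_distance(D, fallback_raw=fallback_raw)
            else:
                d[i, j] = d[j, i] = D
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` with the standard branch-length and
    distance-reduction formulas; consistent (exact recovery) on additive
    matrices.  Ties in Q are broken by lexicographic order of the clusters'
    smallest leaf labels.  Negative branch lengths are clamped to zero with
    the deficit moved to the sibling edge so the pair's path length is kept.
    Returns an unrooted tree (degree-3 root surrogate).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = dm.d.astype(float).copy()
    nodes = [Clade(name=l) for l in dm.labels]
    # tie-break key: smallest leaf label within each active cluster
    keys = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q[np.tril_indices(m)] = np.inf  # scan i < j only
        qmin = Q.min()
        pairs = [tuple(sorted((keys[i], keys[j]))) + (i, j)
                 for i, j in np.argwhere(Q == qmin)]
        _, _, i, j = min(pairs)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, lj = 0.0, D[i, j]
        elif lj < 0:
            li, lj = D[i, j], 0.0
        ni, nj = nodes[i], nodes[j]
        ni.branch_length, nj.branch_length = float(li), float(lj)
        new = Clade(children=[ni, nj])
        du = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((len(keep) + 1, len(keep) + 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        D = D_new

    # final three clusters joined at the surrogate root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01)]
    order = sorted(range(3), key=lambda k: keys[k])
    children = []
    for k in order:
        nodes[k].branch_length = float(max(lens[k], 0.0))
        children.append(nodes[k])
    return PhyloTree(Clade(children=children), rooted=False).sort()


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(msa: Mapping[str, str], n_reps: int = 1000,
              seed: int | None = None, *,
              correction: str = "kimura") -> dict[frozenset, float]:
    """Column-resampling bootstrap supports for the NJ tree of an alignment.

    Columns are resampled with replacement ``n_reps`` times; each replicate's
    distance matrix (read off the resampled alignment) is re-joined and every
    nontrivial bipartition tallied.  Returns support percentages keyed by
    canonical bipartition (the leaf side not containing the alphabetically
    first taxon).  Distances beyond the Kimura domain fall back to raw D so
    extreme replicates cannot abort the resampling.  Resampling depends only
    on the seed, never on taxon order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = sorted(msa)
    L = len(next(iter(msa.values())))
    if L < 2:
        raise ValueError("alignment must have at least 2 columns")
    rng = np.random.default_rng(seed)
    tally: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        dm = alignment_distance_matrix(msa, correction=correction,
                                       fallback_raw=True, columns=cols)
        tree = neighbor_joining(dm)
        for bip in tree.bipartitions():
            tally[bip] = tally.get(bip, 0) + 1
    return {bip: 100.0 * c / n_reps for bip, c in tally.items()}


def apply_supports(tree: PhyloTree, supports: Mapping[frozenset, float]
                   ) -> PhyloTree:
    """Attach bootstrap percentages (rounded to int) to matching internal nodes."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    n = len(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(l.name for l in node.leaves())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= n - 2 and side in supports:
            node.support = int(round(supports[side]))
    return tree


def nj_tree(proteins, *, outgroup: str | None = None,
            msa: Mapping[str, str] | None = None, n_reps: int = 1000,
            seed: int | None = None, **dm_kwargs) -> PhyloTree:
    """Convenience pipeline: distances → NJ → optional bootstrap and rooting."""
    dm = distance_matrix(proteins, **dm_kwargs)
    tree = neighbor_joining(dm)
    if msa is not None:
        tree = apply_supports(tree, bootstrap(msa, n_reps=n_reps, seed=seed))
    if outgroup is not None:
        tree = root_with_outgroup(tree, outgroup)
    return tree
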