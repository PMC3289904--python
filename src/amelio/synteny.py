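"""Anchored gene-neighborhood synteny: extraction, ortholog matching by
reciprocal best pairwise alignment, gene-pair orientation classes, and a
cross-genome synteny table.

Neighborhoods are anchored on one gene per genome (here, the dps-like gene)
and orientation-normalized so every anchor is transcribed left-to-right,
which makes gene order and relative orientation directly comparable across
genomes.  Orientation vocabulary for two adjacent genes, taking the one with
the smaller start as upstream:

* **co-directional** — same strand, transcribed in tandem;
* **face-to-face** — convergent ``+ ... -``, transcribed toward each other;
* **back-to-back** — divergent ``- ... +``, transcribed apart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from . import phylo
from .seqio import (GeneFeature, SequenceRecord, extract_cds, reverse_complement,
                    translate)

CO_DIRECTIONAL = "co-directional"
FACE_TO_FACE = "face-to-face"
BACK_TO_BACK = "back-to-back"


@dataclass(frozen=True)
class Neighborhood:
    """The genes around an anchor on one genome, with their proteins."""

    genome_id: str
    anchor: GeneFeature
    flank: tuple[GeneFeature, ...]
    proteins: Mapping[str, str]
    orientation_normalized: bool = False

    def __post_init__(self) -> None:
        starts = [f.start for f in self.flank]
        if starts != sorted(starts):
            raise ValueError("flank genes must be sorted by start")
        if self.anchor.locus_tag not in {f.locus_tag for f in self.flank}:
            raise ValueError("anchor must be part of the flank")
        if self.orientation_normalized and self.anchor.strand != "+":
            raise ValueError("normalized neighborhood must have a + anchor")

    @property
    def tags(self) -> list[str]:
        return [f.locus_tag for f in self.flank]

    def rank_offset(self, tag: str) -> int:
        """Gene-rank offset from the anchor (anchor = 0, upstream negative)."""
        tags = self.tags
        return tags.index(tag) - tags.index(self.anchor.locus_tag)


def mirror(nbr: Neighborhood, span: int | None = None) -> Neighborhood:
    """Reverse-complement a neighborhood's coordinate frame.

    Coordinates are mirrored within the neighborhood's footprint, strands
    flip and gene order reverses; proteins are untouched.  Applying mirror
    twice returns the original neighborhood.
    """
    lo = min(f.start for f in nbr.flank)
    hi = max(f.end for f in nbr.flank)
    if span is not None:
        lo, hi = 0, span

    def flip(f: GeneFeature) -> GeneFeature:
        return replace(f, start=lo + hi - f.end, end=lo + hi - f.start,
                       strand="-" if f.strand == "+" else "+")

    flank = tuple(sorted((flip(f) for f in nbr.flank), key=lambda f: f.start))
    anchor = next(f for f in flank if f.locus_tag == nbr.anchor.locus_tag)
    return Neighborhood(genome_id=nbr.genome_id, anchor=anchor, flank=flank,
                        proteins=nbr.proteins,
                        orientation_normalized=anchor.strand == "+")


def extract_neighborhood(record: SequenceRecord,
                         features: Sequence[GeneFeature],
                         anchor_tag: str, k: int = 8, *,
                         normalize: bool = True,
                         actinobacterial_starts: bool = True) -> Neighborhood:
    """Up to ``k`` genes on each side of the anchor, orientation-normalized.

    Neighborhood extent is counted in genes, not base pairs, so genomes with
    different intergenic spacing stay comparable.  When the anchor lies on
    the minus strand (and ``normalize``), the whole neighborhood is mirrored
    so the anchor is transcribed rightward.
    """
    ordered = sorted(features, key=lambda f: (f.start, f.locus_tag))
    tags = [f.locus_tag for f in ordered]
    if anchor_tag not in tags:
        raise ValueError(f"anchor {anchor_tag!r} not found among features")
    i = tags.index(anchor_tag)
    window = ordered[max(0, i - k): i + k + 1]
    proteins = {}
    for f in window:
        cds = extract_cds(record, f)
        try:
            proteins[f.locus_tag] = str(
                translate(cds, actinobacterial_starts=actinobacterial_starts))
        except ValueError:
            continue  # partial CDS: carried as a feature, unmatched
    nbr = Neighborhood(genome_id=record.id, anchor=ordered[i],
                       flank=tuple(window), proteins=proteins,
                       orientation_normalized=ordered[i].strand == "+")
    if normalize and nbr.anchor.strand == "-":
        nbr = mirror(nbr)
    return nbr


def classify_orientation(geneA: GeneFeature, geneB: GeneFeature) -> str:
    """Orientation class of two non-overlapping genes on one replicon."""
    if geneA.contig_id != geneB.contig_id:
        raise ValueError("genes lie on different replicons")
    up, down = sorted((geneA, geneB), key=lambda f: f.start)
    overlap = up.end - down.start
    if overlap > 0:
        raise ValueError(f"genes overlap by {overlap} bp")
    if up.strand == down.strand:
        return CO_DIRECTIONAL
    return FACE_TO_FACE if up.strand == "+" else BACK_TO_BACK


def match_orthologs(nbrA: Neighborhood, nbrB: Neighborhood,
                    min_score_frac: float = 0.3
                    ) -> list[tuple[str, str, float]]:
    """Reciprocal best hits between two neighborhoods' proteins.

    A pair (a, b) is kept when b is a's best-scoring partner and vice versa
    (ties broken by tag), and the alignment score reaches ``min_score_frac``
    of the self-score of the shorter protein.  Each gene joins at most one
    pair.  Returns (tagA, tagB, score) sorted by tagA.
    """
    scores: dict[tuple[str, str], float] = {}
    for ta, pa in nbrA.proteins.items():
        for tb, pb in nbrB.proteins.items():
            scores[(ta, tb)] = phylo.align_pair(pa, pb).score
    if not scores:
        return []

    def best(options: list[tuple[float, str]]) -> str | None:
        if not options:
            return None
        return sorted(options, key=lambda t: (-t[0], t[1]))[0][1]

    best_a = {ta: best([(scores[(ta, tb)], tb) for tb in nbrB.proteins])
              for ta in nbrA.proteins}
    best_b = {tb: best([(scores[(ta, tb)], ta) for ta in nbrA.proteins])
              for tb in nbrB.proteins}
    pairs = []
    for ta, tb in sorted(best_a.items()):
        if best_b.get(tb) != ta:
            continue
        score = scores[(ta, tb)]
        shorter = min(nbrA.proteins[ta], nbrB.proteins[tb], key=len)
        if score >= min_score_frac * phylo.self_score(shorter):
            pairs.append((ta, tb, score))
    return pairs


SYNTENY_COLUMNS = ["genome_id", "group_id", "locus_tag", "offset", "strand",
                   "conserved"]


def synteny_table(neighborhoods: Sequence[Neighborhood],
                  min_score_frac: float = 0.3) -> pd.DataFrame:
    """Cross-genome ortholog groups of neighborhood genes.

    Pairwise reciprocal best hits are merged transitively, processing edges
    by descending score and skipping any merge that would place two genes of
    the same genome in one group.  Groups present in >= 2 genomes are marked
    conserved.  Rows are sorted by genome then rank offset from the anchor.
    """
    if len(neighborhoods) < 2:
        raise ValueError("synteny table requires at least 2 neighborhoods")
    ids = [n.genome_id for n in neighborhoods]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")

    edges = []  # (score, (genome_a, tag_a), (genome_b, tag_b))
    for i in range(len(neighborhoods)):
        for j in range(i + 1, len(neighborhoods)):
            a, b = neighborhoods[i], neighborhoods[j]
            for ta, tb, score in match_orthologs(a, b, min_score_frac):
                edges.append((score, (a.genome_id, ta), (b.genome_id, tb)))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    parent: dict = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict = {}
    for _, ga, gb in edges:
        ra, rb = find(ga), find(gb)
        if ra == rb:
            continue
        gen_a = members.setdefault(ra, {ga[0]})
        gen_b = members.setdefault(rb, {gb[0]})
        if gen_a & gen_b:
            continue  # would mix two genes of one genome
        parent[rb] = ra
        members[ra] = gen_a | gen_b

    groups: dict = {}
    for nbr in neighborhoods:
        for tag in nbr.tags:
            key = find((nbr.genome_id, tag))
            groups.setdefault(key, []).append((nbr, tag))

    # name groups I, II, III... in anchor-offset order of the first genome
    def group_sort_key(items):
        nbr, tag = min(items, key=lambda it: (it[0].genome_id,
                                              it[0].rank_offset(it[1])))
        return (nbr.rank_offset(tag), nbr.genome_id, tag)

    named = sorted(groups.values(), key=group_sort_key)
    rows = []
    for gi, items in enumerate(named, start=1):
        n_genomes = len({nbr.genome_id for nbr, _ in items})
        for nbr, tag in items:
            feat = next(f for f in nbr.flank if f.locus_tag == tag)
            rows.append({"genome_id": nbr.genome_id, "group_id": f"G{gi:03d}",
                         "locus_tag": tag, "offset": nbr.rank_offset(tag),
                         "strand": feat.strand, "conserved": n_genomes >= 2})
    df = pd.DataFrame(rows, columns=SYNTENY_COLUMNS)
    return df.sort_values(["genome_id", "offset"]).reset_index(drop=True)


def render_synteny(table: pd.DataFrame) -> str:
    """Plain-text sketch of the synteny table, one genome per line.

    Genes are drawn as ``[group>`` / ``<group]`` boxes in neighborhood order;
    genome-specific (non-conserved) genes appear as ``.``.
    """
    lines = []
    for genome, sub in table.groupby("genome_id", sort=True):
        cells = []
        for row in sub.sort_values("offset").itertuples():
            if not row.conserved:
                cells.append(".")
            elif row.strand == "+":
                cells.append(f"[{row.group_id}>")
            else:
                cells.append(f"<{row.group_id}]")
        lines.append(f"{genome:<20s} " + " ".join(cells))
    return "\n".join(lines)
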