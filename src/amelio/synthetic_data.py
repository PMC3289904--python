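"""Synthetic annotated contigs, genome panels and protein families.

These generators define the controlled conditions under which every analysis
stage is exercised:

* :func:`gen_genome` builds an annotated contig of protein-coding genes whose
  first/second and third codon-position GC are sampled independently
  (``target_gc12`` vs ``target_gc3``) — the minimal model realizing the
  GC12/GC3 decoupling that makes amelioration detectable; stop codons are
  drawn from explicit weights.
* :func:`insert_foreign_gene` plants a gene with near-saturated GC3,
  depressed GC12 and a TAA stop into a host contig — the compositional
  signature of a horizontally acquired, ameliorated gene.
* :func:`gen_genome_panel` spreads genomes across a GC range with TAA usage
  falling and TGA usage rising in GC — the canonical stop-codon-vs-GC trend.
* :func:`simulate_protein_family` evolves a protein family along a random
  tree under a 20-state Jukes–Cantor-like model without indels, so the true
  alignment is the leaf set itself and tree inference can be scored against
  the generating topology.

Every generator is a pure function of its spec and seed: identical calls are
byte-identical.  Each returns a machine-readable *truth record* with the
realized per-gene statistics so downstream modules can be scored without
re-deriving ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import composition
from .seqio import GeneFeature, SequenceRecord, STOP_CODONS, reverse_complement
from .tree import Clade, PhyloTree

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic annotated contig.

    Defaults emulate a high-GC actinobacterial replicon: ~69% genomic GC
    realized from GC3 near 0.9 with GC12 ~0.58, TGA-dominated stops.
    """

    n_genes: int = 30
    mean_gene_len: int = 200          # codons, incl. start and stop
    target_gc3: float = 0.90
    target_gc12: float = 0.58
    stop_codon_weights: dict = field(
        default_factory=lambda: {"TAA": 0.1, "TAG": 0.25, "TGA": 0.65})
    mean_intergenic_len: int = 120    # bp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.mean_gene_len < 5:
            raise ValueError("need n_genes >= 1 and mean_gene_len >= 5 codons")
        for name in ("target_gc3", "target_gc12"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        w = self.stop_codon_weights
        if set(w) - set(STOP_CODONS) or any(x < 0 for x in w.values()) \
                or sum(w.values()) <= 0:
            raise ValueError("stop weights must be non-negative over "
                             "TAA/TAG/TGA with positive sum")
        if self.mean_intergenic_len < 1:
            raise ValueError("mean_intergenic_len must be >= 1")


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a simulated protein family."""

    n_taxa: int = 8
    mean_branch_length: float = 0.1   # expected substitutions per site scale
    min_branch_length: float = 0.02   # floor keeping every edge resolvable
    rate: float = 1.0                 # substitution events per site per unit length
    seq_length: int = 500             # residues
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.mean_branch_length <= 0 or self.rate < 0 or self.seq_length < 1:
            raise ValueError("branch lengths and sequence length must be positive")
        if not 0 <= self.min_branch_length < self.mean_branch_length:
            raise ValueError("min_branch_length must be in [0, mean)")


# ---------------------------------------------------------------------------
# codon machinery
# ---------------------------------------------------------------------------

def _position_bases(rng: np.random.Generator, n: int, p_gc: float) -> np.ndarray:
    gc = rng.random(n) < p_gc
    pick = rng.integers(0, 2, size=n)
    out = np.where(gc, np.where(pick == 0, ord("G"), ord("C")),
                   np.where(pick == 0, ord("A"), ord("T"))).astype(np.uint8)
    return out


def _sample_codons(rng: np.random.Generator, n: int, gc12: float, gc3: float
                   ) -> np.ndarray:
    """n sense codons as a (n, 3) byte array; stop codons rejection-sampled."""
    codons = np.empty((n, 3), dtype=np.uint8)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        codons[todo, 0] = _position_bases(rng, m, gc12)
        codons[todo, 1] = _position_bases(rng, m, gc12)
        codons[todo, 2] = _position_bases(rng, m, gc3)
        c = codons[todo]
        is_stop = (c[:, 0] == ord("T")) & (
            ((c[:, 1] == ord("A")) & ((c[:, 2] == ord("A")) | (c[:, 2] == ord("G"))))
            | ((c[:, 1] == ord("G")) & (c[:, 2] == ord("A"))))
        todo = todo[is_stop]
    return codons


def _gen_cds(rng: np.random.Generator, length_codons: int, gc12: float,
             gc3: float, stop: str) -> str:
    body = _sample_codons(rng, length_codons - 2, gc12, gc3)
    return "ATG" + body.tobytes().decode() + stop


def _intergenic(rng: np.random.Generator, mean_len: int, p_gc: float) -> str:
    length = max(1, int(rng.poisson(mean_len)))
    return _position_bases(rng, length, p_gc).tobytes().decode()


def _gene_truth(tag: str, cds: str, strand: str) -> dict:
    gc1, gc2, gc3 = composition.codon_position_gc(cds)
    return {"locus_tag": tag, "strand": strand, "len_codons": len(cds) // 3,
            "gc1": gc1, "gc2": gc2, "gc3": gc3, "stop": cds[-3:]}


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------

def gen_genome(spec: GenomeSpec, *, contig_id: str | None = None
               ) -> tuple[SequenceRecord, list[GeneFeature], dict]:
    """Generate an annotated contig from a :class:`GenomeSpec`.

    Genes are laid down left to right with Poisson-length intergenic spacers;
    strands are random.  The truth record stores the realized per-gene
    GC1/GC2/GC3 and stop codon (computed from the emitted sequences) plus the
    spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    cid = contig_id or f"synctg{spec.seed:04d}"
    stops, weights = zip(*sorted(spec.stop_codon_weights.items()))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    background_gc = (2 * spec.target_gc12 + spec.target_gc3) / 3.0

    chunks: list[str] = []
    features: list[GeneFeature] = []
    truth_genes: dict[str, dict] = {}
    pos = 0
    for g in range(spec.n_genes):
        spacer = _intergenic(rng, spec.mean_intergenic_len, background_gc)
        chunks.append(spacer)
        pos += len(spacer)
        length = max(10, int(rng.poisson(spec.mean_gene_len)))
        stop = stops[rng.choice(len(stops), p=w)]
        cds = _gen_cds(rng, length, spec.target_gc12, spec.target_gc3, stop)
        strand = "+" if rng.random() < 0.5 else "-"
        tag = f"gene_{g + 1:04d}"
        chunks.append(cds if strand == "+" else reverse_complement(cds))
        features.append(GeneFeature(contig_id=cid, start=pos,
                                    end=pos + len(cds), strand=strand,
                                    locus_tag=tag,
                                    product="hypothetical protein"))
        truth_genes[tag] = _gene_truth(tag, cds, strand)
        pos += len(cds)
    chunks.append(_intergenic(rng, spec.mean_intergenic_len, background_gc))
    record = SequenceRecord(id=cid, residues="".join(chunks),
                            moltype="nucleotide",
                            description="synthetic annotated contig")
    truth = {"spec": dataclasses.asdict(spec), "contig_id": cid,
             "genes": truth_genes}
    return record, features, truth


def insert_foreign_gene(record: SequenceRecord,
                        features: list[GeneFeature], truth: dict, *,
                        foreign_gc3: float = 0.95, foreign_gc12: float = 0.35,
                        stop: str = "TAA", length_codons: int = 150,
                        seed: int = 0, locus_tag: str = "foreign_0001"
                        ) -> tuple[SequenceRecord, list[GeneFeature], dict]:
    """Insert one compositionally foreign gene into a host contig.

    The insert's codons have GC3 near saturation and depressed GC12 and the
    gene terminates with the requested stop codon (TAA by default) — an
    ameliorated low-GC-donor gene in a high-GC host.  Insertion happens at a
    uniformly random intergenic position; downstream features shift right.
    """
    rng = np.random.default_rng(seed)
    occupied = sorted((f.start, f.end) for f in features)
    gaps = []
    prev = 0
    for a, b in occupied:
        if a > prev:
            gaps.append((prev, a))
        prev = max(prev, b)
    if prev < len(record):
        gaps.append((prev, len(record)))
    if not gaps:
        raise ValueError("no intergenic space to insert into")
    gi = int(rng.integers(0, len(gaps)))
    point = int(rng.integers(gaps[gi][0], gaps[gi][1] + 1))
    cds = _gen_cds(rng, length_codons, foreign_gc12, foreign_gc3, stop)
    strand = "+" if rng.random() < 0.5 else "-"
    inserted = cds if strand == "+" else reverse_complement(cds)

    residues = record.residues[:point] + inserted + record.residues[point:]
    new_features = []
    for f in features:
        if f.start >= point:
            new_features.append(dataclasses.replace(
                f, start=f.start + len(inserted), end=f.end + len(inserted)))
        else:
            new_features.append(f)
    new_features.append(GeneFeature(contig_id=record.id, start=point,
                                    end=point + len(inserted), strand=strand,
                                    locus_tag=locus_tag,
                                    product="foreign gene"))
    new_features.sort(key=lambda f: f.start)
    new_truth = {**truth, "genes": dict(truth["genes"]),
                 "foreign": locus_tag}
    new_truth["genes"][locus_tag] = _gene_truth(locus_tag, cds, strand)
    new_record = dataclasses.replace(record, residues=residues)
    return new_record, new_features, new_truth


def aah_like_contig(seed: int = 0) -> tuple[SequenceRecord, list[GeneFeature], dict]:
    """A 27-gene contig in the style of the studied M. arborescens insert.

    26 host genes drawn from a high-GC actinobacterial model (contig GC
    ~0.69, TAG/TGA stops only) plus one planted foreign gene carrying the
    ameliorated signature: GC3 near saturation (~0.94), GC12 depressed to
    ~0.54 (gene GC ~0.68), a ~17 kD product, and the contig's sole TAA stop.
    """
    spec = GenomeSpec(n_genes=26, mean_gene_len=180, target_gc3=0.85,
                      target_gc12=0.615,
                      stop_codon_weights={"TAA": 0.0, "TAG": 0.35, "TGA": 0.65},
                      seed=seed)
    record, features, truth = gen_genome(spec)
    return insert_foreign_gene(record, features, truth, foreign_gc3=0.944,
                               foreign_gc12=0.54, stop="TAA",
                               length_codons=146, seed=seed + 1,
                               locus_tag="aah_like")


# ---------------------------------------------------------------------------
# genome panels
# ---------------------------------------------------------------------------

def panel_stop_weights(u: float, trend_strength: float) -> dict[str, float]:
    """Stop-codon weights at relative GC position ``u`` in [0, 1].

    At full strength TAA falls from 0.85 to 0 and TGA rises symmetrically as
    GC grows, with TAG flat and low; at strength 0 the three are uniform.
    """
    t = float(np.clip(trend_strength, 0.0, 1.0))
    return {"TAA": (1 - t) / 3 + t * 0.85 * (1 - u),
            "TAG": (1 - t) / 3 + t * 0.15,
            "TGA": (1 - t) / 3 + t * 0.85 * u}


def gen_genome_panel(n_genomes: int = 30,
                     gc_range: tuple[float, float] = (0.25, 0.75),
                     trend_strength: float = 1.0, seed: int = 0, *,
                     n_genes: int = 60, mean_gene_len: int = 150
                     ) -> list[tuple[SequenceRecord, list[GeneFeature], dict]]:
    """A panel of annotated genomes spread across a GC range.

    Genome GC is spaced evenly over ``gc_range`` (both GC12 and GC3 track the
    target); stop-codon weights follow :func:`panel_stop_weights`, giving the
    TAA-down/TGA-up trend at full ``trend_strength`` and no trend at 0.
    """
    if n_genomes < 4:
        raise ValueError("panel requires at least 4 genomes")
    lo, hi = gc_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid gc_range {gc_range}")
    rng = np.random.default_rng(seed)
    targets = np.linspace(lo, hi, n_genomes)
    panel = []
    for i, g in enumerate(targets):
        u = (g - lo) / (hi - lo)
        spec = GenomeSpec(n_genes=n_genes, mean_gene_len=mean_gene_len,
                          target_gc3=float(g), target_gc12=float(g),
                          stop_codon_weights=panel_stop_weights(u, trend_strength),
                          seed=int(rng.integers(0, 2**31 - 1)))
        panel.append(gen_genome(spec, contig_id=f"genome_{i + 1:03d}"))
    return panel


# ---------------------------------------------------------------------------
# protein families on trees
# ---------------------------------------------------------------------------

def _random_topology(rng: np.random.Generator, labels: list[str]) -> Clade:
    active = [Clade(name=l) for l in labels]
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(int(j))
        a = active.pop(int(i))
        active.append(Clade(children=[a, b]))
    return Clade(children=active)


def expected_mismatch(path_length: float, rate: float = 1.0) -> float:
    """Closed-form expected mismatch fraction between two sequences separated
    by total path length ``t`` under the 20-state uniform-replacement model:
    ``19/20 * (1 - exp(-20/19 * rate * t))``."""
    return 19.0 / 20.0 * (1.0 - np.exp(-20.0 / 19.0 * rate * path_length))


def simulate_protein_family(spec: TreeSpec
                            ) -> tuple[PhyloTree, dict[str, SequenceRecord],
                                       dict[str, str]]:
    """Evolve a protein family along a random tree.

    Topology: random binary joins; branch lengths i.i.d.
    ``min_branch_length + Exponential(mean - min)`` — the floor keeps every
    internal edge long enough to be statistically resolvable at the
    simulated sequence lengths.  The root sequence is uniform over the 20
    residues; along each branch every site receives Poisson(rate x length)
    substitution events, each replacing the residue with a uniform draw from
    the other 19.  No indels, so the leaves are their own true alignment.

    Returns (true tree, leaf protein records, true alignment).
    """
    rng = np.random.default_rng(spec.seed)
    labels = [f"taxon{i + 1:02d}" for i in range(spec.n_taxa)]
    root = _random_topology(rng, labels)
    scale = spec.mean_branch_length - spec.min_branch_length
    for node in root.walk():
        if node is not root:
            node.branch_length = spec.min_branch_length + \
                float(rng.exponential(scale))

    aa = np.frombuffer(AA20.encode(), dtype=np.uint8)
    root_seq = rng.integers(0, 20, size=spec.seq_length)

    leaf_seqs: dict[str, str] = {}

    def evolve(node: Clade, seq: np.ndarray) -> None:
        for child in node.children:
            s = seq.copy()
            n_events = rng.poisson(spec.rate * child.branch_length,
                                   size=spec.seq_length)
            for site in np.nonzero(n_events)[0]:
                for _ in range(int(n_events[site])):
                    shift = int(rng.integers(1, 20))
                    s[site] = (s[site] + shift) % 20
            if child.is_leaf:
                leaf_seqs[child.name] = aa[s].tobytes().decode()
            else:
                evolve(child, s)

    evolve(root, root_seq)
    proteins = {l: SequenceRecord(id=l, residues=s, moltype="protein")
                for l, s in leaf_seqs.items()}
    tree = PhyloTree(root, rooted=True).sort()
    return tree, proteins, dict(leaf_seqs)
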