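"""Stop-codon usage per replicon and its correlation with genomic GC.

Across bacteria the three stop codons are not used interchangeably: TAA
dominates in low-GC genomes, TGA takes over as genomic GC rises, and TAG
stays rare throughout.  A gene whose stop codon bucks its host genome's
pattern (e.g. the single TAA-terminated gene on a high-GC contig) is a
second, codon-level hint of foreign origin alongside the GC3 signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from . import composition
from .seqio import GeneFeature, SequenceRecord, STOP_CODONS, extract_cds

logger = logging.getLogger(__name__)

PARTIAL = "partial"


@dataclass(frozen=True)
class StopCodonCensus:
    """Stop-codon counts and fractions of one replicon (or genome)."""

    replicon_id: str
    genome_gc: float
    counts: dict[str, int]
    n_partial: int = 0

    @property
    def n_genes(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_genes
        if n == 0:
            return {c: float("nan") for c in STOP_CODONS}
        return {c: self.counts[c] / n for c in STOP_CODONS}

    def to_row(self) -> dict:
        row = {"replicon_id": self.replicon_id, "genome_gc": self.genome_gc,
               "n_genes": self.n_genes, "n_partial": self.n_partial}
        row.update({c: self.counts[c] for c in STOP_CODONS})
        row.update({f"frac_{c}": self.fractions[c] for c in STOP_CODONS})
        return row


def gene_stop(feature: GeneFeature, record: SequenceRecord) -> str:
    """The stop codon of one gene: TAA/TAG/TGA, or ``"partial"``.

    The last in-frame codon of the strand-aware CDS; genes whose length is
    not a multiple of 3 or that end in a non-stop codon are reported partial.
    """
    cds = str(extract_cds(record, feature))
    if len(cds) % 3 != 0:
        return PARTIAL
    last = cds[-3:]
    return last if last in STOP_CODONS else PARTIAL


def census(record: SequenceRecord, features: Iterable[GeneFeature],
           replicon_id: str | None = None) -> StopCodonCensus:
    """Tabulate stop-codon usage of all complete CDS on one replicon.

    Genes without a canonical in-frame stop are excluded from the counts and
    reported via ``n_partial``; genomic GC is computed on the full record.
    """
    counts = {c: 0 for c in STOP_CODONS}
    n_partial = 0
    for f in features:
        stop = gene_stop(f, record)
        if stop == PARTIAL:
            n_partial += 1
        else:
            counts[stop] += 1
    if n_partial:
        logger.info("census %s: %d partial CDS excluded",
                    replicon_id or record.id, n_partial)
    return StopCodonCensus(replicon_id=replicon_id or record.id,
                           genome_gc=composition.gc_content(record),
                           counts=counts, n_partial=n_partial)


def census_genome(replicons: Sequence[tuple[SequenceRecord, Sequence[GeneFeature]]],
                  genome_id: str) -> StopCodonCensus:
    """Pooled census over a multi-replicon genome; GC is length-weighted."""
    counts = {c: 0 for c in STOP_CODONS}
    n_partial = 0
    gc_weighted = 0.0
    total_len = 0
    for record, features in replicons:
        sub = census(record, features)
        for c in STOP_CODONS:
            counts[c] += sub.counts[c]
        n_partial += sub.n_partial
        gc_weighted += sub.genome_gc * len(record)
        total_len += len(record)
    return StopCodonCensus(replicon_id=genome_id,
                           genome_gc=gc_weighted / total_len,
                           counts=counts, n_partial=n_partial)


def census_table(censuses: Iterable[StopCodonCensus]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in censuses])


def correlate(censuses: Sequence[StopCodonCensus], *,
              method: str = "spearman",
              metric: str = "fraction") -> dict[str, tuple[float, float]]:
    """Correlate each stop codon's usage against genomic GC across genomes.

    Returns ``{codon: (coefficient, two-sided p-value)}``.  Spearman rank
    correlation is the default — the usage-vs-GC relationship is monotone but
    visibly nonlinear — with Pearson available via ``method="pearson"``.
    ``metric`` selects fractions (default) or raw counts as the response.
    """
    if len(censuses) < 4:
        raise ValueError("correlation requires at least 4 genomes")
    gc = [c.genome_gc for c in censuses]
    if len(set(gc)) == 1:
        raise ValueError("degenerate predictor: genomic GC constant across genomes")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if metric not in ("fraction", "count"):
        raise ValueError(f"unknown metric {metric!r}")
    out = {}
    for codon in STOP_CODONS:
        if metric == "fraction":
            y = [c.fractions[codon] for c in censuses]
        else:
            y = [c.counts[codon] for c in censuses]
        if method == "spearman":
            rho, p = _spearman(gc, y)
        else:
            rho, p = stats.pearsonr(gc, y)
        out[codon] = (float(rho), float(p))
    return out


def _spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with exact arithmetic in the tie-free case.

    The rank statistic is exact by construction (rho = +-1 on monotone data);
    computing it as a Pearson correlation of ranks loses that to rounding, so
    without ties the integer formula 1 - 6*sum(d^2)/(n(n^2-1)) is used.  A
    constant response (e.g. one stop codon never used) yields rho = nan.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if len(set(rx)) == len(rx) and len(set(ry)) == len(ry):
        n = len(rx)
        d2 = sum((int(a) - int(b)) ** 2 for a, b in zip(rx, ry))
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(rho), float(p)
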