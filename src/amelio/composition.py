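"""Base-composition statistics: GC content, windowed GC profiles, codon-position
GC (GC1/GC2/GC3), a per-gene compositional-outlier report, and protein mass.

The codon-position statistics are the workhorse of amelioration analysis:
in GC-rich bacteria mutational bias saturates the weakly constrained third
codon position (high GC3) while selection holds GC1/GC2 lower.  A gene whose
GC3 is extreme *and* whose GC1/GC2 are depressed relative to its neighbours
carries the signature of a horizontally acquired gene from a low-GC donor
that has ameliorated toward the host's composition.

Conventions: the ambiguity base N is excluded from both numerator and
denominator of every GC fraction; the terminal stop codon is excluded from
codon-position statistics by default (it is censused separately by
:mod:`amelio.stopcodons`), switchable via ``drop_terminal_stop``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .seqio import STOP_CODONS, SequenceRecord


@dataclass(frozen=True)
class CompositionProfile:
    """A windowed composition series along a sequence.

    ``kind`` is one of ``nucleotide_gc`` (window/step in bp) or
    ``codon_gc1``/``codon_gc2``/``codon_gc3`` (window/step in codons).
    ``centers`` are window midpoints (start + window/2) in the profile's unit.
    """

    kind: str
    window: int
    step: int
    centers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide_gc", "codon_gc1", "codon_gc2", "codon_gc3"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be positive")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("window centers must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("profile fractions must lie in [0, 1]")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.centers.tolist(), self.values.tolist()))

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, self.kind: self.values})


def _seq(x: str | SequenceRecord) -> str:
    return str(x).upper()


def gc_content(seq: str | SequenceRecord) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); N excluded throughout."""
    s = _seq(x=seq)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    gc = int(np.sum((arr == ord("G")) | (arr == ord("C"))))
    total = int(np.sum(arr != ord("N")))
    if total == 0:
        raise ValueError("no unambiguous bases (empty or all-N sequence)")
    return gc / total


def windowed_gc(seq: str | SequenceRecord, window: int, step: int = 1
                ) -> CompositionProfile:
    """Sliding-window GC along a nucleotide sequence.

    One point per complete window (trailing partial window discarded); the
    point coordinate is the window center ``start + window/2``.
    """
    s = _seq(seq)
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if window > len(s):
        raise ValueError(f"window {window} exceeds sequence length {len(s)}")
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    is_gc = np.concatenate(([0], np.cumsum((arr == ord("G")) | (arr == ord("C")))))
    informative = np.concatenate(([0], np.cumsum(arr != ord("N"))))
    starts = np.arange(0, len(s) - window + 1, step)
    gc = is_gc[starts + window] - is_gc[starts]
    total = informative[starts + window] - informative[starts]
    if np.any(total == 0):
        raise ValueError("window containing only N bases")
    return CompositionProfile(kind="nucleotide_gc", window=window, step=step,
                              centers=starts + window / 2.0,
                              values=gc / total)


def _codon_array(cds: str | SequenceRecord, drop_terminal_stop: bool
                 ) -> np.ndarray:
    s = _seq(cds)
    if len(s) % 3 != 0:
        raise ValueError(f"CDS length {len(s)} not a multiple of 3")
    if drop_terminal_stop and len(s) >= 6 and s[-3:] in STOP_CODONS:
        s = s[:-3]
    if not s:
        raise ValueError("no codons left after stop exclusion")
    return np.frombuffer(s.encode(), dtype=np.uint8).reshape(-1, 3)


def codon_position_gc(cds: str | SequenceRecord, *,
                      drop_terminal_stop: bool = True
                      ) -> tuple[float, float, float]:
    """(GC1, GC2, GC3): fraction of codons with G/C at each codon position.

    All codons including the start are counted; the terminal stop codon is
    excluded by default (set ``drop_terminal_stop=False`` to include it).
    N bases are excluded per position from numerator and denominator.
    """
    codons = _codon_array(cds, drop_terminal_stop)
    out = []
    for k in range(3):
        col = codons[:, k]
        informative = col != ord("N")
        denom = int(informative.sum())
        if denom == 0:
            raise ValueError(f"codon position {k + 1} is all N")
        gc = int(np.sum((col == ord("G")) | (col == ord("C"))))
        out.append(gc / denom)
    return tuple(out)


def sliding_codon_gc(cds: str | SequenceRecord, window_codons: int = 10,
                     step_codons: int = 1, *, drop_terminal_stop: bool = True
                     ) -> tuple[CompositionProfile, CompositionProfile,
                                CompositionProfile]:
    """Sliding codon-window GC1/GC2/GC3 profiles of one coding sequence.

    Defaults (window 10 codons, step 1 codon) match the classic FramePlot-style
    coding-frame diagnostic.  Coordinates are codon indices of window centers.
    """
    codons = _codon_array(cds, drop_terminal_stop)
    n = len(codons)
    if n < window_codons:
        raise ValueError(
            f"only {n} codons after stop exclusion; window is {window_codons}")
    starts = np.arange(0, n - window_codons + 1, step_codons)
    centers = starts + window_codons / 2.0
    profiles = []
    for k, kind in enumerate(("codon_gc1", "codon_gc2", "codon_gc3")):
        col = codons[:, k]
        gc = np.concatenate(([0], np.cumsum((col == ord("G")) | (col == ord("C")))))
        informative = np.concatenate(([0], np.cumsum(col != ord("N"))))
        num = gc[starts + window_codons] - gc[starts]
        den = informative[starts + window_codons] - informative[starts]
        if np.any(den == 0):
            raise ValueError("codon window with position all N")
        profiles.append(CompositionProfile(kind=kind, window=window_codons,
                                           step=step_codons, centers=centers,
                                           values=num / den))
    return tuple(profiles)


OUTLIER_COLUMNS = ["locus_tag", "gc", "gc1", "gc2", "gc3", "z3", "z12", "flag"]


def outlier_report(cds_by_tag: dict[str, str | SequenceRecord],
                   z_thresh: float = 2.0, *,
                   drop_terminal_stop: bool = True) -> pd.DataFrame:
    """Per-gene compositional report with amelioration-outlier flags.

    For every gene the whole-CDS GC and GC1/GC2/GC3 are computed, then two
    standard scores across the contig's genes: ``z3`` for GC3 and ``z12`` for
    mean(GC1, GC2).  A gene is flagged when ``z3 >= z_thresh`` and
    ``z12 <= -z_thresh`` — extreme third-position GC combined with depressed
    first/second-position GC, the compositional signature of an ameliorated
    foreign gene.  This scoring is a convention of this package, not a
    published formula.

    Requires at least 3 genes; rows are ordered by locus tag.  Z-scores use
    the population standard deviation so they have mean 0 and sd 1 exactly.
    """
    if len(cds_by_tag) < 3:
        raise ValueError("outlier report requires at least 3 genes")
    rows = []
    for tag in sorted(cds_by_tag):
        cds = cds_by_tag[tag]
        gc1, gc2, gc3 = codon_position_gc(cds, drop_terminal_stop=drop_terminal_stop)
        codons = _codon_array(cds, drop_terminal_stop)
        gc = gc_content(codons.tobytes().decode())
        rows.append({"locus_tag": tag, "gc": gc, "gc1": gc1, "gc2": gc2,
                     "gc3": gc3})
    df = pd.DataFrame(rows)

    def zscore(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        if sd == 0:
            return pd.Series(np.zeros(len(x)), index=x.index)
        return (x - x.mean()) / sd

    df["z3"] = zscore(df["gc3"])
    df["z12"] = zscore((df["gc1"] + df["gc2"]) / 2.0)
    df["flag"] = (df["z3"] >= z_thresh) & (df["z12"] <= -z_thresh)
    return df[OUTLIER_COLUMNS]


def protein_mw(protein: str | SequenceRecord) -> float:
    """Average molecular weight of a protein in kilodaltons.

    Sum of average residue masses plus one water.  Sequences containing X are
    rejected (mass undefined).
    """
    seq = _seq(protein)
    if not seq:
        raise ValueError("empty protein")
    if "X" in seq:
        raise ValueError("molecular weight undefined for ambiguous residue X")
    return ProteinAnalysis(seq).molecular_weight() / 1000.0
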