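"""End-to-end orchestration: run every analysis stage on one annotated input
and write a reproducible report bundle.

Outputs are plain TSV/Newick/text files, each prefixed with ``#`` header
lines recording the exact parameters that produced it, so a rerun with the
same configuration is byte-identical.  A MANIFEST file lists each stage with
its status; a stage failure stops the run with the completed outputs kept.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import composition, phylo, seqio, stopcodons, synteny

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the MANIFEST records which outputs were completed."""


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run.

    Round-trips losslessly through YAML (:meth:`to_yaml` / :meth:`from_yaml`).
    """

    # inputs (either a GenBank file, or FASTA + feature TSV)
    genbank: str | None = None
    fasta: str | None = None
    features: str | None = None
    msa: str | None = None            # aligned protein FASTA for bootstrap
    output_dir: str = "amelio_out"

    # parameters
    gc_window: int = 500
    gc_step: int = 10
    gene_gc_window: int = 40
    codon_window: int = 10
    codon_step: int = 1
    focal_gene: str | None = None     # default: gene with the largest |z3|
    z_thresh: float = 2.0
    bootstrap_reps: int = 100
    seed: int = 0
    outgroup: str | None = None
    synteny_k: int = 8

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("genbank", "fasta", "features", "msa"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        if self.genbank is None and (self.fasta is None or self.features is None):
            raise ValueError("provide either a GenBank file or FASTA + features TSV")


def _params_header(config: RunConfig, keys: list[str]) -> list[str]:
    return [f"{k}={getattr(config, k)}" for k in keys]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all applicable stages; return the map of output name -> path."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    outputs: dict[str, Path] = {}

    def done(stage: str, path: Path) -> None:
        manifest.append(f"{stage}\tok\t{path.name}")
        outputs[stage] = path
        logger.info("stage %s -> %s", stage, path)

    def write_manifest(status: str) -> None:
        lines = manifest + [f"RUN\t{status}"]
        (outdir / "MANIFEST").write_text("\n".join(lines) + "\n")

    try:
        # -- load -----------------------------------------------------------
        if config.genbank:
            record, features = seqio.read_genbank(config.genbank)
        else:
            record = seqio.read_fasta(config.fasta)[0]
            features = seqio.read_features_tsv(config.features)
        cds = {f.locus_tag: str(seqio.extract_cds(record, f))
               for f in features}
        complete = {t: s for t, s in cds.items()
                    if len(s) % 3 == 0 and s[-3:] in seqio.STOP_CODONS}

        # -- contig GC profile ---------------------------------------------
        prof = composition.windowed_gc(record, config.gc_window, config.gc_step)
        path = outdir / "gc_profile.tsv"
        seqio.write_tsv(prof.to_frame(), path,
                        _params_header(config, ["gc_window", "gc_step"])
                        + [f"input={record.id}"])
        done("gc_profile", path)

        # -- outlier report -------------------------------------------------
        report = composition.outlier_report(complete, z_thresh=config.z_thresh)
        path = outdir / "outliers.tsv"
        seqio.write_tsv(report, path, _params_header(config, ["z_thresh"]))
        done("outliers", path)

        # -- focal-gene codon profile + 40 bp GC profile ---------------------
        focal = config.focal_gene
        if focal is None:
            focal = report.loc[report["z3"].abs().idxmax(), "locus_tag"]
        if focal not in complete:
            raise PipelineError(f"focal gene {focal!r} has no complete CDS")
        profs = composition.sliding_codon_gc(complete[focal],
                                             config.codon_window,
                                             config.codon_step)
        frame = profs[0].to_frame()
        for p in profs[1:]:
            frame[p.kind] = p.values
        path = outdir / "codon_profile.tsv"
        seqio.write_tsv(frame, path,
                        _params_header(config, ["codon_window", "codon_step"])
                        + [f"focal_gene={focal}"])
        done("codon_profile", path)

        gene_prof = composition.windowed_gc(complete[focal],
                                            config.gene_gc_window, 1)
        path = outdir / "focal_gene_gc_profile.tsv"
        seqio.write_tsv(gene_prof.to_frame(), path,
                        _params_header(config, ["gene_gc_window"])
                        + [f"focal_gene={focal}"])
        done("focal_gene_gc", path)

        # -- stop-codon census ----------------------------------------------
        cen = stopcodons.census(record, features)
        path = outdir / "stop_census.tsv"
        seqio.write_tsv(stopcodons.census_table([cen]), path, [f"input={record.id}"])
        done("stop_census", path)

        # -- tree -------------------------------------------------------------
        proteins = {}
        for tag, s in complete.items():
            try:
                proteins[tag] = str(seqio.translate(s, actinobacterial_starts=True))
            except ValueError:
                continue
        if len(proteins) >= 3:
            msa = None
            if config.msa:
                msa = {r.id: r.residues
                       for r in seqio.read_fasta(config.msa, moltype="protein")}
            t = phylo.nj_tree(proteins, msa=msa, n_reps=config.bootstrap_reps,
                              seed=config.seed, outgroup=config.outgroup)
            path = outdir / "tree.nwk"
            seqio.write_newick(t, path)
            done("tree", path)

        # -- summary ----------------------------------------------------------
        flagged = report[report["flag"]]["locus_tag"].tolist()
        lines = [
            f"input: {record.id} ({len(record)} bp, "
            f"{composition.gc_content(record):.3f} GC)",
            f"genes: {len(features)} annotated, {len(complete)} complete CDS",
            f"focal gene: {focal} "
            f"(GC={composition.gc_content(complete[focal]):.3f}, "
            f"GC3={composition.codon_position_gc(complete[focal])[2]:.3f})",
            f"compositional outliers (|z| >= {config.z_thresh}): "
            f"{', '.join(flagged) if flagged else 'none'}",
            "stop codons: " + ", ".join(
                f"{c}={cen.counts[c]}" for c in stopcodons.STOP_CODONS)
            + f" (partial={cen.n_partial})",
        ]
        path = outdir / "summary.txt"
        path.write_text("\n".join(lines) + "\n")
        done("summary", path)
    except Exception:
        write_manifest("failed")
        raise
    write_manifest("ok")
    return outputs
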