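"""End-to-end comparative plastome analysis.

``run_pipeline`` composes the library stages over a set of records (plus
per-group alignments for the diversity stage) and writes the standard report
bundle: an architecture summary, a junction report, per-group window series
and highly-polymorphic-region tables, per-taxon ENC extremes, optimal-codon
sets, codon-aversion motifs with their distance matrix, and a neighbor-
joining tree. Every threshold applied is echoed into a run manifest, and
every number in a report comes from a library call — the pipeline does no
computation of its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .architecture import architecture_summary, junction_report
from .codonlab import (
    cam_distance_matrix,
    cam_profile,
    count_codons,
    enc,
    nj_newick,
    optimal_codons,
    rscu,
    select_groups,
    UndefinedENCError,
)
from .diversity import (
    AlignmentMatrix,
    call_hprs,
    hpr_table,
    label_hprs,
    sliding_pi,
    write_bed,
)
from .plastome_io import PlastomeRecord, extract_cds, write_cds_fasta


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All thresholds of the comparative analysis, with their defaults."""

    outdir: str = "plastcomp_out"
    groups: Mapping[str, Sequence[str]] = field(default_factory=dict)  # name -> taxa
    min_cds_len: int = 300
    enc_fraction: float = 0.05
    delta_rscu_min: float = 0.08
    window: int = 600
    step: int = 200
    hpr_quantile: float = 0.975
    min_ir_len: int = 1000
    cam_mode: str = "gene_labeled"
    seed: int = 0


def run_pipeline(
    records: Sequence[PlastomeRecord],
    config: RunConfig,
    alignments: Mapping[str, AlignmentMatrix] | None = None,
) -> dict[str, Path]:
    """Run every stage and write the report bundle into ``config.outdir``.

    ``alignments`` maps diversity-group names to alignments; groups named in
    ``config.groups`` are taken as taxon subsets of those alignments (or of
    an alignment named "all"). Returns the written paths keyed by artifact
    name; partial outputs are preserved when a later stage fails.
    """
    if not records:
        raise ValueError("need at least one record")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        written[name] = path

    # -- architecture ------------------------------------------------------
    try:
        summaries = [architecture_summary(r, min_ir_len=config.min_ir_len) for r in records]
        p = out / "architecture_summary.json"
        p.write_text(json.dumps(summaries, indent=1))
        emit("architecture_summary", p)
        rep = junction_report(records, min_ir_len=config.min_ir_len)
        p = out / "junction_report.tsv"
        rep.to_csv(p, sep="\t", index=False)
        emit("junction_report", p)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _write_manifest(out, config, written, failed="architecture")
        raise PipelineError("architecture", exc) from exc

    # -- codon usage per taxon --------------------------------------------
    try:
        enc_rows, opt_rows, cam_profiles, rscu_rows = [], [], [], []
        for rec in records:
            cds = extract_cds(rec, min_len=config.min_cds_len, dedupe=True)
            if not cds:
                continue
            write_cds_fasta(cds, out / f"cds_{rec.accession}.fasta")
            counts = [count_codons(c) for c in cds]
            encs = []
            for cc in counts:
                try:
                    encs.append(enc(cc))
                except UndefinedENCError:
                    continue
            for e in encs:
                enc_rows.append({"taxon": rec.taxon, "accession": rec.accession,
                                 "gene": e.gene, "enc": round(e.nc, 2)})
            table = rscu(counts)
            for codon, value in sorted(table.values.items()):
                rscu_rows.append({"taxon": rec.taxon, "codon": codon.replace("T", "U"),
                                  "rscu": round(value, 4)})
            groups = select_groups(encs, fraction=config.enc_fraction)
            by_gene = {cc.gene: cc for cc in counts}
            optset = optimal_codons(
                [by_gene[g] for g in groups.high],
                [by_gene[g] for g in groups.low],
                delta_min=config.delta_rscu_min,
            )
            opt_rows.append({
                "taxon": rec.taxon,
                "optimal_codons": " ".join(sorted(optset.codons)),
                "n_optimal": len(optset.codons),
                "high_group(lowest ENC)": ",".join(groups.high),
                "low_group(highest ENC)": ",".join(groups.low),
            })
            cam_profiles.append(cam_profile(rec.taxon, cds))
        p = out / "enc_per_gene.tsv"
        pd.DataFrame(enc_rows).to_csv(p, sep="\t", index=False)
        emit("enc_per_gene", p)
        p = out / "rscu_per_taxon.tsv"
        pd.DataFrame(rscu_rows).to_csv(p, sep="\t", index=False)
        emit("rscu_per_taxon", p)
        enc_df = pd.DataFrame(enc_rows)
        extremes = _enc_extremes(enc_df, config.enc_fraction)
        p = out / "enc_extremes.tsv"
        extremes.to_csv(p, sep="\t", index=False)
        emit("enc_extremes", p)
        p = out / "optimal_codons.tsv"
        pd.DataFrame(opt_rows).to_csv(p, sep="\t", index=False)
        emit("optimal_codons", p)
    except Exception as exc:  # noqa: BLE001
        _write_manifest(out, config, written, failed="codon")
        raise PipelineError("codon", exc) from exc

    # -- CAM motifs, distances, tree --------------------------------------
    try:
        cam_rows = []
        for prof in cam_profiles:
            for gene, motif in sorted(prof.motifs.items()):
                cam_rows.append({"taxon": prof.species, "gene": gene,
                                 "n_unused": len(motif.unused),
                                 "unused_codons": ",".join(motif.unused)})
        p = out / "cam_motifs.tsv"
        pd.DataFrame(cam_rows).to_csv(p, sep="\t", index=False)
        emit("cam_motifs", p)
        if len(cam_profiles) >= 3:
            dm = cam_distance_matrix(cam_profiles, mode=config.cam_mode)
            p = out / "cam_distances.phylip"
            _write_phylip(dm, p)
            emit("cam_distances", p)
            p = out / "cam_tree.nwk"
            p.write_text(nj_newick(dm) + "\n")
            emit("cam_tree", p)
    except Exception as exc:  # noqa: BLE001
        _write_manifest(out, config, written, failed="cam")
        raise PipelineError("cam", exc) from exc

    # -- diversity per group ----------------------------------------------
    try:
        alignments = dict(alignments or {})
        groups = dict(config.groups)
        if alignments and not groups:
            groups = {name: list(aln.taxa) for name, aln in alignments.items()}
        for gname, taxa in groups.items():
            aln = alignments.get(gname) or alignments.get("all")
            if aln is None:
                continue
            if set(taxa) != set(aln.taxa):
                aln = aln.subset([t for t in aln.taxa if t in set(taxa)])
            series = sliding_pi(aln, window=config.window, step=config.step)
            p = out / f"pi_windows_{gname}.tsv"
            series.to_frame().to_csv(p, sep="\t", index=False)
            emit(f"pi_windows_{gname}", p)
            regions = call_hprs(series, aln, threshold_quantile=config.hpr_quantile)
            regions = label_hprs(regions, records[0])
            p = out / f"hpr_{gname}.tsv"
            hpr_table(regions).to_csv(p, sep="\t", index=False)
            emit(f"hpr_{gname}", p)
            p = out / f"hpr_{gname}.bed"
            write_bed(regions, p, chrom=records[0].accession)
            emit(f"hpr_bed_{gname}", p)
    except Exception as exc:  # noqa: BLE001
        _write_manifest(out, config, written, failed="diversity")
        raise PipelineError("diversity", exc) from exc

    _write_manifest(out, config, written, failed=None)
    written["manifest"] = out / "run_manifest.json"
    return written


def _enc_extremes(enc_df: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Per-taxon lowest/highest ENC genes (the expression-proxy extremes)."""
    rows = []
    import math

    for taxon, sub in enc_df.groupby("taxon"):
        size = math.ceil(fraction * len(sub))
        ranked = sub.sort_values(["enc", "gene"])
        for _, r in ranked.head(size).iterrows():
            rows.append({"taxon": taxon, "group": "low_enc(high_expression)",
                         "gene": r["gene"], "enc": r["enc"]})
        for _, r in ranked.tail(size).iterrows():
            rows.append({"taxon": taxon, "group": "high_enc(low_expression)",
                         "gene": r["gene"], "enc": r["enc"]})
    return pd.DataFrame(rows)


def _write_phylip(dm, path: Path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for name in dm.ids:
            row = "  ".join(f"{dm[name, other]:.6f}" for other in dm.ids)
            fh.write(f"{name:<12s}{row}\n")


def _write_manifest(out: Path, config: RunConfig, written: Mapping[str, Path], failed: str | None) -> None:
    manifest = {
        "version": __version__,
        "config": {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in asdict(config).items()},
        "outputs": {k: str(v) for k, v in written.items()},
        "failed_stage": failed,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
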