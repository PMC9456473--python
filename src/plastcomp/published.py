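"""Verification against the four deposited Bletilla plastomes.

The reported comparative values for the four GenBank accessions
(OP104328 B. formosana, OP104329 B. ochracea, OP104330 B. striata,
MT806143 B. sinensis) can be re-derived from the records themselves. This
module recomputes them with the library and compares. The records are not
bundled: fetch them with ``scripts/fetch_accessions.py`` (network required)
into a directory, then run ``verify_published(directory)`` or
``scripts/verify_published.py``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .architecture import architecture_summary, gene_overlap
from .codonlab import (
    cam_profile,
    count_codons,
    enc,
    optimal_codons,
    select_groups,
    UndefinedENCError,
)
from .plastome_io import PlastomeRecord, extract_cds, read_genbank

ACCESSIONS = ("OP104328", "OP104329", "OP104330", "MT806143")

#: reported reference values, keyed by accession
EXPECTED: Mapping[str, Mapping[str, float]] = {
    "OP104328": {"total": 160022, "lsc": 87636, "ir": 26801, "ssc": 18784, "gc": 0.372},
    "OP104329": {"total": 160168, "lsc": 87746, "ir": 26809, "ssc": 18804, "gc": 0.372},
    "OP104330": {"total": 159484, "lsc": 87114, "ir": 26793, "ssc": 18784, "gc": 0.372},
    "MT806143": {"total": 156942, "lsc": 86289, "ir": 26202, "ssc": 18249, "gc": 0.372},
}
EXPECTED_OVERLAP_BP = 55        # pseudo-ycf1 x ndhF at JSB, every accession
EXPECTED_CDS_COUNT = 53         # CDSs of >= 300 bp after IR-duplicate dedup
EXPECTED_SHARED_CAM = 27        # genes with identical motifs in the three non-sinensis taxa
EXPECTED_OPTIMAL = {
    "OP104328": {"GGU", "UUG", "UCC", "CGU"},
    "OP104329": {"GGU", "UUG", "UCC", "CGU"},
    "OP104330": {"GGU", "UUG", "UCC", "CGU"},
    "MT806143": {"GGU", "CGA"},
}


def load_accessions(directory: str | Path) -> dict[str, PlastomeRecord]:
    directory = Path(directory)
    records = {}
    for acc in ACCESSIONS:
        hits = sorted(directory.glob(f"{acc}*.gb*"))
        if not hits:
            raise FileNotFoundError(
                f"{acc} not found under {directory}; run scripts/fetch_accessions.py first"
            )
        records[acc] = read_genbank(hits[0])
    return records


def verify_published(directory: str | Path, enc_tol: float = 0.05) -> dict:
    """Recompute the reference table values from the records and compare.

    Returns a dict of named checks, each ``{"computed": ..., "expected": ...,
    "ok": bool}``. Raises ``FileNotFoundError`` when the records are absent.
    """
    records = load_accessions(directory)
    checks: dict[str, dict] = {}

    def add(name: str, computed, expected, ok: bool) -> None:
        checks[name] = {"computed": computed, "expected": expected, "ok": bool(ok)}

    for acc, rec in records.items():
        summ = architecture_summary(rec)
        exp = EXPECTED[acc]
        add(f"{acc}:genome_length", len(rec), exp["total"], len(rec) == exp["total"])
        add(f"{acc}:ir_length", summ["ir_length"], exp["ir"], summ["ir_length"] == exp["ir"])
        add(f"{acc}:lsc_length", summ["regions"]["LSC"]["length"], exp["lsc"],
            summ["regions"]["LSC"]["length"] == exp["lsc"])
        add(f"{acc}:ssc_length", summ["regions"]["SSC"]["length"], exp["ssc"],
            summ["regions"]["SSC"]["length"] == exp["ssc"])
        add(f"{acc}:gc", round(summ["gc_total"], 3), exp["gc"],
            abs(summ["gc_total"] - exp["gc"]) < 5e-4)

        pseudo_ycf1 = [f for f in rec.features if f.name == "ycf1" and f.kind == "pseudogene"]
        ndhf = [f for f in rec.features if f.name == "ndhF" and f.kind == "CDS"]
        if pseudo_ycf1 and ndhf:
            ov = max(gene_overlap(p, n, len(rec)) for p in pseudo_ycf1 for n in ndhf)
            add(f"{acc}:ycf1_ndhF_overlap", ov, EXPECTED_OVERLAP_BP, ov == EXPECTED_OVERLAP_BP)

        cds = extract_cds(rec, min_len=300, dedupe=True)
        add(f"{acc}:cds_count", len(cds), EXPECTED_CDS_COUNT, len(cds) == EXPECTED_CDS_COUNT)

        counts = [count_codons(c) for c in cds]
        encs = []
        for cc in counts:
            try:
                encs.append(enc(cc))
            except UndefinedENCError:
                pass
        groups = select_groups(encs, fraction=0.05)
        by_gene = {cc.gene: cc for cc in counts}
        opt = optimal_codons([by_gene[g] for g in groups.high],
                             [by_gene[g] for g in groups.low], delta_min=0.08)
        add(f"{acc}:optimal_codons", sorted(opt.codons), sorted(EXPECTED_OPTIMAL[acc]),
            opt.codons == frozenset(EXPECTED_OPTIMAL[acc]))
        if acc == "OP104328":
            rps18 = next((e for e in encs if e.gene == "rps18"), None)
            if rps18 is not None:
                add("OP104328:enc_rps18", round(rps18.nc, 2), 36.65,
                    abs(rps18.nc - 36.65) <= enc_tol)

    profiles = {
        acc: cam_profile(acc, extract_cds(records[acc], min_len=300, dedupe=True))
        for acc in ACCESSIONS
    }
    non_sinensis = [profiles[a] for a in ("OP104328", "OP104329", "OP104330")]
    shared = set.intersection(*(set(p.labeled_pairs()) for p in non_sinensis))
    add("shared_cam_non_sinensis", len(shared), EXPECTED_SHARED_CAM,
        len(shared) == EXPECTED_SHARED_CAM)
    return checks
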