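"""Reading, writing and slicing annotated plastome records.

Coordinates are 0-based half-open internally; GenBank I/O converts to/from
the 1-based inclusive convention. On a circular genome an exon whose start is
greater than or equal to its end wraps the origin, and splicing resolves it as
``[start, L) + [0, end)``.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "pseudogene", "other")


class GenBankParseError(ValueError):
    """Raised when a flat file lacks a sequence block or is malformed."""


class FeatureValidationError(ValueError):
    """Raised when a feature's coordinates fall outside the genome."""


def revcomp(residues: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """An uppercase DNA sequence, circular by default (plastomes are)."""

    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty genome sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}; expected A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Substring [start, end); wraps the origin when start >= end."""
        if start < end:
            return self.residues[start:end]
        if not self.circular:
            raise ValueError("wrapped interval on a linear genome")
        return self.residues[start:] + self.residues[:end]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene with its exon structure.

    ``exons`` are 0-based half-open intervals in genomic (ascending) order;
    a wrapped exon (start >= end) is only legal on a circular genome.
    ``copy_tag`` distinguishes inverted-repeat duplicates of the same symbol.
    """

    name: str
    kind: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    copy_tag: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"feature {self.name}: no exons")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))

    def exon_lengths(self, genome_length: int) -> list[int]:
        out = []
        for s, e in self.exons:
            out.append(e - s if s < e else genome_length - s + e)
        return out

    def extent(self, genome_length: int) -> tuple[int, int]:
        """Genomic interval from the first exon start to the last exon end.

        Wrap-aware: the extent of a feature whose exons cross the origin is
        itself a wrapped interval.
        """
        start = self.exons[0][0]
        end = self.exons[-1][1]
        return start, end

    def extent_length(self, genome_length: int) -> int:
        s, e = self.extent(genome_length)
        return e - s if s < e else genome_length - s + e

    @property
    def label(self) -> str:
        return f"{self.name}#{self.copy_tag}" if self.copy_tag else self.name


@dataclass(frozen=True)
class PlastomeRecord:
    """A circular annotated plastid genome."""

    accession: str
    taxon: str
    sequence: GenomeSequence
    features: tuple[GeneFeature, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        object.__setattr__(self, "features", tuple(self.features))
        L = len(self.sequence)
        for f in self.features:
            for s, e in f.exons:
                if not (0 <= s < L) or not (0 < e <= L):
                    raise FeatureValidationError(
                        f"feature {f.label}: interval ({s}, {e}) outside genome of {L} bp"
                    )
                if s >= e and not self.sequence.circular:
                    raise FeatureValidationError(
                        f"feature {f.label}: wrapped exon on a linear genome"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]

    def feature_census(self) -> dict[str, int]:
        census = collections.Counter(f.kind for f in self.features)
        census["total"] = len(self.features)
        return dict(census)


@dataclass(frozen=True)
class CodingSeq:
    """A spliced, strand-corrected coding sequence for one gene."""

    gene: str
    nucleotides: str
    source_accession: str

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError(f"empty coding sequence for {self.gene}")

    def __len__(self) -> int:
        return len(self.nucleotides)


def splice(record: PlastomeRecord, feature: GeneFeature) -> str:
    """Exon-concatenated, strand-corrected nucleotide sequence of a feature."""
    parts = [record.sequence.fetch(s, e) for s, e in feature.exons]
    joined = "".join(parts)
    return revcomp(joined) if feature.strand == "-" else joined


# ---------------------------------------------------------------------------
# GenBank I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def _feature_name(feat: SeqFeature, default: str) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return default


def _is_pseudo(feat: SeqFeature) -> bool:
    return "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    Captures CDS/tRNA/rRNA features (and pseudo-flagged genes without a
    same-extent functional feature) with strand and exon structure. Biopython
    already yields 0-based half-open coordinates.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:  # includes empty/absent ORIGIN block
        raise GenBankParseError(f"{path}: {exc}") from exc
    residues = str(rec.seq).upper()
    if not residues or set(residues) == {"N"} and len(residues) < 2:
        raise GenBankParseError(f"{path}: record has no sequence")
    residues = "".join(c if c in _ALPHABET else "N" for c in residues)
    topology = rec.annotations.get("topology", "circular")
    seq = GenomeSequence(residues, circular=(topology != "linear"))
    taxon = rec.annotations.get("organism", rec.description or rec.id)

    L = len(residues)
    features: list[GeneFeature] = []
    functional_extents: set[tuple[int, int]] = set()
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        kind = "pseudogene" if _is_pseudo(feat) else feat.type
        gf = _from_biopython(feat, kind, L)
        features.append(gf)
        functional_extents.add((gf.exons[0][0], gf.exons[-1][1]))
    for feat in rec.features:
        if feat.type != "gene" or not _is_pseudo(feat):
            continue
        gf = _from_biopython(feat, "pseudogene", L)
        if (gf.exons[0][0], gf.exons[-1][1]) in functional_extents:
            continue
        features.append(gf)
    features.sort(key=lambda f: (f.exons[0][0], f.name))
    features = _assign_copy_tags(features)
    return PlastomeRecord(rec.id or rec.name, taxon, seq, tuple(features))


def _from_biopython(feat: SeqFeature, kind: str, genome_length: int) -> GeneFeature:
    name = _feature_name(feat, default=f"{feat.type}_{int(feat.location.start)}")
    strand = "-" if feat.location.strand == -1 else "+"
    parts = sorted(((int(p.start), int(p.end)) for p in feat.location.parts))
    # collapse an origin-spanning join [x, L) + [0, y) to one wrapped exon
    if (
        len(parts) == 2
        and parts[0][0] == 0
        and parts[1][1] == genome_length
        and parts[1][0] > parts[0][1]
    ):
        parts = [(parts[1][0], parts[0][1])]
    for s, e in parts:
        if e > genome_length or s >= genome_length:
            raise FeatureValidationError(
                f"feature {name}: interval ({s}, {e}) beyond sequence length {genome_length}"
            )
    return GeneFeature(name=name, kind=kind, strand=strand, exons=tuple(parts))


def _assign_copy_tags(features: Sequence[GeneFeature]) -> list[GeneFeature]:
    counts = collections.Counter((f.name, f.kind) for f in features)
    seen: collections.Counter = collections.Counter()
    out = []
    for f in features:
        key = (f.name, f.kind)
        if counts[key] > 1:
            seen[key] += 1
            f = replace(f, copy_tag=str(seen[key]))
        out.append(f)
    return out


_KIND_TO_GB = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "gene", "other": "misc_feature"}


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Write a record as a GenBank flat file (round-trips through read_genbank)."""
    L = len(record)
    rec = SeqRecord(
        Seq(record.sequence.residues),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=f"{record.taxon} plastid, complete genome",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.sequence.circular else "linear"
    rec.annotations["organism"] = record.taxon
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = []
        for s, e in f.exons:
            if s < e:
                locs.append(SimpleLocation(s, e, strand))
            else:  # wrapped exon
                locs.append(SimpleLocation(s, L, strand))
                locs.append(SimpleLocation(0, e, strand))
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [f.name]}
        if f.kind == "pseudogene":
            qualifiers["pseudo"] = [""]
        rec.features.append(SeqFeature(location, type=_KIND_TO_GB[f.kind], qualifiers=qualifiers))
    SeqIO.write(rec, str(path), "genbank")


# ---------------------------------------------------------------------------
# CDS extraction and composition
# ---------------------------------------------------------------------------

def extract_cds(
    record: PlastomeRecord, min_len: int = 300, dedupe: bool = True
) -> list[CodingSeq]:
    """Spliced coding sequences of a record, pseudogenes excluded.

    With ``dedupe`` the inverted-repeat duplicates and trans-spliced fragments
    of one gene symbol collapse to a single entry (the longest spliced
    sequence). The result is filtered to ``len >= min_len`` and sorted by
    gene symbol.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    spliced: list[CodingSeq] = []
    for f in record.features:
        if f.kind != "CDS":
            continue
        spliced.append(CodingSeq(f.name, splice(record, f), record.accession))
    if dedupe:
        best: dict[str, CodingSeq] = {}
        for cds in spliced:
            cur = best.get(cds.gene)
            if cur is None or len(cds) > len(cur):
                best[cds.gene] = cds
        spliced = list(best.values())
    spliced = [c for c in spliced if len(c) >= min_len]
    spliced.sort(key=lambda c: c.gene)
    return spliced


def gc_content(residues: str) -> float:
    """(G + C) / (A + C + G + T); N sites excluded from the denominator."""
    if not residues:
        raise ValueError("empty sequence")
    residues = residues.upper()
    gc = residues.count("G") + residues.count("C")
    at = residues.count("A") + residues.count("T")
    if gc + at == 0:
        raise ValueError("undefined GC content: no unambiguous bases")
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# FASTA I/O (70-column wrap)
# ---------------------------------------------------------------------------

def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_cds_fasta(cds_list: Iterable[CodingSeq], path: str | Path) -> None:
    """Multi-FASTA of extracted coding sequences, headers ``gene|accession``."""
    write_fasta(((f"{c.gene}|{c.source_accession}", c.nucleotides) for c in cds_list), path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
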