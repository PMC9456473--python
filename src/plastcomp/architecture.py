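"""Quadripartite plastome architecture.

Detects the two inverted-repeat (IR) copies, partitions the circle into
LSC / IRb / SSC / IRa, and characterizes gene placement at the four junctions
JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa) and JLA (IRa|LSC).

Conventions: IRb is the IR copy encountered first after the LSC in genome
order; a junction's position is the 0-based coordinate of the first base of
the downstream region. Only exact (mismatch-free) repeats are considered:
plastid IRs are exact in practice, and exactness keeps the result canonical.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .plastome_io import (
    GeneFeature,
    GenomeSequence,
    PlastomeRecord,
    gc_content,
    revcomp,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

JUNCTION_NAMES = ("JLB", "JSB", "JSA", "JLA")


class NoIRFoundError(ValueError):
    """No inverted repeat of the requested minimum length exists."""


class DegenerateArchitectureError(ValueError):
    """The quadripartite layout is ambiguous or degenerate (e.g. LSC == SSC)."""


# -- circular interval helpers (0-based half-open; start >= end wraps) -------

def interval_length(iv: tuple[int, int], L: int) -> int:
    s, e = iv
    return e - s if s < e else L - s + e


def _linear_pieces(iv: tuple[int, int], L: int) -> list[tuple[int, int]]:
    s, e = iv
    if s < e:
        return [(s, e)]
    return [(s, L), (0, e)]


def interval_contains(iv: tuple[int, int], pos: int, L: int) -> bool:
    return any(a <= pos < b for a, b in _linear_pieces(iv, L))


def circular_intersection(a: tuple[int, int], b: tuple[int, int], L: int) -> int:
    """Total overlap (bp) of two circular intervals."""
    total = 0
    for a0, a1 in _linear_pieces(a, L):
        for b0, b1 in _linear_pieces(b, L):
            total += max(0, min(a1, b1) - max(a0, b0))
    return total


@dataclass(frozen=True)
class IRPair:
    """The two inverted-repeat copies, as circular intervals of equal length."""

    irb: tuple[int, int]
    ira: tuple[int, int]
    length: int
    exact: bool = True


@dataclass(frozen=True)
class QuadripartiteMap:
    """LSC/IRb/SSC/IRa partition of a circular genome plus its junctions."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    junctions: dict[str, int]
    genome_length: int

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def region_lengths(self) -> dict[str, int]:
        return {k: interval_length(v, self.genome_length) for k, v in self.regions.items()}

    def region_of(self, pos: int) -> str:
        for name, iv in self.regions.items():
            if interval_contains(iv, pos, self.genome_length):
                return name
        raise ValueError(f"position {pos} outside genome of {self.genome_length} bp")


@dataclass(frozen=True)
class GenePlacement:
    """Where one gene sits relative to the quadripartite layout."""

    gene: str
    status: str  # "contained" | "spanning"
    region: str | None = None
    junctions: tuple[tuple[str, int, int], ...] = ()
    # each spanning entry: (junction name, bp upstream of junction, bp downstream)


# ---------------------------------------------------------------------------
# IR detection: k-mer seeded maximal extension, exact matches only
# ---------------------------------------------------------------------------

def detect_inverted_repeats(seq: GenomeSequence, min_len: int = 1000) -> IRPair:
    """Find the maximal pair of disjoint, exactly reverse-complementary
    intervals on the circle.

    Seeds with k-mers shared between the sequence and its reverse complement,
    then extends each seed's anti-diagonal maximally. Rotation-invariant: the
    reported per-copy length is the same for any rotation of the circle.

    Raises :class:`NoIRFoundError` if no repeat of at least ``min_len``
    exists.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    s = seq.residues
    L = len(s)
    circular = seq.circular
    k = min(20, min_len)
    if L < 2 * k:
        raise NoIRFoundError(f"genome of {L} bp too short for min_len={min_len}")

    text = s + s[: k - 1] if circular else s
    index: dict[str, list[int]] = collections.defaultdict(list)
    for i in range(len(text) - k + 1):
        index[text[i : i + k]].append(i)

    comp = _COMP
    seen: set[int] = set()
    best: tuple[int, int, int] | None = None  # (arm_length, start1, start2)
    modulus = L if circular else None

    for j in range(len(text) - k + 1):
        rc = revcomp(text[j : j + k])
        hits = index.get(rc)
        if not hits or len(hits) > 64:  # low-complexity seed; skip
            continue
        for i in hits:
            c = (i + j + k - 1) % L if circular else i + j + k - 1
            if c in seen:
                continue
            seen.add(c)
            pair = _extend_antidiagonal(s, L, i % L if circular else i, c, circular)
            if pair is None:
                continue
            m, a, b = pair
            if best is None or m > best[0] or (m == best[0] and (a, b) < (best[1], best[2])):
                best = (m, a, b)

    if best is None or best[0] < min_len:
        raise NoIRFoundError(f"no inverted repeat of >= {min_len} bp")
    m, a, b = best
    copy1 = (a, (a + m) % L if circular else a + m)
    copy2 = (b, (b + m) % L if circular else b + m)
    return _orient_pair(copy1, copy2, m, L)


def _match(s: str, L: int, p: int, c: int, circular: bool) -> bool:
    q = c - p
    if circular:
        p %= L
        q %= L
    elif not (0 <= p < L and 0 <= q < L):
        return False
    return s[p] == _COMP[s[q]] and s[p] != "N"


def _extend_antidiagonal(
    s: str, L: int, p0: int, c: int, circular: bool
) -> tuple[int, int, int] | None:
    """Maximal run of complementary pairs through seed position p0 on the
    anti-diagonal p + q = c. Returns (arm_length, start_copy1, start_copy2)."""
    if not _match(s, L, p0, c, circular):
        return None
    lo = p0
    steps = 0
    while steps < L and _match(s, L, lo - 1, c, circular):
        lo -= 1
        steps += 1
    hi = p0
    while (hi - lo + 1) < L and _match(s, L, hi + 1, c, circular):
        hi += 1
    run = hi - lo + 1
    # mirror of position p is c - p; the run is self-symmetric iff it contains
    # its own mirror, in which case the two arms meet and must be split.
    mlo = c - hi
    if circular:
        contains_mirror = ((mlo - lo) % L) < run
    else:
        contains_mirror = lo <= mlo <= hi
    if contains_mirror:
        m = run // 2
        if m == 0:
            return None
        a, b = lo, c - lo - m + 1
    else:
        m = run
        a, b = lo, mlo
    if circular:
        a %= L
        b %= L
    elif not (0 <= a and a + m <= L and 0 <= b and b + m <= L):
        return None
    if a > b:
        a, b = b, a
    # disjointness on the circle
    if circular:
        if circular_intersection((a, (a + m) % L), (b, (b + m) % L), L) > 0:
            return None
    elif b < a + m:
        return None
    return m, a, b


def _orient_pair(copy1: tuple[int, int], copy2: tuple[int, int], m: int, L: int) -> IRPair:
    """Name the copies: IRb is the one that follows the longer single-copy gap
    (the LSC). On a tie the lower-coordinate copy is called IRb; the partition
    step raises on genuinely ambiguous layouts."""
    gap12 = (copy2[0] - copy1[1]) % L  # copy1 end -> copy2 start
    gap21 = (copy1[0] - copy2[1]) % L
    if gap21 > gap12:
        irb, ira = copy1, copy2
    else:
        irb, ira = copy2, copy1
        if gap12 == gap21:
            irb, ira = sorted((copy1, copy2))
    return IRPair(irb=irb, ira=ira, length=m)


def partition_regions(record: PlastomeRecord | GenomeSequence, ir: IRPair) -> QuadripartiteMap:
    """Assign the two single-copy gaps between the IR copies to LSC (longer)
    and SSC (shorter) and name the four junctions."""
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    L = len(seq)
    gap_b_to_a = (ir.ira[0] - ir.irb[1]) % L  # after IRb
    gap_a_to_b = (ir.irb[0] - ir.ira[1]) % L  # after IRa
    if gap_b_to_a == 0 or gap_a_to_b == 0:
        raise DegenerateArchitectureError("IR copies are adjacent: zero-length single-copy region")
    if gap_a_to_b == gap_b_to_a:
        raise DegenerateArchitectureError("LSC and SSC would be equal length; architecture ambiguous")
    # convention: genome order LSC -> IRb -> SSC -> IRa
    if gap_a_to_b > gap_b_to_a:
        lsc = (ir.ira[1], ir.irb[0])
        ssc = (ir.irb[1], ir.ira[0])
        irb, ira = ir.irb, ir.ira
    else:
        # the longer gap follows the copy named irb: swap the names
        lsc = (ir.irb[1], ir.ira[0])
        ssc = (ir.ira[1], ir.irb[0])
        irb, ira = ir.ira, ir.irb
    junctions = {
        "JLB": irb[0],
        "JSB": ssc[0],
        "JSA": ira[0],
        "JLA": lsc[0],
    }
    qmap = QuadripartiteMap(lsc=lsc, irb=irb, ssc=ssc, ira=ira, junctions=junctions, genome_length=L)
    total = sum(qmap.region_lengths().values())
    if total != L:
        raise DegenerateArchitectureError(f"region lengths sum to {total}, genome is {L} bp")
    return qmap


def classify_gene_at_junctions(qmap: QuadripartiteMap, feature: GeneFeature) -> GenePlacement:
    """Contained in one region, or spanning one or more junctions with the
    base-pair split on each side."""
    L = qmap.genome_length
    start, end = feature.extent(L)
    extent_len = feature.extent_length(L)
    crossed: list[tuple[str, int, int]] = []
    for name in JUNCTION_NAMES:
        j = qmap.junctions[name]
        offset = (j - start) % L
        if 0 < offset < extent_len:
            crossed.append((name, offset, extent_len - offset))
    if crossed:
        crossed.sort(key=lambda t: t[1])
        return GenePlacement(feature.label, "spanning", junctions=tuple(crossed))
    return GenePlacement(feature.label, "contained", region=qmap.region_of(start))


def gene_overlap(a: GeneFeature, b: GeneFeature, genome_length: int) -> int:
    """Overlap (bp) of two features' genomic extents, circular-aware and
    strand-ignorant."""
    return circular_intersection(a.extent(genome_length), b.extent(genome_length), genome_length)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def architecture_summary(record: PlastomeRecord, min_ir_len: int = 1000) -> dict:
    """Region intervals, lengths and per-region GC content (plus gene census)."""
    ir = detect_inverted_repeats(record.sequence, min_len=min_ir_len)
    qmap = partition_regions(record, ir)
    regions = {}
    for name, iv in qmap.regions.items():
        sub = record.sequence.fetch(*iv)
        regions[name] = {
            "interval": list(iv),
            "length": interval_length(iv, qmap.genome_length),
            "gc": round(gc_content(sub), 4),
        }
    return {
        "accession": record.accession,
        "taxon": record.taxon,
        "genome_length": len(record),
        "gc_total": round(gc_content(record.sequence.residues), 4),
        "ir_length": ir.length,
        "regions": regions,
        "junctions": qmap.junctions,
        "gene_census": record.feature_census(),
    }


def junction_report(
    records: Iterable[PlastomeRecord], min_ir_len: int = 1000
) -> pd.DataFrame:
    """Per record and junction: spanning genes with their splits and the
    nearest flanking genes with their distances to the junction.

    A record with no detectable IR contributes one flagged row instead of
    failing the whole report.
    """
    rows = []
    for rec in records:
        L = len(rec)
        try:
            ir = detect_inverted_repeats(rec.sequence, min_len=min_ir_len)
            qmap = partition_regions(rec, ir)
        except (NoIRFoundError, DegenerateArchitectureError) as exc:
            rows.append(
                {"accession": rec.accession, "junction": "NA", "position": -1,
                 "gene": "NA", "status": f"no_quadripartite ({exc})"}
            )
            continue
        placements = [(f, classify_gene_at_junctions(qmap, f)) for f in rec.features]
        for jname in JUNCTION_NAMES:
            jpos = qmap.junctions[jname]
            any_row = False
            for f, pl in placements:
                for name, left, right in pl.junctions:
                    if name == jname:
                        rows.append(
                            {"accession": rec.accession, "junction": jname,
                             "position": jpos, "gene": f.label, "kind": f.kind,
                             "status": "spanning", "bp_upstream": left,
                             "bp_downstream": right, "distance": 0}
                        )
                        any_row = True
            for side, dist, f in _nearest_flanks(placements, jpos, L):
                rows.append(
                    {"accession": rec.accession, "junction": jname, "position": jpos,
                     "gene": f.label, "kind": f.kind, "status": f"flanking_{side}",
                     "bp_upstream": 0, "bp_downstream": 0, "distance": dist}
                )
                any_row = True
            if not any_row:
                rows.append(
                    {"accession": rec.accession, "junction": jname, "position": jpos,
                     "gene": "NA", "status": "no_gene"}
                )
    return pd.DataFrame(rows)


def _nearest_flanks(
    placements: Sequence[tuple[GeneFeature, GenePlacement]], jpos: int, L: int
) -> list[tuple[str, int, GeneFeature]]:
    """Nearest gene end upstream of a junction and nearest gene start
    downstream, skipping genes that span it (reported separately)."""
    best_up: tuple[int, GeneFeature] | None = None
    best_down: tuple[int, GeneFeature] | None = None
    for f, pl in placements:
        if any(name for name, _, _ in pl.junctions):
            continue
        s, e = f.extent(L)
        d_up = (jpos - e) % L
        d_down = (s - jpos) % L
        if best_up is None or d_up < best_up[0]:
            best_up = (d_up, f)
        if best_down is None or d_down < best_down[0]:
            best_down = (d_down, f)
    out = []
    if best_up:
        out.append(("upstream", best_up[0], best_up[1]))
    if best_down:
        out.append(("downstream", best_down[0], best_down[1]))
    return out
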