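"""Codon-usage and codon-aversion statistics.

Implements per-gene codon counting under the plastid/bacterial genetic code
(translation table 11), relative synonymous codon usage (RSCU), Wright's
effective number of codons (ENC, Nc), the ΔRSCU optimal-codon procedure
(putative expression groups taken from the ENC extremes), codon aversion
motifs (CAM: the set of sense codons a gene never uses), Jaccard distances
between CAM profiles, and a neighbor-joining tree over those distances.

ENC background: within each synonymous family the codon homozygosity is
estimated as F̂ = (n·Σp_i² − 1)/(n − 1) with n the family's codon total and
p_i the within-family codon proportions. Families are grouped by degeneracy
(nine 2-fold, one 3-fold, five 4-fold, three 6-fold under table 11; Met and
Trp and the stops are excluded) and

    Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6

with F̄k the mean F̂ of the k-fold class. Nc runs from 20 (one codon per
family: maximal bias) to 61 (uniform synonymous usage).
"""

from __future__ import annotations

import collections
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable
from skbio import DistanceMatrix

from .plastome_io import CodingSeq

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA) + sorted(STOP_CODONS))

#: synonymous families: amino acid -> sorted codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa)) for aa in FAMILIES
}

#: degeneracy classes used by Wright's estimator (single-codon families excluded)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(sorted(aa for aa, cods in FAMILIES.items() if len(cods) == k))
    for k in (2, 3, 4, 6)
}
_CLASS_WEIGHT = {2: 9, 3: 1, 4: 5, 6: 3}
assert all(len(DEGENERACY_CLASSES[k]) == w for k, w in _CLASS_WEIGHT.items())


class FrameError(ValueError):
    """CDS length not divisible by three."""


class UndefinedENCError(ValueError):
    """ENC cannot be estimated (no usable synonymous family)."""


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.replace("U", "T")


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonCounts:
    """Exact codon tally of one gene (stops counted but flagged)."""

    gene: str
    counts: Mapping[str, int]
    code: str = "11"
    ambiguous_dropped: int = 0

    def sense_counts(self) -> dict[str, int]:
        return {c: n for c, n in self.counts.items() if c in CODON_TO_AA}

    def stop_counts(self) -> dict[str, int]:
        return {c: n for c, n in self.counts.items() if c in STOP_CODONS}

    def family_total(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in FAMILIES[aa])


def count_codons(cds: CodingSeq | tuple[str, str]) -> CodonCounts:
    """Triplet tally of a coding sequence in frame 0.

    Codons containing an ambiguous base are dropped and reported in
    ``ambiguous_dropped``. Raises :class:`FrameError` when the length is not
    a multiple of three.
    """
    if isinstance(cds, tuple):
        cds = CodingSeq(cds[0], cds[1], "anonymous")
    seq = cds.nucleotides.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"gene {cds.gene}: length {len(seq)} not divisible by 3")
    counts: collections.Counter = collections.Counter()
    dropped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in CODON_TO_AA or codon in STOP_CODONS:
            counts[codon] += 1
        else:
            dropped += 1
    return CodonCounts(cds.gene, dict(counts), ambiguous_dropped=dropped)


def pool_counts(counts_list: Iterable[CodonCounts], gene: str = "pooled") -> CodonCounts:
    total: collections.Counter = collections.Counter()
    dropped = 0
    for cc in counts_list:
        total.update(cc.counts)
        dropped += cc.ambiguous_dropped
    return CodonCounts(gene, dict(total), ambiguous_dropped=dropped)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RSCUTable:
    """RSCU per codon; codons of unused families are absent (undefined)."""

    values: Mapping[str, float]
    family_sizes: Mapping[str, int]

    def get(self, codon: str) -> float | None:
        return self.values.get(to_dna(codon))


def rscu(counts: CodonCounts | Iterable[CodonCounts]) -> RSCUTable:
    """RSCU(c) = count(c) / mean count within c's synonymous family.

    Stop codons are excluded; single-codon families (Met, Trp) come out as
    exactly 1 when used, as the formula implies.
    """
    if not isinstance(counts, CodonCounts):
        counts = pool_counts(counts)
    sense = counts.sense_counts()
    if sum(sense.values()) == 0:
        raise ValueError("no sense codons counted")
    values: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for aa, codons in FAMILIES.items():
        total = sum(sense.get(c, 0) for c in codons)
        if total == 0:
            continue
        mean = total / len(codons)
        sizes[aa] = len(codons)
        for c in codons:
            values[c] = sense.get(c, 0) / mean
    return RSCUTable(values, sizes)


# ---------------------------------------------------------------------------
# ENC (Wright's Nc)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ENCValue:
    gene: str
    nc: float
    family_homozygosity: Mapping[str, float]
    class_means: Mapping[int, float]


def enc(counts: CodonCounts) -> ENCValue:
    """Wright's effective number of codons for one gene.

    Families with fewer than two counted codons are skipped. A missing
    3-fold class mean is repaired as the average of the 2- and 4-fold means;
    any other missing or non-positive class mean leaves ENC undefined.
    The result is capped to [20, 61].
    """
    sense = counts.sense_counts()
    fhat: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if len(codons) == 1:
            continue
        n = sum(sense.get(c, 0) for c in codons)
        if n < 2:
            continue
        p2 = sum((sense.get(c, 0) / n) ** 2 for c in codons)
        fhat[aa] = (n * p2 - 1.0) / (n - 1.0)
    class_means: dict[int, float] = {}
    for k, fams in DEGENERACY_CLASSES.items():
        vals = [fhat[aa] for aa in fams if aa in fhat]
        if vals:
            class_means[k] = float(np.mean(vals))
    if (3 not in class_means or class_means[3] <= 0) and 2 in class_means and 4 in class_means:
        class_means[3] = 0.5 * (class_means[2] + class_means[4])
    missing = [k for k in _CLASS_WEIGHT if k not in class_means or class_means[k] <= 0]
    if missing:
        raise UndefinedENCError(
            f"gene {counts.gene}: degeneracy class(es) {missing} unusable for ENC"
        )
    nc = 2.0 + sum(w / class_means[k] for k, w in _CLASS_WEIGHT.items())
    nc = min(61.0, max(20.0, nc))
    return ENCValue(counts.gene, nc, fhat, class_means)


# ---------------------------------------------------------------------------
# Expression groups and optimal codons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionGroups:
    """ENC-extreme gene groups used as an expression proxy.

    ``high`` holds the lowest-ENC fraction (strong bias, putatively highly
    expressed); ``low`` the highest-ENC fraction.
    """

    high: tuple[str, ...]
    low: tuple[str, ...]
    fraction: float


def select_groups(encs: Sequence[ENCValue], fraction: float = 0.05) -> ExpressionGroups:
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    if len(encs) < 2:
        raise ValueError("need at least two genes")
    size = math.ceil(fraction * len(encs))
    ranked = sorted(encs, key=lambda e: (e.nc, e.gene))
    high = tuple(e.gene for e in ranked[:size])
    low = tuple(e.gene for e in ranked[-size:])
    if set(high) & set(low):
        raise ValueError("expression groups overlap: too few genes for this fraction")
    return ExpressionGroups(high=high, low=low, fraction=fraction)


@dataclass(frozen=True)
class OptimalCodonSet:
    """Codons preferred in the high-expression group (RNA alphabet)."""

    codons: frozenset[str]
    delta_rscu: Mapping[str, float]
    rscu_high: Mapping[str, float]
    rscu_low: Mapping[str, float]


def optimal_codons(
    high: CodonCounts | Iterable[CodonCounts],
    low: CodonCounts | Iterable[CodonCounts],
    delta_min: float = 0.08,
) -> OptimalCodonSet:
    """ΔRSCU optimal codons from pooled counts of the two groups.

    A codon is optimal iff RSCU_high − RSCU_low > ``delta_min`` and
    RSCU_high > 1 and RSCU_low < 1.
    """
    t_high = rscu(high)
    t_low = rscu(low)
    deltas: dict[str, float] = {}
    winners: set[str] = set()
    for codon in SENSE_CODONS:
        h = t_high.values.get(codon)
        lo = t_low.values.get(codon)
        if h is None or lo is None:
            continue
        rna = to_rna(codon)
        deltas[rna] = h - lo
        if h - lo > delta_min and h > 1.0 and lo < 1.0:
            winners.add(rna)
    return OptimalCodonSet(
        codons=frozenset(winners),
        delta_rscu=deltas,
        rscu_high={to_rna(c): v for c, v in t_high.values.items()},
        rscu_low={to_rna(c): v for c, v in t_low.values.items()},
    )


# ---------------------------------------------------------------------------
# Codon aversion motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CAMotif:
    """The sorted tuple of sense codons absent from one gene."""

    gene: str
    unused: tuple[str, ...]


@dataclass(frozen=True)
class CAMProfile:
    """One species' collection of per-gene codon aversion motifs."""

    species: str
    motifs: Mapping[str, CAMotif]  # gene -> motif

    def labeled_pairs(self) -> frozenset[tuple[str, tuple[str, ...]]]:
        return frozenset((g, m.unused) for g, m in self.motifs.items())

    def unlabeled_motifs(self) -> frozenset[tuple[str, ...]]:
        return frozenset(m.unused for m in self.motifs.values())


def cam_motif(counts: CodonCounts) -> CAMotif:
    sense = counts.sense_counts()
    unused = tuple(sorted(c for c in SENSE_CODONS if sense.get(c, 0) == 0))
    return CAMotif(counts.gene, unused)


def cam_profile(species: str, cds_list: Iterable[CodingSeq]) -> CAMProfile:
    motifs = {}
    for cds in cds_list:
        m = cam_motif(count_codons(cds))
        motifs[m.gene] = m
    if not motifs:
        raise ValueError(f"no genes for species {species}")
    return CAMProfile(species, motifs)


def cam_distance(a: CAMProfile, b: CAMProfile, mode: str = "gene_labeled") -> float:
    """Jaccard distance between two CAM profiles, in [0, 1].

    ``gene_labeled`` compares (gene, motif) pairs; ``unlabeled`` compares the
    bare motif sets.
    """
    if mode == "gene_labeled":
        sa, sb = a.labeled_pairs(), b.labeled_pairs()
    elif mode == "unlabeled":
        sa, sb = a.unlabeled_motifs(), b.unlabeled_motifs()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not sa and not sb:
        return 0.0
    inter = len(sa & sb)
    union = len(sa | sb)
    return 1.0 - inter / union


def cam_distance_matrix(
    profiles: Sequence[CAMProfile], mode: str = "gene_labeled"
) -> DistanceMatrix:
    """Symmetric pairwise CAM distance matrix (taxa sorted lexicographically)."""
    profiles = sorted(profiles, key=lambda p: p.species)
    taxa = [p.species for p in profiles]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = cam_distance(profiles[i], profiles[j], mode=mode)
    return DistanceMatrix(d, ids=taxa)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Classical neighbor joining (Saitou–Nei, Studier–Keppler Q criterion).

    Deterministic: ties in Q are broken by the lexicographically smallest
    pair of clade labels (a clade is labeled by its smallest leaf name).
    A negative branch length is clamped to zero and the deficit moved to the
    sister edge. Returns an unrooted tree with branch lengths.
    """
    newick = nj_newick(dm)
    return dendropy.Tree.get(data=newick, schema="newick")


def nj_newick(dm: DistanceMatrix) -> str:
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    order = np.argsort(ids)
    ids = [ids[i] for i in order]
    D = D[np.ix_(order, order)]
    nwk = {i: ids[i] for i in range(len(ids))}
    label = {i: ids[i] for i in range(len(ids))}  # smallest leaf in clade
    active = list(range(len(ids)))
    next_id = len(ids)
    dist = {(i, j): D[i, j] for i in active for j in active if i < j}

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (n - 2) * d(i, j) - r[i] - r[j]
            key = (q, *sorted((label[i], label[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        nwk[u] = f"({nwk[i]}:{li:.12g},{nwk[j]}:{lj:.12g})"
        label[u] = min(label[i], label[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - dij)
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda k: label[k])
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    return f"({nwk[a]}:{la:.12g},{nwk[b]}:{lb:.12g},{nwk[c]}:{lc:.12g});"
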