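"""Synthetic plastomes and plastome families with known ground truth.

The generator emulates the salient features of a real chloroplast genome at
full plastome scale: a circular quadripartite layout (LSC + IRb + SSC + IRa
with IRa the exact reverse complement of IRb), annotated CDS/tRNA/rRNA
features including genes spanning the region junctions (an rpl22-like gene
across JLB, an ndhF-like gene across JSB on the minus strand, a large
ycf1-like gene across JSA whose inverted-repeat portion mirrors into IRb as
a pseudogene fragment overlapping the ndhF-like gene), tunable per-gene
synonymous codon preferences, and families of descendant genomes evolved
from the ancestor along a known tree under a Jukes–Cantor site model with
designated hotspot intervals of elevated substitution rate.

Evolution is substitution-only (no indels), so the true alignment of a
family is the leaf sequence matrix itself. Indel realism is deliberately
sacrificed for exact, free alignment truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .codonlab import FAMILIES, STOP_CODONS
from .diversity import AlignmentMatrix
from .plastome_io import (
    GeneFeature,
    GenomeSequence,
    PlastomeRecord,
    revcomp,
)


class SynthConfigError(ValueError):
    """Configuration does not fit (e.g. genes exceed region capacity)."""


@dataclass(frozen=True)
class Hotspot:
    """A genome interval whose per-site substitution rate is multiplied."""

    start: int
    end: int
    multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("hotspot rate multiplier must be >= 1")
        if self.end <= self.start:
            raise ValueError("empty hotspot interval")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic plastome (family).

    Defaults mirror a real plastome: ~157 kb circular genome with a 26.5 kb
    inverted repeat, 53 protein-coding genes of at least 300 bp (three of
    them junction-spanning), moderate synonymous codon bias, a four-leaf
    family tree with two cherries, and three 1.2 kb hotspot intervals at
    ten-fold substitution rate in the LSC.
    """

    lsc_len: int = 86000
    irb_len: int = 26500
    ssc_len: int = 18300
    n_lsc_genes: int = 38
    n_ssc_genes: int = 8
    n_ir_genes: int = 4
    n_trna: int = 4
    n_rrna: int = 2
    gene_codon_range: tuple[int, int] = (100, 400)
    bias_strength: float = 0.6
    codon_jitter: float = 0.4
    cds_rate_factor: float = 0.2
    gc: float = 0.37
    junction_genes: bool = True
    tree: str = "((A:0.001,B:0.001):0.003,(C:0.001,D:0.001):0.003);"
    hotspots: tuple[Hotspot, ...] = (
        Hotspot(10000, 11200, 10.0),
        Hotspot(40000, 41200, 10.0),
        Hotspot(70000, 71200, 10.0),
    )
    divergent_leaves: tuple[str, ...] = ()
    divergent_codon_fraction: float = 0.5
    enforce_ir: bool = True
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.irb_len + self.ssc_len


@dataclass(frozen=True)
class TruthSet:
    """Ground truth planted by the generator."""

    regions: Mapping[str, tuple[int, int]]
    junctions: Mapping[str, int]
    ir_length: int
    gene_truth: Mapping[str, tuple]  # name -> ("contained", region) | ("spanning", junction, (up, down))
    preferences: Mapping[str, Mapping[str, tuple[float, ...]]]
    hotspots: tuple[Hotspot, ...]
    tree: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": {k: list(v) for k, v in self.regions.items()},
            "junctions": dict(self.junctions),
            "ir_length": self.ir_length,
            "gene_truth": {k: list(v) for k, v in self.gene_truth.items()},
            "hotspots": [[h.start, h.end, h.multiplier] for h in self.hotspots],
            "tree": self.tree,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=list))


_BASES = np.frombuffer(b"ACGT", dtype="S1")
_SENSE_NONSTOP = {aa: cods for aa, cods in FAMILIES.items()}
_AA_LIST = tuple(sorted(_SENSE_NONSTOP))
_STOPS = tuple(sorted(STOP_CODONS))


def _background(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return [b.decode() for b in rng.choice(_BASES, size=n, p=p)]


def _shared_bias(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Genome-wide per-family preference directions (mutation-bias analog)."""
    return {aa: rng.standard_normal(len(_SENSE_NONSTOP[aa])) for aa in _AA_LIST}


def _draw_preferences(
    rng: np.random.Generator,
    shared: Mapping[str, np.ndarray],
    bias_strength: float,
    jitter: float = 0.0,
) -> dict[str, np.ndarray]:
    """Per-family synonymous codon weights for one gene.

    Softmax of ``s_g * bias_strength * (shared + jitter * N(0,1))`` where the
    per-gene scale ``s_g ~ U(0.2, 1.8)`` spreads genes over a realistic range
    of bias (hence of ENC). ``bias_strength`` 0 gives exactly exchangeable
    (uniform) codons.
    """
    s_g = rng.uniform(0.2, 1.8)
    prefs = {}
    for aa in _AA_LIST:
        k = len(_SENSE_NONSTOP[aa])
        z = s_g * bias_strength * (shared[aa] + jitter * rng.standard_normal(k))
        w = np.exp(z - z.max())
        prefs[aa] = w / w.sum()
    return prefs


def _make_gene(
    rng: np.random.Generator, n_codons: int, prefs: Mapping[str, np.ndarray]
) -> str:
    """A CDS: ATG start, biased sense codons, one stop. Length 3*n_codons."""
    if n_codons < 3:
        raise SynthConfigError("genes need at least 3 codons")
    codons = ["ATG"]
    aas = rng.choice(len(_AA_LIST), size=n_codons - 2)
    for ai in aas:
        aa = _AA_LIST[ai]
        fam = _SENSE_NONSTOP[aa]
        codons.append(fam[rng.choice(len(fam), p=prefs[aa])])
    codons.append(_STOPS[rng.choice(len(_STOPS))])
    return "".join(codons)


def _place(
    region_len: int, reserved_head: int, reserved_tail: int, lengths: Sequence[int]
) -> list[int]:
    """Evenly spaced start offsets for genes inside one region."""
    usable = region_len - reserved_head - reserved_tail
    total = sum(lengths)
    gap = (usable - total) // (len(lengths) + 1) if lengths else 0
    if lengths and gap < 10:
        raise SynthConfigError(
            f"genes ({total} bp) exceed region capacity ({usable} bp usable)"
        )
    starts = []
    pos = reserved_head + gap
    for glen in lengths:
        starts.append(pos)
        pos += glen + gap
    return starts


def generate_plastome(config: SynthConfig) -> tuple[PlastomeRecord, TruthSet]:
    """Build one annotated quadripartite plastome plus its truth set.

    Deterministic: the same seed and config give byte-identical records.
    """
    rng = np.random.default_rng([config.seed, 1])
    lsc_len, m, ssc_len = config.lsc_len, config.irb_len, config.ssc_len
    L = config.genome_length
    jlb, jsb, jsa = lsc_len, lsc_len + m, lsc_len + m + ssc_len

    lsc = _background(rng, lsc_len, config.gc)
    irb = _background(rng, m, config.gc)
    ssc = _background(rng, ssc_len, config.gc)

    features: list[GeneFeature] = []
    gene_truth: dict[str, tuple] = {}
    preferences: dict[str, dict[str, tuple[float, ...]]] = {}
    shared = _shared_bias(rng)

    def draw_prefs() -> dict[str, np.ndarray]:
        return _draw_preferences(rng, shared, config.bias_strength, config.codon_jitter)

    def new_gene(name: str) -> tuple[str, dict[str, np.ndarray]]:
        prefs = draw_prefs()
        n_codons = int(rng.integers(*config.gene_codon_range, endpoint=True))
        seq = _make_gene(rng, n_codons, prefs)
        preferences[name] = {aa: tuple(map(float, w)) for aa, w in prefs.items()}
        return seq, prefs

    # ---- junction-spanning genes (fixed splits, plastome-like) ----
    res_lsc_tail = res_irb_head = res_irb_tail = res_ssc_head = res_ssc_tail = 0
    if config.junction_genes:
        # rpl22-like across JLB: 240 bp in LSC, 120 bp in IRb
        prefs = draw_prefs()
        rpl22 = _make_gene(rng, 120, prefs)  # 360 bp
        preferences["rpl22"] = {aa: tuple(map(float, w)) for aa, w in prefs.items()}
        lsc[-240:] = list(rpl22[:240])
        irb[:120] = list(rpl22[240:])
        features.append(GeneFeature("rpl22", "CDS", "+", ((jlb - 240, jlb + 120),)))
        gene_truth["rpl22"] = ("spanning", "JLB", (240, 120))
        # its IRb portion mirrors to the IRa end: a pseudogene fragment at JLA
        features.append(GeneFeature("rpl22", "pseudogene", "-", ((L - 120, L),)))

        # ycf1-like across JSA: 4001 bp in SSC + 1000 bp in IRa (written as
        # the reverse-complement constraint on the IRb tail)
        prefs = draw_prefs()
        ycf1 = _make_gene(rng, 1667, prefs)  # 5001 bp
        preferences["ycf1"] = {aa: tuple(map(float, w)) for aa, w in prefs.items()}
        ssc[-4001:] = list(ycf1[:4001])
        irb[-1000:] = list(revcomp(ycf1[4001:5001]))
        features.append(GeneFeature("ycf1", "CDS", "+", ((jsa - 4001, jsa + 1000),)))
        gene_truth["ycf1"] = ("spanning", "JSA", (4001, 1000))
        # the mirrored fragment sits at the IRb end, adjacent to JSB
        features.append(GeneFeature("ycf1", "pseudogene", "-", ((jsb - 1000, jsb),)))

        # ndhF-like across JSB on the minus strand: 55 bp in IRb + 2165 in SSC,
        # overwriting the last 55 bp of the mirrored ycf1 fragment -> the
        # classic 55 bp pseudo-ycf1/ndhF overlap
        prefs = draw_prefs()
        ndhf = _make_gene(rng, 740, prefs)  # 2220 bp
        preferences["ndhF"] = {aa: tuple(map(float, w)) for aa, w in prefs.items()}
        rc = revcomp(ndhf)
        irb[-55:] = list(rc[:55])
        ssc[:2165] = list(rc[55:])
        features.append(GeneFeature("ndhF", "CDS", "-", ((jsb - 55, jsb + 2165),)))
        gene_truth["ndhF"] = ("spanning", "JSB", (55, 2165))
        res_lsc_tail, res_irb_head = 240 + 20, 120 + 20
        res_irb_tail, res_ssc_head, res_ssc_tail = 1000 + 20, 2165 + 20, 4001 + 20

    # ---- contained genes ----
    def plant(region: list[str], offset: int, region_name: str,
              names: list[str], reserved: tuple[int, int], kind: str = "CDS",
              fixed_len: int | None = None) -> list[GeneFeature]:
        made = []
        seqs = []
        for name in names:
            if kind == "CDS":
                seq, _ = new_gene(name)
            else:
                seq = "".join(_background(rng, fixed_len, 0.53))
            seqs.append(seq)
        starts = _place(len(region), reserved[0], reserved[1], [len(s) for s in seqs])
        for name, seq, s in zip(names, seqs, starts):
            strand = "+" if rng.random() < 0.5 else "-"
            region[s : s + len(seq)] = list(seq if strand == "+" else revcomp(seq))
            made.append(GeneFeature(name, kind, strand, ((offset + s, offset + s + len(seq)),)))
            gene_truth[name] = ("contained", region_name)
        return made

    lsc_names = [f"lscg{i:02d}" for i in range(1, config.n_lsc_genes + 1)]
    ssc_names = [f"sscg{i:02d}" for i in range(1, config.n_ssc_genes + 1)]
    ir_names = [f"irg{i:02d}" for i in range(1, config.n_ir_genes + 1)]
    # a dedicated tRNA zone at the LSC head keeps feature types from colliding
    trna_zone = min(max(int(0.04 * lsc_len), 1200), lsc_len // 3) if config.n_trna else 0
    if config.n_trna:
        trna_names = [f"trnX{i}" for i in range(1, config.n_trna + 1)]
        features += plant(lsc, 0, "LSC", trna_names, (50, lsc_len - trna_zone),
                          kind="tRNA", fixed_len=75)
    features += plant(lsc, 0, "LSC", lsc_names, (trna_zone + 50, res_lsc_tail + 200))
    features += plant(ssc, jsb, "SSC", ssc_names, (res_ssc_head + 200, res_ssc_tail + 200))
    # IRb: CDS genes in the first ~60%, rRNA operon-like genes in the last ~30%
    rrna_zone = int(0.30 * m) if config.n_rrna else 0
    irb_feats = plant(irb, jlb, "IRb", ir_names,
                      (res_irb_head + 50, res_irb_tail + rrna_zone + 50))
    features += irb_feats
    rrn_feats = []
    if config.n_rrna:
        rrna_names = [f"rrnX{i}" for i in range(1, config.n_rrna + 1)]
        rrn_feats = plant(irb, jlb, "IRb", rrna_names,
                          (m - rrna_zone, res_irb_tail + 50), kind="rRNA", fixed_len=1500)
        features += rrn_feats

    # mirrored IR copies (coordinates reflected into IRa, strand flipped)
    for f in irb_feats + rrn_feats:
        (s, e), = f.exons
        u, v = s - jlb, e - jlb  # IRb-local
        ms, me = jsa + (m - v), jsa + (m - u)
        flipped = "-" if f.strand == "+" else "+"
        features.append(GeneFeature(f.name, f.kind, flipped, ((ms, me),), copy_tag="2"))

    features = [
        replace(f, copy_tag="1") if any(
            g is not f and g.name == f.name and g.kind == f.kind for g in features
        ) and not f.copy_tag else f
        for f in features
    ]

    genome = list("".join(lsc) + "".join(irb) + "".join(ssc) + revcomp("".join(irb)))
    # Break chance complementarity at the IR boundary pairs so the planted
    # repeat is exactly maximal: extension pairs are (JLB-1, 0) and
    # (JSB, JSA-1). Only the second position of each pair is touched.
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for keep, free in ((jlb - 1, 0), (jsb, jsa - 1)):
        if genome[free] == comp[genome[keep]]:
            genome[free] = next(b for b in "ACGT" if b != comp[genome[keep]] and b != genome[free])
    residues = "".join(genome)
    assert len(residues) == L
    record = PlastomeRecord(
        accession=f"SYNP{config.seed:06d}",
        taxon="Synthoplast demo",
        sequence=GenomeSequence(residues, circular=True),
        features=tuple(sorted(features, key=lambda f: (f.exons[0][0], f.name))),
    )
    for h in config.hotspots:
        if h.end > L:
            raise SynthConfigError(f"hotspot {h} outside genome of {L} bp")
    truth = TruthSet(
        regions={"LSC": (0, jlb), "IRb": (jlb, jsb), "SSC": (jsb, jsa), "IRa": (jsa, L)},
        junctions={"JLB": jlb, "JSB": jsb, "JSA": jsa, "JLA": 0},
        ir_length=m,
        gene_truth=gene_truth,
        preferences=preferences,
        hotspots=tuple(config.hotspots),
        tree=config.tree,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Family evolution
# ---------------------------------------------------------------------------

def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    if (codes == 255).any():
        raise ValueError("ancestor sequence must be unambiguous A/C/G/T")
    return codes


def _decode(codes: np.ndarray) -> str:
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]).decode()


def _evolve(
    codes: np.ndarray, t: float, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Jukes–Cantor step of expected length t substitutions/site."""
    if t <= 0:
        return codes.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * t * rates))
    mask = rng.random(codes.size) < p
    child = codes.copy()
    k = int(mask.sum())
    if k:
        child[mask] = (child[mask] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
    return child


def generate_family(
    config: SynthConfig,
) -> tuple[list[PlastomeRecord], AlignmentMatrix, TruthSet]:
    """Evolve a family of plastomes from one synthetic ancestor.

    Substitution-only Jukes–Cantor evolution along ``config.tree`` (branch
    lengths in expected substitutions/site), with hotspot intervals at
    multiplied rate. Because no indels are introduced the leaf sequence
    matrix is the true alignment. Leaves named in ``divergent_leaves`` get
    a synonymous codon-preference shift applied to their protein-coding
    genes, emulating a codon-usage-divergent taxon; when ``enforce_ir`` is
    set, IRa is re-imposed as the exact reverse complement of IRb in every
    leaf so descendants stay quadripartite.
    """
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("family tree needs at least 3 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels in tree")

    ancestor, truth = generate_plastome(config)
    L = len(ancestor)
    rates = np.ones(L)
    # purifying selection: protein-coding intervals evolve slower
    for f in ancestor.features:
        if f.kind == "CDS":
            for s, e in f.exons:
                rates[s:e] = config.cds_rate_factor
    # hypervariability dominates purifying selection inside a hotspot
    for h in config.hotspots:
        rates[h.start : h.end] = np.maximum(rates[h.start : h.end], h.multiplier)

    rng = np.random.default_rng([config.seed, 2])
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): _encode(ancestor.sequence.residues)}
    leaf_codes: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        child = _evolve(seqs[id(node.parent_node)], t, rates, rng)
        seqs[id(node)] = child
        if node.is_leaf():
            leaf_codes[node.taxon.label] = child

    jlb = config.lsc_len
    jsb = jlb + config.irb_len
    jsa = jsb + config.ssc_len
    records = []
    rows: dict[str, str] = {}
    for idx, leaf in enumerate(sorted(leaf_codes)):
        residues = _decode(leaf_codes[leaf])
        if leaf in config.divergent_leaves:
            residues = _shift_codon_usage(
                residues, ancestor, config,
                np.random.default_rng([config.seed, 3, idx]),
            )
        if config.enforce_ir:
            seq_list = list(residues)
            seq_list[jsa:L] = list(revcomp("".join(seq_list[jlb:jsb])))
            residues = "".join(seq_list)
        rows[leaf] = residues
        records.append(
            PlastomeRecord(
                accession=f"SYN{idx:03d}",
                taxon=leaf,
                sequence=GenomeSequence(residues, circular=True),
                features=ancestor.features,
            )
        )
    taxa = sorted(rows)
    aln = AlignmentMatrix(taxa, [rows[t] for t in taxa])
    return records, aln, truth


def _shift_codon_usage(
    residues: str,
    ancestor: PlastomeRecord,
    config: SynthConfig,
    rng: np.random.Generator,
) -> str:
    """Resample a fraction of each CDS's codons under fresh synonymous
    preferences (amino-acid sequence preserved)."""
    from .codonlab import CODON_TO_AA

    seq = list(residues)
    shared = _shared_bias(rng)  # a fresh genome-wide preference direction
    for f in ancestor.features:
        if f.kind != "CDS":
            continue
        prefs = _draw_preferences(
            rng, shared, max(config.bias_strength, 1.0), config.codon_jitter
        )
        (s, e), = f.exons
        sub = "".join(seq[s:e])
        if f.strand == "-":
            sub = revcomp(sub)
        codons = [sub[i : i + 3] for i in range(0, len(sub) - len(sub) % 3, 3)]
        for ci in range(1, len(codons) - 1):
            if rng.random() >= config.divergent_codon_fraction:
                continue
            aa = CODON_TO_AA.get(codons[ci])
            if aa is None:
                continue
            fam = _SENSE_NONSTOP[aa]
            codons[ci] = fam[rng.choice(len(fam), p=prefs[aa])]
        new = "".join(codons) + sub[len(codons) * 3 :]
        if f.strand == "-":
            new = revcomp(new)
        seq[s:e] = list(new)
    return "".join(seq)
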