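"""Codon statistics: RSCU, ENC, optimal codons, CAM, neighbor joining."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from plastcomp import (
    CAMProfile,
    CAMotif,
    CodingSeq,
    cam_distance,
    cam_distance_matrix,
    cam_motif,
    cam_profile,
    count_codons,
    enc,
    nj_tree,
    optimal_codons,
    pool_counts,
    rscu,
    select_groups,
)
from plastcomp.codonlab import (
    CodonCounts,
    FAMILIES,
    FrameError,
    SENSE_CODONS,
    nj_newick,
)

# ---------------------------------------------------------------------------
# independent Wright-formula oracle (families hardcoded, not imported)
# ---------------------------------------------------------------------------

_ORACLE_FAMILIES = {
    "Phe": ["TTT", "TTC"], "Tyr": ["TAT", "TAC"], "His": ["CAT", "CAC"],
    "Gln": ["CAA", "CAG"], "Asn": ["AAT", "AAC"], "Lys": ["AAA", "AAG"],
    "Asp": ["GAT", "GAC"], "Glu": ["GAA", "GAG"], "Cys": ["TGT", "TGC"],
    "Ile": ["ATT", "ATC", "ATA"],
    "Val": ["GTT", "GTC", "GTA", "GTG"], "Pro": ["CCT", "CCC", "CCA", "CCG"],
    "Thr": ["ACT", "ACC", "ACA", "ACG"], "Ala": ["GCT", "GCC", "GCA", "GCG"],
    "Gly": ["GGT", "GGC", "GGA", "GGG"],
    "Leu": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "Ser": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "Arg": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
}


def enc_oracle(counts: dict) -> float:
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for codons in _ORACLE_FAMILIES.values():
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        s = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        per_class[len(codons)].append((n * s - 1) / (n - 1))
    means = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    if (3 not in means or means[3] <= 0) and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(61.0, max(20.0, nc))


def _random_counts(rng, low=1, high=30) -> dict:
    return {c: int(rng.integers(low, high + 1)) for c in SENSE_CODONS}


class TestCounting:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGTGGTAA", {"ATG": 1, "TGG": 1, "TAA": 1}),
            ("ATGATGATG", {"ATG": 3}),
        ],
    )
    def test_known_tallies(self, seq, expected):
        cc = count_codons(CodingSeq("g", seq, "x"))
        assert dict(cc.counts) == expected

    def test_stop_flagged_separately(self):
        cc = count_codons(CodingSeq("g", "ATGTAA", "x"))
        assert cc.stop_counts() == {"TAA": 1}
        assert cc.sense_counts() == {"ATG": 1}

    def test_frame_error_names_gene(self):
        with pytest.raises(FrameError, match="badgene"):
            count_codons(CodingSeq("badgene", "ATGC", "x"))

    def test_ambiguous_codons_dropped_and_counted(self):
        cc = count_codons(CodingSeq("g", "ATGNNNTGG", "x"))
        assert cc.ambiguous_dropped == 1
        assert sum(cc.counts.values()) == 2

    def test_random_cds_matches_sliding_tally(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        cc = count_codons(CodingSeq("g", seq, "x"))
        manual: dict = {}
        for i in range(0, 900, 3):
            manual[seq[i : i + 3]] = manual.get(seq[i : i + 3], 0) + 1
        assert dict(cc.counts) == manual


class TestRSCU:
    def test_uniform_usage_gives_all_ones(self):
        counts = CodonCounts("g", {c: 2 for c in SENSE_CODONS})
        table = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in table.values.values())

    def test_phe_hand_example(self):
        counts = CodonCounts("g", {"TTT": 3, "TTC": 1})
        table = rscu(counts)
        assert table.values["TTT"] == pytest.approx(1.5)
        assert table.values["TTC"] == pytest.approx(0.5)

    def test_unused_family_absent(self):
        table = rscu(CodonCounts("g", {"TTT": 3}))
        assert "GGT" not in table.values

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_family_mean_is_one_property(self, seed):
        rng = np.random.default_rng(seed)
        counts = CodonCounts("g", _random_counts(rng, low=0, high=9))
        if sum(counts.sense_counts().values()) == 0:
            return
        table = rscu(counts)
        for aa, codons in FAMILIES.items():
            vals = [table.values[c] for c in codons if c in table.values]
            if vals:
                assert np.mean(vals) == pytest.approx(1.0, abs=1e-12)

    def test_pooled_counts_normalization(self):
        rng = np.random.default_rng(4)
        genes = [CodonCounts(f"g{i}", _random_counts(rng)) for i in range(10)]
        table = rscu(genes)
        for codons in FAMILIES.values():
            vals = [table.values[c] for c in codons]
            assert np.mean(vals) == pytest.approx(1.0, abs=1e-12)


class TestENC:
    def test_single_codon_per_family_is_exactly_20(self):
        counts = {FAMILIES[aa][0]: 5 for aa in FAMILIES}
        assert enc(CodonCounts("g", counts)).nc == 20.0

    def test_uniform_long_gene_approaches_61(self):
        counts = {c: 10_000 // 61 for c in SENSE_CODONS}
        assert enc(CodonCounts("g", counts)).nc > 59

    def test_matches_oracle_on_random_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            counts = _random_counts(rng)
            got = enc(CodonCounts("g", counts)).nc
            assert got == pytest.approx(enc_oracle(counts), abs=1e-9)

    def test_monotone_in_within_family_concentration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = _random_counts(rng, low=2, high=20)
            fam = FAMILIES["G"]  # glycine, 4-fold
            lo = min(fam, key=lambda c: counts[c])
            hi = max(fam, key=lambda c: counts[c])
            if lo == hi or counts[lo] < 1:
                continue
            before = enc(CodonCounts("g", counts)).nc
            shifted = dict(counts)
            shifted[lo] -= 1
            shifted[hi] += 1
            after = enc(CodonCounts("g", shifted)).nc
            assert after <= before + 1e-12


class TestGroups:
    def test_53_genes_at_5pct_gives_3_each(self):
        from plastcomp.codonlab import ENCValue

        encs = [ENCValue(f"g{i:02d}", 30 + i * 0.5, {}, {}) for i in range(53)]
        groups = select_groups(encs, 0.05)
        assert len(groups.high) == len(groups.low) == math.ceil(0.05 * 53) == 3
        assert groups.high == ("g00", "g01", "g02")
        assert groups.low == ("g50", "g51", "g52")

    def test_two_genes_one_each(self):
        from plastcomp.codonlab import ENCValue

        encs = [ENCValue("a", 25.0, {}, {}), ENCValue("b", 55.0, {}, {})]
        groups = select_groups(encs, 0.4)
        assert groups.high == ("a",) and groups.low == ("b",)

    def test_overlapping_groups_rejected(self):
        from plastcomp.codonlab import ENCValue

        encs = [ENCValue("a", 25.0, {}, {}), ENCValue("b", 55.0, {}, {})]
        with pytest.raises(ValueError):
            select_groups(encs, 0.49999)  # ceil -> 1 each is fine; force overlap
            select_groups(encs[:1] * 2, 0.4)

    def test_tie_broken_lexicographically(self):
        from plastcomp.codonlab import ENCValue

        encs = [ENCValue(g, 40.0, {}, {}) for g in ("zz", "aa", "mm", "bb")]
        groups = select_groups(encs, 0.25)
        assert groups.high == ("aa",) and groups.low == ("zz",)


class TestOptimalCodons:
    def test_identical_groups_give_empty_set(self):
        rng = np.random.default_rng(1)
        counts = CodonCounts("g", _random_counts(rng))
        out = optimal_codons(counts, counts)
        assert out.codons == frozenset()

    def test_constructed_single_winner(self):
        # high group: GGT favored within Gly; low group: GGT disfavored;
        # all other families perfectly even in both groups.
        base = {c: 10 for c in SENSE_CODONS}
        high = dict(base)
        high.update({"GGT": 30, "GGC": 4, "GGA": 3, "GGG": 3})
        low = dict(base)
        low.update({"GGT": 2, "GGC": 13, "GGA": 13, "GGG": 12})
        out = optimal_codons(CodonCounts("h", high), CodonCounts("l", low))
        assert out.codons == frozenset({"GGU"})
        assert out.delta_rscu["GGU"] > 0.08

    def test_rna_alphabet_output(self):
        high = {c: 10 for c in SENSE_CODONS}
        high["TTG"] = 40
        low = {c: 10 for c in SENSE_CODONS}
        low["TTG"] = 1
        out = optimal_codons(CodonCounts("h", high), CodonCounts("l", low))
        assert all("T" not in c for c in out.codons)
        assert "UUG" in out.codons

    def test_invariant_to_gene_input_order(self):
        rng = np.random.default_rng(8)
        high = [CodonCounts(f"h{i}", _random_counts(rng)) for i in range(3)]
        low = [CodonCounts(f"l{i}", _random_counts(rng)) for i in range(3)]
        a = optimal_codons(high, low)
        b = optimal_codons(high[::-1], low[::-1])
        assert a.codons == b.codons and a.delta_rscu == b.delta_rscu


class TestCAM:
    def test_all_61_used_gives_empty_motif(self):
        counts = CodonCounts("g", {c: 1 for c in SENSE_CODONS})
        assert cam_motif(counts).unused == ()

    def test_complement_of_used_set(self):
        cc = count_codons(CodingSeq("g", "ATGAAATTTTAA", "x"))
        motif = cam_motif(cc)
        assert len(motif.unused) == 58
        assert set(motif.unused) == set(SENSE_CODONS) - {"ATG", "AAA", "TTT"}

    def test_distance_identical_zero_disjoint_one(self):
        m = CAMotif("g1", ("AAA",))
        a = CAMProfile("A", {"g1": m})
        b = CAMProfile("B", {"g1": m})
        assert cam_distance(a, b) == 0.0
        c = CAMProfile("C", {"g1": CAMotif("g1", ("CCC",))})
        assert cam_distance(a, c) == 1.0

    def test_jaccard_arithmetic(self):
        motifs = {f"g{i}": CAMotif(f"g{i}", (c,)) for i, c in enumerate(["AAA", "AAC", "AAG"])}
        a = CAMProfile("A", motifs)
        b = CAMProfile("B", {"g0": motifs["g0"]})
        assert cam_distance(a, b) == pytest.approx(2 / 3)

    def test_unlabeled_mode_ignores_gene_names(self):
        m = ("AAA", "CCC")
        a = CAMProfile("A", {"x": CAMotif("x", m)})
        b = CAMProfile("B", {"y": CAMotif("y", m)})
        assert cam_distance(a, b, mode="gene_labeled") == 1.0
        assert cam_distance(a, b, mode="unlabeled") == 0.0

    @staticmethod
    def _random_profile(rng, species):
        genes = {}
        for i in range(rng.integers(1, 8)):
            size = rng.integers(0, 6)
            motif = tuple(sorted(rng.choice(SENSE_CODONS, size=size, replace=False)))
            genes[f"g{i}"] = CAMotif(f"g{i}", motif)
        return CAMProfile(species, genes)

    def test_metric_axioms_on_random_profiles(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            a = self._random_profile(rng, "A")
            b = self._random_profile(rng, "B")
            c = self._random_profile(rng, "C")
            dab, dba = cam_distance(a, b), cam_distance(b, a)
            assert dab == dba and 0 <= dab <= 1
            assert cam_distance(a, a) == 0.0
            if dab == 0:
                assert a.labeled_pairs() == b.labeled_pairs()
            assert cam_distance(a, c) <= dab + cam_distance(b, c) + 1e-12


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["A", "B", "C"])
        nwk = nj_newick(dm)
        assert nwk == "(A:1,B:2,C:3);"

    def test_four_taxon_additive_exact(self):
        # true tree ((A:2,B:3):1,(C:4,D:5))
        ids = ["A", "B", "C", "D"]
        d = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
             ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        mat = [[0 if i == j else d[tuple(sorted((i, j)))] for j in ids] for i in ids]
        nwk = nj_newick(DistanceMatrix(mat, ids=ids))
        assert nwk == "((A:2,B:3):1,C:4,D:5);"

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_newick(DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"]))

    @staticmethod
    def random_additive(rng, n):
        """Random binary tree newick with uniform branch lengths, plus its
        path-length distance matrix."""
        labels = [f"T{i}" for i in range(n)]
        nodes = {lb: (lb, {lb: 0.0}) for lb in labels}  # newick, leaf depths
        avail = list(labels)
        while len(avail) > 1:
            i, j = sorted(rng.choice(len(avail), size=2, replace=False))
            a, b = avail[j], avail[i]  # pop larger index first
            na, da = nodes.pop(a)
            nb, db = nodes.pop(b)
            la, lb_ = rng.uniform(0.1, 1.0, size=2)
            merged = f"({na}:{la:.6f},{nb}:{lb_:.6f})"
            depths = {k: v + la for k, v in da.items()}
            depths.update({k: v + lb_ for k, v in db.items()})
            key = f"i{len(nodes)}_{a}"
            nodes[key] = (merged, depths)
            avail = [x for x in avail if x not in (a, b)] + [key]
        newick, _ = nodes[avail[0]]
        tree = dendropy.Tree.get(data=newick + ";", schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        mat = [[pdm.distance(taxa[x], taxa[y]) for y in labels] for x in labels]
        return newick + ";", DistanceMatrix(mat, ids=labels)

    @staticmethod
    def rf_distance(nwk1, nwk2):
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
        t1.is_rooted = t2.is_rooted = False
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        return dendropy.calculate.treecompare.symmetric_difference(t1, t2)

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            true_nwk, dm = self.random_additive(rng, n)
            assert self.rf_distance(true_nwk, nj_newick(dm)) == 0

    def test_agrees_with_skbio_topology(self):
        rng = np.random.default_rng(31)
        true_nwk, dm = self.random_additive(rng, 7)
        ours = nj_newick(dm)
        theirs = str(skbio_nj(dm))
        assert self.rf_distance(ours, theirs) == 0

    def test_returns_dendropy_tree_with_all_leaves(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["A", "B", "C"])
        tree = nj_tree(dm)
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"A", "B", "C"}


class TestProfilesFromGenes:
    def test_profile_has_one_motif_per_gene(self, small_plastome):
        from plastcomp import extract_cds

        rec, _ = small_plastome
        cds = extract_cds(rec, min_len=0, dedupe=True)
        prof = cam_profile(rec.taxon, cds)
        assert set(prof.motifs) == {c.gene for c in cds}

    def test_distance_matrix_is_symmetric_zero_diagonal(self, divergent_family):
        from plastcomp import extract_cds

        records, _, _ = divergent_family
        profiles = [
            cam_profile(r.taxon, extract_cds(r, 300, True)) for r in records
        ]
        dm = cam_distance_matrix(profiles)
        assert list(dm.ids) == sorted(dm.ids)
        data = np.asarray(dm.data)
        assert np.allclose(data, data.T) and np.allclose(np.diag(data), 0)
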