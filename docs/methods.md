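# Methods

## Coordinates and circularity

All coordinates are 0-based half-open. Plastomes are circular; an interval
whose start is ≥ its end wraps the origin, and splicing resolves it as
`[start, L) + [0, end)`. GenBank I/O converts to and from the 1-based
inclusive convention via Biopython. Every architecture quantity (region
lengths, junction splits, overlaps) is computed with modular arithmetic, so
rotating the circle changes nothing — a property the suite tests directly.

## Inverted-repeat detection

Only exact (mismatch-free) inverted repeats are considered: plastid IRs are
exact in practice, and exactness makes the result canonical and checkable
against a brute-force oracle. The detector indexes 20-mers of the (doubled,
for circularity) sequence, looks up each position's reverse-complement
20-mer, and extends each seed maximally along its anti-diagonal
(`p + q = const` pairs of complementary positions). Each anti-diagonal is
extended once; seeds occurring at more than 64 positions are skipped as
low-complexity. A self-symmetric run (a palindrome crossing its own center)
is split into two disjoint arms. The longest disjoint pair wins; ties go to
the lower coordinate. Runtime is effectively linear for plastome-sized
inputs (~0.5 s at 160 kb).

Naming follows the common convention: IRb is the IR copy entered first when
traversing from the LSC in genome order; the junctions are JLB (LSC|IRb),
JSB (IRb|SSC), JSA (SSC|IRa), JLA (IRa|LSC), each recorded as the coordinate
of the first base of the downstream region. If the two single-copy regions
have equal length the layout is ambiguous and partitioning raises instead of
guessing.

## Codon statistics

The plastid/bacterial genetic code (translation table 11) is used
throughout; its synonymous families are nine 2-fold, one 3-fold (Ile), five
4-fold and three 6-fold (Leu, Ser, Arg), with Met, Trp and the stops
excluded from bias statistics.

*RSCU* is a codon's count divided by its family's mean count; families with
zero usage have undefined (absent) entries, and single-codon families come
out as exactly 1 when used.

*ENC* follows Wright: per family, `F̂ = (nΣp_i² − 1)/(n − 1)` with `n` the
family total; families with `n < 2` are skipped; degeneracy-class means
feed `Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6`, capped to [20, 61]. When the
3-fold class (only Ile) is missing or its estimate is non-positive — common
in short genes — it is repaired as the mean of the 2- and 4-fold class
means, the standard practice; a missing or non-positive mean in any other
class leaves ENC undefined for that gene, and such genes are excluded from
group selection.

*Expression groups.* ENC is used as an inverse expression proxy: the genes
in the lowest-ENC `ceil(f·N)` (default f = 0.05) form the putative
high-expression group, the highest-ENC fraction the low group. Group labels
in all reports carry both readings ("low_enc(high_expression)") because the
two conventions are easy to confuse. Ties break lexicographically by gene
symbol so outputs are deterministic.

*Optimal codons* are computed from the pooled codon counts of each group
(not the mean of per-gene RSCU values — pooling is the common convention and
is stable for short genes): optimal iff ΔRSCU > 0.08, RSCU_high > 1 and
RSCU_low < 1. Reported in the RNA alphabet.

*CAM.* A gene's codon aversion motif is the sorted tuple of sense codons
with zero count. The distance between two species' profiles is a Jaccard
distance, by default on (gene, motif) pairs; an `unlabeled` mode compares
bare motif sets instead. Both modes are provided because the choice is a
configuration, not a settled convention; the gene-labeled form is the
default since it uses strictly more information. Jaccard distance is a
metric, which the suite verifies on random profiles.

*Neighbor joining* is implemented classically (Q-criterion agglomeration,
Studier–Keppler formulas). It is deterministic: Q-ties are broken by the
lexicographically smallest pair of clade labels, a clade being labeled by
its smallest leaf name. A negative branch length is clamped to zero with
the deficit moved to the sister edge, so path lengths within the joined
cherry are preserved. On additive matrices the method provably recovers the
generating topology and branch lengths; the suite checks this on random
5–8-leaf trees and cross-checks topology against scikit-bio's independent
implementation.

## Nucleotide diversity and hotspot calling

π over an interval is the mean across unordered sequence pairs of
(differences / compared sites), with pairwise deletion: a column with a gap
or N in either member of a pair leaves that pair's numerator and
denominator untouched. Pairwise deletion (rather than complete deletion) is
the default because indel-rich intergenic spacers would otherwise discard
most columns; it is a configurable choice, not a claim about any particular
reference tool. Eta counts, per column, the number of distinct unambiguous
bases minus one, so multi-allelic columns count multiply; the segregating
site count S is also available since published "mutation" columns are
sometimes one and sometimes the other.

Sliding windows default to 600 bp at 200 bp steps — conventional values for
plastome π scans that yield called regions in the 600–1800 bp range typical
of published hotspot tables. A final partial window is kept when at least
half a window long. HPRs are the windows at or above the 97.5th percentile
of window π (configurable), merged when separated by at most one step, and
re-scored over the merged span (region π, Eta, length). Because real
analyses rarely publish their exact window parameters, HPR agreement with
published tables should be judged as overlap of called regions with listed
loci, never as coordinate equality. Region labels are assigned post hoc
from overlapping (else flanking) annotated genes and assume the alignment
is in the coordinate system of the supplied reference record — exactly true
for the substitution-only synthetic families.

## The synthetic generator

`generate_plastome` builds a full-scale circular quadripartite genome:
86 kb LSC + 26.5 kb IRb + 18.3 kb SSC + IRa as the exact reverse complement
of IRb (~157 kb total, GC 0.37). It plants 53 protein-coding genes of
300–1200 bp (38 LSC, 8 SSC, 4 IRb — the IR genes duplicated into IRa with
flipped strand and a copy tag), 4 tRNAs and 2 rRNA-like genes, and three
junction-spanning genes modeled on their real namesakes: an rpl22-like gene
across JLB (240/120 bp split), an ndhF-like minus-strand gene across JSB
(55 bp in IRb), and a 5 kb ycf1-like gene across JSA whose 1 kb IRa portion
mirrors into the IRb tail as an annotated pseudogene fragment — reproducing
the classic 55 bp pseudo-ycf1 × ndhF overlap at JSB. Boundary bases flanking
the IR are adjusted when necessary so the planted repeat is exactly maximal
(otherwise chance complementarity would extend it and no detector could
return the planted length).

Codon usage per gene is drawn per synonymous family as a softmax of
`s_g · b · (z_shared + 0.4 · z_gene)` where `z_shared` is a genome-wide
preference direction (the mutation-bias analog), `z_gene` a per-gene jitter,
and `s_g ~ U(0.2, 1.8)` a per-gene bias scale. With the default b = 0.6 the
53 genes span ENC ≈ 31–61 with a median near 48, matching the spread
reported for real plastome CDS sets; b = 0 gives exactly exchangeable
codons (ENC → 61 for long genes).

`generate_family` evolves the ancestor along a user tree (default four
leaves, `((A:0.001,B:0.001):0.003,(C:0.001,D:0.001):0.003)`) under
Jukes–Cantor substitution with per-site rates: 1 in intergenic/RNA
sequence, 0.2 inside CDSs (purifying selection), and hotspot intervals —
three 1.2 kb LSC segments by default — raised to 10× (hypervariability
overrides the CDS slowdown where they overlap). These defaults give a
background π near 0.006 and hotspot π near 0.04–0.08, the magnitudes
reported for real congeneric plastome comparisons. Because no indels are
introduced, the leaf sequence matrix *is* the true alignment: indel realism
is deliberately sacrificed for exact alignment truth. Leaves listed as
divergent get half of each CDS's codons resampled under a freshly drawn
genome-wide preference (synonymous only — the protein is preserved),
emulating a codon-usage-divergent taxon; IRa is then re-imposed as the
reverse complement of IRb in every leaf so descendants stay quadripartite.

What passing tests on this generator do **not** show about real data:
alignment quality is never at issue (no indels, no misalignment), IR
boundaries do not expand or contract along the tree, rearrangements and
inversions never occur, and codon-usage divergence is planted as a clean
genome-wide shift rather than arising from lineage-specific mutation or
selection processes.

## Problem sizes and numerical choices

The acceptance battery and tests run at: 100 seeded compact genomes
(~10.7 kb) for exact IR recovery; 50 full-scale (~157 kb) four-leaf families
for hotspot recovery at default window/step/quantile; 20 families for
divergent-taxon CAM separation; 100 random 5–8-leaf additive matrices for
NJ; 100 random alignments (≤ 6 × 300) against a brute-force π oracle; 100
random genes against an independently coded Wright formula (1e-9). The
compact IR-genome size keeps the quadratic oracle comparisons tractable
while exercising the same code paths as full scale.

Tolerances: RSCU normalization to 1e-12; π oracle parity to 1e-12; ENC
oracle parity to 1e-9; everything architectural is exact integer
arithmetic. Degenerate inputs are errors, not guesses: all-N GC content,
zero comparable sites for π, equal-length single-copy regions, overlapping
ENC expression groups, sub-3-taxon trees.

## Known limitations

- Exact-repeat IR detection will under-report an IR containing even one
  internal mismatch between its copies (rare in practice, but real).
- CAM motifs are fragile characters: a single substitution can add or
  remove an unused codon, so motif distances saturate quickly with
  divergence; they are most informative among close relatives.
- HPR boundaries are window-quantized and threshold-relative (a quantile of
  the observed window distribution), so called coordinates are comparable
  only under identical window parameters.
- The diversity module consumes alignments; it never aligns, and its region
  labels assume alignment coordinates match the reference record.
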