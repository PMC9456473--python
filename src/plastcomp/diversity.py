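"""Sliding-window nucleotide diversity and highly polymorphic regions.

π is the mean over all unordered sequence pairs of (pairwise differences /
compared sites), with pairwise deletion: a column with a gap or ambiguous
base in either member of a pair is excluded from that pair's numerator and
denominator. Eta is the total mutation count: per column, the number of
distinct unambiguous bases minus one (multi-allelic columns count multiply).

The module consumes an existing alignment; it never aligns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plastome_io import PlastomeRecord, read_fasta

_CODE = {b: i for i, b in enumerate(b"ACGT")}


class UndefinedPiError(ValueError):
    """No comparable site pair in the requested interval."""


class AlignmentMatrix:
    """A multiple alignment over {A,C,G,T,N,-}, rows in a fixed taxon order."""

    def __init__(self, taxa: Sequence[str], rows: Sequence[str] | np.ndarray):
        if len(taxa) < 2:
            raise ValueError("alignment needs at least two taxa")
        if isinstance(rows, np.ndarray):
            data = rows.astype("S1")
        else:
            lengths = {len(r) for r in rows}
            if len(lengths) != 1:
                raise ValueError("alignment rows differ in length")
            data = np.array([list(r.upper()) for r in rows], dtype="S1")
        if data.shape[0] != len(taxa):
            raise ValueError("taxa / row count mismatch")
        allowed = np.isin(data, np.frombuffer(b"ACGTN-", dtype="S1"))
        if not allowed.all():
            bad = sorted({x.decode() for x in data[~allowed]})
            raise ValueError(f"invalid alignment characters {bad}")
        self.taxa = list(taxa)
        self.data = data

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.length

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        entries = read_fasta(path)
        if not entries:
            raise ValueError(f"no sequences in {path}")
        taxa = [h.split()[0] for h, _ in entries]
        return cls(taxa, [s for _, s in entries])

    def subset(self, taxa: Sequence[str]) -> "AlignmentMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return AlignmentMatrix(list(taxa), self.data[idx])

    def _valid(self) -> np.ndarray:
        return np.isin(self.data, np.frombuffer(b"ACGT", dtype="S1"))


@dataclass(frozen=True)
class WindowSeries:
    """Per-window π along an alignment."""

    starts: np.ndarray
    ends: np.ndarray
    pi: np.ndarray
    window: int
    step: int

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start": self.starts, "end": self.ends, "midpoint": self.midpoints, "pi": self.pi}
        )


@dataclass(frozen=True)
class HPRegion:
    """One called highly polymorphic region (alignment coordinates)."""

    start: int
    end: int
    pi: float
    mutations: int
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def _pair_arrays(aln: AlignmentMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair boolean arrays (npairs x L): comparable sites and differences."""
    valid = aln._valid()
    n = len(aln.taxa)
    pairs = list(itertools.combinations(range(n), 2))
    comp = np.empty((len(pairs), aln.length), dtype=bool)
    diff = np.empty_like(comp)
    for p, (i, j) in enumerate(pairs):
        comp[p] = valid[i] & valid[j]
        diff[p] = comp[p] & (aln.data[i] != aln.data[j])
    return comp, diff


def nucleotide_diversity(
    aln: AlignmentMatrix, interval: tuple[int, int] | None = None
) -> float:
    """π over an interval (whole alignment by default), pairwise deletion.

    Pairs with zero comparable sites are dropped from the average; if every
    pair is dropped an :class:`UndefinedPiError` is raised.
    """
    s, e = interval if interval is not None else (0, aln.length)
    if not (0 <= s < e <= aln.length):
        raise ValueError(f"interval ({s}, {e}) outside alignment of {aln.length} columns")
    comp, diff = _pair_arrays(aln)
    ncomp = comp[:, s:e].sum(axis=1)
    ndiff = diff[:, s:e].sum(axis=1)
    usable = ncomp > 0
    if not usable.any():
        raise UndefinedPiError(f"no comparable sites in ({s}, {e})")
    return float(np.mean(ndiff[usable] / ncomp[usable]))


def sliding_pi(aln: AlignmentMatrix, window: int = 600, step: int = 200) -> WindowSeries:
    """π per window at the given stride.

    The final partial window is kept when it is at least half a window long,
    otherwise dropped. A window longer than the alignment degenerates to one
    whole-alignment window.
    """
    if step < 1 or window < step:
        raise ValueError("need window >= step >= 1")
    L = aln.length
    if window >= L:
        bounds = [(0, L)]
    else:
        bounds = []
        for start in range(0, L, step):
            end = min(start + window, L)
            if end - start == window or end - start >= window / 2:
                bounds.append((start, end))
    comp, diff = _pair_arrays(aln)
    ccum = np.concatenate([np.zeros((comp.shape[0], 1), dtype=np.int64), comp.cumsum(axis=1)], axis=1)
    dcum = np.concatenate([np.zeros((diff.shape[0], 1), dtype=np.int64), diff.cumsum(axis=1)], axis=1)
    pis = np.empty(len(bounds))
    for w, (s, e) in enumerate(bounds):
        ncomp = ccum[:, e] - ccum[:, s]
        ndiff = dcum[:, e] - dcum[:, s]
        usable = ncomp > 0
        pis[w] = np.mean(ndiff[usable] / ncomp[usable]) if usable.any() else np.nan
    starts = np.array([b[0] for b in bounds])
    ends = np.array([b[1] for b in bounds])
    return WindowSeries(starts=starts, ends=ends, pi=pis, window=window, step=step)


def count_mutations(aln: AlignmentMatrix, interval: tuple[int, int] | None = None) -> int:
    """Eta: sum over columns of (distinct unambiguous bases − 1)."""
    s, e = interval if interval is not None else (0, aln.length)
    sub = aln.data[:, s:e]
    distinct = np.zeros(e - s, dtype=np.int64)
    for base in b"ACGT":
        distinct += (sub == np.bytes_([base])).any(axis=0)
    return int(np.maximum(distinct - 1, 0).sum())


def segregating_sites(aln: AlignmentMatrix, interval: tuple[int, int] | None = None) -> int:
    """S: number of columns with at least two distinct unambiguous bases."""
    s, e = interval if interval is not None else (0, aln.length)
    sub = aln.data[:, s:e]
    distinct = np.zeros(e - s, dtype=np.int64)
    for base in b"ACGT":
        distinct += (sub == np.bytes_([base])).any(axis=0)
    return int((distinct >= 2).sum())


def call_hprs(
    series: WindowSeries,
    aln: AlignmentMatrix,
    threshold_quantile: float = 0.975,
    merge_gap: int | None = None,
) -> list[HPRegion]:
    """Call highly polymorphic regions from a window series.

    Windows with π at or above the ``threshold_quantile`` quantile of all
    window π values are selected; runs of selected windows whose spans are
    separated by at most ``merge_gap`` bp (default: one step) are merged, and
    each merged span is re-scored with region-wide π and Eta. A flat series
    (all π zero) yields no regions.
    """
    if merge_gap is None:
        merge_gap = series.step
    pis = series.pi
    finite = pis[np.isfinite(pis)]
    if finite.size == 0 or finite.max() <= 0:
        return []
    thr = float(np.quantile(finite, threshold_quantile))
    selected = [i for i in range(len(pis)) if np.isfinite(pis[i]) and pis[i] >= thr and pis[i] > 0]
    if not selected:
        return []
    spans: list[list[int]] = []
    for i in selected:
        s, e = int(series.starts[i]), int(series.ends[i])
        if spans and s - spans[-1][1] <= merge_gap:
            spans[-1][1] = max(spans[-1][1], e)
        else:
            spans.append([s, e])
    regions = []
    for s, e in spans:
        try:
            region_pi = nucleotide_diversity(aln, (s, e))
        except UndefinedPiError:
            region_pi = float("nan")
        regions.append(
            HPRegion(start=s, end=e, pi=region_pi, mutations=count_mutations(aln, (s, e)))
        )
    return regions


def label_hprs(
    regions: Iterable[HPRegion], record: PlastomeRecord
) -> list[HPRegion]:
    """Attach gene-context labels, assuming alignment coordinates match the
    record's genome coordinates (true for the substitution-only synthetic
    families; for real data, supply the reference-coordinate record).

    Overlapping genes are joined with '-'; a region in an intergenic span is
    labelled by its flanking genes.
    """
    L = len(record)
    feats = sorted(record.features, key=lambda f: f.exons[0][0])
    out = []
    for reg in regions:
        hit = [
            f.name
            for f in feats
            if min(reg.end, f.exons[-1][1]) - max(reg.start, f.exons[0][0]) > 0
        ]
        if hit:
            label = "-".join(dict.fromkeys(hit))
        else:
            before = [f for f in feats if f.exons[-1][1] <= reg.start]
            after = [f for f in feats if f.exons[0][0] >= reg.end]
            left = before[-1].name if before else (feats[-1].name if feats else "?")
            right = after[0].name if after else (feats[0].name if feats else "?")
            label = f"{left}-{right}"
        out.append(HPRegion(reg.start, reg.end, reg.pi, reg.mutations, label=label))
    return out


def hpr_table(regions: Iterable[HPRegion]) -> pd.DataFrame:
    """Region table with the conventional columns."""
    return pd.DataFrame(
        [
            {
                "region": r.label or f"{r.start}-{r.end}",
                "start": r.start,
                "end": r.end,
                "nucleotide_diversity": round(r.pi, 5) if np.isfinite(r.pi) else np.nan,
                "mutations": r.mutations,
                "length": r.length,
            }
            for r in regions
        ]
    )


def write_bed(regions: Iterable[HPRegion], path: str | Path, chrom: str = "plastome") -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.label or f"{r.start}-{r.end}"
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{name}\t{r.pi:.5f}\n")
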