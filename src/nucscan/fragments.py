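"""Mononucleosome fragment sets: BED ingest, pair joining, coverage.

A fragment is the genomic interval protected by one nucleosome, i.e. one
sequenced read pair after alignment. The pipeline consumes fragments as
BED3; alignment itself happens upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .genome import GenomeAssembly

logger = logging.getLogger(__name__)

#: Sanity bounds on joined pair fragment length (bp); MNase
#: mononucleosome inserts run roughly 110-180 bp, so anything outside
#: [50, 500] is a mispair or a di-nucleosome.
DEFAULT_LENGTH_BOUNDS = (50, 500)


class FragmentSet:
    """Sorted fragment intervals per chromosome.

    ``total`` is the library size used as the FPKM normalisation
    denominator. Intervals are 0-based half-open and sorted by
    (start, end) within each chromosome; duplicates are retained.
    """

    def __init__(self, intervals: Mapping[str, np.ndarray]):
        self._ivals: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"{chrom}: fragment with start >= end")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            self._ivals[chrom] = arr[order]
        self.total = sum(len(a) for a in self._ivals.values())

    @property
    def chromosomes(self) -> list[str]:
        return list(self._ivals)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def midpoints(self, chrom: str) -> np.ndarray:
        arr = self.intervals(chrom)
        return (arr[:, 0] + arr[:, 1]) // 2

    def __len__(self) -> int:
        return self.total

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self._ivals.items():
                for s, e in arr:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_fragments(path: str | Path, genome: GenomeAssembly | None = None) -> FragmentSet:
    """Read fragments from a BED3+ file (columns beyond 3 ignored).

    Records with start >= end are rejected with a warning; records on
    chromosomes absent from `genome` (when given) are dropped with a
    warning count. Output is sorted regardless of input order.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    n_bad = n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
            if start >= end:
                n_bad += 1
                continue
            if genome is not None and chrom not in genome:
                n_unknown += 1
                continue
            per_chrom.setdefault(chrom, []).append((start, end))
    if n_bad:
        logger.warning("%s: rejected %d records with start >= end", path, n_bad)
    if n_unknown:
        logger.warning("%s: dropped %d records on chromosomes absent from genome",
                       path, n_unknown)
    return FragmentSet({c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()})


@dataclass
class PairFilterStats:
    """Counts of read pairs discarded while joining mates into fragments."""
    kept: int = 0
    different_chrom: int = 0
    same_strand: int = 0
    bad_length: int = 0


def pairs_to_fragments(pairs: Iterable[tuple],
                       length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
                       ) -> tuple[FragmentSet, PairFilterStats]:
    """Join aligned read pairs into fragments.

    Each pair is ``((start1, end1, strand1), (start2, end2, strand2), chrom)``
    or ``(start1, end1, strand1, start2, end2, strand2, chrom)``. The
    fragment spans [min(starts), max(ends)). Pairs with mates on
    different chromosomes, on the same strand, or yielding a fragment
    length outside ``length_bounds`` are discarded; counts are returned.
    """
    lo, hi = length_bounds
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    stats = PairFilterStats()
    for pair in pairs:
        if len(pair) == 3:
            (s1, e1, st1), (s2, e2, st2), chrom = pair
        else:
            s1, e1, st1, s2, e2, st2, chrom = pair
        if isinstance(chrom, (tuple, list)):  # two chroms given
            c1, c2 = chrom
            if c1 != c2:
                stats.different_chrom += 1
                continue
            chrom = c1
        if st1 == st2:
            stats.same_strand += 1
            continue
        start, end = min(s1, s2), max(e1, e2)
        if not lo <= end - start <= hi:
            stats.bad_length += 1
            continue
        per_chrom.setdefault(chrom, []).append((start, end))
        stats.kept += 1
    dropped = stats.different_chrom + stats.same_strand + stats.bad_length
    if dropped:
        logger.warning("pairs_to_fragments: discarded %d pairs "
                       "(%d cross-chromosome, %d same-strand, %d length outside %s)",
                       dropped, stats.different_chrom, stats.same_strand,
                       stats.bad_length, length_bounds)
    fs = FragmentSet({c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()})
    return fs, stats


def union_length(intervals: np.ndarray) -> int:
    """Total bases covered by a union of sorted-by-start intervals."""
    if len(intervals) == 0:
        return 0
    starts = intervals[:, 0]
    ends = np.maximum.accumulate(intervals[:, 1])
    # a new covered block starts where the interval begins past the running end
    new_block = np.empty(len(starts), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > ends[:-1]
    block_starts = starts[new_block]
    block_ends = np.concatenate((ends[:-1][new_block[1:]], [ends[-1]]))
    return int((block_ends - block_starts).sum())


def coverage_rate(fragments: FragmentSet, genome: GenomeAssembly) -> float:
    """Fraction of genome bases covered by at least one fragment.

    Overlapping fragments count once (per-base union). This is the
    per-base definition of the detected nucleosome coverage rate.
    """
    covered = 0
    for chrom, L in genome.chromosomes:
        ivals = fragments.intervals(chrom)
        if len(ivals):
            clipped = np.clip(ivals, 0, L)
            clipped = clipped[clipped[:, 0] < clipped[:, 1]]
            covered += union_length(clipped)
    return covered / genome.total_length
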