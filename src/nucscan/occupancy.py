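"""Window grids, fragment counting and FPKM occupancy tracks.

Occupancy is quantified as FPKM — fragments per kilobase of window per
million library fragments:

    FPKM_w = count_w / ((len_w / 1000) * (total_fragments / 1e6))

Two fragment-to-window assignment rules are provided. The default
``midpoint`` rule assigns each fragment to the single window containing
its midpoint base floor((start+end)/2), which conserves total count and
keeps windows statistically independent; the ``overlap`` rule adds 1 to
every window the fragment touches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .genome import FEATURE_LABELS, FeaturePartition, GenomeAssembly

ASSIGNMENT_RULES = ("midpoint", "overlap")


class WindowGrid:
    """Fixed-width tiling of every chromosome, global window index.

    All windows are full width except possibly the trailing window of
    each chromosome, which keeps its true (shorter) length.
    """

    def __init__(self, chrom_lengths: dict[str, int], width: int):
        if width < 1:
            raise ValueError("window width must be >= 1")
        self.width = int(width)
        self.chrom_lengths = dict(chrom_lengths)
        self._n = {c: -(-L // width) for c, L in self.chrom_lengths.items()}
        self._offset: dict[str, int] = {}
        off = 0
        for c in self.chrom_lengths:
            self._offset[c] = off
            off += self._n[c]
        self.n_windows = off

    def n_windows_on(self, chrom: str) -> int:
        return self._n[chrom]

    def offset(self, chrom: str) -> int:
        return self._offset[chrom]

    def window_lengths(self) -> np.ndarray:
        """True length of every window, in global index order."""
        out = np.empty(self.n_windows, dtype=np.int64)
        for chrom, L in self.chrom_lengths.items():
            n, off = self._n[chrom], self._offset[chrom]
            lens = np.full(n, self.width, dtype=np.int64)
            lens[-1] = L - (n - 1) * self.width
            out[off:off + n] = lens
        return out

    def bounds(self) -> pd.DataFrame:
        """chrom/start/end for every window, in global index order."""
        rows = []
        for chrom, L in self.chrom_lengths.items():
            n = self._n[chrom]
            starts = np.arange(n, dtype=np.int64) * self.width
            ends = np.minimum(starts + self.width, L)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def same_grid(self, other: "WindowGrid") -> bool:
        return (self.width == other.width
                and self.chrom_lengths == other.chrom_lengths)


def make_windows(genome: GenomeAssembly, width: int) -> WindowGrid:
    """Tile the genome into `width`-bp windows (trailing window clipped)."""
    return WindowGrid(dict(genome.chromosomes), width)


def count_fragments(fragments: FragmentSet, grid: WindowGrid,
                    rule: str = "midpoint") -> np.ndarray:
    """Per-window fragment counts under the chosen assignment rule."""
    if rule not in ASSIGNMENT_RULES:
        raise ValueError(f"unknown assignment rule {rule!r}")
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    w = grid.width
    for chrom in fragments.chromosomes:
        if chrom not in grid.chrom_lengths:
            continue
        off, n = grid.offset(chrom), grid.n_windows_on(chrom)
        ivals = fragments.intervals(chrom)
        if rule == "midpoint":
            idx = (ivals[:, 0] + ivals[:, 1]) // 2 // w
            np.clip(idx, 0, n - 1, out=idx)
            counts[off:off + n] += np.bincount(idx, minlength=n)
        else:
            first = np.clip(ivals[:, 0] // w, 0, n - 1)
            last = np.clip((ivals[:, 1] - 1) // w, 0, n - 1)
            # +1 over [first, last] per fragment via a difference array
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            counts[off:off + n] += np.cumsum(diff[:-1])
    return counts


@dataclass
class OccupancyTrack:
    """FPKM occupancy per window of a grid, for one condition."""

    grid: WindowGrid
    counts: np.ndarray
    fpkm: np.ndarray
    total_fragments: int
    rule: str = "midpoint"
    label: str = ""

    def to_bedgraph(self, path: str | Path) -> None:
        df = self.grid.bounds()
        df["fpkm"] = self.fpkm
        df.to_csv(path, sep="\t", header=False, index=False,
                  float_format="%.6g")

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.bounds()
        df["count"] = self.counts
        df["fpkm"] = self.fpkm
        return df


def fpkm(counts: np.ndarray, grid: WindowGrid, total_fragments: int,
         rule: str = "midpoint", label: str = "") -> OccupancyTrack:
    """Normalise per-window counts to FPKM.

    Partial trailing windows are normalised by their true length so
    their FPKM stays comparable with full windows.
    """
    if total_fragments <= 0:
        raise ValueError("empty library: total_fragments must be > 0")
    lens_kb = grid.window_lengths() / 1000.0
    per_million = total_fragments / 1e6
    values = counts / (lens_kb * per_million)
    return OccupancyTrack(grid, np.asarray(counts, dtype=np.int64), values,
                          total_fragments, rule, label)


def occupancy_track(fragments: FragmentSet, grid: WindowGrid,
                    rule: str = "midpoint", label: str = "") -> OccupancyTrack:
    """Count fragments on the grid and normalise to FPKM in one step."""
    counts = count_fragments(fragments, grid, rule)
    return fpkm(counts, grid, fragments.total, rule, label)


def region_occupancy_ratio(fragments: FragmentSet, partition: FeaturePartition,
                           rule: str = "midpoint") -> pd.DataFrame:
    """Percentage of fragments attributed to each feature label.

    Midpoint rule (default): each fragment counts once, toward the label
    at its midpoint base. Overlap rule: each fragment is spread over the
    labels it overlaps in proportion to overlapping bases. Either way the
    percentages sum to 100.
    """
    if rule not in ASSIGNMENT_RULES:
        raise ValueError(f"unknown assignment rule {rule!r}")
    mass = np.zeros(len(FEATURE_LABELS))
    for chrom in fragments.chromosomes:
        if chrom not in partition.chrom_lengths:
            continue
        ivals = fragments.intervals(chrom)
        if not len(ivals):
            continue
        if rule == "midpoint":
            L = partition.chrom_lengths[chrom]
            mids = np.clip((ivals[:, 0] + ivals[:, 1]) // 2, 0, L - 1)
            codes = partition.label_at(chrom, mids)
            mass += np.bincount(codes, minlength=len(FEATURE_LABELS))
        else:
            starts, ends, codes = partition.intervals(chrom)
            for fs, fe in ivals:
                i = np.searchsorted(starts, fs, side="right") - 1
                j = np.searchsorted(starts, fe - 1, side="right")
                ov = (np.minimum(ends[i:j], fe) - np.maximum(starts[i:j], fs))
                length = fe - fs
                for c, o in zip(codes[i:j], ov):
                    mass[c] += o / length
    total = mass.sum()
    percent = 100.0 * mass / total if total > 0 else np.zeros_like(mass)
    return pd.DataFrame({"label": list(FEATURE_LABELS),
                         "fragments": mass,
                         "percent": percent})
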