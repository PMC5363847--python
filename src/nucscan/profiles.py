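"""TSS metaprofiles, phasing landmarks and GC-quintile summaries.

The TSS metaprofile aggregates fragment midpoints over all genes in
TSS-relative coordinates (upstream always on the left, so minus-strand
genes are reversed) and normalises each bin to FPKM per gene. On active
chromatin it shows the canonical phasing: a -1 nucleosome, a
nucleosome-depleted region (NDR) just upstream of the TSS, and +1/+2/...
nucleosomes downstream.

The GC-quintile summary ranks fixed windows by sequence GC fraction,
splits them into five equal-count groups and summarises the FPKM
distribution per group and condition, exposing the coupling between GC
content and nucleosome occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .genome import GeneAnnotation, GenomeAssembly
from .occupancy import OccupancyTrack


@dataclass
class TssProfile:
    """Mean FPKM in fixed bins over [-flank, +flank) around the TSS."""

    flank: int
    bin: int
    values: np.ndarray        # per-bin FPKM per covering gene
    counts: np.ndarray        # raw midpoint counts per bin
    gene_coverage: np.ndarray  # genes whose (clipped) flank covers each bin
    n_genes: int
    total_fragments: int

    @property
    def offsets(self) -> np.ndarray:
        """Bin centers in bp relative to the TSS."""
        return -self.flank + self.bin * np.arange(len(self.values)) + self.bin / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_bp": self.offsets,
                             "value": self.values,
                             "n_genes_covering": self.gene_coverage})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def tss_metaprofile(fragments: FragmentSet, ann: GeneAnnotation,
                    genome: GenomeAssembly,
                    flank: int = 1000, bin: int = 10) -> TssProfile:
    """Aggregate fragment midpoints around every TSS, strand-aware.

    For each gene, midpoints within [TSS-flank, TSS+flank) are binned in
    TSS-relative coordinates; the axis is reversed for minus-strand genes
    so upstream is always left. The per-bin value is

        count / (bin_kb * total_fragments/1e6 * genes_covering_bin)

    Genes whose flank runs off a chromosome edge are clipped, and
    ``genes_covering_bin`` tracks, per bin, how many genes actually cover
    it, so truncated genes do not dilute edge bins.
    """
    if flank % bin != 0:
        raise ValueError("flank must be divisible by bin")
    if len(ann) == 0:
        raise ValueError("empty annotation")
    n_bins = 2 * flank // bin
    counts = np.zeros(n_bins, dtype=np.int64)
    coverage = np.zeros(n_bins, dtype=np.int64)
    for rec in ann:
        if rec.chrom not in genome:
            continue
        L = genome.length(rec.chrom)
        tss = rec.tss
        mids = fragments.midpoints(rec.chrom)
        if rec.strand == "+":
            rel = mids - tss
            lo_clip, hi_clip = -min(flank, tss), min(flank, L - tss)
        else:
            rel = tss - mids
            lo_clip, hi_clip = -min(flank, L - 1 - tss), min(flank, tss + 1)
        sel = (rel >= -flank) & (rel < flank)
        if sel.any():
            idx = (rel[sel] + flank) // bin
            counts += np.bincount(idx, minlength=n_bins)
        # bins fully inside the clipped flank count this gene as covering
        first = (lo_clip + flank) // bin
        last = (hi_clip + flank - 1) // bin  # inclusive
        coverage[first:last + 1] += 1
    per_million = fragments.total / 1e6
    bin_kb = bin / 1000.0
    if fragments.total == 0:
        values = np.zeros(n_bins)
    else:
        values = np.where(coverage > 0,
                          counts / (bin_kb * per_million * np.maximum(coverage, 1)),
                          0.0)
    return TssProfile(flank, bin, values, counts, coverage, len(ann),
                      fragments.total)


#: Default landmark search ranges, bp relative to the TSS.
NDR_RANGE = (-300, 100)
PLUS1_RANGE = (0, 300)
MINUS1_RANGE = (-400, 0)


def profile_landmarks(profile: TssProfile,
                      ndr_range: tuple[int, int] = NDR_RANGE,
                      plus1_range: tuple[int, int] = PLUS1_RANGE,
                      minus1_range: tuple[int, int] = MINUS1_RANGE,
                      ) -> dict[str, float]:
    """Locate the NDR trough and the -1/+1 nucleosome peaks.

    The NDR center is the offset of the minimum within `ndr_range`; the
    +1 (-1) peak is the maximum within `plus1_range` (`minus1_range`).
    Offsets are reported at bin centers. When several bins tie at the
    extremum — typical for an NDR, whose interior bins are all at the
    floor — the center of the longest contiguous run of tied bins is
    reported (isolated ties break toward the smaller offset; on a flat
    profile the landmark degenerates to the center of its search range).
    """
    if not np.any(profile.values > 0):
        raise ValueError("all-zero profile: no landmarks")
    offsets = profile.offsets

    def _extremum(lo: int, hi: int, kind: str) -> float:
        sel = np.flatnonzero((offsets >= lo) & (offsets < hi))
        if len(sel) == 0:
            raise ValueError(f"search range [{lo},{hi}) holds no bins")
        vals = profile.values[sel]
        target = vals.min() if kind == "min" else vals.max()
        tied = vals == target
        # longest run of tied bins; earliest run wins on equal length
        best_start = best_len = 0
        run_start = run_len = 0
        for i, t in enumerate(tied):
            if t:
                if run_len == 0:
                    run_start = i
                run_len += 1
                if run_len > best_len:
                    best_start, best_len = run_start, run_len
            else:
                run_len = 0
        mid = best_start + (best_len - 1) // 2
        return float(offsets[sel[mid]])

    return {"ndr_center": _extremum(*ndr_range, "min"),
            "plus1_peak": _extremum(*plus1_range, "max"),
            "minus1_peak": _extremum(*minus1_range, "max")}


def window_gc(genome: GenomeAssembly, grid) -> tuple[np.ndarray, np.ndarray]:
    """Per-window GC fraction and N fraction from genome sequence.

    N bases are excluded from both the numerator and the denominator of
    the GC fraction.
    """
    gc = np.full(grid.n_windows, np.nan)
    nfrac = np.zeros(grid.n_windows)
    for chrom, L in grid.chrom_lengths.items():
        seq = np.frombuffer(genome.fetch(chrom, 0, L).encode("ascii"), dtype=np.uint8)
        is_gc = (seq == ord("G")) | (seq == ord("C"))
        is_n = (seq == ord("N"))
        n, off, w = grid.n_windows_on(chrom), grid.offset(chrom), grid.width
        edges = np.arange(n, dtype=np.intp) * w
        gc_cnt = np.add.reduceat(is_gc.astype(np.int64), edges)
        n_cnt = np.add.reduceat(is_n.astype(np.int64), edges)
        lens = np.full(n, w, dtype=np.int64)
        lens[-1] = L - (n - 1) * w
        denom = lens - n_cnt
        gc[off:off + n] = np.where(denom > 0, gc_cnt / np.maximum(denom, 1), np.nan)
        nfrac[off:off + n] = n_cnt / lens
    return gc, nfrac


def gc_quintile_summary(tracks: dict[str, OccupancyTrack],
                        genome: GenomeAssembly,
                        max_n_fraction: float = 0.5) -> pd.DataFrame:
    """Summarise FPKM per GC quintile for each condition.

    Windows are ranked by GC fraction (stable sort, so equal-GC windows
    keep grid order) and split into five groups whose sizes differ by at
    most one. Windows with more than ``max_n_fraction`` N bases are
    dropped before ranking. One row per (quintile, condition) with the
    window count, GC range and the FPKM five-number summary plus mean.
    """
    if not tracks:
        raise ValueError("no tracks given")
    grids = [t.grid for t in tracks.values()]
    if not all(g.same_grid(grids[0]) for g in grids):
        raise ValueError("tracks are on different window grids")
    gc, nfrac = window_gc(genome, grids[0])
    keep = np.flatnonzero(~np.isnan(gc) & (nfrac <= max_n_fraction))
    order = keep[np.argsort(gc[keep], kind="stable")]
    groups = np.array_split(order, 5)
    rows = []
    for q, idx in enumerate(groups, start=1):
        for label, track in tracks.items():
            v = track.fpkm[idx]
            rows.append({
                "quintile": q, "condition": label, "n_windows": len(idx),
                "gc_min": float(gc[idx].min()) if len(idx) else np.nan,
                "gc_max": float(gc[idx].max()) if len(idx) else np.nan,
                "fpkm_min": float(np.min(v)) if len(idx) else np.nan,
                "fpkm_q1": float(np.percentile(v, 25)) if len(idx) else np.nan,
                "fpkm_median": float(np.median(v)) if len(idx) else np.nan,
                "fpkm_q3": float(np.percentile(v, 75)) if len(idx) else np.nan,
                "fpkm_max": float(np.max(v)) if len(idx) else np.nan,
                "fpkm_mean": float(np.mean(v)) if len(idx) else np.nan,
            })
    return pd.DataFrame(rows)
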