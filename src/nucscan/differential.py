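"""Bin-by-bin comparison of two occupancy tracks.

Two views, matching how comparative MNase-seq occupancy is scanned:

* a coarse categorical view (default 10-kb windows, 1.5-fold): every
  window is classified as increase in A, decrease in A, absent (no
  signal in either library) or other;
* a strict differential scan (default 500-bp windows, 2-fold): windows
  whose FPKM changes at least ``fold``-fold between conditions are
  selected, then mapped to genes whose body or promoter they overlap.

No hypothesis test is applied: selection is by pure fold-change
threshold, with a minimum-FPKM floor to suppress shot-noise calls on
near-empty windows (a 1-vs-0 count is a 2-fold change but carries no
evidence).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GeneAnnotation
from .occupancy import OccupancyTrack

CATEGORIES = ("increase_A", "decrease_A", "absent", "other")


def default_min_fpkm(total_fragments: int, width: int, min_count: int = 5) -> float:
    """FPKM floor equivalent to `min_count` fragments in one window.

    At library size ``total_fragments`` and window width ``width`` bp,
    this is the FPKM a window with `min_count` fragments would have —
    windows below it are dominated by shot noise.
    """
    return min_count / ((width / 1000.0) * (total_fragments / 1e6))


def _check_grids(track_a: OccupancyTrack, track_b: OccupancyTrack) -> None:
    if not track_a.grid.same_grid(track_b.grid):
        raise ValueError("tracks are on different window grids")


def classify_bins(track_a: OccupancyTrack, track_b: OccupancyTrack,
                  fold: float = 1.5) -> pd.DataFrame:
    """Classify every window of a shared grid by occupancy change.

    ``increase_A`` if fpkm_A >= fold * fpkm_B (and A > 0); ``decrease_A``
    if fpkm_B >= fold * fpkm_A (and B > 0); ``absent`` if both are zero;
    ``other`` otherwise. The fold boundary is inclusive. The categories
    partition the grid: every window gets exactly one.
    """
    _check_grids(track_a, track_b)
    a, b = track_a.fpkm, track_b.fpkm
    cat = np.full(len(a), CATEGORIES.index("other"), dtype=np.int64)
    cat[(a >= fold * b) & (a > 0)] = CATEGORIES.index("increase_A")
    cat[(b >= fold * a) & (b > 0)] = CATEGORIES.index("decrease_A")
    cat[(a == 0) & (b == 0)] = CATEGORIES.index("absent")
    df = track_a.grid.bounds()
    df["fpkm_A"] = a
    df["fpkm_B"] = b
    df["category"] = pd.Categorical.from_codes(cat, categories=list(CATEGORIES))
    return df


def category_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}


def differential_windows(track_a: OccupancyTrack, track_b: OccupancyTrack,
                         fold: float = 2.0,
                         min_fpkm: float | None = None) -> pd.DataFrame:
    """Select windows whose occupancy changes >= `fold`-fold.

    A window qualifies when max(fpkm_A, fpkm_B) / min(fpkm_A, fpkm_B)
    >= fold and max(fpkm_A, fpkm_B) >= min_fpkm. If exactly one value is
    zero the ratio is +infinity, so the window qualifies whenever the
    nonzero value clears the floor; windows with both values zero are
    excluded. Direction is ``up_in_A`` when A is larger, ``down_in_A``
    when B is larger.

    ``min_fpkm`` defaults to the FPKM of 5 fragments at the smaller of
    the two library sizes (the stricter floor of the two).
    """
    _check_grids(track_a, track_b)
    if min_fpkm is None:
        min_fpkm = default_min_fpkm(
            min(track_a.total_fragments, track_b.total_fragments),
            track_a.grid.width)
    a, b = track_a.fpkm, track_b.fpkm
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    with np.errstate(divide="ignore"):
        ratio = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    selected = (hi > 0) & (hi >= min_fpkm) & (ratio >= fold)
    df = track_a.grid.bounds()[selected].reset_index(drop=True)
    df["fpkm_A"] = a[selected]
    df["fpkm_B"] = b[selected]
    df["direction"] = np.where(a[selected] > b[selected], "up_in_A", "down_in_A")
    df["fold"] = ratio[selected]
    return df


def map_windows_to_genes(windows: pd.DataFrame, ann: GeneAnnotation,
                         scope: str = "promoter",
                         promoter_span: int = 1000) -> pd.DataFrame:
    """Map selected differential windows to overlapping genes.

    ``scope="genic"`` reports a gene when any window overlaps the
    transcript extended upstream by ``promoter_span`` (strand-aware), so
    genic = promoter + 5'UTR + exon + intron + 3'UTR. ``scope="promoter"``
    restricts the overlap to the promoter interval itself. Genes are
    deduplicated; a gene hit in both directions reports both.

    Returns a table (gene_id, directions, n_windows) sorted by gene id.
    """
    if scope not in ("genic", "promoter"):
        raise ValueError(f"unknown scope {scope!r}")
    wins_by_chrom = {c: g for c, g in windows.groupby("chrom")} if len(windows) else {}
    rows = []
    for rec in ann:
        grp = wins_by_chrom.get(rec.chrom)
        if grp is None:
            continue
        if scope == "promoter":
            gs, ge = rec.promoter(promoter_span)
        else:
            if rec.strand == "+":
                gs, ge = max(0, rec.tx_start - promoter_span), rec.tx_end
            else:
                gs, ge = rec.tx_start, rec.tx_end + promoter_span
        hit = (grp["start"].to_numpy() < ge) & (grp["end"].to_numpy() > gs)
        if hit.any():
            dirs = sorted(set(grp["direction"].to_numpy()[hit]))
            rows.append((rec.gene_id, ",".join(dirs), int(hit.sum())))
    out = pd.DataFrame(rows, columns=["gene_id", "directions", "n_windows"])
    if len(out):
        # a gene with several transcripts is reported once, directions merged
        out = (out.groupby("gene_id", as_index=False)
               .agg(directions=("directions",
                                lambda d: ",".join(sorted(set(",".join(d).split(","))))),
                    n_windows=("n_windows", "max"))
               .sort_values("gene_id", ignore_index=True))
    return out


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    """Export differential windows as BED6 (name=direction, score=100*fold capped at 1000)."""
    with open(path, "w") as fh:
        for row in windows.itertuples(index=False):
            score = 1000 if np.isinf(row.fold) else min(1000, round(100 * row.fold))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.direction}\t{score}\t.\n")
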