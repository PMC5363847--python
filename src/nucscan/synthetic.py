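"""Synthetic genomes, annotations and two-condition MNase-seq fragments.

Everything downstream of alignment can be exercised against known truth:
the generator plants phased nucleosomes around each TSS (a -1 dyad, a
nucleosome-depleted region, a +1 dyad and a regularly spaced background
array), couples dyad weight to local GC content, and multiplies dyad
weights inside chosen intervals or gene promoters for one condition to
create planted differential occupancy. Fragments are then drawn per
condition by weighted dyad choice with positional jitter and
truncated-normal lengths around the ~147-bp nucleosome core.

All randomness flows from ``SimulationSpec.seed``; per-condition fragment
streams are derived from (seed, condition label) so the two libraries are
independent but reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .fragments import FragmentSet
from .genome import GeneAnnotation, GeneRecord, GenomeAssembly

logger = logging.getLogger(__name__)

BASES_AT = np.frombuffer(b"AT", dtype=np.uint8)
BASES_GC = np.frombuffer(b"GC", dtype=np.uint8)

#: Weight multiplier for the positioned -1/+1 dyads relative to the
#: GC-modulated background weight at the same site.
FLANK_DYAD_BOOST = 2.0


@dataclass(frozen=True)
class PlantedEffect:
    """A condition-specific fold change on dyad weights.

    Target is either an explicit interval (chrom, start, end) or a gene
    id, in which case the gene's promoter is the target interval.
    """

    condition: str
    fold: float
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    gene_id: str | None = None

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold multiplier must be > 0")
        interval = self.chrom is not None and self.start is not None and self.end is not None
        if interval == (self.gene_id is not None):
            raise ValueError("give either (chrom, start, end) or gene_id")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic two-condition dataset.

    Defaults encode a nucleosome repeat length of 190 bp (147-bp core
    plus linker), an NDR of half-width 70 bp at each TSS with positioned
    -1/+1 dyads at -200/+120 bp, and fragment lengths of 147 +/- 10 bp
    truncated to [100, 200].
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 100_000
    gc_block_length: int = 1000
    gc_low: float = 0.35
    gc_high: float = 0.65
    n_genes: int = 20
    promoter_span: int = 1000
    spacing_mean: int = 190
    dyad_jitter_sd: float = 5.0
    ndr_halfwidth: int = 70
    plus1_offset: int = 120
    minus1_offset: int = -200
    gc_coupling: float = 1.0
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 10.0
    length_bounds: tuple[int, int] = (100, 200)
    depth: int = 100_000
    conditions: tuple[str, str] = ("A", "B")
    planted_effects: list[PlantedEffect] = field(default_factory=list)

    def __post_init__(self):
        for name in ("chrom_length", "gc_block_length", "spacing_mean",
                     "ndr_halfwidth", "promoter_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.gc_low <= 1 and 0 <= self.gc_high <= 1:
            raise ValueError("gc fractions must lie in [0, 1]")


def _condition_rng(spec: SimulationSpec, condition: str, salt: int = 0) -> np.random.Generator:
    mix = zlib.crc32(condition.encode()) ^ (salt * 0x9E3779B1)
    return np.random.default_rng((spec.seed * 1_000_003 + mix) % (2**31 - 1))


def simulate_genome(spec: SimulationSpec) -> GenomeAssembly:
    """Generate chromosomes of alternating GC-low / GC-high blocks.

    Block GC targets alternate strictly between ``gc_low`` and
    ``gc_high`` along each chromosome; bases are drawn i.i.d. within a
    block. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed % (2**31 - 1))
    seqs = {}
    for i in range(spec.n_chrom):
        L, w = spec.chrom_length, spec.gc_block_length
        arr = np.empty(L, dtype=np.uint8)
        for b, start in enumerate(range(0, L, w)):
            end = min(start + w, L)
            target = spec.gc_low if b % 2 == 0 else spec.gc_high
            n = end - start
            is_gc = rng.random(n) < target
            block = np.where(is_gc,
                             rng.choice(BASES_GC, size=n),
                             rng.choice(BASES_AT, size=n))
            arr[start:end] = block
        seqs[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return GenomeAssembly(sequences=seqs)


def simulate_annotation(genome: GenomeAssembly, spec: SimulationSpec) -> GeneAnnotation:
    """Place non-overlapping genes on both strands.

    Transcripts are separated by at least ``2 * promoter_span`` bp so
    promoters never collide; each gene has 1-3 exons and a valid CDS. If
    a chromosome cannot hold its share of genes, fewer are generated with
    a warning.
    """
    rng = np.random.default_rng((spec.seed + 1) % (2**31 - 1))
    records: list[GeneRecord] = []
    n_target = spec.n_genes
    if n_target == 0:
        return GeneAnnotation([])
    per_chrom = -(-n_target // max(1, len(genome.names)))
    gid = 0
    for chrom, L in genome.chromosomes:
        gap = 2 * spec.promoter_span
        cursor = gap
        placed = 0
        while placed < per_chrom and gid < n_target:
            tx_len = int(rng.integers(1500, 4000))
            if cursor + tx_len + gap > L:
                break
            tx_start = cursor + int(rng.integers(0, gap // 2))
            tx_end = tx_start + tx_len
            if tx_end + gap > L:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            # split the transcript into alternating exon/intron blocks
            cuts = np.sort(rng.choice(
                np.arange(tx_start + 100, tx_end - 100, 50),
                size=2 * (n_exons - 1), replace=False)) if n_exons > 1 else np.array([], int)
            bounds = np.concatenate(([tx_start], cuts, [tx_end]))
            exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1]))
                          for i in range(n_exons))
            exonic = sum(e - s for s, e in exons)
            # CDS strictly inside the first/last exon ends
            cds_start = exons[0][0] + int(rng.integers(50, min(300, exons[0][1] - exons[0][0])))
            cds_end = exons[-1][1] - int(rng.integers(50, min(300, exons[-1][1] - exons[-1][0])))
            if cds_start >= cds_end:
                cds_start, cds_end = exons[0][0], exons[-1][1]
            records.append(GeneRecord(f"gene{gid + 1:04d}", chrom, strand,
                                      tx_start, tx_end, cds_start, cds_end, exons))
            gid += 1
            placed += 1
            cursor = tx_end + gap
    if gid < n_target:
        logger.warning("simulate_annotation: placed %d of %d requested genes "
                       "(chromosomes too small)", gid, n_target)
    return GeneAnnotation(records)


class NucleosomeMap:
    """Ground-truth dyad positions with per-condition weights."""

    def __init__(self, positions: dict[str, np.ndarray],
                 weights: dict[str, dict[str, np.ndarray]],
                 conditions: Sequence[str],
                 chrom_lengths: dict[str, int] | None = None):
        if not conditions:
            raise ValueError("at least one condition required")
        self.conditions = tuple(conditions)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self.positions = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
        self.weights = {c: {k: np.asarray(w, dtype=float) for k, w in cw.items()}
                        for c, cw in weights.items()}
        for chrom, pos in self.positions.items():
            for cond in self.conditions:
                w = self.weights[chrom][cond]
                if len(w) != len(pos):
                    raise ValueError("weights/positions length mismatch")
                if np.any(w < 0):
                    raise ValueError("weights must be >= 0")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def total_weight(self, condition: str) -> float:
        return float(sum(w[condition].sum() for w in self.weights.values()))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\t" + "\t".join(
                f"weight_{c}" for c in self.conditions) + "\n")
            for chrom in self.positions:
                pos = self.positions[chrom]
                ws = [self.weights[chrom][c] for c in self.conditions]
                for i in range(len(pos)):
                    fh.write(f"{chrom}\t{pos[i]}\t"
                             + "\t".join(f"{w[i]:.6g}" for w in ws) + "\n")


def _local_gc(genome: GenomeAssembly, chrom: str, positions: np.ndarray,
              halfwidth: int = 73) -> np.ndarray:
    L = genome.length(chrom)
    seq = np.frombuffer(genome.fetch(chrom, 0, L).encode("ascii"), dtype=np.uint8)
    is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_gc)))
    lo = np.clip(positions - halfwidth, 0, L)
    hi = np.clip(positions + halfwidth + 1, 0, L)
    return (cum[hi] - cum[lo]) / np.maximum(hi - lo, 1)


def plant_nucleosome_map(genome: GenomeAssembly, ann: GeneAnnotation,
                         spec: SimulationSpec) -> NucleosomeMap:
    """Lay out ground-truth dyads with GC coupling, NDRs and planted effects.

    Background dyads are spaced ``spacing_mean`` bp apart with positional
    jitter; each dyad's base weight is ``max(0, 1 + gc_coupling * (local
    GC - 0.5))``. Dyads within ``ndr_halfwidth`` of any TSS get weight 0
    in every condition; strand-aware -1/+1 dyads are added at
    ``minus1_offset``/``plus1_offset`` from each TSS with
    ``FLANK_DYAD_BOOST`` times the base weight. Each planted effect then
    multiplies the weights of dyads inside its target interval for its
    condition only.
    """
    rng = np.random.default_rng((spec.seed + 2) % (2**31 - 1))
    genes_by_chrom = ann.by_chrom()
    positions: dict[str, np.ndarray] = {}
    weights: dict[str, dict[str, np.ndarray]] = {}
    for chrom, L in genome.chromosomes:
        base = np.arange(spec.spacing_mean // 2, L, spec.spacing_mean, dtype=np.int64)
        if spec.dyad_jitter_sd > 0:
            base = base + rng.normal(0, spec.dyad_jitter_sd, len(base)).round().astype(np.int64)
        base = np.clip(base, 0, L - 1)
        flank_pos, flank_strength = [], []
        tss_list = []
        for rec in genes_by_chrom.get(chrom, ()):
            tss = rec.tss
            tss_list.append(tss)
            sign = 1 if rec.strand == "+" else -1
            for off in (spec.plus1_offset, spec.minus1_offset):
                p = tss + sign * off
                if 0 <= p < L:
                    flank_pos.append(p)
                    flank_strength.append(FLANK_DYAD_BOOST)
        pos = np.concatenate((base, np.asarray(flank_pos, dtype=np.int64)))
        strength = np.concatenate((np.ones(len(base)),
                                   np.asarray(flank_strength, dtype=float)))
        order = np.argsort(pos, kind="stable")
        pos, strength = pos[order], strength[order]

        gc = _local_gc(genome, chrom, pos)
        w = strength * np.clip(1.0 + spec.gc_coupling * (gc - 0.5), 0.0, None)
        if tss_list:
            tss_arr = np.asarray(sorted(tss_list), dtype=np.int64)
            idx = np.searchsorted(tss_arr, pos)
            near = np.full(len(pos), np.iinfo(np.int64).max)
            left_ok = idx > 0
            near[left_ok] = np.abs(pos[left_ok] - tss_arr[idx[left_ok] - 1])
            right_ok = idx < len(tss_arr)
            near[right_ok] = np.minimum(near[right_ok],
                                        np.abs(pos[right_ok] - tss_arr[np.clip(idx[right_ok], 0, len(tss_arr) - 1)]))
            w = np.where(near <= spec.ndr_halfwidth, 0.0, w)
        positions[chrom] = pos
        weights[chrom] = {cond: w.copy() for cond in spec.conditions}

    gene_index = {rec.gene_id: rec for rec in ann}
    for eff in spec.planted_effects:
        if eff.gene_id is not None:
            rec = gene_index[eff.gene_id]
            chrom = rec.chrom
            start, end = rec.promoter(spec.promoter_span, genome.length(chrom))
        else:
            chrom, start, end = eff.chrom, eff.start, eff.end
        if chrom not in positions:
            continue
        pos = positions[chrom]
        inside = (pos >= start) & (pos < end)
        weights[chrom][eff.condition][inside] *= eff.fold
    return NucleosomeMap(positions, weights, spec.conditions,
                         dict(genome.chromosomes))


def simulate_fragments(nmap: NucleosomeMap, condition: str, depth: int,
                       spec: SimulationSpec) -> FragmentSet:
    """Draw `depth` fragments for one condition by weighted dyad choice.

    Each fragment's dyad is chosen with probability proportional to its
    weight, jittered by Normal(0, dyad_jitter_sd), given a
    truncated-normal length, and centered on the jittered dyad (the
    fragment midpoint equals the dyad when jitter and length spread are
    zero). Fragments are clipped to the chromosome. Deterministic given
    the spec seed and condition label.
    """
    if depth == 0:
        return FragmentSet({})
    total = nmap.total_weight(condition)
    if total <= 0:
        raise ValueError(f"no nucleosome signal for condition {condition!r}")
    rng = _condition_rng(spec, condition)
    chroms = nmap.chromosomes
    chrom_w = np.array([nmap.weights[c][condition].sum() for c in chroms])
    n_per = rng.multinomial(depth, chrom_w / chrom_w.sum())
    lo, hi = spec.length_bounds
    mu, sd = spec.fragment_length_mean, spec.fragment_length_sd
    out = {}
    for chrom, n in zip(chroms, n_per):
        if n == 0:
            continue
        pos, w = nmap.positions[chrom], nmap.weights[chrom][condition]
        p = w / w.sum() if w.sum() > 0 else None
        if p is None:
            continue
        dyads = rng.choice(pos, size=n, p=p)
        if spec.dyad_jitter_sd > 0:
            dyads = dyads + rng.normal(0, spec.dyad_jitter_sd, n).round().astype(np.int64)
        if sd > 0:
            lens = truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd,
                                 size=n, random_state=rng).round().astype(np.int64)
        else:
            lens = np.full(n, int(round(mu)), dtype=np.int64)
        starts = dyads - lens // 2
        ends = starts + lens
        starts = np.maximum(starts, 0)
        if nmap.chrom_lengths is not None:
            L = nmap.chrom_lengths[chrom]
            ends = np.minimum(ends, L)
            starts = np.minimum(starts, ends - 1)
        ends = np.maximum(ends, starts + 1)
        out[chrom] = np.column_stack((starts, ends))
    return FragmentSet(out)


def simulate_dataset(spec: SimulationSpec, outdir: str | Path | None = None):
    """End-to-end generation: genome, annotation, truth map, two fragment sets.

    When `outdir` is given, writes genome FASTA, annotation genePred TSV,
    one fragments BED per condition, and the ground truth beside the data
    (dyad map TSV and planted-effect BED).
    """
    genome = simulate_genome(spec)
    ann = simulate_annotation(genome, spec)
    nmap = plant_nucleosome_map(genome, ann, spec)
    frags = {cond: simulate_fragments(nmap, cond, spec.depth, spec)
             for cond in spec.conditions}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.write_fasta(outdir / "genome.fa")
        ann.write_genepred(outdir / "annotation.genePred")
        for cond, fs in frags.items():
            fs.write_bed(outdir / f"fragments_{cond}.bed")
        nmap.to_tsv(outdir / "truth_dyads.tsv")
        gene_index = {rec.gene_id: rec for rec in ann}
        with open(outdir / "truth_effects.bed", "w") as fh:
            for eff in spec.planted_effects:
                if eff.gene_id is not None:
                    rec = gene_index[eff.gene_id]
                    s, e = rec.promoter(spec.promoter_span, genome.length(rec.chrom))
                    fh.write(f"{rec.chrom}\t{s}\t{e}\t{eff.condition}:{eff.fold}\n")
                else:
                    fh.write(f"{eff.chrom}\t{eff.start}\t{eff.end}\t"
                             f"{eff.condition}:{eff.fold}\n")
    return genome, ann, nmap, frags
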