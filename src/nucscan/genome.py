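"""Genome assembly, gene annotation and the exclusive feature partition.

The genome is the coordinate system and GC-content source for every
downstream stage. The annotation (UCSC genePred/refFlat-style table)
supplies transcription start sites and the gene structure from which the
six-way exclusive partition of the genome — promoter, 5' UTR, exon,
intron, 3' UTR, intergenic — is derived. Every base receives exactly one
label, so feature percentages sum to 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Partition labels in precedence order (highest first). When features
#: overlap, the earlier label wins, so each base has one label.
FEATURE_LABELS = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")

_LABEL_CODE = {lab: i for i, lab in enumerate(FEATURE_LABELS)}
_INTERGENIC = _LABEL_CODE["intergenic"]


class GenomeAssembly:
    """Ordered chromosomes with lengths and random-access sequence.

    Backed either by an in-memory dict of sequences (synthetic genomes)
    or by a pyfaidx-indexed FASTA on disk.
    """

    def __init__(self, sequences: Mapping[str, str] | None = None,
                 lengths: Mapping[str, int] | None = None,
                 fasta=None):
        if sequences is not None:
            self._seqs = {name: str(s).upper() for name, s in sequences.items()}
            self._lengths = {name: len(s) for name, s in self._seqs.items()}
        elif fasta is not None:
            self._seqs = None
            self._fasta = fasta
            self._lengths = {name: len(fasta[name]) for name in fasta.keys()}
        elif lengths is not None:
            # lengths-only assembly: coordinate arithmetic works, fetch does not
            self._seqs = None
            self._fasta = None
            self._lengths = dict(lengths)
        else:
            raise ValueError("need sequences, a FASTA handle, or lengths")
        for name, length in self._lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        from pyfaidx import Fasta
        return cls(fasta=Fasta(str(path), sequence_always_upper=True))

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return list(self._lengths.items())

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def length(self, name: str) -> int:
        return self._lengths[name]

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def fetch(self, name: str, start: int, end: int) -> str:
        """Uppercase sequence of [start, end), 0-based half-open."""
        if not 0 <= start <= end <= self._lengths[name]:
            raise ValueError(f"{name}:{start}-{end} outside chromosome bounds")
        if self._seqs is not None:
            return self._seqs[name][start:end]
        if self._fasta is None:
            raise ValueError("assembly has no sequence (lengths only)")
        return str(self._fasta[name][start:end]).upper()

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f">{name}\n")
                seq = self.fetch(name, 0, length)
                for i in range(0, length, width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass(frozen=True)
class GeneRecord:
    """One transcript in UCSC genePred convention (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError("txStart must be < txEnd")

    @property
    def tss(self) -> int:
        """Transcription start site: txStart on +, txEnd-1 on - (last covered base)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def coding(self) -> bool:
        return self.cds_start < self.cds_end

    def promoter(self, span: int, chrom_length: int | None = None) -> tuple[int, int]:
        """Promoter interval: `span` bp immediately upstream of the TSS,
        strand-aware, clipped to the chromosome."""
        if self.strand == "+":
            start, end = self.tx_start - span, self.tx_start
        else:
            start, end = self.tx_end, self.tx_end + span
        start = max(start, 0)
        if chrom_length is not None:
            end = min(end, chrom_length)
        return start, max(start, end)


@dataclass
class GeneAnnotation:
    records: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.chrom, []).append(rec)
        return out

    def write_genepred(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                starts = ",".join(str(s) for s, _ in r.exons) + ","
                ends = ",".join(str(e) for _, e in r.exons) + ","
                fh.write("\t".join(map(str, (
                    r.gene_id, r.chrom, r.strand, r.tx_start, r.tx_end,
                    r.cds_start, r.cds_end, len(r.exons), starts, ends))) + "\n")


def _parse_block_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def load_annotation(path: str | Path,
                    genome: GenomeAssembly | None = None) -> GeneAnnotation:
    """Read a genePred/refFlat-style TSV into a :class:`GeneAnnotation`.

    Expected columns: name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds (UCSC 0-based half-open).
    Records with ``txStart >= txEnd`` are dropped with a warning; records
    on chromosomes absent from `genome` (when given) are dropped with a
    warning. Malformed lines raise a parse error naming the line number.
    """
    records: list[GeneRecord] = []
    n_invalid = n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            try:
                gene_id, chrom, strand = parts[0], parts[1], parts[2]
                tx_start, tx_end = int(parts[3]), int(parts[4])
                cds_start, cds_end = int(parts[5]), int(parts[6])
                n_exons = int(parts[7])
                starts = _parse_block_list(parts[8])
                ends = _parse_block_list(parts[9])
                if len(starts) != n_exons or len(ends) != n_exons:
                    raise ValueError("exon count does not match block lists")
                exons = tuple(zip(starts, ends))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed genePred line {lineno}: {exc}") from exc
            if tx_start >= tx_end:
                n_invalid += 1
                continue
            if genome is not None and chrom not in genome:
                n_unknown += 1
                continue
            records.append(GeneRecord(gene_id, chrom, strand, tx_start, tx_end,
                                      cds_start, cds_end, exons))
    if n_invalid:
        logger.warning("%s: dropped %d records with txStart >= txEnd", path, n_invalid)
    if n_unknown:
        logger.warning("%s: dropped %d records on chromosomes absent from genome",
                       path, n_unknown)
    return GeneAnnotation(records)


class FeaturePartition:
    """Exclusive tiling of every chromosome by the six feature labels.

    Stored as sorted, non-overlapping labeled intervals per chromosome
    that cover each chromosome exactly.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 chrom_lengths: dict[str, int]):
        # intervals[chrom] = (starts, ends, label_codes), tiling [0, L)
        self._ivals = intervals
        self._lengths = dict(chrom_lengths)
        for chrom, (s, e, c) in intervals.items():
            if len(s) == 0 or s[0] != 0 or e[-1] != self._lengths[chrom]:
                raise ValueError(f"partition does not tile {chrom}")
            if np.any(s[1:] != e[:-1]):
                raise ValueError(f"partition has gaps/overlaps on {chrom}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._ivals[chrom]

    def label_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Label code for each 0-based position (vectorised)."""
        starts, _, codes = self._ivals[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        return codes[idx]

    def base_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(FEATURE_LABELS, 0)
        for starts, ends, codes in self._ivals.values():
            widths = ends - starts
            for code, lab in enumerate(FEATURE_LABELS):
                counts[lab] += int(widths[codes == code].sum())
        return counts

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self._ivals:
                starts, ends, codes = self._ivals[chrom]
                for s, e, c in zip(starts, ends, codes):
                    fh.write(f"{chrom}\t{s}\t{e}\t{FEATURE_LABELS[c]}\n")


def _paint(arr: np.ndarray, start: int, end: int, code: int) -> None:
    start, end = max(0, start), min(len(arr), end)
    if start < end:
        arr[start:end] = code


def derive_feature_partition(ann: GeneAnnotation, genome: GenomeAssembly,
                             promoter_span: int = 1000) -> FeaturePartition:
    """Derive the exclusive six-way feature partition of the genome.

    The promoter is ``promoter_span`` bp immediately upstream of each TSS
    (strand-aware, clipped to the chromosome). 5' UTR bases are exonic
    bases between the transcript start side and the CDS start; 3' UTR is
    symmetric on the other side; exon keeps the CDS-overlapping exonic
    bases; intron is intragenic non-exonic; everything else is
    intergenic. Overlaps between features (within or across transcripts)
    are resolved per base by the precedence
    promoter > utr5 > utr3 > exon > intron > intergenic.
    Non-coding transcripts (cdsStart == cdsEnd) contribute exon labels
    only, no UTRs.
    """
    if promoter_span <= 0:
        raise ValueError("promoter_span must be positive")

    # collect intervals per label per chromosome, then paint in ascending
    # precedence so higher-precedence labels overwrite lower ones
    per_label: dict[str, dict[str, list[tuple[int, int]]]] = {
        lab: {} for lab in FEATURE_LABELS[:-1]}
    n_dropped = 0
    for rec in ann:
        if rec.chrom not in genome:
            n_dropped += 1
            continue
        L = genome.length(rec.chrom)
        add = lambda lab, s, e: per_label[lab].setdefault(rec.chrom, []).append(
            (max(0, s), min(L, e)))
        add("intron", rec.tx_start, rec.tx_end)
        if rec.coding:
            if rec.strand == "+":
                utr_left, utr_right = "utr5", "utr3"
            else:
                utr_left, utr_right = "utr3", "utr5"
            for es, ee in rec.exons:
                if es < rec.cds_start:
                    add(utr_left, es, min(ee, rec.cds_start))
                if ee > rec.cds_end:
                    add(utr_right, max(es, rec.cds_end), ee)
                cs, ce = max(es, rec.cds_start), min(ee, rec.cds_end)
                if cs < ce:
                    add("exon", cs, ce)
        else:
            for es, ee in rec.exons:
                add("exon", es, ee)
        ps, pe = rec.promoter(promoter_span, L)
        if ps < pe:
            add("promoter", ps, pe)
    if n_dropped:
        logger.warning("derive_feature_partition: dropped %d records on "
                       "chromosomes absent from genome", n_dropped)

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, L in genome.chromosomes:
        arr = np.full(L, _INTERGENIC, dtype=np.uint8)
        for lab in reversed(FEATURE_LABELS[:-1]):  # intron first, promoter last
            for s, e in per_label[lab].get(chrom, ()):
                _paint(arr, s, e, _LABEL_CODE[lab])
        # compress the per-base array into labeled run intervals
        breaks = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [L]))
        intervals[chrom] = (starts.astype(np.int64), ends.astype(np.int64),
                            arr[starts].astype(np.int64))
    return FeaturePartition(intervals, dict(genome.chromosomes))


def compute_genome_ratios(partition: FeaturePartition) -> pd.DataFrame:
    """Fraction of the genome covered by each feature label.

    Returns a table with columns ``label``, ``bases``, ``percent``; the
    percentages sum to 100 (up to rounding).
    """
    counts = partition.base_counts()
    total = sum(counts.values())
    return pd.DataFrame({
        "label": list(FEATURE_LABELS),
        "bases": [counts[lab] for lab in FEATURE_LABELS],
        "percent": [100.0 * counts[lab] / total for lab in FEATURE_LABELS],
    })
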