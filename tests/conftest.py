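import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucscan import (FragmentSet, GeneAnnotation, GeneRecord, GenomeAssembly,
                     SimulationSpec, derive_feature_partition,
                     simulate_dataset)

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked_genome():
    """10-kb single-chromosome genome with a fixed random sequence."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return GenomeAssembly(sequences={"chr1": seq})


@pytest.fixture(scope="session")
def worked_gene():
    """Plus-strand gene: tx [2000,5000), cds [2500,4500), two exons."""
    return GeneRecord("geneA", "chr1", "+", 2000, 5000, 2500, 4500,
                      ((2000, 3000), (4000, 5000)))


@pytest.fixture(scope="session")
def worked_partition(worked_genome, worked_gene):
    """Hand-tileable partition: promoter 1000, utr5 500, exon 1000,
    intron 1000, utr3 500, intergenic 6000 bp."""
    return derive_feature_partition(GeneAnnotation([worked_gene]),
                                    worked_genome, promoter_span=1000)


@pytest.fixture(scope="session")
def small_dataset():
    """Small end-to-end synthetic dataset (100 kb, 10 genes, 20k fragments)."""
    spec = SimulationSpec(seed=5, chrom_length=100_000, n_genes=10,
                          depth=20_000)
    genome, ann, nmap, frags = simulate_dataset(spec)
    return spec, genome, ann, nmap, frags


# ---- coordinate-mirror helpers (shared by symmetry tests) ----

def mirror_record(rec: GeneRecord, L: int) -> GeneRecord:
    exons = tuple(sorted((L - e, L - s) for s, e in rec.exons))
    return GeneRecord(rec.gene_id, rec.chrom,
                      "-" if rec.strand == "+" else "+",
                      L - rec.tx_end, L - rec.tx_start,
                      L - rec.cds_end, L - rec.cds_start, exons)


def mirror_annotation(ann: GeneAnnotation, L: int) -> GeneAnnotation:
    return GeneAnnotation([mirror_record(r, L) for r in ann])


def mirror_genome(genome: GenomeAssembly) -> GenomeAssembly:
    return GenomeAssembly(sequences={
        name: genome.fetch(name, 0, length)[::-1]
        for name, length in genome.chromosomes})


def mirror_fragments(fs: FragmentSet, lengths: dict[str, int]) -> FragmentSet:
    return FragmentSet({
        chrom: np.column_stack((lengths[chrom] - arr[:, 1],
                                lengths[chrom] - arr[:, 0]))
        for chrom in fs.chromosomes
        for arr in [fs.intervals(chrom)]})
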