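"""Synthetic genomes, annotations, nucleosome maps and fragment sampling."""

import numpy as np
import pytest

from nucscan import (GeneAnnotation, NucleosomeMap, PlantedEffect,
                     SimulationSpec, load_annotation, plant_nucleosome_map,
                     simulate_annotation, simulate_dataset,
                     simulate_fragments, simulate_genome)


class TestSimulateGenome:
    def test_equal_gc_levels_give_uniform_blocks(self):
        spec = SimulationSpec(seed=1, chrom_length=20_000, gc_low=0.5, gc_high=0.5)
        genome = simulate_genome(spec)
        seq = genome.fetch("chr1", 0, 20_000)
        for start in range(0, 20_000, 1000):
            block = seq[start:start + 1000]
            gc = (block.count("G") + block.count("C")) / 1000
            assert abs(gc - 0.5) < 0.05  # ~3 binomial sd at n=1000

    def test_zero_gc_blocks_are_pure_at(self):
        spec = SimulationSpec(seed=1, chrom_length=4000, gc_low=0.0, gc_high=1.0)
        seq = simulate_genome(spec).fetch("chr1", 0, 4000)
        assert set(seq[0:1000]) <= set("AT")       # even blocks at gc_low
        assert set(seq[1000:2000]) <= set("GC")    # odd blocks at gc_high

    def test_seed_determinism(self):
        spec = SimulationSpec(seed=9, chrom_length=5000)
        g1, g2 = simulate_genome(spec), simulate_genome(spec)
        assert g1.fetch("chr1", 0, 5000) == g2.fetch("chr1", 0, 5000)


class TestSimulateAnnotation:
    def test_zero_genes(self):
        spec = SimulationSpec(seed=1, chrom_length=10_000, n_genes=0)
        genome = simulate_genome(spec)
        assert len(simulate_annotation(genome, spec)) == 0

    def test_reproducible_and_roundtrips_through_genepred(self, tmp_path):
        spec = SimulationSpec(seed=3, chrom_length=100_000, n_genes=10)
        genome = simulate_genome(spec)
        ann1 = simulate_annotation(genome, spec)
        ann2 = simulate_annotation(genome, spec)
        assert ann1.records == ann2.records
        path = tmp_path / "ann.genePred"
        ann1.write_genepred(path)
        assert load_annotation(path, genome).records == ann1.records

    def test_structure_invariants_and_spacing(self):
        spec = SimulationSpec(seed=3, chrom_length=200_000, n_genes=20)
        genome = simulate_genome(spec)
        ann = simulate_annotation(genome, spec)
        assert len(ann) == 20
        prev_end = -10_000
        for rec in sorted(ann, key=lambda r: r.tx_start):
            assert rec.tx_start - prev_end >= 2 * spec.promoter_span
            assert rec.exons[0][0] == rec.tx_start
            assert rec.exons[-1][1] == rec.tx_end
            assert rec.tx_start <= rec.cds_start < rec.cds_end <= rec.tx_end
            for (s1, e1), (s2, e2) in zip(rec.exons, rec.exons[1:]):
                assert s1 < e1 <= s2 < e2
            prev_end = rec.tx_end
        strands = {r.strand for r in ann}
        assert strands == {"+", "-"}


class TestPlantNucleosomeMap:
    def test_no_genes_no_coupling_all_weights_equal(self):
        spec = SimulationSpec(seed=2, chrom_length=50_000, n_genes=0,
                              gc_coupling=0.0)
        genome = simulate_genome(spec)
        nmap = plant_nucleosome_map(genome, GeneAnnotation([]), spec)
        w = nmap.weights["chr1"]["A"]
        assert np.allclose(w, w[0]) and w[0] > 0

    def test_dyads_inside_ndr_have_zero_weight(self):
        spec = SimulationSpec(seed=2, chrom_length=100_000, n_genes=5)
        genome = simulate_genome(spec)
        ann = simulate_annotation(genome, spec)
        nmap = plant_nucleosome_map(genome, ann, spec)
        pos = nmap.positions["chr1"]
        w = nmap.weights["chr1"]["A"]
        for rec in ann:
            near = np.abs(pos - rec.tss) <= spec.ndr_halfwidth
            assert (w[near] == 0).all()

    def test_planted_fold_is_exact_on_weights(self):
        effect = PlantedEffect(condition="B", fold=3.0, chrom="chr1",
                               start=10_000, end=12_000)
        spec = SimulationSpec(seed=2, chrom_length=50_000, n_genes=0,
                              planted_effects=[effect])
        genome = simulate_genome(spec)
        nmap = plant_nucleosome_map(genome, GeneAnnotation([]), spec)
        pos = nmap.positions["chr1"]
        inside = (pos >= 10_000) & (pos < 12_000)
        wa = nmap.weights["chr1"]["A"][inside]
        wb = nmap.weights["chr1"]["B"][inside]
        assert inside.sum() > 0
        assert np.allclose(wb, 3.0 * wa)
        outside = ~inside
        assert np.allclose(nmap.weights["chr1"]["B"][outside],
                           nmap.weights["chr1"]["A"][outside])

    def test_promoter_targeted_effect_by_gene_id(self):
        spec0 = SimulationSpec(seed=4, chrom_length=100_000, n_genes=5)
        genome = simulate_genome(spec0)
        ann = simulate_annotation(genome, spec0)
        gene = ann.records[0]
        spec = SimulationSpec(seed=4, chrom_length=100_000, n_genes=5,
                              planted_effects=[PlantedEffect(
                                  condition="B", fold=2.5, gene_id=gene.gene_id)])
        nmap = plant_nucleosome_map(genome, ann, spec)
        ps, pe = gene.promoter(spec.promoter_span, 100_000)
        pos = nmap.positions[gene.chrom]
        inside = (pos >= ps) & (pos < pe)
        wa = nmap.weights[gene.chrom]["A"][inside]
        wb = nmap.weights[gene.chrom]["B"][inside]
        assert np.allclose(wb, 2.5 * wa)


class TestSimulateFragments:
    @pytest.fixture
    def flat_map(self):
        spec = SimulationSpec(seed=2, chrom_length=50_000, n_genes=0)
        genome = simulate_genome(spec)
        return spec, plant_nucleosome_map(genome, GeneAnnotation([]), spec)

    def test_zero_depth(self, flat_map):
        spec, nmap = flat_map
        assert simulate_fragments(nmap, "A", 0, spec).total == 0

    def test_exact_depth_and_mean_length(self, flat_map):
        spec, nmap = flat_map
        fs = simulate_fragments(nmap, "A", 10_000, spec)
        assert fs.total == 10_000
        ivals = fs.intervals("chr1")
        mean_len = (ivals[:, 1] - ivals[:, 0]).mean()
        assert abs(mean_len - 147) < 1.0  # CLT bound, sd 10, n 1e4

    def test_weighted_two_dyad_split(self):
        spec = SimulationSpec(seed=6, dyad_jitter_sd=0.0, fragment_length_sd=0.0)
        nmap = NucleosomeMap({"chr1": np.array([1000, 5000])},
                             {"chr1": {"A": np.array([1.0, 3.0]),
                                       "B": np.array([1.0, 1.0])}},
                             conditions=("A", "B"),
                             chrom_lengths={"chr1": 10_000})
        fs = simulate_fragments(nmap, "A", 40_000, spec)
        mids = fs.midpoints("chr1")
        n_low = int((mids == 1000).sum())
        sd = np.sqrt(40_000 * 0.25 * 0.75)
        assert abs(n_low - 10_000) < 3 * sd
        assert n_low + (mids == 5000).sum() == 40_000

    def test_midpoints_equal_dyads_without_jitter(self, flat_map):
        spec, nmap = flat_map
        exact = SimulationSpec(seed=2, chrom_length=50_000, n_genes=0,
                               dyad_jitter_sd=0.0, fragment_length_sd=0.0)
        nmap0 = plant_nucleosome_map(simulate_genome(exact), GeneAnnotation([]),
                                     exact)
        fs = simulate_fragments(nmap0, "A", 5000, exact)
        mids = np.unique(fs.midpoints("chr1"))
        assert np.isin(mids, nmap0.positions["chr1"]).all()

    def test_zero_weight_condition_rejected(self):
        spec = SimulationSpec(seed=1)
        nmap = NucleosomeMap({"chr1": np.array([100])},
                             {"chr1": {"A": np.array([0.0])}}, conditions=("A",))
        with pytest.raises(ValueError, match="no nucleosome signal"):
            simulate_fragments(nmap, "A", 10, spec)


class TestDatasetDeterminism:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        spec = SimulationSpec(seed=8, chrom_length=30_000, n_genes=3, depth=2000)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        simulate_dataset(spec, d1)
        simulate_dataset(spec, d2)
        for name in ("genome.fa", "annotation.genePred", "fragments_A.bed",
                     "fragments_B.bed", "truth_dyads.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_files_emitted_beside_data(self, tmp_path):
        effect = PlantedEffect(condition="B", fold=2.0, chrom="chr1",
                               start=0, end=500)
        spec = SimulationSpec(seed=8, chrom_length=10_000, n_genes=0,
                              depth=100, planted_effects=[effect])
        simulate_dataset(spec, tmp_path)
        assert (tmp_path / "truth_dyads.tsv").exists()
        assert "chr1\t0\t500\tB:2.0" in (tmp_path / "truth_effects.bed").read_text()
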