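"""Run the whole comparison from files, the way the CLI does.

Writes a synthetic dataset to disk, then runs the end-to-end pipeline
(coverage, coarse classification, differential windows, feature ratios,
GC quintiles, TSS profiles and gene lists) and prints the manifest of
outputs. Equivalent shell command:

    nucscan simulate --seed 5 --outdir scratch/pipe_data
    nucscan run --genome ... --annotation ... \
        --fragments-a A ... --fragments-b B ... --outdir scratch/pipe_out
"""

import json
from pathlib import Path

import nucscan as ns

data = Path("scratch/pipe_data")
spec = ns.SimulationSpec(seed=5, chrom_length=100_000, n_genes=10,
                         depth=50_000)
ns.simulate_dataset(spec, data)

cfg = ns.RunConfig(
    genome_fasta=str(data / "genome.fa"),
    annotation=str(data / "annotation.genePred"),
    fragments={"A": str(data / "fragments_A.bed"),
               "B": str(data / "fragments_B.bed")},
    outdir="scratch/pipe_out")
manifest = ns.run_compare(cfg)

print("outputs written:")
for name in manifest["outputs"]:
    print("  ", name)
coverage = Path("scratch/pipe_out/coverage.tsv").read_text()
print("\ncoverage.tsv:")
print(coverage)
landmarks = json.loads(Path("scratch/pipe_out/tss_landmarks.json").read_text())
print("TSS landmarks per condition:", landmarks)
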