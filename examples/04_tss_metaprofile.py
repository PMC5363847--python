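"""Average nucleosome occupancy around transcription start sites.

Pools fragment midpoints over all genes in TSS-relative coordinates
(strand-aware: upstream is always left), normalises each 10-bp bin to
FPKM per covering gene, and calls the phasing landmarks. The generator
plants an NDR centered on the TSS with positioned dyads at -200 and
+120 bp, so the called landmarks should land within a bin or two of
those offsets.
"""

import nucscan as ns

spec = ns.SimulationSpec(seed=4, chrom_length=400_000, n_genes=50,
                         depth=200_000)
genome, ann, nmap, frags = ns.simulate_dataset(spec)

for cond in ("A", "B"):
    profile = ns.tss_metaprofile(frags[cond], ann, genome, flank=1000, bin=10)
    lm = ns.profile_landmarks(profile)
    print(f"condition {cond}: NDR center {lm['ndr_center']:+.0f} bp, "
          f"-1 peak {lm['minus1_peak']:+.0f} bp, "
          f"+1 peak {lm['plus1_peak']:+.0f} bp "
          f"(planted: 0 / {spec.minus1_offset:+d} / {spec.plus1_offset:+d})")

profile = ns.tss_metaprofile(frags["A"], ann, genome)
df = profile.to_frame()
peak = df.loc[df.value.idxmax()]
print(f"\nhighest bin: offset {peak.offset_bp:+.0f} bp, "
      f"FPKM {peak.value:.1f} over {profile.n_genes} genes")
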