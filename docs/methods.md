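# Methods

## Model and quantities

`nucscan` treats aligned mononucleosome fragments as the unit of
evidence: one sequenced read pair = one fragment = one nucleosome
footprint. Occupancy over any region is the normalised fragment density

    FPKM = count / ((region length in kb) · (library fragments / 10^6)),

the fragment-based analogue of RPKM; the two names are used
interchangeably in the MNase-seq literature and all outputs here are
labelled FPKM. The denominator is always the *library* total (all
fragments read for that condition), not the number of fragments assigned
to the analysed regions, so tracks from libraries of different depth are
directly comparable.

### Fragment-to-window assignment

How a fragment spanning a window boundary is counted is a genuine choice:

- **midpoint** (default): a fragment counts once, in the window holding
  its midpoint base `floor((start+end)/2)`. Total mass is conserved
  (Σ window counts = total fragments), windows are disjoint samples, and
  differential statistics are well defined.
- **overlap**: a fragment adds 1 to every window it touches. Available
  behind a flag for comparability with pileup-style pipelines; it
  double-counts boundary fragments.

Trailing windows shorter than the nominal width are normalised by their
true length, never padded.

### Differential occupancy

Two views mirror how comparative occupancy is usually scanned:

1. a 10-kb categorical view at 1.5-fold: each bin is `increase_A`
   (FPKM_A ≥ 1.5·FPKM_B, A > 0), `decrease_A` (symmetric), `absent`
   (both exactly 0) or `other`; the boundary is inclusive and the
   categories partition the grid;
2. a 500-bp selection at 2-fold: windows with
   max(FPKM)/min(FPKM) ≥ 2 and max(FPKM) ≥ `min_fpkm`.

Selection is by pure fold change — no hypothesis test, no multiple-
testing correction, and no p-values are produced. The `min_fpkm` floor
exists because fold change alone is meaningless at the shot-noise floor
(1 fragment vs 0 is "2-fold"): the default floor is the FPKM equivalent
of 5 fragments in one window, computed from the smaller of the two
library sizes (the stricter of the two floors). When exactly one value
is zero and the other clears the floor, the window qualifies with fold
reported as infinity; windows empty in both libraries are excluded.

Selected windows map to genes by interval overlap: *genic* scope uses
the transcript extended upstream by the promoter span (strand-aware), so
genic = promoter + 5'UTR + exon + intron + 3'UTR; *promoter* scope uses
only the promoter interval. A window overlapping two genes reports both;
a gene hit in both directions reports both directions.

### Feature partition

Every base receives exactly one of six labels. The promoter is the
`promoter_span` bases (default 1000) immediately upstream of the TSS,
strand-aware and clipped at chromosome ends; 5'UTR = exonic bases
between the transcript start side and the CDS start (strand-aware), 3'UTR
symmetric; exon = CDS-overlapping exonic bases; intron = remaining
intragenic bases; intergenic = the rest. Overlaps within or across
transcripts resolve per base by precedence
promoter > utr5 > utr3 > exon > intron > intergenic, which makes the
partition independent of record order and lets feature percentages sum
to 100. Non-coding transcripts (cdsStart == cdsEnd) contribute exon
labels only. There is no isoform collapsing beyond this per-base
precedence, and no alternative-promoter handling.

The per-base precedence is resolved by painting labels onto a uint8
array per chromosome, then compressing runs to intervals. This is
simple and exact but allocates one byte per base, which is fine at the
megabase scales this package targets; a gigabase genome would want an
interval-algebra implementation instead.

### TSS metaprofile and landmarks

Fragment midpoints within ±`flank` (default 1000 bp) of each TSS are
binned at `bin` bp (default 10) in TSS-relative coordinates, with the
axis reversed for minus-strand genes so upstream is always left. The
per-bin value is

    count / (bin_kb · library/10^6 · genes covering the bin),

i.e. pooled counts normalised per covering gene. Genes whose flank runs
off a chromosome end are clipped rather than dropped, and the per-bin
gene coverage keeps truncated genes from diluting edge bins (relevant on
the short synthetic chromosomes; negligible on real genomes).

Landmarks are called from the profile: the NDR center is the minimum
within [−300, +100), the +1 peak the maximum within [0, +300), the −1
peak the maximum within [−400, 0), all reported at bin centers and all
ranges configurable. When several bins tie at the extremum — an NDR
interior is typically a plateau of zero bins — the center of the longest
run of tied bins is reported (earliest run on equal length). Isolated
ties therefore break toward the smaller offset, and a flat profile
degenerates to the center of the search range.

### GC stratification

Per-window GC is computed from sequence with N bases excluded from both
numerator and denominator; windows over 50% N are dropped. Windows are
ranked by GC with a stable sort (equal-GC windows keep grid order — the
degenerate all-equal case still yields equal-count groups) and split
into five groups whose sizes differ by at most one; each group's FPKM
distribution is summarised (five-number summary plus mean) per condition.

### Coverage rate

Fraction of genome bases covered by at least one fragment (per-base
union; overlaps count once). This per-base definition is recorded in the
output metadata, since "coverage rate" is sometimes computed per window.

## Synthetic data generator

The generator emulates the structure the analysis is designed to detect,
with all randomness derived from one seed (per-condition fragment
streams are sub-seeded from (seed, condition label), so conditions are
independent but jointly reproducible):

- **Genome**: blocks of `gc_block_length` (default 1000 bp) whose target
  GC alternates between `gc_low` and `gc_high` (defaults 0.35/0.65);
  bases i.i.d. within a block. Alternation, rather than a per-block
  draw, keeps the degenerate cases exact (equal levels → uniform genome;
  `gc_low=0` → pure-AT blocks).
- **Annotation**: non-overlapping genes on both strands, 1–3 exons,
  valid CDS, at least `2 × promoter_span` between transcripts so
  promoters never collide.
- **Nucleosome map**: background dyads every `spacing_mean` bp (default
  190 ≈ 147-bp core + linker) with positional jitter; dyad weight
  `max(0, 1 + gc_coupling · (local GC − 0.5))` with local GC over ±73 bp
  (one nucleosome footprint); dyads within `ndr_halfwidth` (default
  70 bp) of any TSS are silenced; positioned −1/+1 dyads at −200/+120 bp
  from each TSS (strand-aware) carry 2× the GC-modulated base weight —
  enough to make the peaks unambiguous against background without
  dwarfing it. Planted effects multiply dyad weights inside a target
  interval (or a gene's promoter) for one condition only; because
  effects act on weights, not on read counts, realized FPKM fold changes
  scatter around the planted fold with sampling noise.
- **Fragments**: weighted dyad choice, Normal(0, `dyad_jitter_sd`)
  positional jitter, truncated-normal lengths (147 ± 10 bp, bounded to
  [100, 200], matching mononucleosome insert sizes), fragment centered
  on the jittered dyad and clipped to the chromosome. With jitter and
  length spread at zero, every fragment midpoint equals its dyad
  exactly, which is what makes exact counting oracles possible.

What the generator does **not** model — and hence what passing tests do
not establish about real data: MNase sequence preference (the enzyme's
AT-biased cutting), mappability and duplicate structure, di-nucleosome
contamination, sub-nucleosomal particles, copy-number variation, and
any dependence between GC content and gene density. Results on real
libraries additionally depend on alignment quality, which is upstream of
this package.

## Defaults and scales

| parameter | default | why |
|---|---|---|
| coarse / fine window | 10 kb / 500 bp | the two scan scales of the analysis |
| fold thresholds | 1.5 (coarse) / 2.0 (fine) | categorical view vs strict selection |
| promoter span | 1000 bp | matches the ±1-kb TSS analysis scale; configurable |
| TSS flank / bin | 1000 bp / 10 bp | phasing features are 100–200 bp wide |
| min_fpkm | FPKM of 5 fragments | smallest count where 2-fold is distinguishable from shot noise |
| pair length bounds | [50, 500] bp | outside = mispair or di-nucleosome |
| nucleosome spacing | 190 bp | 147-bp core + linker |
| fragment length | 147 ± 10, [100, 200] | mononucleosome insert distribution |

Validation runs use desk-scale problem sizes chosen so each property is
measured with comfortable statistical margin: counting oracles on 100-kb
genomes with 10^4 fragments; differential recovery and GC coupling on a
1-Mb genome at 3×10^5 fragments per condition (~150 fragments per 500-bp
window, so a planted 3-fold change is ~10 sampling sd from null while a
2-fold sampling excursion is a >5 sd Poisson event — recovery and
false-positive bounds follow binomially); TSS landmarks over 50 genes at
2×10^5 fragments. The full analysis of a real mammalian-scale dataset is
the same code path; only the array sizes grow.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere (genePred and BED are
  native to this convention); the TSS of a minus-strand transcript is
  `txEnd − 1`, the last covered base.
- Midpoints use floor division, making counting integer-exact; FPKM is
  the only floating-point quantity and is checked against the hand
  formula to 1e-9.
- Records with inverted coordinates, unknown chromosomes or out-of-bound
  pairs are dropped with logged counts, never silently: the headline
  outputs (window counts, gene-list sizes) are filter-sensitive, so every
  filter reports what it removed.
- Empty libraries are an error for FPKM (division by zero has no
  sensible value); an empty fragment set is fine everywhere else and
  yields zero tracks/profiles.
- `classify_bins` categories are provably exclusive: `increase_A` and
  `decrease_A` can only both hold when both values are 0, which the
  `absent` rule captures first.

## Known limitations

- No nucleosome calling (dyad inference à la DANPOS/nucleR): the
  analysis is window-level by design.
- No GTF/GFF3 input in v1; genePred/refFlat only.
- No BAM ingest in the core path; `pairs_to_fragments` joins mates that
  an upstream step extracted (BED3 is the interchange format).
- The per-base partition array limits practical genome size to a few
  hundred Mb of memory headroom (see above).
- GO enrichment itself is out of scope; the gene lists are formatted for
  external enrichment tools.
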