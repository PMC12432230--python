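# l1select

Design PCR primers that preferentially amplify **individual subfamilies of a
highly homologous repeat lineage**, and validate their selectivity in
silico. The motivating case is the human LINE1 L1PA lineage: ~18 subfamilies
(L1HS youngest → L1PA17 oldest) that share most of their ~6 kb sequence yet
each carry private consensus substitutions. Those subfamily-discriminating
bases are the substrate of selective primer design; this package automates
finding them and turning them into validated primer pairs.

Intended users: molecular biologists and genomicists who want qPCR/ChIP-qPCR
handles on specific retrotransposon subfamilies, and anyone needing a
scriptable in-silico PCR with on/off-target accounting against a repeat
annotation.

## What it does

1. **Diagnostics** — align subfamily consensuses (built-in star-progressive
   Needleman–Wunsch, or accept an external Clustal Omega/MAFFT MSA) and find
   *discriminating columns*: positions where the target subfamily's base
   differs from every other compared subfamily. Enumerate candidate regions
   ≤200 bp with discriminating bases at both ends.
2. **Primer design** — enumerate footprint placements in those regions under
   length (18–22 nt), %GC (35–60) and Tm constraints; every primer covers at
   least one discriminating base. %GC = 100·(G+C)/len; Tm by the Wallace 2-4
   rule or nearest-neighbour ΔH/ΔS (SantaLucia unified parameters).
3. **In-silico PCR** — mismatch-tolerant, 3'-anchored binding-site search
   (Hamming distance ≤ `max_mismatch`, exact match over the 3'-terminal
   `anchor_len` bases) on both strands, paired into predicted amplicons
   within a product-size window. An exhaustive brute-force oracle guards the
   fast anchor-indexed implementation.
4. **Selectivity scoring** — assign each amplicon to the annotation category
   with the largest base-pair overlap (per-subfamily, `other_LINE1`,
   `non_LINE1`); report counts, percentages, and the top-2 subfamily share.
5. **Validation analytics** — amplicon-seq style readout: per-category
   fragment fractions, amplified-locus calling (merged intervals supported
   by ≥3 fragments), intersection with the four standard annotation tracks
   (all LINE1 / non-LINE1 complement / full-length >6 kb / full-length &
   intact), and per-subfamily FPKM summation,
   FPKM = 10⁹·count/(length·total).
6. **Synthetic lineage simulator** — a seeded generator of consensus chains,
   genomes with planted diverged and 5'-truncated copies, matching
   annotation, and weighted fragment sets, so the entire pipeline is
   testable without downloading genomes.

The package also ships the six published L1PA subfamily-selective primer
pairs (`l1select.load_reference_primers()`).

## Worked example

`examples/04_selectivity_report.py` runs the full loop on a synthetic
lineage (6 subfamilies, 7 kb consensus, 2% divergence per lineage step,
30 copies per subfamily at 3% private divergence) and scores the best
designed pair:

```
target subfamily: L1SIM1 (adjacent: L1SIM2)
best pair: F 5'-GGGAAAGGGGTCGATTTT-3' / R 5'-CGAGAAACCGGTCAATAG-3'
predicted amplicons: 8

category       count  percent
L1SIM1             8    100.0
L1SIM2             0      0.0
...
target-or-adjacent share: 100.0%
top-2 subfamily share:    100.0%
```

All 8 predicted amplicons fall in annotated copies of the target subfamily:
the designed pair is fully selective at these conditions. Real primers on
the real genome behave less cleanly (copies are older and more diverged, and
degraded unannotated copies exist), which is why the in-silico report is
paired with the fragment-level validation analytics in module 5. The other
examples (`examples/01…05`) each exercise one capability and print a short
interpretation.

A thin CLI mirrors the stages:

```bash
l1select simulate --n-subfamilies 6 --length 7000 --seed 1 --outdir sim/
l1select diagnose --consensus sim/consensus.fa --target L1SIM1 --outdir sim/
l1select design --regions sim/regions.tsv --consensus sim/consensus.fa \
    --target L1SIM1 --out sim/primers.tsv
l1select ispcr --genome sim/genome.fa --primers sim/primers.tsv --bed sim/amplicons.bed
l1select score --amplicons sim/amplicons.bed --annotation sim/annotation.bed \
    --chrom-sizes sim/genome.sizes --lineage L1SIM1,L1SIM2,... --outdir sim/score/
l1select run --config run.toml   # all stages from one TOML config, hashed manifest
```

For real data, supply subfamily consensuses (e.g. UCSC Repeat Browser), a
genome FASTA, and a RepeatMasker `.out` or BED annotation in place of the
simulated files.

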