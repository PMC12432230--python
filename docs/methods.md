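# Methods

## The problem and the model

LINE1 (L1) retrotransposons make up >17% of the human genome. The
primate-specific L1PA lineage is a chain of subfamilies deposited in
successive waves of retrotransposition; each subfamily's consensus carries
substitutions that accumulated after it diverged from its predecessor.
Because copies of different subfamilies are >90% identical, a PCR primer
placed arbitrarily on L1 sequence amplifies the whole family. Selectivity
comes from *subfamily-discriminating bases*: alignment columns where one
subfamily's consensus base differs from every other compared subfamily.
`l1select` operationalizes this: find discriminating columns, require a
primer pair whose two footprints each cover at least one, and verify the
outcome by in-silico PCR against an annotated genome.

Working definitions used throughout:

- **Discriminating column** (for target T, comparison set C): T's residue is
  a base (A/C/G/T) and differs from the residue of every member of C. A gap
  in a non-target row counts as different — a base versus an absent base is
  PCR-discriminating — but a gap in T's own row never qualifies, because a
  primer must physically cover a base. The comparison set is an explicit
  parameter: selectivity is always relative to a chosen set of relatives
  (e.g. the youngest subfamily versus its five closest relatives, or the old
  lineage end compared only among itself).
- **Candidate region**: a window of at most `max_region_len` (default
  200 bp, matching the practical upper bound for short-amplicon PCR/qPCR)
  whose two prospective primer footprints both cover ≥1 discriminating
  position.
- **Binding site**: genomic window with Hamming distance ≤ `max_mismatch`
  to the primer on the appropriate strand AND an exact match over the
  primer's 3'-terminal `anchor_len` bases. The exact 3' anchor encodes the
  biochemical fact that polymerase extension tolerates internal mismatches
  far better than 3'-terminal ones. Defaults `max_mismatch=2`,
  `anchor_len=5` are stated design choices of this implementation, not
  values taken from any published webtool configuration; both are exposed.
- **Amplicon**: forward-site start to reverse-site end, with the two sites
  on opposite strands, non-overlapping, and `min_product` ≤ length ≤
  `max_product` (defaults 40 and 1000 bp; 1000 matches the usual
  paired-end insert-size bound used when mapping amplicon libraries).
  Both template orientations are searched, since repeat copies sit on
  either genomic strand.

## Alignment

`progressive_align` is a star-progressive MSA seeded on the first
(youngest) sequence: every other sequence is aligned to it by global
Needleman–Wunsch with a linear gap penalty (match +1, mismatch −1, gap −2;
the pairwise step is Biopython's `PairwiseAligner`), and the pairwise
alignments are merged on a shared column structure. Insertions relative to
the centre are left-justified and padded to the maximum insertion length
observed at that centre position; de-gapping any row recovers its input
exactly. This is deliberately simple — it is exact for the
substitution-only synthetic lineages used in testing, and adequate for
closely related consensuses. For real, indel-containing consensus sets an
externally computed MSA (Clustal Omega, MAFFT) can be supplied via
`accept_external_msa`, which is the recommended path.

## Primer design

Within a candidate region, all footprint placements of length 18–22 nt
covering ≥1 discriminating base are enumerated for each end; a placement
survives if %GC ∈ [35, 60] (and Tm ∈ `tm_range` when set). Pairs are ranked
by (|Tm_F − Tm_R| ascending, combined |%GC − 50| ascending, leftmost
placement) — a deterministic heuristic encoding the usual preferences of Tm
balance and moderate GC. Two optional stringency knobs exist because the
right choice is context-dependent and no published recipe fixes them:
`min_diag_per_footprint` (default 1) and `require_diag_in_3prime_k`
(default off), the latter demanding a discriminating base within k nt of
the 3' terminus, the classic allele-specific-PCR placement which combines
with the in-silico anchor rule to exclude non-target subfamilies outright.

%GC is reported rounded half-up to one decimal. Tm offers two standard
methods: the Wallace 2-4 rule (2·(A+T) + 4·(G+C)), and nearest-neighbour
ΔH/ΔS with the SantaLucia–Hicks unified parameter set at 50 mM Na⁺ and
500 nM primer (via Biopython's `MeltingTemp`). Commercial design tools use
proprietary Tm variants, so absolute Tm values are tool-dependent;
selectivity conclusions here never rest on Tm.

## In-silico PCR implementation

The fast path seeds on exact 3'-anchor matches (vectorized equality scans
over a byte-encoded genome) and verifies full-length Hamming distance only
at surviving positions; N in the genome never matches any primer base.
`brute_force_pcr_oracle` re-derives the answer with a shortcut-free
position-by-position scan and quadratic site pairing, and the test suite
asserts exact equality of the two on hundreds of seeded 10-kb genomes with
planted sites straddling the mismatch and anchor thresholds. Indel-tolerant
binding is out of scope (primer-template bulges are rare at these lengths).

## Scoring and validation analytics

Each amplicon or fragment is assigned to the annotation record with the
largest base-pair overlap; ties break to the longer record, then the
lexicographically smaller name, making assignment independent of annotation
order. Categories are the configured lineage subfamilies plus
`other_LINE1` (a LINE1 outside the lineage) and `non_LINE1` (no overlap, or
best overlap with a non-LINE1 repeat). Percentages are rounded half-up to
one decimal; the report includes the top-2 subfamily share, since selective
primers on a graded lineage typically amplify the target plus its nearest
relative.

The four annotation tracks are: merged LINE1 intervals; their genomic
complement; full-length LINE1 records (length > 6000 bp by default — at toy
scale the pipeline uses ≥90% of the simulated consensus length instead, and
records this in its manifest); and the subset of full-length records
overlapping an externally curated intact-locus set. Amplified loci are
maximal merges of strictly overlapping fragments retained at ≥3 supporting
fragments (boundary inclusive). Bookended fragments are *not* merged — the
definition is "supported by overlapping fragments", and zero shared bases
is not overlap. Two calls (e.g. from unique-filtered and unfiltered
alignments) can be unioned with `union_loci`. FPKM is
10⁹·count/(length·total); fragments are what is counted, and with
single-end data the identical formula is conventionally called RPKM.
Strand-matched counting is a flag (`strand_matched`), default off for
amplicon DNA and intended on for stranded RNA-seq.

Read mapping, duplicate marking and multi-mapper reassignment are
deliberately upstream of this package: it consumes fragment intervals as
BED (one-line `samtools`/`bedtools` recipe in the `validation` docstring),
which keeps the analytics deterministic and dependency-light.

## Synthetic lineage generator

`SimParams` defaults describe the study conditions used throughout the
acceptance checks: 6 subfamilies of a 7 kb element (full-length L1 is
~6 kb), 2% substitutions per site per lineage step (adjacent real L1PA
consensuses differ by a few percent), 30 copies per subfamily each with 3%
private divergence, 50% of copies 5'-truncated by a uniform 10–90% of their
length (real genomic L1 copies are predominantly 5'-truncated, which is
what makes a "full-length" track meaningful), on a 500 kb background of
i.i.d. uniform bases. Copies are inserted between background bases at
distinct offsets on random strands, so planted copies never overlap and the
annotation records their exact intervals; a truth table carries realized
per-copy divergence and truncation. Everything is a pure function of the
seed (NumPy `default_rng` with per-stage seed sequences), and FASTA/BED
outputs are byte-identical across reruns.

What the simulator does *not* emulate — and hence what passing synthetic
tests cannot show about real data: indels between subfamily consensuses
(v1 is substitution-only, keeping alignment columns in register and the MSA
stage exactly testable), transition/transversion and CpG mutation bias,
target-site duplications, poly-A tails, inversions, nested insertions, and
the background of old, degraded, unannotated repeat fragments that real
genomes carry. Real-genome selectivity is therefore expected to be lower
than synthetic selectivity, and real validation requires user-supplied
consensuses, genome and annotation.

## Numerical and degenerate-input choices

- Coordinates are uniformly 0-based half-open; the RepeatMasker `.out`
  parser converts its 1-based inclusive query coordinates at the boundary,
  and strand `C` maps to `-`.
- Rounding of reported percentages is decimal half-up (not banker's).
- Zero amplicons/fragments produce an explicit empty report (total = 0),
  never a division by zero; zero-length loci and zero totals in FPKM raise.
- The BED placeholder name `.` reads back as an empty name so that
  write∘read is the identity on the intervals this package writes.
- Region enumeration emits one canonical region per ordered pair of
  discriminating positions (left footprint starting at the left position,
  right footprint ending just after the right one, both at minimum
  footprint length); primer design then slides and resizes footprints
  within the region, so no placement is lost by the canonicalization.
- The pipeline tries candidate regions in order of decreasing
  discriminating-base coverage of their footprints — more discriminating
  bases make a pair more selective — and scores every designed pair,
  reporting the best.

## Known limitations

No hairpin/dimer screening or thermodynamic secondary-structure checks; no
degenerate-base or multiplex-aware design; no indel-tolerant binding model;
no statistical enrichment testing on the category reports; sub-element
labels (5'UTR/ORF1/ORF2) for designed regions would need a consensus
feature map and are not attempted. Genome-scale inputs work (the binding
search is linear-time with a small constant) but desk-scale synthetic data
is the tested surface.
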