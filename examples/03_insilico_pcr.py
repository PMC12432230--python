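"""In-silico PCR with the published LINE1 subfamily primers.

Reproduces the printed %GC of the six published primer pairs from their
sequences, then predicts the product of primer pair 1 on a constructed
template (forward primer + 110 bp spacer + reverse-complemented reverse
primer): one amplicon of 20 + 110 + 22 = 152 bp.
"""

import numpy as np

from l1select import (
    gc_percent,
    load_reference_primers,
    pair_from_sequences,
    predict_amplicons,
    reverse_complement,
)

records = load_reference_primers()
print("primer        %GC   Tm-independent check from sequence alone")
for rec in records:
    print(f"{rec.id:<12}  {gc_percent(rec.seq):>4}  5'-{rec.seq}-3'")

seqs = {r.id: r.seq for r in records}
pair = pair_from_sequences(seqs["Primer1_F"], seqs["Primer1_R"], name="Primer1")
rng = np.random.default_rng(0)
spacer = "".join(rng.choice(list("ACGT"), 110))
flank = "".join(rng.choice(list("ACGT"), 300))
genome = flank + pair.forward.seq + spacer + reverse_complement(pair.reverse.seq) + flank

amps = predict_amplicons(genome, pair, max_mismatch=2, anchor_len=5)
print(f"\npredicted amplicons: {len(amps)}")
for amp in amps:
    print(f"  {amp.interval.chrom}:{amp.interval.start}-{amp.interval.end}  "
          f"{amp.product_len} bp, mismatches F={amp.f_site.mismatches} R={amp.r_site.mismatches}")
print("\nBinding requires <=2 mismatches over the primer and an exact match")
print("of the 5 3'-terminal bases (polymerase extension needs a matched 3' end).")
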