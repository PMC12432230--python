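"""Find subfamily-discriminating bases and design selective primers.

Aligns the simulated consensuses, scans for columns where the youngest
subfamily's base differs from every other subfamily, enumerates candidate
regions (<=200 bp with discriminating bases at both ends), and designs
ranked primer pairs for the best region.
"""

from l1select import SimParams, simulate_lineage
from l1select.pipeline import candidate_pairs_for_target

params = SimParams(n_subfamilies=4, consensus_length=1000,
                   step_substitution_rate=0.03, seed=7)
consensuses = simulate_lineage(params)
target = consensuses.names[0]  # youngest subfamily

columns, regions, pairs = candidate_pairs_for_target(
    consensuses, target, max_candidate_pairs=5
)
print(f"target {target}: {len(columns)} discriminating columns, "
      f"{len(regions)} candidate regions, {len(pairs)} designed pairs\n")
for i, pair in enumerate(pairs[:3]):
    f, r = pair.forward, pair.reverse
    print(f"pair {i}: product {pair.expected_product_len} bp")
    print(f"  F 5'-{f.seq}-3'  %GC={f.gc}  Tm={f.tm_c}C  footprint={f.footprint}")
    print(f"  R 5'-{r.seq}-3'  %GC={r.gc}  Tm={r.tm_c}C  footprint={r.footprint}")
print("\nEach footprint covers >=1 base unique to the target subfamily, so")
print("the primers preferentially hybridize to its copies. Tm is the 2-4")
print("Wallace rule; use tm_method='nn_santalucia' for nearest-neighbour.")
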