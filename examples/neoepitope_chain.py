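"""Somatic variant -> neoepitope candidate chain on a generated variant table.

Filters variants by depth/VAF evidence and caller concordance, builds 25-mer
mutant windows, enumerates the mutation-spanning 8-11mers, prioritizes by
transcript level, and ranks with the built-in deterministic stub scorer
(swap in an external MHC binding predictor via the scorer argument).
"""

import io

from tilkit.neoepitope import (
    build_window,
    caller_concordance,
    enumerate_peptides,
    filter_variants,
    prioritize_fpkm,
    rank_candidates,
    read_variants_csv,
    stub_scorer,
)
from tilkit.synthetic import gen_variants

table = gen_variants(60, pass_fraction=0.4, seed=8)
buf = io.StringIO()
table.drop(columns=["truth_pass", "truth_violations"]).to_csv(buf, index=False)
buf.seek(0)
records = read_variants_csv(buf)

kept, rejected = filter_variants(records)
print(f"{len(records)} variants; {len(rejected)} rejected by depth/VAF filters, e.g.:")
for idx in list(rejected)[:3]:
    print(f"  {records[idx].gene}: {', '.join(rejected[idx])}")

kept = caller_concordance(kept, k=2)
print(f"{len(kept)} variants remain after requiring >=2 of 4 callers")

cands = [enumerate_peptides(build_window(v)) for v in kept]
n_pep = sum(len(c.peptides) for c in cands)
print(f"{n_pep} mutation-spanning 8-11mer peptides from {len(cands)} windows")
print("  (a mutation with 12 residues of flank on both sides yields 38 peptides)")

cands = prioritize_fpkm(cands, threshold=100.0)
print(f"{sum(c.prioritized for c in cands)} candidates exceed 100 FPKM (prioritized)")

ranked = rank_candidates(cands, stub_scorer, cutoff=0.5)
print(f"{len(ranked)} candidates carry a peptide scoring <= 0.5 with the stub scorer")
print("-> these are the peptides one would synthesize for ELISpot screening.")
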