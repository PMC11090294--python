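"""Candidate-variant prioritization: association x conservation x MAF.

Builds a toy candidate table, keeps markers with MAF > 0.1 and phyloP
in the top 5% of the score universe, and lists missense variants
separately — the screen used to nominate causal candidates.
"""

import numpy as np

from ailqtl import CandidateRow, candidate_filter, candidate_frame, missense_table

rng = np.random.default_rng(5)
rows = []
for i in range(200):
    rows.append(
        CandidateRow(
            marker_id=f"v{i:03d}",
            pos=150_000_000 + i * 10_000,
            ref="A",
            alt="G",
            neglog10p=float(rng.exponential(3.0)),
            phylop=float(rng.normal(0.5, 1.5)),
            aaf=float(rng.uniform(0.02, 0.98)),
            effect_category=rng.choice(
                ["intron_variant", "intergenic_region", "missense_variant"],
                p=[0.6, 0.3, 0.1],
            ),
        )
    )

kept = candidate_filter(rows, maf_min=0.1, phylop_q=0.05)
print(f"{len(kept)} of {len(rows)} markers pass MAF > 0.1 and top-5% phyloP")
print(candidate_frame(kept[:5])[["marker_id", "neglog10p", "phylop", "maf", "effect"]]
      .to_string(index=False))

mis = missense_table(rows, phylop_q=0.25)
print(f"\n{len(mis)} conserved missense variants (top-25% phyloP), by p:")
for r in mis[:3]:
    print(f"  {r.marker_id}  -log10 p = {r.neglog10p:.2f}  phyloP = {r.phylop:.2f}")
# Rows are ordered by association strength; the phyloP cut keeps only
# markers in evolutionarily constrained positions.
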