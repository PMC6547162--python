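"""Per-residue phosphopeptide aggregation with planted fold changes.

Generates a peptide intensity table where residues 1-10 are enriched
2.8-fold (log2 = 1.5) and residues 11-20 depleted 2-fold in the mutant,
plus reference-protein (Smc3) peptides carrying a 3x IP-efficiency
bias, then recovers the planted per-residue log2 ratios.
"""

import numpy as np

import meioquant as mq
from meioquant.phospho import PHOSPHO, per_residue_pipeline

protein_length = 30
fc = np.concatenate([np.full(10, 1.5), np.full(10, -1.0), np.zeros(10)])
target, reference, _ = mq.make_peptide_table(
    protein_length,
    [(1, 10, PHOSPHO), (11, 20, PHOSPHO)],
    fc,
    smc3_factors={"mutant": 3.0},  # mutant IP pulled 3x more material
    n_replicates=3,
    seed=0,
    jitter_sd=0.1,
)

table = per_residue_pipeline(target, reference, protein_length,
                             condition="mutant", baseline="WT")
for residue in (1, 5, 15, 20):
    row = table[table["residue"] == residue].iloc[0]
    star = "*" if row["significant"] else " "
    print(f"residue {residue:>2}: mean log2 ratio {row['mean']:+.3f} "
          f"(sd {row['sd']:.3f}, n={row['n']}, p={row['p']:.3g}){star}")
# The Smc3-based normalization cancels the 3x IP bias; recovered means
# sit near the planted +1.5 / -1.0 despite the replicate jitter, and
# the one-sample t-test flags residues whose mean ratio differs from 0.
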