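"""Diversity and differentiation statistics on a study-shaped dataset.

Prints per-lineage haplotype and nucleotide diversity, the three AMOVA
designs (no groups / two lineage groups / three), pairwise F_ST between
lineages, and the Pons & Petit G_ST/N_ST contrast whose one-tailed
permutation test detects phylogeographic structure (N_ST > G_ST means
closely related haplotypes co-occur within populations).
"""

import numpy as np
import pandas as pd

from cpphylo.alignment import filter_complete_columns
from cpphylo.haplotypes import collapse_haplotypes, hamming_matrix
from cpphylo.popgen import (
    amova, gst_nst, haplotype_diversity, nucleotide_diversity,
    pairwise_fst, tamura_nei_distance,
)
from cpphylo.synthetic import FixtureSpec, generate_study_like

aln, meta = generate_study_like(FixtureSpec(seed=7))
filtered, _ = filter_complete_columns(aln)
lineage = {m.sample_id: m.lineage for m in meta}
pop = {m.sample_id: m.population for m in meta}

for g in ("north", "central", "south"):
    seqs = [s for sid, s in zip(filtered.sample_ids, filtered.sequences)
            if lineage[sid] == g]
    hd = haplotype_diversity(pd.Series(seqs).value_counts().to_numpy())
    pi = nucleotide_diversity(seqs)
    print(f"{g:8s} n={len(seqs):2d}  Hd={hd.hd:.2f}±{hd.hd_sd:.2f}  pi={pi.pi:.5f}")

dist = tamura_nei_distance(filtered).to_numpy()
pops = [pop[s] for s in filtered.sample_ids]
lineages = [lineage[s] for s in filtered.sample_ids]

res = amova(dist, pops, n_perm=500, seed=1)
print("\nAMOVA (no groups): F_ST=%.3f p=%.3f; among-population %%=%.1f"
      % (res.fixation_indices["F_ST"], res.p_values["F_ST"],
         res.table["percent"].iloc[0]))
three = {pop[m.sample_id]: m.lineage for m in meta}
res3 = amova(dist, pops, three, n_perm=500, seed=2)
print("AMOVA (three lineages): F_CT=%.3f p=%.3f among-group %%=%.1f"
      % (res3.fixation_indices["F_CT"], res3.p_values["F_CT"],
         res3.table["percent"].iloc[0]))

fst, fst_p = pairwise_fst(dist, lineages, n_perm=500, seed=3)
print("\npairwise lineage F_ST:\n", fst.round(3).to_string())

table = collapse_haplotypes(filtered, meta)
diff = gst_nst(table.counts, hamming_matrix(table.sequences), n_perm=2000, seed=4)
print("\nG_ST=%.3f  N_ST=%.3f  P(N_ST>G_ST null)=%.3f"
      % (diff.g_st, diff.n_st, diff.p_nst_gt_gst))
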