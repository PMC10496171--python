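"""Generate a small synthetic two-species study and inspect its truth.

The generator plants everything downstream stages estimate: motif-structured
DE effects (log2, chimp vs human), per-gene cis fractions, NB counts with
individual/replicate random effects, and hybrid cells whose allele split
encodes the cis fraction.
"""

import numpy as np

from ebcomp import SimulationConfig, simulate_hybrid_cells, \
    simulate_species_cells, simulate_truth

cfg = SimulationConfig(n_genes=500, n_celltypes=4, n_cells_per_sample=30,
                       seed=42)
truth = simulate_truth(cfg)
study = simulate_species_cells(truth, cfg)
hyb = simulate_hybrid_cells(truth, cfg)

print(f"genes: {cfg.n_genes}, cell types: {cfg.n_celltypes}")
print(f"diploid cells: {study.counts.shape[0]} "
      f"({study.cell_meta['species'].value_counts().to_dict()})")
print(f"hybrid cells: {hyb.hybrid_human.shape[0]}")
de_frac = truth.de_indicator.any(axis=1).mean()
print(f"genes DE in >= 1 cell type: {de_frac:.1%}")
de = truth.effect[truth.de_indicator == 1]
print(f"mean |log2FC| of planted DE effects: {np.abs(de).mean():.2f}")
print(f"mean planted cis fraction: {truth.cis_fraction.mean():.2f}")
# the allelic ratio of a hybrid gene encodes rho * beta (per cell type):
g = int(np.argmax(np.abs(truth.effect[:, 0]) * (truth.baseline > 1)))
ct0 = (hyb.hybrid_meta["cell_type"] == truth.celltypes[0]).to_numpy()
h = hyb.hybrid_human[ct0][:, g].sum()
c = hyb.hybrid_chimp[ct0][:, g].sum()
print(f"example gene {truth.genes[g]}: planted rho*beta = "
      f"{truth.cis_fraction[g] * truth.effect[g, 0]:+.2f}, observed allelic "
      f"log2(chimp/human) = {np.log2((c + 0.5) / (h + 0.5)):+.2f}")
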