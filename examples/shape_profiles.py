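"""Affinity-stratified DNA shape profiles and core/flank co-dependencies.

Builds a core-aligned 12-mer affinity table from a small simulated
selection, computes decile-binned minor-groove-width profiles, and the
classic 16 x 64 heatmap of core dinucleotide vs upstream trinucleotide.
"""

import numpy as np

from pasbind import (SyntheticTruth, build_affinity_table,
                     filter_single_core, fit_positional_background,
                     simulate_selex)
from pasbind.dna_shape import affinity_binned_shape, codependency_heatmap

truth = SyntheticTruth(seed=1, reads_per_round=50_000)
rounds = simulate_selex(truth)
filtered = {r: filter_single_core(rounds[r]).reads for r in rounds}
bg = fit_positional_background(filtered[0])
table = build_affinity_table(filtered[2], bg, k=12, r=2)

# keep the modal core register so every k-mer aligns on its CGTG
offsets = table.df["kmer"].str.find("CGTG")
modal = int(offsets[offsets >= 2].mode().iloc[0])
aligned = dict(zip(table.df.loc[offsets == modal, "kmer"],
                   table.df.loc[offsets == modal, "affinity"]))
print(f"{len(aligned)} core-aligned 12-mers (CGTG at offset {modal})")

profile = affinity_binned_shape(aligned, align="core_CGTG", n_bins=10)
top, bottom = profile.mean["MGW"][-1], profile.mean["MGW"][0]
downstream = slice(modal + 4, 12)
print(f"mean MGW downstream of the core: top decile "
      f"{np.nanmean(top[downstream]):.2f} A, bottom decile "
      f"{np.nanmean(bottom[downstream]):.2f} A")

heat = codependency_heatmap(table, row_positions=(0, 1),
                            col_positions=(-3, -2, -1))
print(f"co-dependency heatmap: {heat.shape[0]} core dinucleotides x "
      f"{heat.shape[1]} upstream trinucleotides, "
      f"{int(heat.notna().sum().sum())} cells populated")
best = heat.stack().idxmax()
print(f"highest mean affinity cell: core {best[0]}CGTG with upstream {best[1]}")
print("a lower top-decile MGW would indicate AT-rich preference at those "
      "positions (here the planted downstream preference is mild); the "
      "heatmap exposes core/flank coupling and should peak at TACGTG.")
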