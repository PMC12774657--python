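"""Build round-normalised k-mer affinity tables and annotate the cores.

Applies the single-core read filter, fits a position-aware round-0
background, tabulates 12-mer enrichments for rounds 1 and 2, and checks
that the two independently selected rounds agree on relative affinities.
"""

from pasbind import (SyntheticTruth, annotate_kmer, build_affinity_table,
                     compare_tables, derive_consensus, filter_single_core,
                     fit_positional_background, simulate_selex)

truth = SyntheticTruth(seed=1, reads_per_round=50_000)
rounds = simulate_selex(truth)
filtered = {r: filter_single_core(rounds[r]).reads for r in rounds}
print(f"single-core filter kept "
      f"{len(filtered[1])}/{len(rounds[1])} round-1 reads")

bg = fit_positional_background(filtered[0])
t1 = build_affinity_table(filtered[1], bg, k=12, r=1)
t2 = build_affinity_table(filtered[2], bg, k=12, r=2)

r, merged = compare_tables(t1, t2)
print(f"round-1 vs round-2 affinity agreement: r^2 = {r**2:.3f} "
      f"over {len(merged)} shared 12-mers")

consensus = derive_consensus(t2, top_n=50)
print(f"consensus from top core-aligned 12-mers: {consensus}")

for kmer in t2.df["kmer"].head(3):
    ann = annotate_kmer(kmer)
    print(f"  {kmer}: class={ann.core_class} c1c2={ann.c1c2} "
          f"core at {ann.core_offset}")
print("affinity = enrichment^(1/round), max-normalised to 1; high r^2 "
      "between rounds means the relative affinities are reproducible.")
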