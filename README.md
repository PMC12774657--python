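# pasbind

Analysis of in-vitro DNA-binding specificity for bHLH-PAS
transcription-factor dimers (ARNT, ARNT2, HIF1α/2α, SIM1, NPAS4, AhR and
their heterodimers), from raw SELEX-seq selection rounds to genomic
validation. The package is aimed at computational biologists who want to

- turn selection-round FASTQ files into **relative k-mer affinity tables**
  over a round-0 background model,
- fit a **biophysical binding-energy model** of the 12–15 bp dimer
  footprint and score arbitrary sequences, IUPAC spaces or BED intervals
  with it,
- validate models against **ChIP-seq peaks** (AUROC vs random regions,
  binned score-vs-intensity regression, cross-model comparison),
- relate affinity to **DNA shape** (pentamer-lookup MGW/ProT/HelT/Roll
  profiles, core/flank co-dependency heatmaps), and
- test whether **CpG methylation** suppresses occupancy (coverage-filtered
  per-peak methylation, methylated/unmethylated classes, rank tests and
  binned regression).

A first-class synthetic-data module generates every input with known
ground truth (Boltzmann-selection SELEX rounds, genomes with planted
binding sites, methylation-attenuated peak intensities), so the whole
pipeline is testable end to end without any external data.

## The model

A probe sequence S is bound through any length-L window v of
flank + S + flank on either strand. Each window contributes a Boltzmann
weight determined by an additive mononucleotide energy matrix ε(b, i) ≥ 0
(natural-log units, per-position minimum gauged to 0):

    W(S) = Σ_windows v, strands  exp( − Σ_i ε(base_v[i], i) )

Selection round r enriches sequence S in proportion to W(S)^r. The matrix
is fitted by maximising the penalised log-likelihood

    Σ_reads r·log W(S) − N_r·log Z_r − λ‖ε‖² ,   Z_r = E₀[W^r]

with Z_r estimated by importance sampling over a fixed pool of
unselected-library (round 0) sequences, analytic gradients and L-BFGS.
Relative k-mer affinity is defined as enrichment over the round-0
background, E = observed/expected, exponentiated by 1/r and max-normalised
to 1. Core elements follow the E-box-like convention NNCGTG (positions
c1–c6), with flanks labelled f−n upstream and f+n downstream.

## Worked example

```bash
python examples/simulate_and_fit.py
```

prints (seed 1, 5×10⁴ reads/round):

```
simulated rounds: [0, 1, 2] x 50000 reads (library fixedcore_8N_CGTG_10N)
fit converged: True after 74 iterations
fitted consensus: GACTACGTGATA
parameter recovery: Pearson r = 0.980 (orientation +, register shift 0)
```

The simulator plants a TACGTG-preferring 12-bp truth matrix and selects a
fixed-core 8N-CGTG-10N library through two rounds; the fitted energy
matrix recovers the planted consensus (the TACGTG core with its flanking
preferences) and correlates with the truth at r = 0.98. The other scripts
in `examples/` walk through affinity tables and consensus calling, ChIP
peak validation (AUROC ≈ 0.93 for the true model vs ≈ 0.5 for a
shuffled-energy decoy), affinity-binned shape profiles, and the negative
methylation–occupancy relationship, each printing the statistics it
computes and one line on how to read them.

The same capabilities are available from the shell:

```bash
pasbind simulate --what selex --seed 1 --reads 50000 --outdir sim/
pasbind filter-core --in sim/selex_r2.fastq --out sim/r2.filt.fastq
pasbind kmer-table --round0 sim/selex_r0.fastq --selected sim/r2.filt.fastq \
        --k 12 --round 2 --out sim/k12_r2.tsv
pasbind fit --round0 sim/selex_r0.fastq --selected 2:sim/selex_r2.fastq \
        --out sim/model.json
pasbind run --outdir run/   # full pipeline with a consolidated report
```

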