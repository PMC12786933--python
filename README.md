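# genestrata

Phylostratigraphic gene-age inference and the downstream evolutionary analyses
that typically accompany it, built for comparative genomicists studying the
origin and fate of lineage-specific ("new") genes — for example in rapidly
adapting insect pests.

## What it does

**Gene ages.** Every protein-coding gene is assigned a *phylostratum*: the
oldest node PS ∈ {1, …, K} of the focal species' root-to-tip taxonomic lineage
at which homologs are still detectable (PS1 = oldest, PSK = species-specific).
The raw deepest-homolog call is refined in three ways:

1. *Taxonomic representativeness* — a gene whose hits cover < 30 % of the
   database-represented subclades of its assigned stratum is flagged as a
   likely contaminant or horizontal transfer and excluded.
2. *Family founder ages* — the focal proteome is clustered into families with
   the Markov Cluster algorithm (MCL) on all-vs-all similarities; each family
   inherits the oldest reliable member age as its founder age, so young-looking
   duplicates of old families are dated correctly.
3. *Homology detection failure (HDF)* — per gene, detected bitscores are fit
   to `s(d) = a·exp(−b·d)` in divergence time d; if the extrapolated score in
   the closest outgroup beyond the founder stratum has probability ≥ 0.05 of
   falling below the detection threshold (Gaussian error around the curve),
   the age is kept but flagged `hdf_uncertain`.

**Downstream analyses.** Per-stratum gene birth rates `n_r / Δt_r` with peak
detection; CDS-length/exon-count vs. age trends with permutation and one-sided
Wilcoxon rank-sum tests; reciprocal-best-hit orthologs and Nei–Gojobori (1986)
Ka/Ks with Jukes–Cantor correction; expression breadth, tissue-specificity
`tau = Σ(1 − x̂_i)/(n − 1)`, and the transcriptome age index
`TAI = Σ(PS_i·e_i)/Σ e_i`; moderated-t differential expression for stress
contrasts; and a weighted co-expression network (adjacency `|cor|^β`,
topological overlap, module eigengenes, kME, module–trait correlation, hub
calling).

**Synthetic data.** A first-class generator produces every input the pipeline
consumes — hit tables with exponentially decaying bitscores encoding planted
true ages (including planted HDF and contaminant cases), gene families, GFF3 +
protein FASTA with age-correlated gene structure, tissue TPM matrices with
planted breadth/specificity, stress count matrices with planted DEGs, planted
co-expression modules containing young hub genes, and codon-aligned ortholog
pairs with exact planted substitution counts — together with serialized ground
truth, so every stage is testable without downloads.

## Worked example

```bash
genestrata simulate --seed 1 --outdir demo/sim
genestrata ages --hits demo/sim/hits.tsv --self-hits demo/sim/self_hits.tsv \
    --lineages demo/sim/lineages.tsv --stratum-ages demo/sim/stratum_ages.tsv \
    --seed 1 --outdir demo/ages
genestrata features --gene-ages demo/ages/gene_ages.tsv \
    --gff3 demo/sim/genes.gff3 --fasta demo/sim/proteins.faa \
    --lineages demo/sim/lineages.tsv --stratum-ages demo/sim/stratum_ages.tsv \
    --n-perm 10000 --seed 1 --outdir demo/features
```

prints

```
wrote 23 files to demo/sim
called ages for 826 genes
mean birth rate 0.2424 genes/MY; peaks at [5, 9, 15]
```

`demo/ages/gene_ages.tsv` holds one call per gene:

```
gene_id  raw_ps  family_id  founder_ps  representativeness  hdf_probability  status
g0001    1       f191       1           100                                  confident
g0003    1       f192       1           87.5                                 confident
```

`raw_ps`/`founder_ps` are stratum ranks (1 = oldest), `representativeness` the
percent of subclades covered at the assigned stratum, and `status` one of
`confident`, `hdf_uncertain`, `excluded_low_representativeness`, `unassigned`.
The birth-rate peaks at ranks 5, 9 and 15 recover exactly the three planted
birth bursts of the simulated cohort. `demo/features/feature_tests.json`
reports, among others, the new-gene CDS-length permutation test
(observed mean 1124 bp vs. expected 1519 bp, p = 1e-4 at n_perm = 10,000) and
the one-sided Wilcoxon comparison against PS1 genes (p ≈ 1.7e-25) — the
planted "young genes are shorter" signal.

The remaining subcommands (`kaks`, `expression`, `de`, `network`) consume the
same simulated directory; every subcommand is byte-reproducible for a fixed
seed.

## Layout

- `src/genestrata/formats.py` — file formats (GFF3, FASTA, outfmt-6 hit
  tables, TSV matrices) and run configuration
- `src/genestrata/ages.py` — the age-inference pipeline
- `src/genestrata/features.py` — per-stratum statistics and tests
- `src/genestrata/molevol.py` — RBH orthologs and NG86 Ka/Ks
- `src/genestrata/transcriptome.py` — breadth, tau, TAI, expression report
- `src/genestrata/networks.py` — differential expression and co-expression
  networks
- `src/genestrata/simulate.py` — the synthetic-data generator
- `src/genestrata/cli.py` — the `genestrata` command
- `docs/methods.md` — modelling assumptions, parameter defaults, limitations
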