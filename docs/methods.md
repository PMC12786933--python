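# Methods

This note records the models implemented in `genestrata`, the defaults and why
they were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducing results.

## Phylostratigraphic age model

A gene's age is the rank of the oldest stratum on the focal species'
root-to-tip lineage containing a detectable homolog. The pipeline composes
four estimators, in order:

**Raw age.** Each hit's subject taxon is mapped to the most derived focal
stratum whose name occurs in the taxon's lineage; the gene's raw age is the
minimum such rank over its hits. Hits whose taxa have no lineage record are
ignored with a warning; genes without usable hits are `unassigned`. Hits are
pre-filtered at an e-value cutoff (default 1e-5, exposed in `RunConfig` — the
typical choice for sensitive-mode protein searches).

**Representativeness.** The score is the percentage of database-represented
subclades of the assigned stratum that contain at least one hit, where a
taxon's subclade is the lineage level immediately below the stratum (the taxon
itself for terminal taxa) and the census is computed from the full lineage
table. Genes scoring strictly below 30 % are excluded as putative
contaminants or horizontal transfers; a stratum with an empty census makes the
score undefined and the gene `unassigned`. The published pipelines that use
such a filter name the score without printing a formula; this definition —
hit-covered fraction of database-represented subclades — is the natural
census-normalized choice and is documented here as this package's definition.

**Families and founder ages.** The focal proteome's all-vs-all hits become a
similarity matrix (`−log10 e-value`, capped at 200, symmetrized by the
maximum, self-similarity at the cap) and are clustered with a standard MCL
iteration: column-normalize, then alternate expansion (matrix self-product)
and inflation (elementwise power, default 2.0, re-normalize), pruning entries
below 1e-5, until the largest column change falls below 1e-6 (hard cap 200
iterations, warning on non-convergence). Families are connected components of
the attractor support; components are labelled by decreasing size for
determinism. Every family inherits the minimum (oldest) raw age among its
*reliable* members — members that are neither excluded nor unassigned — and a
family with no reliable member leaves its genes unassigned.

**Homology detection failure.** For each confident gene with founder rank
r > 1, the best bitscore per detected stratum is regressed on divergence time
as `s(d) = a·exp(−b·d)` (ordinary least squares on the score scale,
initialized by log-linear regression, `b ≥ 0`). Distances default to stratum
ages in MY; conspecific hits sit at d = 0. The score a homolog *would* have in
the closest outgroup beyond the founder stratum (distance = age of rank r−1)
is modelled as Gaussian around the fitted curve with the fit's residual
standard deviation (floored at 0.01·a so that noiseless fits keep a proper
distribution). If P(score < detection threshold) ≥ 0.05 the call is flagged
`hdf_uncertain`: the non-detection that made the gene look young is consistent
with ordinary score decay, so the age is not a high-confidence founder event.
Flagged genes keep their age and are reported separately — they are never
reassigned. Genes with fewer than three distinct detected distances cannot be
fit; they stay `confident` with a logged caveat. The detection threshold
bitscore defaults to 30, roughly the score at the e-value cutoff in a small
database partition, and is configurable. The Gaussian error model is an
approximation to the published detectability-curve approach and behaves
equivalently for flag decisions.

## Downstream statistics

- **Birth rates**: genes founded in stratum r divided by the age interval
  (age(r−1) − age(r); rank 1 uses its own age). Ranks whose rate exceeds the
  unweighted mean across ranks are flagged as birth peaks.
- **Permutation test** for new-gene CDS length: the observed mean is compared
  with means of random same-size gene sets; the one-sided p-value uses the
  add-one estimator (1 + #{perm ≤ obs})/(n_perm + 1), which cannot return 0.
- **Correlations**: "gene age" means stratum age in MY; per-rank means are the
  default unit for the CDS-vs-age Pearson correlation (the per-gene version is
  reported alongside). Copy-number trends use Spearman correlation of per-rank
  multicopy percentage (family size ≥ 2) against stratum age.
- **Group comparisons** (CDS, exons, Ka, Ks, Ka/Ks, breadth, tau) use
  one-sided Wilcoxon rank-sum tests in the direction of the biological
  hypothesis (new genes shorter, simpler, faster-evolving, narrower, more
  specific); scipy's implementation switches to the exact distribution for
  small tie-free samples.
- **Ka/Ks** is Nei–Gojobori counting: per-codon synonymous site fractions over
  non-stop single-nucleotide mutations (positions whose every mutation creates
  a stop count as fully nonsynonymous, keeping S + N = 3 per codon);
  multi-difference codons average over all mutation orderings, excluding
  pathways through stops, and fall back to an even split when every ordering
  is blocked; Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)` with p ≥ 3/4
  reported as saturated (NaN). NG86 ignores transition/transversion bias and
  codon frequencies, so absolute Ks runs slightly high relative to
  maximum-likelihood codon models; the stratified new-vs-old comparisons this
  package makes are insensitive to that shift. Note that at degenerate scales
  (single-codon alignments) the proportion p can exceed the correction's
  domain even for one substitution; saturation is the honest report there.
- **tau** is computed on log2(TPM+1)-transformed per-tissue means by default
  (the convention of the commonly used implementation), with a raw-TPM mode;
  replicates collapse to tissues by arithmetic mean. Genes expressed nowhere
  are skipped; tau is undefined for single-tissue designs.
- **TAI** uses founder ranks as integer weights over genes with positive
  expression, per sample and per tissue.
- **Differential expression** is a self-contained stand-in for
  negative-binomial tools, intended for synthetic and exploratory use (real
  studies can ingest external DE tables): median-of-ratios size factors, a
  two-sample t-statistic on log2(normalized + 1) with empirical-Bayes variance
  moderation toward a lowess mean–variance trend (prior df from the
  log-variance moment estimator). Moderation is what makes 3–4 replicates per
  group workable: an unmoderated per-gene t at n = 4 leaves planted 4-fold
  effects mostly below the BH threshold (measured recall ~0.31 vs ~0.99 with
  moderation at matched null calibration, type-I ≈ 0.045–0.05 at α = 0.05).
  DEG calls require BH-adjusted p < 0.05 *and* |log2FC| ≥ 1.
- **Co-expression network**: unsigned adjacency `|cor|^β` (β = 8), unsigned
  topological overlap, average-linkage clustering of 1−TOM with a *static*
  height cut (default 0.25) and minimum module size 30; modules are labelled
  m1, m2, … by decreasing size, the remainder grey. Static cutting is a
  documented simplification of dynamic tree cutting: it requires tightly
  correlated modules (within-module |cor| ≳ 0.95 at β = 8) and the cut height
  is exposed in the configuration for looser data. Eigengenes are first
  principal components of standardized module submatrices, sign-oriented so
  the mean correlation with members is positive (making runs reproducible and
  order-invariant); kME is the Pearson correlation of a gene with a module
  eigengene; traits are numeric per-sample vectors (e.g. a 0/1 treatment
  indicator); per trait, the module with the largest |r| is highlighted and
  its members with kME > 0.7 are called hubs (membership listed at kME > 0.6).

## Synthetic study conditions

The generator's defaults are the study conditions for all tests; they were
chosen once as a realistic desk-scale cohort.

- **Ladder**: 18 strata in the style of an insect lineage with anchor ages
  4250, 1598, 35 and 9 MYA from published divergence-time compilations and
  interpolated intermediates. A fixture, not a claim about any species.
- **Cohort**: a piecewise-constant birth process (base 0.05 genes/MY, 20×
  bursts at ranks 5, 9 and 15) gives ~790 genes, plus 20 planted HDF cases and
  16 planted contaminants (~830 total). Eight database subclades per stratum;
  normal genes hit 4–8 of them at their deepest stratum, contaminants exactly
  one deep subclade.
- **Bitscores**: `a ~ U(150, 250)`, Gaussian noise sd 3. Normal genes decay so
  the expected score at the first undetected stratum is 60 — comfortably above
  the detection threshold 30, so their young call is confident. HDF genes
  decay so their deepest *detected* score is 30–34, putting the extrapolated
  outgroup score below threshold and triggering the flag.
- **Families**: multicopy probability rises with age from ~0.27 to 0.8
  (matching the direction reported across eukaryotes); ten cross-stratum
  families exercise founder propagation. HDF and contaminant genes stay
  singletons so family information cannot mask those cases.
- **Gene structure**: CDS length lognormal around 1000–1800 bp (old genes
  longer), exon count Poisson around 3–8.3 (old genes more exons); 30 % of
  genes carry a shorter decoy isoform to exercise longest-isoform selection.
- **Expression**: 14 tissues × 2 replicates; expressed tissue means ≥ ~5 TPM
  with 0 elsewhere, so planted breadths are exactly recoverable; young genes
  narrow (breadth ≤ 3, 80 % of the specific ones peaking in brain), old genes
  broad; ~10 %/4 % of new/old genes silent.
- **Stress counts**: negative binomial, dispersion 0.1, baseline lognormal
  (median 150); four contrasts (parasitization, pesticide, virus, host plant)
  with 4 treated vs 4 control replicates and 4-fold planted effects, 70 %
  upregulated, planted on genes with baseline mean ≥ 50 (where real DE calls
  live).
- **Co-expression**: two 40-gene latent-factor blocks (one tied to the
  treatment indicator and containing 10 young genes as planted hubs) plus 30
  noise genes over 20 samples; gene noise sd 0.12 gives within-module
  correlations ~0.98, tight enough for the static tree cut.
- **Ortholog pairs**: 150 pairs of 300 codons; planted synonymous /
  nonsynonymous change counts (new genes 10–14 / 18–26, old genes 6–9 / 2–6)
  sit in distinct codons, one nucleotide each, so pathway-averaged difference
  counts equal the planted counts exactly. RBH tables carry 5 % decoy paralogs
  at 90 % of the query's best score.

**What passing tests show — and don't.** The generator plants exactly the
structures the pipeline is built to detect, with detection guaranteed by
construction (scores above threshold at every planted stratum, expressed
tissues separated from the TPM cutoff). Recovery is therefore expected to be
essentially perfect, and the tests check that the machinery is correct, not
that the method would perform this well on real data. Real hit tables carry
alignment-length and compositional artifacts, incomplete and biased taxon
sampling, and non-exponential score decay; real expression matrices have
batch structure and replicate imbalance. None of these are emulated.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
  rerunning any stage or CLI subcommand with the same seed reproduces outputs
  byte for byte. Run reports record the seed, a config hash and input
  checksums, and deliberately no timestamps.
- MCL convergence: max column change < 1e-6; ties in family labelling broken
  by size then smallest member index.
- Decay fits floor the residual sd at 0.01·a; `b` is bounded at 0 so constant
  scores give the no-decay limit rather than oscillating fits.
- Isoform ties (equal summed CDS) break to the lexicographically smallest
  transcript id — a declared convention, since annotation sources rarely state
  one.
- Wilcoxon/Mann–Whitney on empty groups, correlations on constant vectors, tau
  on all-zero genes, TAI on all-zero samples and chi-square cells with
  expected counts < 1 are all handled explicitly (NaN / skip / pool, reported
  in the output structures rather than raised mid-pipeline, except where the
  inputs are unusable outright).
- The hypergeometric over-representation test uses the survival function at
  k−1 (P(X ≥ k) exactly).

## Known limitations

- The representativeness formula and census are this package's definitions;
  other pipelines may weight subclades or use database-wide taxon counts.
- HDF uses a single closest outgroup and a Gaussian score model; no
  uncertainty is propagated from the curve fit into the flag decision beyond
  the residual sd.
- NG86 only; no transition/transversion or codon-frequency correction, no
  alignment construction (codon alignments are consumed, not produced).
- The DE stand-in tests one contrast at a time with a moderated t on
  log-counts; it is not a replacement for negative-binomial GLMs on real
  designs with covariates.
- Static tree cutting will under-segment loosely correlated modules; the cut
  height must be raised for noisy data, at the cost of merging risk.
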