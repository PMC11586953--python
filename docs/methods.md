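# Methods

## The assay being modeled

PhIP-seq profiles serum antibodies against a phage library displaying a
proteome as overlapping linear peptides. Serum IgG is captured on Protein
A/G beads together with the phage it binds; sequencing the immunoprecipitate
and counting reads per clone yields a clones × samples count matrix.
Bead-only mock immunoprecipitations (no serum) define the null count
distribution per clone. Everything downstream is a comparison of one serum
library against that bead-only reference.

## Tiling library

Proteins are tiled into 49-mer peptides with 25-residue overlaps (step 24).
Two boundary rules make coverage exact with fixed-length peptides:

* if residues remain after the last regular tile, one terminal 49-mer is
  anchored at `length − 49` (its overlap with its predecessor then exceeds
  25);
* proteins shorter than 49 residues yield a single full-length tile
  (padding chemistry is not modeled).

Reverse translation uses a deterministic table of the most-used codon per
residue in highly expressed E. coli genes, so translation of every insert
reproduces its peptide exactly; `X` maps to `NNN`, which the standard
table reads back as `X`. FLAG (`DYKDDDDK`) and STREP (`WSHPQFEK`) tag
sequences flank every insert, and the amplicon template used for read
simulation and mapping is `flank5 + insert + flank3`. Identical peptides
from different proteins keep distinct clone ids because all downstream
pooling is protein-scoped.

## Synthetic data generator

The generator emulates the statistical structure of the study design, not
its chemistry. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `group_sizes` | oMMP 12, MMP 6, BP 3, mcPV 3 | disease-group sera |
| `n_bead_controls` | 36 | bead-only mock IPs |
| `spike_doses` | (10, 2) | two antibody spike-in dose levels |
| `abundance_lognormal_mu/sigma` | 0 / 1 | log-normal baseline clone abundance |
| `nb_dispersion` (φ) | 0.2 | NB overdispersion, variance = μ + φμ² |
| `depth_per_sample` | 50 × clones | total reads per library |
| `signature_proteins_per_group` | 5 | shared antigens per group |
| `epitope_fraction` | 0.5 | fraction of a signature protein's clones enriched |
| `fold_change` | 16 | enrichment of reactive clones |
| `sporadic_rate` | 1.0 | Poisson rate of private reactive proteins per serum |

The per-clone abundance distribution of real display libraries is
unpublished; log-normal with σ = 1 is an assumption recorded in the config.
A fold change of 16 (log2 = 4) represents a clearly reactive antigen — well
above the log2 ≥ 2 hit threshold but low enough that per-clone sampling
noise still matters. Depth of 50 reads per clone keeps control means at a
level where the exact test has resolution (and is far above the 1×/5×
coverage QC lines).

Counts are drawn with an NB/multinomial scheme: per-clone gamma rates
(shape 1/φ, scale φμ, so the marginal is NB(μ, φ)) are renormalized by a
single multinomial draw at fixed depth. Column sums therefore equal the
configured depth exactly while per-clone counts stay overdispersed. At
φ = 0 the rates are the means themselves and counts are effectively
Poisson. Because sample totals are fixed, strong enrichment necessarily
depresses all other clones (composition effect); at realistic library sizes
the reactive mass fraction is small and the effect negligible, but in very
small toy libraries it visibly erodes fold changes — worth knowing when
constructing miniature examples.

Signature antigens are drawn disjointly across groups (each group's
antigens private to it), every member of a group shares its group's
signature set, and each reactive protein contributes a random
`epitope_fraction` subset of its clones. Spike-in folds scale linearly with
dose (`fold − 1 ∝ dose`), reaching `fold_change` at the highest dose and
1 at dose 0. Reads, when simulated, are 5'-anchored prefixes of the clone
template with i.i.d. per-base substitutions.

Not emulated: PCR amplification bias, barcode demultiplexing, non-uniform
error profiles, phage dropout, and cross-reactive epitopes. Passing tests
on this generator show that the statistics behave as designed under the
assumed count model — not that the model captures every pathology of real
libraries.

## Read mapping

Seed-and-extend ungapped alignment: exact 25-mer seeds nominate
(clone, diagonal) candidates; each candidate is scored over the full
read–template overlap at +1 per match, −1 per mismatch (bases hanging off
the template are clipped at score 0). A read is assigned to the unique
best-scoring clone with score ≥ 50 — the threshold then reads directly as
"at least 50 net matching positions" on a 100-nt read, i.e. at most 25
mismatches. Ties between distinct clones are discarded as ambiguous rather
than fractionally assigned: protein-level pooling makes fractional counts
unnecessary and exact tallies keep the conservation invariant (assigned +
ambiguous + sub-threshold = total) testable. Amplicon reads are modeled
ungapped and forward-only by default (clone templates are single-stranded);
a both-strands toggle exists. Coverage QC reports mapped reads ÷ clone
count per sample with 1× and 5× flags (1.0 counts as passing 1×).

## Enrichment test

The two-group comparison for overdispersed counts is an exact conditional
negative-binomial test. After rescaling to a common library size
(size factor = total ÷ geometric mean of totals, rescaled counts rounded),
the serum count X and the pooled control sum Y are modeled as NB(μ, φ) and
NB(n·μ, φ/n) for n controls. Both share the same success parameter, so

    P(X = k | X + Y = t) ∝ C(k + r₁ − 1, k) · C(t − k + r₂ − 1, t − k),

with r₁ = 1/φ, r₂ = n/φ, independent of μ. The two-sided p-value sums the
probabilities of all splits no more probable than the observed one
(minimum-likelihood convention, with a 1 + 1e−7 relative slack so exactly
tied splits are always included — the same convention as R's exact tests).
At φ = 0 the conditional law is Binomial(t, 1/(1 + n)).

Numerical note: the conditional log-weights are computed as cumulative sums
of `log((r + i)/(1 + i))` rather than `gammaln` differences. For φ → 0,
r exceeds 10⁸ and the gammaln route cancels catastrophically (≈1e−6
relative noise); the ratio form is exact to machine precision and lets the
implementation match the conditional binomial limit to < 1e−6 relative
error at φ = 1e−8. The genuine NB-vs-binomial gap at φ = 1e−8 grows as
~k²φ/2, so such limit statements only hold at small counts regardless of
implementation.

Fold change is pseudocount-stabilized on the normalized scale:
`log2((x + 0.5)/(mean(controls) + 0.5))`, with 0.5 chosen so zero counts
are well-defined without dominating moderate counts.

**Dispersion.** Per-clone method-of-moments estimates on normalized
controls, `φ̂ = (var − mean)/mean²` floored at 0, are shrunk toward a
10%-trimmed mean of the per-clone values: `φ = w·φ_common + (1 − w)·φ̂`
with w = 0.7 by default. Tagwise moment estimates from ≤ 36 replicates are
noisy, and *under*-estimating φ inflates significance exactly in the deep
tail the −log10 p > 4 threshold probes, so moderation is deliberately
strong; the weight is exposed for data where clone-specific dispersion
clearly dominates.

**Hit thresholds.** log2 fold change ≥ 2 (inclusive — "at least") and
−log10 p > 4 (strict). Both must hold.

**Blacklist.** Each bead-only control is tested leave-one-out against the
remaining controls with the same test and thresholds; any clone called a
hit in any control is excluded from protein pooling for every serum
sample. Dispersion is re-estimated from the remaining controls within each
leave-one-out fold — estimating it once from all controls would let a
contaminated control inflate the dispersion used to judge itself and
escape the blacklist.

## Group analysis

A sample is reactive to a protein iff at least one non-blacklisted clone of
that protein is a hit (Boolean OR across epitopes). Each group is compared
against the pooled remaining sera per protein with the two-sided Fisher
exact test under the same minimum-likelihood convention (a doubled-one-tail
variant sits behind a flag but is not the default, because the
minimum-likelihood convention reproduces the published worked-example
p-values). Significance is p < 0.05 per protein with no multiple-testing
correction — false discovery is controlled upstream by the bead-control
blacklist, and a BH option exists in the annotation module where it is
standard. Displayed percentages truncate toward zero (8/12 → 66), matching
the reporting style of the source tables.

Row z-scores of the protein × group proportion matrix use the sample
(ddof = 1) standard deviation by default — with four groups this makes a
lone reactive group come out at exactly (1.5, −0.5, −0.5, −0.5) — with a
ddof switch for the population convention; zero-spread rows map to zeros.

## Annotation

Over-representation is the upper-tail hypergeometric test of a gene list
against each GMT set over an explicit background, BH-adjusted across terms.
The background defaults to the tiled proteome's gene symbols: the assay
cannot report genes it does not display, so a whole-genome universe would
overstate enrichment. Symbols match case-insensitively with an alias-map
hook. Expression cross-referencing reports, per query gene, detection, the
maximal cell type, and an "epithelial" flag over a configurable cell-type
grouping (by default any column naming corneal/limbal/conjunctival/goblet
epithelium); absent genes are flagged not detected rather than dropped.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at reduced
scale: a ~2,000-clone library (300 proteins of 60–300 residues) for null
calibration, the default 200-protein design for recovery and spike-in
checks, and a 25-protein library for read-level round trips. These sizes
give tens of thousands of clone-level tests — enough to measure tail rates
near 1e−4 — while a full run completes in about a minute on one CPU. Every
stochastic step draws from `numpy.random.default_rng` seeded from a single
configuration seed (sub-streams per component), so identical configurations
are byte-identical.

## Known limitations

* The enrichment test conditions on rounded size-factor-normalized counts;
  with near-equal sequencing depths (the simulator's regime) rounding is
  a no-op, but with extreme depth imbalance the rounding step loses
  information a GLM would keep.
* Geometric-mean size factors do not correct composition bias from very
  large reactive fractions (no trimmed-mean-of-ratios normalization).
* The mapper is exact-seed based: reads whose every 25-mer contains an
  error find no candidate and are discarded; at 1% substitution error this
  loses well under 1% of 100-nt reads, but error-dense data would need a
  spaced-seed or gapped extension.
* ORA replaces ranked combined-score enrichment (which depends on
  service-internal background statistics) with the plain hypergeometric
  test; results are comparable in ordering but not in score magnitude.
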