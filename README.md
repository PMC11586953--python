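# phipseq

Analysis pipeline for **PhIP-seq** (Phage Immunoprecipitation Sequencing)
autoantibody profiling, built around the study design used to compare
autoimmune blistering disease (AIBD) sera: ocular-predominant mucous
membrane pemphigoid (oMMP) versus non-ocular MMP, bullous pemphigoid and
mucocutaneous pemphigus vulgaris, with bead-only mock immunoprecipitations
as the null reference.

PhIP-seq displays a proteome as overlapping linear peptides on T7 phage,
immunoprecipitates the phage bound by serum IgG, and sequences the
enriched clones. The package covers the full computational arc:

1. **Tiling library construction** (`phipseq.tiling`) — each protein is cut
   into 49-mer peptides overlapping by 25 residues (step 24, one terminal
   tile anchored at `length − 49` so every residue is covered), reverse
   translated with a deterministic E. coli codon table and flanked by
   FLAG/STREP tag sequences.
2. **Synthetic experiments** (`phipseq.simulate`) — a generator with known
   ground truth: log-normal baseline clone abundances, negative-binomial
   counts renormalized to fixed sequencing depth, 36 bead-only controls,
   disease groups of 12/6/3/3 sera sharing per-group signature antigens,
   sporadic private reactivities, and a two-dose antibody spike-in.
3. **Read mapping** (`phipseq.mapping`) — seed-and-extend ungapped
   alignment with +1/−1 scoring; a read is counted to the unique
   best-scoring clone with score ≥ 50 (i.e. at least 50 net matching
   positions); ties and sub-threshold reads are discarded and logged.
   Coverage QC flags the 1× and 5× library-coverage levels.
4. **Enrichment calling** (`phipseq.enrichment`) — for every clone in every
   serum sample, an exact conditional negative-binomial test against the
   pooled bead controls. With serum count X ~ NB(μ, φ) and control sum
   Y ~ NB(n·μ, φ/n) on a common library-size scale, the law of X given
   X + Y is free of μ, and the two-sided p sums all splits no more probable
   than the observed one. Hits require log2 fold change ≥ 2 **and**
   −log10 p > 4. Clones enriched in any bead-only control (leave-one-out)
   are blacklisted.
5. **Group comparison** (`phipseq.groups`) — clone hits pool to Boolean
   protein reactivity (any epitope counts), and each disease group is
   compared against the pooled rest per protein with a two-sided Fisher
   exact test; proteins at p < 0.05 are that group's *distinct antigens*.
   Z-scored proportion matrices and Venn-style set overlaps support
   reporting.
6. **Annotation** (`phipseq.annotation`) — offline hypergeometric
   over-representation analysis of antigen gene lists against GMT gene
   sets with Benjamini–Hochberg adjustment, and cross-referencing against
   a gene × cell-type expression table (e.g. ocular-surface epithelium).

## Worked example

```python
from phipseq import (SimConfig, build_library, random_proteome, simulate_experiment,
                     run_enrichment, collapse_to_protein, group_vs_rest, fisher_exact_2x2)

# The Fisher statistic used for group comparison: 10/12 reactive sera in the
# group of interest vs 2/12 in the pooled rest.
p = fisher_exact_2x2(10, 2, 2, 10)
print(f"two-sided Fisher p for 10/12 vs 2/12 reactive: {p:.6f} (rounds to {round(p, 3)})")

config = SimConfig(seed=1, n_proteins=60, protein_len_range=(80, 250),
                   group_sizes={"oMMP": 6, "BP": 4}, n_bead_controls=12,
                   signature_proteins_per_group=2)
library = build_library(random_proteome(config))
counts, meta, truth = simulate_experiment(config, library, spike_target=library.protein_ids[0])
print(f"library: {library.n_clones} clones; counts: {counts.df.shape[0]} x {counts.df.shape[1]}")

outcome = run_enrichment(counts, meta)
print(f"clone hits: {int(outcome.results['is_hit'].sum())}, blacklisted clones: {len(outcome.blacklist)}")

reactivity = collapse_to_protein(outcome.hits_by_sample(), library,
                                 blacklist=outcome.blacklist)
comp = group_vs_rest(reactivity, meta, "oMMP")
print(comp.loc[comp["distinct"], ["protein_id", "a", "c", "p", "pct_group", "pct_rest"]]
      .to_string(index=False))
```

Output:

```
two-sided Fisher p for 10/12 vs 2/12 reactive: 0.003329 (rounds to 0.003)
library: 381 clones; counts: 381 x 24
clone hits: 111, blacklisted clones: 1
protein_id  a  c        p  pct_group  pct_rest
     P0019  6  0 0.004762        100         0
     P0030  6  0 0.004762        100         0
     P0055  0  4 0.004762          0       100
     P0056  0  4 0.004762          0       100
```

The four distinct antigens are exactly the two signature proteins planted
in each group by the simulator: P0019/P0030 are reactive in all six oMMP
sera and no others (p = 0.0048 for 6/6 vs 0/4), and symmetrically for the
BP signatures. Percentages are truncated toward zero, matching the
convention used when reporting reactive-patient proportions.

There is also a command-line interface with `tile`, `simulate`, `map`,
`call`, `compare`, `enrich` and `crossref` subcommands (`phipseq --help`).

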