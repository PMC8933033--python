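# cstkit

Community state type (CST) analysis for microbiome relative-abundance
profiles: from species-level abundance tables to called CSTs,
compartment-level prevalence and gradient reports, richness and
beta-diversity statistics, and enzyme-class (EC) functional comparisons.
A fully planted-truth synthetic data generator makes every stage testable
offline.

## What it does

- **profiles_io** — load/validate samples×taxa abundance TSVs (percent or
  fraction, autodetected), per-sample metadata (sampling method →
  anatomical compartment), EC-number and pathway tables; align them into
  one dataset.
- **cst_core** — Pearson-correlation distance (`d = 1 − r`), UPGMA
  hierarchical clustering, silhouette-guided selection of the cluster
  number, retention filters (minimum size as a fraction of all samples,
  minimum number of source bioprojects), core-taxon characterization
  (prevalence > 85%, most abundant core taxon names the CST), and
  flagging of putative clusters (unresolved defining species or
  single-bioproject clusters).
- **ordination_stats** — Bray–Curtis, classical PCoA, distance-based
  PERMANOVA with seeded permutations, species richness, Welch
  t / Mann–Whitney tests, one-way ANOVA + Tukey–Kramer HSD,
  Benjamini–Hochberg FDR, and a simple per-feature arcsin-sqrt linear
  association model.
- **gradients** — CST-by-group prevalence tables, shared-species sets per
  compartment (mean abundance > 1%), and ordered abundance-gradient
  detection via a permutation Jonckheere–Terpstra trend test.
- **functional** — EC top-level class profiles (renormalized over
  annotated reads), per-class group comparisons, compartment-unique
  pathway counting.
- **synthetic** — Dirichlet-mixture generator with planted CSTs,
  compartment-linked CST prevalences, gradient taxa, richness gaps,
  EC-class shifts and compartment-private pathways; plus planted-truth
  recovery metrics (ARI, defining-taxon accuracy).

## CLI

```sh
# generate a synthetic dataset with planted truth
cstkit simulate --seed 1 --n-samples 850 --out run/

# cluster and call CSTs (omit --k to pick it by silhouette)
cstkit call-csts --abundance run/abundance.tsv --metadata run/metadata.tsv \
    --k-min 2 --k-max 20 --min-fraction 0.01 --min-datasets 2 \
    --core-prevalence 0.85 --seed 1 --out run/csts/

# gradient and functional reports
cstkit gradients --abundance run/abundance.tsv --metadata run/metadata.tsv \
    --taxon "Streptococcus pneumoniae" --order nasal,throat,sputum,lung \
    --out run/gradients.tsv
cstkit functional --ec run/ec.tsv --pathways run/pathways.tsv \
    --metadata run/metadata.tsv --out run/functional/

# everything at once
cstkit report --abundance run/abundance.tsv --metadata run/metadata.tsv \
    --ec run/ec.tsv --pathways run/pathways.tsv --out run/report/
```

All inputs and outputs are plain TSV/JSON (Newick for the dendrogram);
every run writes a resolved-config copy for bit-for-bit reproduction.

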