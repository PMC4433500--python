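# pedilink

Pedigree-based genetic appraisal of a dominant, low-penetrance disease
locus linked to a biallelic marker, as used to dissect inherited canine
cardiomyopathy in multi-generation show-dog pedigrees:

* **pedigree_core** — PLINK-style PED + phenotype-CSV data model,
  validation, founders/ancestors/descendants, Wright's inbreeding
  coefficient by recursive kinship.
* **descent_tracing** — obligate-transmitter identification (affected
  dogs, and unaffected dogs with affected progeny from several different
  mates), line-of-descent tracing to founder/import sources, and
  at-risk vs clear-by-pedigree classification.
* **linkage_inference** — carrier status, coupling/repulsion phase of the
  marker mutation relative to the disease allele (marker homozygotes are
  phase-certain; heterozygotes only by forced transmission from a
  marker-homozygous carrier parent), recombination-event detection, and
  per-group genotype count tables.
* **assoc_stats** — uncorrected Pearson χ² genotype-frequency comparison,
  Hardy–Weinberg χ² (df = 1), pooled-variance two-sample t test,
  table-plus-footnotes summary report.
* **penetrance** — segregation-ratio penetrance estimate from
  carrier × clear matings (penetrance = 2 × affected fraction, Wilson CI)
  and a transmitter-expression report.
* **synthetic_data** — gene-dropping simulator (two linked loci,
  recombination fraction θ, incomplete penetrance, log-normal onset with
  censoring, popular-sire breeding, Poisson litters) with full ground
  truth, plus a deterministic fixture reproducing the published genotype
  count table.

## Command line

```bash
pedilink simulate --config sim.yaml --seed 7 --out-dir sim/   # gene drop
pedilink validate --ped sim/pedigree.ped --pheno sim/phenotypes.csv --out report.json
pedilink trace    --ped sim/pedigree.ped --pheno sim/phenotypes.csv --min-mates 2 --out lines.json
pedilink phase    --ped sim/pedigree.ped --pheno sim/phenotypes.csv --out phases.json
pedilink recomb   --ped sim/pedigree.ped --pheno sim/phenotypes.csv --out events.json
pedilink penetrance --ped sim/pedigree.ped --pheno sim/phenotypes.csv --out penetrance.json
pedilink assoc --tables tables.json --compare line1_cases,line2_cases \
               --hwe holter_normals --out assoc.json
```

PED dialect: whitespace-delimited `family id sire dam sex phenotype`
(missing parent `0`; sex 1 = male, 2 = female, 0 = unknown; phenotype
1 = unaffected, 2 = affected, 0/-9 = unknown).  The phenotype CSV has
header `id,affection,onset_age,severity,strn` with optional `litter` and
`import` columns; `strn` is `HOM`/`HET`/`WT` or empty for untyped.

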