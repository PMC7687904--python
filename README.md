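# qtlannot

LD-aware annotation of QTL summary statistics, as a local library and CLI.

Genome-wide association studies (GWAS) mostly implicate non-coding variants,
and the usual route from a variant to a candidate gene runs through
quantitative trait loci — eQTLs (expression), pQTLs (protein) and reQTLs
(response).  Public QTL datasets are heterogeneous: different columns,
tissue-name spellings, significance conventions, and often only the
significant tail of the association table.  `qtlannot` harmonizes such tables
into one canonical store, computes per-record prioritization flags and count
statistics, classifies cis/trans by topologically associating domains (TADs)
rather than a fixed base-pair cutoff, links records to the GWAS Catalog, and
answers mixed variant/gene queries with optional linkage-disequilibrium (LD)
proxy expansion.  It is written for statistical geneticists who want the
annotation logic of a hosted QTL portal as inspectable, testable local code.

## The model

The unit of annotation is the **QTL object**: the quadruple
*(variant, gene, tissue, source study)*.  One **tissue-specific study** is a
(source, tissue) pair.  For each record the engine computes:

* **is_sw_significant** — study-wide significance.  If the source published a
  significance call, it is used; otherwise a Bonferroni/FWER rule applies:

  `P ≤ α / (n_variants × n_genes)`

  with α = 0.05, 10⁶ variants and 5×10⁴ genes giving the default threshold
  `10⁻¹²`.
* **is_best** — the lowest P value within its tissue-specific study (ties all
  flagged).
* **is_best_in_ld_group** — lowest P among records whose variants lie in the
  record's **LD group**: the variant plus all variants with pairwise
  r² > 0.2 against it (strictly pairwise, no transitive closure).  Pairwise
  r² and D′ are computed from phased haplotypes by direct 2×2 counting:
  D = p_AB − p_A·p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)), D′ = |D|/D_max.
* **cis / trans** — cis iff a single TAD contains both the variant position
  and the gene start.
* a signed variant–gene distance in kb (0 inside the gene body), GWAS Catalog
  variant/gene hits, and counts `n_qtls`, `n_best`, `n_sw_significant`,
  `n_occ` over tissue-specific studies.

Two explorative analyses are built on top: the distribution of distances from
gene start to the best study-wide-significant eQTL per tissue-specific study,
and cross-study sharing — per gene, best eQTLs are pooled across studies and
single-linkage-grouped into LD blocks at r² thresholds
(>0.6, >0.8, >0.9, >0.95, =1, no LD); the gene is scored by the block
covering the most studies, and the top-k genes are tested for overlap with
reference sets (housekeeping, top-expressed) by a one-sided hypergeometric
test with Benjamini–Hochberg adjustment across the threshold × set family.

## Worked example

The package ships a deterministic fixture generator, so the whole pipeline
runs without downloads:

```sh
qtlannot synth --seed 11 -o fixtures/
qtlannot ingest  --manifest fixtures/manifest.json --genes fixtures/genes.tsv -o store.tsv
qtlannot annotate --store store.tsv --genes fixtures/genes.tsv \
    --tads fixtures/tads.bed --ld fixtures/ld.tsv \
    --gwas fixtures/gwas_catalog.tsv -o annotated.tsv
qtlannot query --terms "rs100000 GENE0000" --store annotated.tsv \
    --genes fixtures/genes.tsv --ld fixtures/ld.tsv -o result.tsv
qtlannot analyze enrich --store annotated.tsv --genes fixtures/genes.tsv \
    --ld fixtures/ld.tsv --geneset hk=fixtures/genesets/housekeeping.txt \
    --top-k 5 -o enrich.tsv
```

In the library, the bundled worked-example store reproduces a typical
GWAS-locus annotation session:

```python
>>> import qtlannot as qa
>>> store = qa.use_case_store()
>>> ann = qa.annotate_store(store)
>>> rows = qa.run_query(qa.parse_terms("rs2306374"), ann,
...                     gene_index=store.gene_index).rows
>>> len(rows)
31
>>> len(qa.aggregate(rows))
7
>>> mras = qa.filter_rows(rows, ["gene=MRAS"])
>>> len(mras), all("is_sw_significant" in r.annotated.flags for r in mras)
(14, True)
```

The index SNP has 31 QTL records; aggregation shows it is an eQTL for seven
genes; restricting to the MRAS gene leaves 14 records, all study-wide
significant, with distance 0 kb (the SNP is intronic of MRAS).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a seeded synthetic bundle, runs ingest → annotate → query →
distance/sharing/enrichment end to end, prints a one-line summary of what was
computed to stderr, and writes the result summary JSON to `--out`.
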