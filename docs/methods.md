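# Methods

## Scope and data model

`qtlannot` annotates QTL summary statistics without statistically combining
them: studies differ in sample size, genotyping and expression platform, so
the engine computes per-record flags and counts that let a user prioritize,
rather than meta-analytic estimates.  The identity of a record is the
quadruple (variant, gene, tissue, source study); statistics (P, beta,
alleles) are attributes, not identity.  Genes are keyed by stable identifier;
symbols and synonyms are labels resolved at query time.  Tissue names are
normalized before identity assignment, because "best per tissue-specific
study" groups on the normalized (source, tissue) pair.

Coordinates: intervals (genes, TADs) are 0-based half-open internally; BED is
read as-is, GTF/TSV/VCF 1-based inputs are converted at the boundary.
Variant positions stay 1-based, matching VCF and summary-statistics
convention; containment checks subtract one.  Genome builds are carried per
record and never mixed within a store (no liftover).

## Significance

Datasets that publish their own significance calls keep them
(`significance_policy: source_provided`); all others get a family-wise
Bonferroni threshold α/(n_variants × n_genes).  Defaults α = 0.05, 10⁶
variants, 5×10⁴ genes (roughly the non-pseudogene gene count) give 10⁻¹².
The boundary is inclusive (P exactly at the threshold passes): "passing a
threshold" is read as ≤, and the choice is documented rather than load-bearing
— P values exactly at a power of ten are measure-zero in real data.

## LD

r² and D′ are computed from phased haplotypes by direct counting; unphased
genotypes (EM estimation) are out of scope since reference panels ship phased.
Monomorphic variants raise an explicit error — LD is undefined, and silent
zeros would corrupt group membership.  Pairwise computation is restricted to
a window (default 1 Mb) to bound cost; a precomputed pairwise TSV
(`variant_a variant_b r2 dprime`) is accepted as an alternative input, and
absent pairs read back as r² = 0.

Two deliberately different threshold semantics coexist:

* **LD group** (drives `is_best_in_ld_group`): seed plus all variants with
  r² **strictly >** 0.2 against the seed, pairwise only.
* **Proxy search** (query expansion): metric (r² or D′) **≥** the
  user-supplied threshold, matching the "set a threshold" UI semantics.

Variants absent from the LD reference form singleton groups and are therefore
conservatively flagged best-in-group; the group object carries a
`no_ld_data` marker.

`is_best_in_ld_group` compares, by default, only records of the same gene
within the tissue-specific study — a QTL is a variant–gene claim, and
comparing across genes would let a strong eQTL of one gene mask an
independent signal for another.  A `same_gene=False` switch (CLI
`--gene-agnostic-ld`) provides the gene-agnostic reading; both are tested.

## cis/trans and distance

cis means a single TAD contains both the variant position and the gene
anchor; everything else — different chromosomes, positions outside all TADs,
an empty TAD set — is trans.  Overlapping TADs are allowed; containment by
*any* one suffices.  The gene anchor is the gene start by default; a
strand-aware TSS anchor is available but off, since the distance analysis is
defined from the gene start.  The per-record distance is signed kb from the
nearest gene boundary, 0 inside the gene body, absent across chromosomes.
The distance *analysis* instead measures gene start → best-eQTL position
(signed bp), which is the quantity whose distribution is summarized;
summary mean/median use absolute values (the distribution is viewed on a log
scale), signed values are retained per entry.

## Sharing and enrichment

Per gene and tissue-specific study, only the best (lowest P, ties broken by
variant key for determinism) study-wide-significant eQTL enters the sharing
analysis.  Pooled best variants are partitioned by single-linkage clustering
over pairwise r² at each threshold — single linkage is the standard "LD
block" notion and is checkable against a hand partition; a pairwise-to-seed
alternative exists in the LD engine but is not used here.  Threshold
semantics: `> t` for t < 1, `= 1` for the perfect-proxy level, and "no LD"
puts every variant in its own block (the strictest partition, so the per-gene
maximum study count is non-increasing along 0.6 → 0.8 → 0.9 → 0.95 → 1.0 →
no-LD).  Unknown pairs count as r² = 0.

Enrichment: the universe is every gene with at least one best study-wide
significant eQTL.  Top-k genes (k = 100 by default; ties at the k-th count
broken by gene id) are tested against each reference set with the one-sided
upper-tail hypergeometric P, then BH-adjusted across the full
threshold × set family (6 × 2 = 12 tests with the default inputs).  The
top-expressed reference set is an input list; a helper derives it from a
genes × tissues expression matrix.

## Synthetic fixtures

The generator emits every input dialect the readers consume and a
ground-truth sidecar.  The stated world of the defaults: 20 genes across two
chromosomes, 120 variants, 4 sources × 3 tissues (12 tissue-specific
studies), 100 phased haplotypes, LD blocks of 3 variants at a within-block
r² target of 0.9 (hit to ±0.05 by rejection sampling on flip-noise copies of
a base column), significance threshold 10⁻¹², 4 planted sharing genes whose
best eQTLs rotate through one block in 6 studies, and best-eQTL distances
drawn log-normal with median 28 kb and σ = 1.6 (mean ≈ 100 kb) — the scale
reported for large multi-tissue eQTL resources.  TAD layouts use gamma
lengths with mean 853 kb, clipped to the published 0.8 kb–4.44 Mb range.

What the generator does *not* emulate: coalescent population structure
(haplotypes are structured noise sufficient to hit r² targets), allele
frequency spectra, distance-decaying LD, multi-population panels, or the
scale of real resources (tens of millions of records).  A green recovery test
therefore establishes that the pipeline's bookkeeping — flags, blocks,
counts, distances — is correct, not that the method would reproduce any
real-data estimate.  The bundled worked-example store mirrors the structure
(31 records / 7 genes / 14 significant) of a published annotation session and
is synthetic.

P values are planted disjointly: the designated best record of a (gene,
study) draws log-uniform from [10⁻²⁰, 10⁻¹⁵], other significant records from
[10⁻¹⁴, 10⁻¹²], non-significant from [10⁻¹¹, 1]; the planted best is
therefore always the study minimum and recovery is exact, not probabilistic.

## Numerical and degenerate-input choices

* r²/D′ are clipped into [0, 1] against floating-point overshoot at the
  boundaries; oracle comparisons run at 10⁻¹² relative error.
* Exact P ties: `is_best` flags all tied records (inventing a tie-break would
  fabricate a distinction); analyses that must pick one record break ties by
  variant key, then gene id — deterministic and order-independent.
* Duplicate quadruples within a dataset keep the smallest-P row and log the
  collision; row accounting (records out = rows in − rejected − duplicates)
  is asserted after every read.
* Empty TAD set ⇒ everything trans; empty significant set ⇒ empty distance
  summary (not an error); reference set disjoint from the universe ⇒
  overlap 0, P = 1.
* Query limits default to 50 terms and 10,000 rows (mirroring the practical
  limits of interactive use) but are plain parameters, since a local tool has
  no browser constraint.  Positional variant terms default to hg19; a
  `:hg38` suffix overrides.
* A record reachable both directly and via a proxy is reported once, with the
  direct route preferred, then the highest-r² proxy route.

## Known limitations

* LD windowing means very distant intra-chromosomal pairs are never computed
  from a panel; genome-wide grouping requires a precomputed table.
* The gene-term resolver is deliberately simple (id > symbol > synonym,
  lexicographic tie-break with the ambiguity reported); no full-text
  prioritization.
* No colocalization statistics: the annotated export is intended as input to
  dedicated tools.
* TAD boundaries are treated as cell-type invariant, which published Hi-C
  comparisons support only approximately.
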