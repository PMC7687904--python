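"""Per-record annotation: significance, best flags, cis/trans, GWAS links, counts.

The transformation stage of the pipeline.  Each QTL object (variant, gene,
tissue, source study) receives:

* ``is_sw_significant`` — P at or below the dataset's study-wide threshold
  (source-provided call, or Bonferroni/FWER over all variant-gene tests:
  alpha / (n_variants x n_genes), the 5% FWER giving 1e-12 at 1e6 variants
  and 5e4 genes);
* ``is_best`` — the overall lowest P in its tissue-specific study
  (one (source, tissue) pair); exact ties are all flagged;
* ``is_best_in_ld_group`` — lowest P among records whose variants fall in the
  record's LD group (seed + pairwise r² > 0.2); variants without LD data are
  their own group and therefore flagged;
* ``cis``/``trans`` — whether a single TAD contains both the variant position
  and the gene anchor (gene start by default);
* a signed variant-gene distance in kb (0 inside the gene body);
* GWAS Catalog variant/gene hits; and
* count statistics n_qtls, n_best, n_sw_significant, n_occ.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import AnnotatedQtl, QtlAnnotError, QtlRecord
from .ingest import GwasIndex, QtlStore, TadSet
from .ld import DEFAULT_LD_GROUP_R2, LdStore

__all__ = [
    "SignificancePolicyResult",
    "fwer_threshold",
    "flag_sw_significant",
    "flag_best",
    "flag_best_in_ld_group",
    "classify_cis_trans",
    "compute_distance",
    "link_gwas",
    "compute_counts",
    "annotate_store",
    "annotated_to_frame",
    "write_annotated_tsv",
    "read_annotated_tsv",
    "ANNOT_COLUMNS",
]


@dataclass(frozen=True)
class SignificancePolicyResult:
    """The significance threshold in force for one dataset, with provenance."""

    threshold: float
    provenance: str  # {"source_provided", "fwer_derived"}
    n_variants: int | None = None
    n_genes: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise QtlAnnotError(
                f"significance threshold must be in (0,1), got {self.threshold}")


def fwer_threshold(alpha: float = 0.05, n_variants: int = 1_000_000,
                   n_genes: int = 50_000) -> float:
    """Bonferroni threshold over all variant-gene tests: alpha / (V x G).

    With the defaults (5% FWER, one million variants, fifty thousand genes —
    roughly the non-pseudogene gene set) this is 1e-12.
    """
    if not (0.0 < alpha < 1.0):
        raise QtlAnnotError(f"alpha must be in (0,1), got {alpha}")
    n_variants, n_genes = int(n_variants), int(n_genes)
    if n_variants < 1 or n_genes < 1:
        raise QtlAnnotError("n_variants and n_genes must be >= 1")
    return alpha / (n_variants * n_genes)


def _wrap(store: QtlStore | list[QtlRecord]) -> list[AnnotatedQtl]:
    records = store.records if isinstance(store, QtlStore) else store
    return [AnnotatedQtl(record=r) for r in records]


def flag_sw_significant(annotated: list[AnnotatedQtl],
                        thresholds: dict[tuple[str, str], float],
                        default_threshold: float = 1e-12) -> None:
    """Study-wide significance: source-provided call, else P <= dataset threshold.

    The boundary is inclusive (a record exactly at the threshold passes).
    """
    for a in annotated:
        r = a.record
        if (r.study.significance_policy == "source_provided"
                and r.source_significant is not None):
            a.is_sw_significant = bool(r.source_significant)
        else:
            thr = thresholds.get((r.study.source, r.study.study),
                                 default_threshold)
            a.is_sw_significant = r.p_value <= thr


def flag_best(annotated: list[AnnotatedQtl]) -> None:
    """Lowest P within each tissue-specific study ((source, tissue) pair).

    Exact P ties are all flagged; inventing a tie-break would fabricate a
    distinction the data does not support.
    """
    best: dict[tuple[str, str], float] = {}
    for a in annotated:
        key = a.record.study.tissue_study
        p = a.record.p_value
        if key not in best or p < best[key]:
            best[key] = p
    for a in annotated:
        a.is_best = a.record.p_value == best[a.record.study.tissue_study]


def flag_best_in_ld_group(annotated: list[AnnotatedQtl],
                          ld_store: LdStore | None,
                          r2_threshold: float = DEFAULT_LD_GROUP_R2,
                          same_gene: bool = True) -> None:
    """Lowest P among all records whose variant lies in the record's LD group,
    within the same tissue-specific study.

    By default the comparison is restricted to records of the same gene (a QTL
    is a variant-gene claim); ``same_gene=False`` compares across genes.
    Variants absent from the LD reference form singleton groups and are
    flagged.  With no LD store at all, every variant is a singleton.
    """
    groups: dict[tuple, list[AnnotatedQtl]] = {}
    for a in annotated:
        key = a.record.study.tissue_study
        if same_gene:
            key = key + (a.record.gene.gene_id,)
        groups.setdefault(key, []).append(a)
    cache: dict[str, frozenset[str]] = {}
    for members in groups.values():
        by_variant: dict[str, float] = {}
        for a in members:
            k = a.record.variant.key
            p = a.record.p_value
            if k not in by_variant or p < by_variant[k]:
                by_variant[k] = p
        for a in members:
            vkey = a.record.variant.key
            if ld_store is None:
                a.is_best_in_ld_group = True
                continue
            if vkey not in cache:
                cache[vkey] = ld_store.build_ld_group(
                    vkey, r2_threshold=r2_threshold).members
            group = cache[vkey]
            min_p = min(by_variant[v] for v in group if v in by_variant)
            a.is_best_in_ld_group = a.record.p_value <= min_p


def compute_distance(record: QtlRecord) -> float | None:
    """Signed variant-gene distance in kb.

    0 when the variant lies within the gene body; positive when it is past the
    gene (position > gene start side), negative upstream; absent (None) when
    variant and gene are on different chromosomes or position is unknown.
    """
    v, g = record.variant, record.gene
    if v.chrom is None or v.pos is None or v.chrom != g.chrom:
        return None
    if g.contains_pos(v.pos):
        return 0.0
    if v.pos > g.end_1based:
        return (v.pos - g.end_1based) / 1000.0
    return (v.pos - g.start_1based) / 1000.0


def classify_cis_trans(record: QtlRecord, tad_set: TadSet | None,
                       strand_aware_anchor: bool = False) -> str:
    """cis iff a single TAD contains both the variant and the gene anchor.

    Different chromosomes, positions outside any TAD, an unknown variant
    position, or an empty TAD set all classify as trans.
    """
    v, g = record.variant, record.gene
    if tad_set is None or len(tad_set) == 0:
        return "trans"
    if v.chrom is None or v.pos is None or v.chrom != g.chrom:
        return "trans"
    anchor = g.anchor(strand_aware=strand_aware_anchor)
    return "cis" if tad_set.same_tad(v.chrom, v.pos - 1, g.chrom, anchor) \
        else "trans"


def link_gwas(annotated: list[AnnotatedQtl],
              catalog: GwasIndex | None) -> None:
    """Variant rsID and gene-symbol matches against the GWAS Catalog index."""
    for a in annotated:
        if catalog is None:
            a.gwas_variant_hit = a.gwas_gene_hit = False
            continue
        a.gwas_variant_hit = catalog.has_variant(a.record.variant.rsid)
        a.gwas_gene_hit = catalog.has_gene(a.record.gene.symbol)


def compute_counts(annotated: list[AnnotatedQtl]) -> None:
    """Count statistics, computed after the flags.

    Per (variant, gene): ``n_occ`` = number of tissue-specific studies
    ((source, tissue) pairs) in which the putative QTL occurs, ``n_best`` /
    ``n_sw_significant`` = those in which it carries the respective flag.
    Per (gene, source, tissue): ``n_qtls`` = number of variant records.
    """
    occ: dict[tuple, set] = {}
    best: dict[tuple, set] = {}
    sig: dict[tuple, set] = {}
    qtls: dict[tuple, int] = {}
    for a in annotated:
        r = a.record
        vg = (r.variant.key, r.gene.gene_id)
        ts = r.study.tissue_study
        occ.setdefault(vg, set()).add(ts)
        if a.is_best:
            best.setdefault(vg, set()).add(ts)
        if a.is_sw_significant:
            sig.setdefault(vg, set()).add(ts)
        gkey = (r.gene.gene_id,) + ts
        qtls[gkey] = qtls.get(gkey, 0) + 1
    for a in annotated:
        r = a.record
        vg = (r.variant.key, r.gene.gene_id)
        a.n_occ = len(occ[vg])
        a.n_best = len(best.get(vg, ()))
        a.n_sw_significant = len(sig.get(vg, ()))
        a.n_qtls = qtls[(r.gene.gene_id,) + r.study.tissue_study]


def annotate_store(store: QtlStore,
                   ld_store: LdStore | None = None,
                   tad_set: TadSet | None = None,
                   gwas_catalog: GwasIndex | None = None,
                   ld_group_r2: float = DEFAULT_LD_GROUP_R2,
                   same_gene_ld: bool = True,
                   strand_aware_anchor: bool = False) -> list[AnnotatedQtl]:
    """Run every annotation stage over the store, in dependency order.

    Deterministic and order-independent: shuffling the input rows changes
    nothing but the row order of the output.
    """
    annotated = _wrap(store)
    flag_sw_significant(annotated, store.thresholds)
    flag_best(annotated)
    flag_best_in_ld_group(annotated, ld_store, r2_threshold=ld_group_r2,
                          same_gene=same_gene_ld)
    for a in annotated:
        a.colocalization = classify_cis_trans(
            a.record, tad_set, strand_aware_anchor=strand_aware_anchor)
        a.distance_kb = compute_distance(a.record)
    link_gwas(annotated, gwas_catalog)
    compute_counts(annotated)
    for a in annotated:
        a.validate()
    return annotated


# ---------------------------------------------------------------------------
# Export / import of the annotated table view

ANNOT_COLUMNS = ["rsid", "chrom", "pos", "build", "gene_id", "gene_symbol",
                 "distance_kb", "tissue", "p", "beta", "ea", "nea", "source",
                 "study", "qtl_type", "colocalization", "flags",
                 "gwas_variant", "gwas_gene", "n_qtls", "n_best",
                 "n_sw_significant", "n_occ", "sig_threshold",
                 "significance_policy"]


def annotated_to_frame(annotated: list[AnnotatedQtl],
                       thresholds: dict[tuple[str, str], float] | None = None,
                       ) -> pd.DataFrame:
    """One row per annotated QTL object, columns matching the table view."""
    thresholds = thresholds or {}
    rows = []
    for a in annotated:
        r = a.record
        rows.append({
            "rsid": r.variant.rsid or "",
            "chrom": r.variant.chrom or "",
            "pos": r.variant.pos if r.variant.pos is not None else "",
            "build": r.variant.build,
            "gene_id": r.gene.gene_id,
            "gene_symbol": r.gene.symbol,
            "distance_kb": "" if a.distance_kb is None else repr(a.distance_kb),
            "tissue": r.study.tissue,
            "p": repr(r.p_value),
            "beta": "" if r.beta is None else repr(r.beta),
            "ea": r.effect_allele or "",
            "nea": r.non_effect_allele or "",
            "source": r.study.source,
            "study": r.study.study,
            "qtl_type": r.study.qtl_type,
            "colocalization": a.colocalization,
            "flags": a.flags,
            "gwas_variant": int(a.gwas_variant_hit),
            "gwas_gene": int(a.gwas_gene_hit),
            "n_qtls": a.n_qtls,
            "n_best": a.n_best,
            "n_sw_significant": a.n_sw_significant,
            "n_occ": a.n_occ,
            "sig_threshold": repr(thresholds.get(
                (r.study.source, r.study.study), 1e-12)),
            "significance_policy": r.study.significance_policy,
        })
    return pd.DataFrame(rows, columns=ANNOT_COLUMNS)


def write_annotated_tsv(annotated: list[AnnotatedQtl], path: str,
                        thresholds=None,
                        header_lines: list[str] | None = None) -> None:
    df = annotated_to_frame(annotated, thresholds)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_annotated_tsv(path: str, gene_index) -> list[AnnotatedQtl]:
    """Round-trip reader for the annotated table view (used by query/analyze)."""
    from .core import StudyKey, VariantKey

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out: list[AnnotatedQtl] = []
    for row in df.itertuples(index=False):
        gene = gene_index.get(row.gene_id)
        if gene is None:
            raise QtlAnnotError(f"{path}: unknown gene_id {row.gene_id!r}")
        variant = VariantKey(rsid=row.rsid or None, chrom=row.chrom or None,
                             pos=int(row.pos) if row.pos else None,
                             build=row.build)
        study = StudyKey(source=row.source, study=row.study,
                         tissue=row.tissue, qtl_type=row.qtl_type,
                         significance_policy=row.significance_policy)
        rec = QtlRecord(variant=variant, gene=gene, study=study,
                        p_value=float(row.p),
                        beta=float(row.beta) if row.beta else None,
                        effect_allele=row.ea or None,
                        non_effect_allele=row.nea or None)
        flags = set(row.flags.split(";")) if row.flags else set()
        out.append(AnnotatedQtl(
            record=rec,
            is_sw_significant="is_sw_significant" in flags,
            is_best="is_best" in flags,
            is_best_in_ld_group="is_best_in_ld_group" in flags,
            colocalization=row.colocalization,
            distance_kb=float(row.distance_kb) if row.distance_kb else None,
            gwas_variant_hit=bool(int(row.gwas_variant)),
            gwas_gene_hit=bool(int(row.gwas_gene)),
            n_qtls=int(row.n_qtls), n_best=int(row.n_best),
            n_sw_significant=int(row.n_sw_significant), n_occ=int(row.n_occ)))
    return out
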