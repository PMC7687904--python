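"""Free-format query parsing, term resolution, proxy expansion and aggregation.

A query is a list of terms in any standard text format (tab-, comma-,
space-separated or a mixture).  Each term identifies either a variant (rsID or
chr:pos, hg19 by default, ``:hg38`` suffix accepted) or a gene (stable id,
primary symbol or synonym — symbols are upper-case letters and Arabic
numerals).  Variant terms may be enriched for LD proxies at an r² or D′
threshold; results are one row per QTL object and can be filtered column-wise
and aggregated into a haplotype-block-centric view (one row per index
variant x gene, tissues unioned, best P kept).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import AnnotatedQtl, QtlAnnotError, VariantKey, normalize_chrom
from .ingest import GeneIndex
from .ld import LdStore

__all__ = [
    "QueryError",
    "ParsedTerm",
    "ResultRow",
    "AggregatedRow",
    "QueryResult",
    "parse_terms",
    "resolve_gene",
    "run_query",
    "filter_rows",
    "aggregate",
    "MAX_TERMS",
    "MAX_ROWS",
]

MAX_TERMS = 50
MAX_ROWS = 10_000

_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_POS_RE = re.compile(
    r"^(?:chr)?([0-9]{1,2}|[XYM]|MT):([0-9,]+)(?::(hg19|hg38))?$",
    re.IGNORECASE)
# gene symbols are upper-case letters and Arabic numerals; stable ids
# (e.g. Ensembl, Entrez) are also upper-case alphanumeric
_GENE_RE = re.compile(r"^[A-Z0-9][A-Z0-9_.\-]*$")
_SPLIT_RE = re.compile(r"[\s,;]+")


class QueryError(QtlAnnotError):
    pass


@dataclass
class ParsedTerm:
    raw: str
    kind: str  # {"variant", "gene", "unresolved"}
    resolved: VariantKey | str | None = None  # VariantKey or gene_id
    ambiguity: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.kind == "unresolved") != (self.resolved is None):
            raise QtlAnnotError("unresolved terms carry no resolved id")


def parse_terms(text: str, max_terms: int = MAX_TERMS,
                default_build: str = "hg19") -> list[ParsedTerm]:
    """Tokenize free-format text and classify each token.

    Matching order per token: rsID pattern, chr:pos pattern (optional build
    tag), then gene identifier/symbol pattern.  Unmatched tokens become
    ``unresolved`` terms — reported, not fatal.  More than ``max_terms``
    tokens is an error.
    """
    tokens = [t for t in _SPLIT_RE.split(text.strip()) if t]
    if len(tokens) > max_terms:
        raise QueryError(
            f"query has {len(tokens)} terms; the maximum is {max_terms}")
    out: list[ParsedTerm] = []
    for tok in tokens:
        if _RSID_RE.match(tok):
            out.append(ParsedTerm(raw=tok, kind="variant",
                                  resolved=VariantKey(rsid=tok.lower())))
            continue
        m = _POS_RE.match(tok)
        if m:
            chrom, pos_s, build = m.groups()
            out.append(ParsedTerm(
                raw=tok, kind="variant",
                resolved=VariantKey(chrom=normalize_chrom(chrom),
                                    pos=int(pos_s.replace(",", "")),
                                    build=(build or default_build).lower())))
            continue
        if _GENE_RE.match(tok):
            out.append(ParsedTerm(raw=tok, kind="gene", resolved=tok))
            continue
        out.append(ParsedTerm(raw=tok, kind="unresolved"))
    return out


def resolve_gene(term: str, gene_index: GeneIndex) -> tuple[str | None, list[str]]:
    """Map a gene term to a stable id: exact id > primary symbol > synonym.

    An ambiguous symbol or synonym resolves to the lexicographically smallest
    gene_id; the alternatives are returned for reporting.  Returns
    (gene_id or None, ambiguity list).
    """
    if term in gene_index.by_id:
        return term, []
    ids = gene_index.by_symbol.get(term.upper())
    if ids:
        return ids[0], ids[1:]
    ids = gene_index.by_synonym.get(term.upper())
    if ids:
        return ids[0], ids[1:]
    return None, []


@dataclass
class ResultRow:
    """One annotated QTL object in a query result, with query provenance."""

    annotated: AnnotatedQtl
    search_type: str           # {"Variant", "Gene"}
    query_term: str
    proxy_of: VariantKey | None = None
    proxy_r2: float | None = None
    proxy_dprime: float | None = None

    def __post_init__(self) -> None:
        if self.proxy_of is not None and self.proxy_r2 is None \
                and self.proxy_dprime is None:
            raise QtlAnnotError("proxy rows must carry an LD metric")

    def to_dict(self) -> dict:
        a, r = self.annotated, self.annotated.record
        return {
            "query_term": self.query_term,
            "search_type": self.search_type,
            "rsid": r.variant.rsid or r.variant.key,
            "proxy_of": self.proxy_of.key if self.proxy_of else "",
            "proxy_r2": "" if self.proxy_r2 is None else self.proxy_r2,
            "proxy_dprime": "" if self.proxy_dprime is None else self.proxy_dprime,
            "chrom": r.variant.chrom or "",
            "pos": r.variant.pos if r.variant.pos is not None else "",
            "gene": r.gene.symbol,
            "gene_id": r.gene.gene_id,
            "distance_kb": "" if a.distance_kb is None else a.distance_kb,
            "tissue": r.study.tissue,
            "p": r.p_value,
            "beta": "" if r.beta is None else r.beta,
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
        }


RESULT_COLUMNS = ["query_term", "search_type", "rsid", "proxy_of", "proxy_r2",
                  "proxy_dprime", "chrom", "pos", "gene", "gene_id",
                  "distance_kb", "tissue", "p", "beta", "ea", "nea", "source",
                  "study", "qtl_type", "colocalization", "flags",
                  "gwas_variant", "gwas_gene", "n_qtls", "n_best",
                  "n_sw_significant", "n_occ"]

_NUMERIC_COLUMNS = {"pos", "proxy_r2", "proxy_dprime", "distance_kb", "p",
                    "beta", "gwas_variant", "gwas_gene", "n_qtls", "n_best",
                    "n_sw_significant", "n_occ"}


@dataclass
class QueryResult:
    rows: list[ResultRow]
    truncated: bool = False
    diagnostics: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


def _matches_variant(a: AnnotatedQtl, vk: VariantKey) -> bool:
    v = a.record.variant
    if vk.rsid:
        return v.rsid is not None and v.rsid.lower() == vk.rsid.lower()
    return (v.chrom == vk.chrom and v.pos == vk.pos
            and v.build == vk.build)


def run_query(terms: list[ParsedTerm], annotated: list[AnnotatedQtl],
              ld_store: LdStore | None = None,
              proxy_metric: str | None = None,
              proxy_threshold: float | None = None,
              gene_index: GeneIndex | None = None,
              max_rows: int = MAX_ROWS) -> QueryResult:
    """Assemble result rows for resolved terms, in query-term order then by P.

    Variant terms return every record for the variant plus, when proxy options
    are set, the records of its LD proxies tagged with the index variant and
    the LD metrics.  A record reachable both directly and via a proxy is
    reported once, through the direct route; one reachable via several proxies
    keeps the highest-r² route.  Gene terms return every record for the gene.
    """
    result = QueryResult(rows=[])
    for term in terms:
        if term.kind == "unresolved":
            result.diagnostics.append(f"unresolved term: {term.raw!r}")
            continue
        picked: dict[int, ResultRow] = {}
        if term.kind == "variant":
            vk = term.resolved
            for i, a in enumerate(annotated):
                if _matches_variant(a, vk):
                    picked[i] = ResultRow(annotated=a, search_type="Variant",
                                          query_term=term.raw)
            if proxy_metric and proxy_threshold is not None and ld_store:
                index_key = vk.key if not vk.rsid else vk.rsid
                proxies = ld_store.find_proxies(index_key,
                                                metric=proxy_metric,
                                                threshold=proxy_threshold)
                for pvar, r2, dp in proxies:
                    for i, a in enumerate(annotated):
                        if a.record.variant.key != pvar:
                            continue
                        if i in picked:
                            prev = picked[i]
                            if prev.proxy_of is None:
                                continue  # direct route wins
                            if (prev.proxy_r2 or 0.0) >= r2:
                                continue  # keep the closest proxy route
                        picked[i] = ResultRow(
                            annotated=a, search_type="Variant",
                            query_term=term.raw, proxy_of=vk,
                            proxy_r2=r2, proxy_dprime=dp)
            if not picked:
                result.diagnostics.append(
                    f"no records for variant term {term.raw!r}")
        else:  # gene
            gene_id, ambiguity = (term.resolved, term.ambiguity)
            if gene_index is not None:
                gene_id, ambiguity = resolve_gene(term.raw, gene_index)
            if gene_id is None:
                result.diagnostics.append(
                    f"unresolved gene term: {term.raw!r}")
                continue
            if ambiguity:
                result.diagnostics.append(
                    f"ambiguous gene term {term.raw!r}: chose {gene_id}, "
                    f"alternatives {ambiguity}")
            for i, a in enumerate(annotated):
                if a.record.gene.gene_id == gene_id:
                    picked[i] = ResultRow(annotated=a, search_type="Gene",
                                          query_term=term.raw)
            if not picked:
                result.diagnostics.append(
                    f"no records for gene term {term.raw!r}")
        rows = sorted(picked.values(),
                      key=lambda r: (r.annotated.record.p_value,
                                     r.annotated.record.variant.key))
        result.rows.extend(rows)
    if len(result.rows) > max_rows:
        result.rows = result.rows[:max_rows]
        result.truncated = True
        result.diagnostics.append(
            f"result truncated to the first {max_rows} rows")
    if not result.rows and all(t.kind == "unresolved" for t in terms):
        result.diagnostics.append("no term could be resolved")
    return result


_PRED_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*"
                      r"(<=|>=|!=|==|<|>|=|~)\s*(.+?)\s*$")


def filter_rows(rows: list[ResultRow], predicates: list[str]) -> list[ResultRow]:
    """Conjunction of column predicates, preserving row order.

    Predicate syntax: ``column OP value`` with OP one of ``< <= > >= = == !=``
    for numeric thresholds or exact values, ``=`` with a comma list for
    value-set membership, and ``~`` for substring/flag-token containment
    (e.g. ``flags~is_sw_significant``).  An unknown column is an error that
    lists the valid columns.
    """
    compiled = []
    for pred in predicates:
        m = _PRED_RE.match(pred)
        if not m:
            raise QueryError(f"cannot parse filter predicate {pred!r}")
        col, op, val = m.groups()
        if col not in RESULT_COLUMNS:
            raise QueryError(
                f"unknown column {col!r}; valid columns: {RESULT_COLUMNS}")
        compiled.append((col, op, val))

    def keep(row: ResultRow) -> bool:
        d = row.to_dict()
        for col, op, val in compiled:
            cell = d[col]
            if op == "~":
                tokens = str(cell).split(";")
                if val not in tokens and val not in str(cell):
                    return False
            elif op in ("=", "=="):
                choices = [v.strip() for v in val.split(",")]
                if str(cell) not in choices:
                    # numeric equality fallback
                    try:
                        if float(cell) not in [float(c) for c in choices]:
                            return False
                    except (TypeError, ValueError):
                        return False
            elif op == "!=":
                if str(cell) == val:
                    return False
            else:
                try:
                    x = float(cell)
                    y = float(val)
                except (TypeError, ValueError):
                    return False
                if op == "<" and not x < y:
                    return False
                if op == "<=" and not x <= y:
                    return False
                if op == ">" and not x > y:
                    return False
                if op == ">=" and not x >= y:
                    return False
        return True

    return [r for r in rows if keep(r)]


@dataclass
class AggregatedRow:
    """Haplotype-block-centric view: one row per index variant and gene."""

    index_variant: str
    gene_id: str
    gene_symbol: str
    tissues: set[str]
    best_p: float
    n_merged: int

    def to_dict(self) -> dict:
        return {"index_variant": self.index_variant,
                "gene": self.gene_symbol, "gene_id": self.gene_id,
                "tissues": ";".join(sorted(self.tissues)),
                "best_p": self.best_p, "n_merged": self.n_merged}


def aggregate(rows: list[ResultRow]) -> list[AggregatedRow]:
    """Merge rows by (index variant, gene): tissues unioned, best P kept.

    Proxy rows collapse onto their index variant, so a proxy-expanded query
    aggregates to the haplotype-block-centric view.  Conserves records:
    sum of ``n_merged`` equals the number of input rows.
    """
    groups: dict[tuple[str, str], list[ResultRow]] = {}
    order: list[tuple[str, str]] = []
    for row in rows:
        index_variant = (row.proxy_of.key if row.proxy_of is not None
                         else row.annotated.record.variant.key)
        key = (index_variant, row.annotated.record.gene.gene_id)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(row)
    out = []
    for key in order:
        members = groups[key]
        out.append(AggregatedRow(
            index_variant=key[0],
            gene_id=key[1],
            gene_symbol=members[0].annotated.record.gene.symbol,
            tissues={m.annotated.record.study.tissue for m in members},
            best_p=min(m.annotated.record.p_value for m in members),
            n_merged=len(members)))
    return out
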