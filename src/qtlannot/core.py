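"""Canonical domain types shared by all pipeline stages.

A QTL object is the quadruple (variant, gene, tissue, source study); everything
downstream — significance flags, best-in-tissue flags, LD-group flags, cis/trans
labels and count statistics — is keyed on that identity.

Coordinate conventions
----------------------
Genomic *intervals* (genes, TADs) are stored 0-based half-open internally; the
readers convert from 1-based inclusive (GTF, TSV) at the boundary, BED is taken
as-is.  Variant *positions* are stored 1-based (the convention of VCF, rsID
databases and summary-statistics tables); interval containment subtracts one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "QtlAnnotError",
    "VariantKey",
    "GeneRecord",
    "StudyKey",
    "QtlRecord",
    "AnnotatedQtl",
    "TadInterval",
    "LdPair",
    "GwasCatalogEntry",
    "record_identity",
    "normalize_chrom",
]

GENOME_BUILDS = ("hg19", "hg38")


class QtlAnnotError(Exception):
    """Base class for all errors raised by this package."""


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome label: no ``chr`` prefix, ``MT`` for mitochondria."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("M", "MT"):
        return "MT"
    return c.upper() if c.upper() in ("X", "Y") else c


@dataclass(frozen=True)
class VariantKey:
    """A small variant (SNP or indel), identified by rsID and/or position.

    ``pos`` is 1-based.  At least one of ``rsid`` or (``chrom``, ``pos``) must
    be present.
    """

    rsid: str | None = None
    chrom: str | None = None
    pos: int | None = None
    build: str = "hg19"
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        if self.rsid is None and (self.chrom is None or self.pos is None):
            raise QtlAnnotError(
                "VariantKey needs an rsid or a (chrom, pos) pair")
        if self.pos is not None and self.pos < 1:
            raise QtlAnnotError(f"variant position must be >= 1, got {self.pos}")
        if self.chrom is not None and not str(self.chrom):
            raise QtlAnnotError("chromosome label must be non-empty")
        if self.build not in GENOME_BUILDS:
            raise QtlAnnotError(f"unknown genome build {self.build!r}")

    @property
    def key(self) -> str:
        """Stable lookup key: the rsID when known, else ``chrom:pos``."""
        if self.rsid:
            return self.rsid
        return f"{self.chrom}:{self.pos}"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.key


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its stable identifier, primary symbol and location.

    ``start``/``end`` are 0-based half-open internally; use
    :meth:`from_1based` when constructing from 1-based inclusive coordinates.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise QtlAnnotError(f"gene {self.gene_id}: empty symbol")
        if self.start >= self.end:
            raise QtlAnnotError(
                f"gene {self.gene_id}: start must be < end "
                f"(got {self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise QtlAnnotError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @classmethod
    def from_1based(cls, gene_id: str, symbol: str, chrom: str,
                    start: int, end: int, strand: str = "+",
                    synonyms=()) -> "GeneRecord":
        return cls(gene_id=gene_id, symbol=symbol, chrom=normalize_chrom(chrom),
                   start=int(start) - 1, end=int(end), strand=strand,
                   synonyms=frozenset(synonyms))

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end

    def anchor(self, strand_aware: bool = False) -> int:
        """Gene anchor position (0-based) for TAD containment and distance.

        Defaults to the gene start; with ``strand_aware`` the transcription
        start site is used (i.e. the ``end`` for minus-strand genes).
        """
        if strand_aware and self.strand == "-":
            return self.end - 1
        return self.start

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class StudyKey:
    """One QTL dataset: source platform, publication label, tissue and type.

    The (source, tissue) pair identifies a *tissue-specific QTL study*, the
    unit over which "best" flags and sharing counts are defined.
    """

    source: str
    study: str
    tissue: str
    qtl_type: str = "eQTL"
    pubmed_id: str | None = None
    significance_policy: str = "fwer_derived"

    def __post_init__(self) -> None:
        if self.qtl_type not in ("eQTL", "pQTL", "reQTL"):
            raise QtlAnnotError(f"unknown QTL type {self.qtl_type!r}")
        if self.significance_policy not in ("source_provided", "fwer_derived"):
            raise QtlAnnotError(
                f"unknown significance policy {self.significance_policy!r}")

    @property
    def tissue_study(self) -> tuple[str, str]:
        """The (source, tissue) pair — one tissue-specific QTL study."""
        return (self.source, self.tissue)


@dataclass(frozen=True)
class QtlRecord:
    """One variant–gene association row from a QTL summary-statistics table."""

    variant: VariantKey
    gene: GeneRecord
    study: StudyKey
    p_value: float
    beta: float | None = None
    effect_allele: str | None = None
    non_effect_allele: str | None = None
    source_significant: bool | None = None  # source-provided significance call

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise QtlAnnotError(
                f"p_value must be in (0, 1], got {self.p_value!r}")


def record_identity(q: QtlRecord) -> tuple[str, str, str, tuple[str, str]]:
    """Identity tuple of a QTL object: (variant, gene, tissue, source study).

    Statistics (P, beta, alleles) are excluded: two rows that differ only in
    them are the same QTL object.
    """
    return (q.variant.key, q.gene.gene_id, q.study.tissue,
            (q.study.source, q.study.study))


@dataclass
class AnnotatedQtl:
    """A QtlRecord plus all derived flags, labels and count statistics."""

    record: QtlRecord
    is_sw_significant: bool = False
    is_best: bool = False
    is_best_in_ld_group: bool = False
    colocalization: str = "trans"  # exactly one of {"cis", "trans"}
    distance_kb: float | None = None
    gwas_variant_hit: bool = False
    gwas_gene_hit: bool = False
    n_qtls: int = 0
    n_best: int = 0
    n_sw_significant: int = 0
    n_occ: int = 0

    def validate(self) -> None:
        if self.is_best and not self.is_best_in_ld_group:
            raise QtlAnnotError("is_best implies is_best_in_ld_group")
        if self.colocalization not in ("cis", "trans"):
            raise QtlAnnotError(f"bad colocalization {self.colocalization!r}")
        if not (0 <= self.n_best <= self.n_occ):
            raise QtlAnnotError("n_best must satisfy 0 <= n_best <= n_occ")
        if not (0 <= self.n_sw_significant <= self.n_occ):
            raise QtlAnnotError("n_sw_significant must be <= n_occ")

    @property
    def flags(self) -> str:
        """Semicolon-joined flag tokens, as exported in the table view."""
        toks = []
        if self.is_sw_significant:
            toks.append("is_sw_significant")
        if self.is_best:
            toks.append("is_best")
        if self.is_best_in_ld_group:
            toks.append("is_best_in_ld_group")
        return ";".join(toks)


@dataclass(frozen=True)
class TadInterval:
    """A topologically associating domain, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise QtlAnnotError(
                f"TAD on {self.chrom}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LdPair:
    """Pairwise LD between two variants; symmetric under swap of a/b."""

    variant_a: str
    variant_b: str
    r2: float
    d_prime: float
    population: str = "EUR"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 and 0.0 <= self.d_prime <= 1.0):
            raise QtlAnnotError(
                f"LD metrics out of [0,1]: r2={self.r2}, d_prime={self.d_prime}")


@dataclass(frozen=True)
class GwasCatalogEntry:
    """One GWAS Catalog association: variant–phenotype or locus–phenotype."""

    variant: VariantKey | None
    gene_symbol: str | None
    phenotype: str
    source_accession: str = ""

    def __post_init__(self) -> None:
        if self.variant is None and not self.gene_symbol:
            raise QtlAnnotError(
                "catalog entry needs a variant or a gene symbol")
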