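"""Readers and the transformation step harmonizing heterogeneous inputs.

Every external dialect is converted at this boundary into the canonical
in-memory model: QTL summary-statistics TSVs (configurable column maps, one
manifest entry per dataset), BED TAD boundaries, GTF or TSV gene annotation,
and the GWAS Catalog association table.  Tissue names are normalized through a
user-editable map; an unmappable tissue aborts ingestion loudly, listing the
offenders, because the tissue name is part of a record's identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (GeneRecord, GwasCatalogEntry, QtlAnnotError, QtlRecord,
                   StudyKey, TadInterval, VariantKey, normalize_chrom,
                   record_identity)

__all__ = [
    "IngestError",
    "IngestReport",
    "TissueNormalizationMap",
    "DatasetManifest",
    "GeneIndex",
    "TadSet",
    "GwasIndex",
    "QtlStore",
    "read_qtl_table",
    "read_tads",
    "read_genes",
    "read_gwas_catalog",
    "load_manifest",
    "ingest_manifest",
    "write_store_tsv",
    "read_store_tsv",
    "DEFAULT_TISSUE_MAP",
]


class IngestError(QtlAnnotError):
    pass


# Curated defaults following the normalized names used in multi-source QTL
# resources ("Artery-Aorta", "Heart-Atrial appendage", ...).  Users extend or
# replace this via the manifest's tissue_map; identity mappings are implied
# for names that are already normalized.
DEFAULT_TISSUE_MAP: dict[str, str] = {
    "Artery - Aorta": "Artery-Aorta",
    "Artery_Aorta": "Artery-Aorta",
    "Artery - Tibial": "Artery-Tibial",
    "Artery_Tibial": "Artery-Tibial",
    "Heart - Atrial Appendage": "Heart-Atrial appendage",
    "Heart_Atrial_Appendage": "Heart-Atrial appendage",
    "Heart - Left Ventricle": "Heart-Left ventricle",
    "Whole Blood": "Blood",
    "whole blood": "Blood",
    "Cells - EBV-transformed lymphocytes": "Lymphoblastoid cell lines",
    "LCL": "Lymphoblastoid cell lines",
    "liver": "Liver",
    "monocyte": "Monocytes",
    "Brain - Cerebellum": "Cerebellum",
}


@dataclass
class TissueNormalizationMap:
    """Raw-tissue-string to normalized-name map; total on ingested data."""

    mapping: dict[str, str] = field(default_factory=dict)
    allow_identity: bool = True

    def normalize(self, raw: str) -> str | None:
        raw = str(raw).strip()
        if raw in self.mapping:
            return self.mapping[raw]
        if self.allow_identity and raw:
            return raw
        return None

    @classmethod
    def with_defaults(cls, extra: dict[str, str] | None = None,
                      allow_identity: bool = True) -> "TissueNormalizationMap":
        m = dict(DEFAULT_TISSUE_MAP)
        if extra:
            m.update(extra)
        return cls(mapping=m, allow_identity=allow_identity)


@dataclass
class IngestReport:
    """Reconciliation of rows in vs records out for one dataset."""

    path: str = ""
    n_rows: int = 0
    n_records: int = 0
    n_rejected: int = 0
    n_duplicates: int = 0
    rejections: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.n_records + self.n_rejected + self.n_duplicates != self.n_rows:
            raise IngestError(
                f"{self.path}: row accounting does not reconcile "
                f"({self.n_records} + {self.n_rejected} rejected + "
                f"{self.n_duplicates} duplicate != {self.n_rows} rows)")


# ---------------------------------------------------------------------------
# Gene annotation


class GeneIndex:
    """Genes keyed by stable id, with a symbol/synonym lookup table."""

    def __init__(self, genes: list[GeneRecord]) -> None:
        self.by_id: dict[str, GeneRecord] = {}
        self.by_symbol: dict[str, list[str]] = {}
        self.by_synonym: dict[str, list[str]] = {}
        for g in genes:
            if g.gene_id in self.by_id:
                raise IngestError(f"duplicate gene_id {g.gene_id!r}")
            self.by_id[g.gene_id] = g
            self.by_symbol.setdefault(g.symbol.upper(), []).append(g.gene_id)
            for syn in g.synonyms:
                self.by_synonym.setdefault(syn.upper(), []).append(g.gene_id)
        for d in (self.by_symbol, self.by_synonym):
            for k in d:
                d[k].sort()

    def __len__(self) -> int:
        return len(self.by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def get(self, gene_id: str) -> GeneRecord | None:
        return self.by_id.get(gene_id)

    def lookup_label(self, label: str) -> GeneRecord | None:
        """Best-effort single-gene lookup by id, then symbol, then synonym."""
        if label in self.by_id:
            return self.by_id[label]
        for table in (self.by_symbol, self.by_synonym):
            ids = table.get(label.upper())
            if ids:
                return self.by_id[ids[0]]
        return None


def _genes_from_gtf(path: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        symbol = feat.attributes.get("gene_name",
                                     feat.attributes.get("gene_id", [feat.id]))[0]
        syns = feat.attributes.get("gene_synonym", [])
        genes.append(GeneRecord.from_1based(
            gene_id=gene_id, symbol=symbol, chrom=feat.seqid,
            start=feat.start, end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            synonyms=syns))
    return genes


def _genes_from_tsv(path: str) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "symbol", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"gene table {path} lacks columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        syns = ()
        if "synonyms" in df.columns and isinstance(row.synonyms, str) and row.synonyms:
            syns = tuple(s for s in row.synonyms.replace("|", ",").split(",") if s)
        genes.append(GeneRecord.from_1based(
            gene_id=str(row.gene_id), symbol=str(row.symbol),
            chrom=str(row.chrom), start=int(row.start), end=int(row.end),
            strand=getattr(row, "strand", "+") or "+", synonyms=syns))
    return genes


def read_genes(path: str) -> GeneIndex:
    """Gene annotation from GTF (1-based inclusive) or TSV with explicit columns.

    Both dialects yield identical GeneRecords internally (0-based half-open).
    Duplicate stable ids are a hard error; shared symbols are allowed — the
    query resolver reports the ambiguity.
    """
    p = str(path)
    if p.endswith((".gtf", ".gff", ".gff3")):
        genes = _genes_from_gtf(p)
    else:
        genes = _genes_from_tsv(p)
    return GeneIndex(genes)


# ---------------------------------------------------------------------------
# TADs


class TadSet:
    """Interval store of TAD boundaries, queryable by position and pair.

    Intervals are 0-based half-open (BED convention, read as-is) and may
    overlap; containment checks scan all intervals on the chromosome, which is
    fine at the few-thousand-TAD scale of published boundary sets.
    """

    def __init__(self, intervals: list[TadInterval]) -> None:
        self.intervals = list(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._by_chrom: dict[str, list[TadInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda t: (t.start, t.end))
            self._starts[chrom] = np.array([t.start for t in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([t.end for t in ivs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.intervals)

    def containing_mask(self, chrom: str, pos0: int) -> np.ndarray:
        chrom = normalize_chrom(chrom)
        if chrom not in self._starts:
            return np.zeros(0, dtype=bool)
        return (self._starts[chrom] <= pos0) & (pos0 < self._ends[chrom])

    def contains(self, chrom: str, pos0: int) -> bool:
        return bool(self.containing_mask(chrom, pos0).any())

    def same_tad(self, chrom_a: str, pos0_a: int,
                 chrom_b: str, pos0_b: int) -> bool:
        """True iff any single TAD contains both positions."""
        if normalize_chrom(chrom_a) != normalize_chrom(chrom_b):
            return False
        mask = self.containing_mask(chrom_a, pos0_a) & \
            self.containing_mask(chrom_b, pos0_b)
        return bool(mask.any())

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[TadInterval]:
        chrom = normalize_chrom(chrom)
        if chrom not in self._starts:
            return []
        mask = (self._starts[chrom] < end0) & (start0 < self._ends[chrom])
        return [iv for iv, m in zip(self._by_chrom[chrom], mask) if m]

    def summary(self) -> dict[str, float]:
        lengths = np.array([iv.length for iv in self.intervals], dtype=float)
        if lengths.size == 0:
            return {"n": 0, "mean_length": 0.0, "min_length": 0.0,
                    "max_length": 0.0}
        return {"n": int(lengths.size),
                "mean_length": float(lengths.mean()),
                "min_length": float(lengths.min()),
                "max_length": float(lengths.max())}


def read_tads(path: str) -> tuple[TadSet, IngestReport]:
    """BED3+ TAD boundaries; rows with start >= end rejected with a diagnostic."""
    report = IngestReport(path=str(path))
    intervals: list[TadInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            report.n_rows += 1
            parts = line.split("\t")
            if len(parts) < 3:
                report.n_rejected += 1
                report.rejections.append(f"line {lineno}: fewer than 3 fields")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                report.n_rejected += 1
                report.rejections.append(f"line {lineno}: non-integer coordinates")
                continue
            if start >= end:
                report.n_rejected += 1
                report.rejections.append(f"line {lineno}: start >= end")
                continue
            intervals.append(TadInterval(chrom=normalize_chrom(parts[0]),
                                         start=start, end=end))
            report.n_records += 1
    report.check()
    return TadSet(intervals), report


# ---------------------------------------------------------------------------
# GWAS Catalog


class GwasIndex:
    """GWAS Catalog entries indexed by rsID and by mapped gene symbol."""

    def __init__(self, entries: list[GwasCatalogEntry]) -> None:
        self.entries = list(entries)
        self.by_rsid: dict[str, list[GwasCatalogEntry]] = {}
        self.by_gene: dict[str, list[GwasCatalogEntry]] = {}
        for e in entries:
            if e.variant is not None and e.variant.rsid:
                self.by_rsid.setdefault(e.variant.rsid, []).append(e)
            if e.gene_symbol:
                self.by_gene.setdefault(e.gene_symbol.upper(), []).append(e)

    def has_variant(self, rsid: str | None) -> bool:
        return rsid is not None and rsid in self.by_rsid

    def has_gene(self, symbol: str | None) -> bool:
        return symbol is not None and symbol.upper() in self.by_gene


def read_gwas_catalog(path: str) -> tuple[GwasIndex, IngestReport]:
    """GWAS Catalog associations TSV.

    Accepts the Catalog download dialect (``SNPS``, ``MAPPED_GENE``,
    ``DISEASE/TRAIT``, ``STUDY ACCESSION``) or a simple dialect (``rsid``,
    ``gene``, ``phenotype``, ``accession``).  Rows lacking both a variant and
    a gene are skipped and counted.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "SNPS" in df.columns:
        cols = {"rsid": "SNPS", "gene": "MAPPED_GENE",
                "phenotype": "DISEASE/TRAIT", "accession": "STUDY ACCESSION"}
    else:
        cols = {"rsid": "rsid", "gene": "gene", "phenotype": "phenotype",
                "accession": "accession"}
    if cols["rsid"] not in df.columns and cols["gene"] not in df.columns:
        raise IngestError(f"GWAS catalog {path}: no variant or gene column")
    report = IngestReport(path=str(path), n_rows=len(df))
    entries: list[GwasCatalogEntry] = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        rsid = str(d.get(cols["rsid"], "")).strip()
        genes_raw = str(d.get(cols["gene"], "")).strip()
        phenotype = str(d.get(cols["phenotype"], "")).strip()
        accession = str(d.get(cols["accession"], "")).strip()
        variant = VariantKey(rsid=rsid) if rsid.startswith("rs") else None
        symbols = [s.strip() for part in genes_raw.split(";")
                   for s in part.replace(" - ", ",").split(",") if s.strip()]
        if variant is None and not symbols:
            report.n_rejected += 1
            report.rejections.append(f"row lacking variant and gene: {d}")
            continue
        if symbols:
            for sym in symbols:
                entries.append(GwasCatalogEntry(variant=variant,
                                                gene_symbol=sym,
                                                phenotype=phenotype,
                                                source_accession=accession))
        else:
            entries.append(GwasCatalogEntry(variant=variant, gene_symbol=None,
                                            phenotype=phenotype,
                                            source_accession=accession))
        report.n_records += 1
    report.check()
    return GwasIndex(entries), report


# ---------------------------------------------------------------------------
# QTL summary statistics


@dataclass
class DatasetManifest:
    """Per-dataset plumbing: file location, dialect and study metadata.

    ``columns`` maps logical names (rsid, chrom, pos, gene, tissue, p, beta,
    ea, nea, significant, source, study) onto file header names.  Constant
    study metadata (source, study, tissue, qtl_type, ...) may be given
    directly instead of via columns.
    """

    path: str
    source: str | None = None
    study: str | None = None
    tissue: str | None = None
    qtl_type: str = "eQTL"
    pubmed_id: str | None = None
    build: str = "hg19"
    columns: dict[str, str] = field(default_factory=dict)
    significance_policy: str = "fwer_derived"
    fwer_alpha: float = 0.05
    fwer_n_variants: int = 1_000_000
    fwer_n_genes: int = 50_000
    sig_threshold: float | None = None  # explicit source threshold, optional

    def resolved_threshold(self) -> float:
        if self.sig_threshold is not None:
            return float(self.sig_threshold)
        return self.fwer_alpha / (self.fwer_n_variants * self.fwer_n_genes)


def load_manifest(path: str) -> tuple[list[DatasetManifest], TissueNormalizationMap]:
    """Manifest file (JSON or YAML): dataset entries plus optional tissue map."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    base = Path(path).parent
    entries = []
    for raw in doc.get("datasets", []):
        raw = dict(raw)
        p = raw.pop("path")
        if not Path(p).is_absolute():
            p = str(base / p)
        fwer = raw.pop("fwer", {})
        entries.append(DatasetManifest(
            path=p,
            fwer_alpha=fwer.get("alpha", 0.05),
            fwer_n_variants=fwer.get("n_variants", 1_000_000),
            fwer_n_genes=fwer.get("n_genes", 50_000),
            **raw))
    tmap = TissueNormalizationMap.with_defaults(
        extra=doc.get("tissue_map"),
        allow_identity=doc.get("tissue_map_allow_identity", True))
    return entries, tmap


def read_qtl_table(path: str, manifest: DatasetManifest,
                   gene_index: GeneIndex,
                   tissue_map: TissueNormalizationMap | None = None,
                   ) -> tuple[list[QtlRecord], IngestReport]:
    """One summary-statistics TSV into QtlRecords.

    Malformed rows (P outside (0,1], unknown gene) are counted and reported;
    duplicate QTL objects within the dataset keep the smallest-P row; a
    missing mandatory column or an unmappable tissue is a hard error.
    """
    tissue_map = tissue_map or TissueNormalizationMap.with_defaults()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    col = dict(manifest.columns)
    # mandatory logical columns
    need = ["gene", "p"]
    if manifest.tissue is None:
        need.append("tissue")
    for logical in need:
        name = col.get(logical, logical)
        if name not in df.columns:
            raise IngestError(
                f"{path}: mandatory column {name!r} (for {logical!r}) missing")
    has_rsid = col.get("rsid", "rsid") in df.columns
    has_pos = (col.get("chrom", "chrom") in df.columns
               and col.get("pos", "pos") in df.columns)
    if not (has_rsid or has_pos):
        raise IngestError(f"{path}: need an rsid column or chrom+pos columns")

    def get(row: dict, logical: str, default: str = "") -> str:
        name = col.get(logical, logical)
        v = row.get(name, default)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return default
        return str(v).strip()

    # fail loudly on unmappable tissues before building any record
    if manifest.tissue is None:
        raw_tissues = sorted(set(df[col.get("tissue", "tissue")].astype(str)))
        bad = [t for t in raw_tissues if tissue_map.normalize(t) is None]
        if bad:
            raise IngestError(
                f"{path}: unmappable tissue names: {bad}")

    report = IngestReport(path=str(path), n_rows=len(df))
    best: dict[tuple, QtlRecord] = {}
    order: list[tuple] = []
    for raw in df.to_dict("records"):
        rsid = get(raw, "rsid") or None
        chrom = get(raw, "chrom") or None
        pos_s = get(raw, "pos")
        pos = int(pos_s) if pos_s else None
        gene_label = get(raw, "gene")
        p_s = get(raw, "p")
        try:
            p = float(p_s)
        except ValueError:
            p = float("nan")
        if not (0.0 < p <= 1.0):
            report.n_rejected += 1
            report.rejections.append(
                f"row with P={p_s!r} outside (0,1] rejected")
            continue
        gene = gene_index.lookup_label(gene_label)
        if gene is None:
            report.n_rejected += 1
            report.rejections.append(f"unknown gene {gene_label!r}")
            continue
        tissue_raw = manifest.tissue if manifest.tissue is not None \
            else get(raw, "tissue")
        tissue = tissue_map.normalize(tissue_raw)
        if tissue is None:
            raise IngestError(f"{path}: unmappable tissue {tissue_raw!r}")
        study = StudyKey(
            source=manifest.source or get(raw, "source") or "unknown",
            study=manifest.study or get(raw, "study") or "unknown",
            tissue=tissue, qtl_type=manifest.qtl_type,
            pubmed_id=manifest.pubmed_id,
            significance_policy=manifest.significance_policy)
        beta_s = get(raw, "beta")
        sig_s = get(raw, "significant")
        try:
            variant = VariantKey(
                rsid=rsid, chrom=normalize_chrom(chrom) if chrom else None,
                pos=pos, build=manifest.build)
            rec = QtlRecord(
                variant=variant, gene=gene, study=study, p_value=p,
                beta=float(beta_s) if beta_s else None,
                effect_allele=get(raw, "ea").upper() or None,
                non_effect_allele=get(raw, "nea").upper() or None,
                source_significant=(sig_s.lower() in ("1", "true", "yes")
                                    if sig_s else None))
        except QtlAnnotError as exc:
            report.n_rejected += 1
            report.rejections.append(str(exc))
            continue
        ident = record_identity(rec)
        if ident in best:
            report.n_duplicates += 1
            report.rejections.append(
                f"duplicate QTL object {ident}; keeping smallest P")
            if rec.p_value < best[ident].p_value:
                best[ident] = rec
        else:
            best[ident] = rec
            order.append(ident)
    records = [best[i] for i in order]
    report.n_records = len(records)
    report.check()
    return records, report


# ---------------------------------------------------------------------------
# The canonical store


@dataclass
class QtlStore:
    """The harmonized collection of QTL records plus dataset-level policies.

    ``thresholds`` maps (source, study) to the significance threshold in force
    for that dataset (source-provided or FWER-derived); mixing genome builds
    in one store is an error.
    """

    records: list[QtlRecord] = field(default_factory=list)
    gene_index: GeneIndex | None = None
    thresholds: dict[tuple[str, str], float] = field(default_factory=dict)
    reports: list[IngestReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        builds = {r.variant.build for r in self.records}
        if len(builds) > 1:
            raise IngestError(
                f"mixed genome builds in one store: {sorted(builds)}")

    def __len__(self) -> int:
        return len(self.records)

    def threshold_for(self, study: StudyKey) -> float:
        return self.thresholds.get((study.source, study.study), 1e-12)


def ingest_manifest(manifest_path: str, gene_index: GeneIndex) -> QtlStore:
    entries, tmap = load_manifest(manifest_path)
    store = QtlStore(gene_index=gene_index)
    for entry in entries:
        records, report = read_qtl_table(entry.path, entry, gene_index, tmap)
        store.records.extend(records)
        store.reports.append(report)
        for rec in records:
            key = (rec.study.source, rec.study.study)
            store.thresholds.setdefault(key, entry.resolved_threshold())
    builds = {r.variant.build for r in store.records}
    if len(builds) > 1:
        raise IngestError(f"mixed genome builds: {sorted(builds)}")
    return store


STORE_COLUMNS = ["rsid", "chrom", "pos", "build", "gene_id", "source",
                 "study", "tissue", "qtl_type", "pubmed_id",
                 "significance_policy", "p", "beta", "ea", "nea",
                 "source_significant", "sig_threshold"]


def write_store_tsv(store: QtlStore, path: str,
                    header_lines: list[str] | None = None) -> None:
    """Normalized store as TSV — the bitwise-stable export used for idempotency."""
    rows = []
    for r in store.records:
        rows.append({
            "rsid": r.variant.rsid or "",
            "chrom": r.variant.chrom or "",
            "pos": r.variant.pos if r.variant.pos is not None else "",
            "build": r.variant.build,
            "gene_id": r.gene.gene_id,
            "source": r.study.source,
            "study": r.study.study,
            "tissue": r.study.tissue,
            "qtl_type": r.study.qtl_type,
            "pubmed_id": r.study.pubmed_id or "",
            "significance_policy": r.study.significance_policy,
            "p": repr(r.p_value),
            "beta": "" if r.beta is None else repr(r.beta),
            "ea": r.effect_allele or "",
            "nea": r.non_effect_allele or "",
            "source_significant": ("" if r.source_significant is None
                                   else str(int(r.source_significant))),
            "sig_threshold": repr(store.threshold_for(r.study)),
        })
    df = pd.DataFrame(rows, columns=STORE_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_store_tsv(path: str, gene_index: GeneIndex) -> QtlStore:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    store = QtlStore(gene_index=gene_index)
    for row in df.itertuples(index=False):
        gene = gene_index.get(row.gene_id)
        if gene is None:
            raise IngestError(f"{path}: unknown gene_id {row.gene_id!r}")
        variant = VariantKey(
            rsid=row.rsid or None, chrom=row.chrom or None,
            pos=int(row.pos) if row.pos else None, build=row.build)
        study = StudyKey(source=row.source, study=row.study,
                         tissue=row.tissue, qtl_type=row.qtl_type,
                         pubmed_id=row.pubmed_id or None,
                         significance_policy=row.significance_policy)
        store.records.append(QtlRecord(
            variant=variant, gene=gene, study=study,
            p_value=float(row.p),
            beta=float(row.beta) if row.beta else None,
            effect_allele=row.ea or None,
            non_effect_allele=row.nea or None,
            source_significant=(bool(int(row.source_significant))
                                if row.source_significant else None)))
        store.thresholds.setdefault((row.source, row.study),
                                    float(row.sig_threshold))
    return store
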