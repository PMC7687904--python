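"""Deterministic synthetic-fixture generator.

Emits, at desk scale, every input dialect the readers consume — QTL
summary-statistics TSV, phased-genotype VCF, pairwise LD TSV, TAD BED, gene
annotation TSV, GWAS Catalog TSV and plain-text gene sets — together with a
ground-truth JSON sidecar recording what was planted (significance threshold,
per-study best variants and their distances, LD-block sharing structure,
enriched gene sets).  A single pseudo-random stream keyed by the seed drives
all randomness, so equal seeds give byte-identical bundles.

The haplotypes are structured noise sufficient to hit within-block r² targets
(no coalescent realism); distances of best eQTLs from gene starts follow a
log-normal whose default parameters (median 28 kb, mean roughly 100 kb) echo
the scale observed in large multi-tissue eQTL resources.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import QtlAnnotError
from .ld import HaplotypePanel, ld_stats_vectors

__all__ = ["FixtureSpec", "FixtureBundle", "generate",
           "haplotypes_with_target_r2", "use_case_store"]

_GENE_SPACING = 20_000_000
_FIRST_GENE_START = 10_000_000
_MAX_ABS_DISTANCE = 9_000_000  # keeps variants inside their gene's territory


@dataclass
class FixtureSpec:
    """The stated world of one synthetic bundle; the seed fully determines it."""

    seed: int = 0
    n_genes: int = 20
    n_variants: int = 120
    n_studies: int = 4          # sources; each covers all tissues
    n_tissues: int = 3
    n_haplotypes: int = 100
    ld_block_size: int = 3
    ld_block_r2: float = 0.9    # within-block target, hit to +/- 0.05
    frac_significant: float = 0.3
    n_sharing_genes: int = 4    # genes whose best eQTL recurs in m studies
    sharing_m: int = 6
    distance_log_mu: float = math.log(28_000.0)
    distance_log_sigma: float = 1.6
    n_tads: int = 40
    tad_mean_length: int = 853_000
    sig_threshold: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_variants", "n_studies", "n_tissues",
                     "n_haplotypes", "ld_block_size", "n_tads"):
            if getattr(self, name) < 1:
                raise QtlAnnotError(f"{name} must be >= 1")
        if self.n_variants // self.n_genes < 1:
            raise QtlAnnotError("need at least one variant per gene")
        if self.ld_block_size > self.n_variants // self.n_genes:
            raise QtlAnnotError(
                "LD block larger than the per-gene variant count")
        if self.sharing_m > self.n_studies * self.n_tissues:
            raise QtlAnnotError(
                "sharing_m exceeds the number of tissue-specific studies")
        if self.n_sharing_genes > self.n_genes:
            raise QtlAnnotError("more sharing genes than genes")
        if not (0.0 <= self.frac_significant <= 1.0):
            raise QtlAnnotError("frac_significant must be in [0, 1]")

    @property
    def variants_per_gene(self) -> int:
        return self.n_variants // self.n_genes


@dataclass
class FixtureBundle:
    """Paths of one generated bundle plus the parsed ground truth."""

    outdir: Path
    qtls: Path
    genes: Path
    vcf: Path
    ld: Path
    tads: Path
    gwas: Path
    manifest: Path
    housekeeping: Path
    top_expressed: Path
    truth_path: Path
    truth: dict


def _column_with_target_r2(rng: np.random.Generator, base: np.ndarray,
                           target: float, tol: float = 0.05,
                           max_tries: int = 5000) -> np.ndarray:
    """A 0/1 column whose realized r² against ``base`` is within tol of target."""
    n = base.size
    if target >= 1.0:
        return base.copy()
    if target <= 0.0:
        for _ in range(max_tries):
            col = (rng.random(n) < 0.5).astype(np.int8)
            if 0 < col.sum() < n:
                r2, _ = ld_stats_vectors(base, col)
                if r2 < max(tol, 1e-9):
                    return col
        raise QtlAnnotError(
            "could not reach target r2=0 within tolerance; use a larger panel")
    flip = (1.0 - math.sqrt(target)) / 2.0
    for _ in range(max_tries):
        col = base ^ (rng.random(n) < flip).astype(np.int8)
        if not (0 < col.sum() < n):
            continue
        r2, _ = ld_stats_vectors(base, col)
        if abs(r2 - target) <= tol:
            return col
    raise QtlAnnotError(
        f"could not reach target r2={target} within +/-{tol} at "
        f"{n} haplotypes; use a larger panel")


def haplotypes_with_target_r2(n_hap: int, r2_target: float,
                              seed: int, tol: float = 0.05) -> HaplotypePanel:
    """A two-variant phased panel whose realized r² is within tol of target."""
    if not (0.0 <= r2_target <= 1.0):
        raise QtlAnnotError("r2_target must be in [0, 1]")
    if n_hap < 8:
        raise QtlAnnotError("need at least 8 haplotypes")
    rng = np.random.default_rng(seed)
    base = None
    for _ in range(1000):
        cand = (rng.random(n_hap) < 0.5).astype(np.int8)
        if 0 < cand.sum() < n_hap:
            base = cand
            break
    if base is None:  # pragma: no cover - astronomically unlikely
        raise QtlAnnotError("could not draw a polymorphic base column")
    other = _column_with_target_r2(rng, base, r2_target, tol=tol)
    return HaplotypePanel(haplotypes=np.stack([base, other], axis=1),
                          variant_ids=["v1", "v2"],
                          positions=np.array([1000, 2000]),
                          chroms=["1", "1"])


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def generate(spec: FixtureSpec, outdir: str | Path) -> FixtureBundle:
    """Write one complete input bundle plus its ground-truth sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "genesets").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    vpg = spec.variants_per_gene
    n_blocks = vpg // spec.ld_block_size  # full blocks; remainder independent

    # --- genes ------------------------------------------------------------
    genes = []  # (gene_id, symbol, chrom, start1, end1, strand)
    for i in range(spec.n_genes):
        chrom = "1" if i % 2 == 0 else "2"
        start1 = _FIRST_GENE_START + (i // 2) * _GENE_SPACING
        length = int(rng.integers(20_000, 200_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"GENE{i:04d}", f"G{i}", chrom, start1,
                      start1 + length - 1, strand))

    # --- variants: positions from the planted distance distribution --------
    variants = []  # (rsid, chrom, pos, gene_idx, block_idx or None)
    pos_used: dict[str, set[int]] = {"1": set(), "2": set()}
    for gi, (gid, _sym, chrom, start1, _end1, _strand) in enumerate(genes):
        for vi in range(vpg):
            while True:
                d = rng.lognormal(spec.distance_log_mu, spec.distance_log_sigma)
                d = min(d, _MAX_ABS_DISTANCE)
                sign = 1 if rng.random() < 0.5 else -1
                pos = int(start1 + sign * round(d))
                if pos >= 1 and pos not in pos_used[chrom]:
                    break
            pos_used[chrom].add(pos)
            block = vi // spec.ld_block_size if vi < n_blocks * spec.ld_block_size \
                else None
            variants.append((f"rs{100000 + gi * 1000 + vi}", chrom, pos, gi,
                             block))

    # --- haplotypes -------------------------------------------------------
    n_hap = spec.n_haplotypes if spec.n_haplotypes % 2 == 0 \
        else spec.n_haplotypes + 1
    columns: dict[str, np.ndarray] = {}
    for gi in range(spec.n_genes):
        gene_vars = [v for v in variants if v[3] == gi]
        bases: dict[int, np.ndarray] = {}
        for rsid, _c, _p, _gi, block in gene_vars:
            if block is None:
                col = (rng.random(n_hap) < rng.uniform(0.2, 0.8)).astype(np.int8)
                while not (0 < col.sum() < n_hap):
                    col = (rng.random(n_hap) < 0.5).astype(np.int8)
                columns[rsid] = col
            elif block not in bases:
                col = (rng.random(n_hap) < 0.5).astype(np.int8)
                while not (0 < col.sum() < n_hap):
                    col = (rng.random(n_hap) < 0.5).astype(np.int8)
                bases[block] = col
                columns[rsid] = col
            else:
                columns[rsid] = _column_with_target_r2(
                    rng, bases[block], spec.ld_block_r2)

    # --- study design, planted sharing and significance --------------------
    studies = [(f"Source{s + 1}", f"Tissue{t + 1}")
               for s in range(spec.n_studies) for t in range(spec.n_tissues)]
    n_pairs = len(studies)
    sharing_gene_idx = sorted(
        rng.choice(spec.n_genes, size=spec.n_sharing_genes, replace=False))
    truth_sharing: dict[str, dict] = {}
    # per (gene_idx, study_idx): the designated best significant variant rsid
    planted_best: dict[tuple[int, int], str] = {}
    for gi in range(spec.n_genes):
        gene_vars = [v for v in variants if v[3] == gi]
        gid = genes[gi][0]
        if gi in sharing_gene_idx:
            block_id = 0
            block_members = [v[0] for v in gene_vars if v[4] == block_id]
            study_idx = sorted(rng.choice(n_pairs, size=spec.sharing_m,
                                          replace=False))
            for j, si in enumerate(study_idx):
                planted_best[(gi, si)] = block_members[j % len(block_members)]
            truth_sharing[gid] = {
                "m": spec.sharing_m,
                "block_members": block_members,
                "block_r2_target": spec.ld_block_r2,
                "studies": [list(studies[si]) for si in study_idx],
            }
        else:
            n_sig = int(rng.integers(1, 4))
            study_idx = sorted(rng.choice(n_pairs, size=n_sig, replace=False))
            for j, si in enumerate(study_idx):
                planted_best[(gi, si)] = gene_vars[j % len(gene_vars)][0]

    # --- QTL records --------------------------------------------------------
    var_by_rsid = {v[0]: v for v in variants}
    qtl_rows = []
    truth_best: dict[str, dict] = {}
    n_significant = 0
    for gi, (gid, _sym, chrom, start1, _end1, _strand) in enumerate(genes):
        gene_vars = [v for v in variants if v[3] == gi]
        for si, (source, tissue) in enumerate(studies):
            best_rsid = planted_best.get((gi, si))
            for rsid, vchrom, pos, _gi, _block in gene_vars:
                if best_rsid is not None and rsid == best_rsid:
                    p = _log_uniform(rng, 1e-20, 1e-15)
                    n_significant += 1
                elif best_rsid is not None and \
                        rng.random() < spec.frac_significant:
                    p = _log_uniform(rng, 1e-14, spec.sig_threshold)
                    n_significant += 1
                else:
                    p = _log_uniform(rng, spec.sig_threshold * 10, 1.0)
                beta = round(float(rng.normal(0.0, 0.5)), 4)
                ea, nea = ("A", "G") if rng.random() < 0.5 else ("T", "C")
                qtl_rows.append((rsid, vchrom, pos, gid, tissue, source,
                                 f"{source}Study", repr(p), repr(beta),
                                 ea, nea))
            if best_rsid is not None:
                _r, _c, bpos, _g, _b = var_by_rsid[best_rsid]
                truth_best["|".join((gid, source, tissue))] = {
                    "variant": best_rsid,
                    "distance_bp": bpos - start1,
                }

    # --- write files --------------------------------------------------------
    genes_path = out / "genes.tsv"
    with open(genes_path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstart\tend\tstrand\tsynonyms\n")
        for gid, sym, chrom, s1, e1, strand in genes:
            fh.write(f"{gid}\t{sym}\t{chrom}\t{s1}\t{e1}\t{strand}\t\n")

    qtls_path = out / "qtls.tsv"
    with open(qtls_path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tgene\ttissue\tsource\tstudy\tp\tbeta"
                 "\tea\tnea\n")
        for row in qtl_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    vcf_path = out / "panel.vcf"
    ordered = sorted(variants, key=lambda v: (v[1], v[2]))
    n_samples = n_hap // 2
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n##contig=<ID=2>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(f"S{i + 1}" for i in range(n_samples)) + "\n")
        for rsid, chrom, pos, _gi, _block in ordered:
            col = columns[rsid]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}"
                            for i in range(n_samples))
            fh.write(f"{chrom}\t{pos}\t{rsid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")

    ld_path = out / "ld.tsv"
    panel = HaplotypePanel(
        haplotypes=np.stack([columns[v[0]] for v in ordered], axis=1),
        variant_ids=[v[0] for v in ordered],
        positions=np.array([v[2] for v in ordered]),
        chroms=[v[1] for v in ordered])
    from .ld import LdStore

    ld_store = LdStore.from_panel(panel, window_bp=50_000_000, min_r2=0.05)
    with open(ld_path, "w") as fh:
        ld_store.to_frame().to_csv(fh, sep="\t", index=False)

    tads_path = out / "tads.bed"
    with open(tads_path, "w") as fh:
        for chrom in ("1", "2"):
            cursor = 1_000_000
            for _ in range(spec.n_tads // 2):
                length = int(max(800, rng.gamma(2.0, spec.tad_mean_length / 2.0)))
                length = min(length, 4_440_000)
                fh.write(f"{chrom}\t{cursor}\t{cursor + length}\n")
                cursor += length + int(rng.integers(1_000, 100_000))

    gwas_path = out / "gwas_catalog.tsv"
    gwas_rsids = sorted(rng.choice([v[0] for v in variants],
                                   size=min(5, len(variants)), replace=False))
    gwas_genes = sorted(rng.choice([g[1] for g in genes],
                                   size=min(3, len(genes)), replace=False))
    with open(gwas_path, "w") as fh:
        fh.write("rsid\tgene\tphenotype\taccession\n")
        for i, rsid in enumerate(gwas_rsids):
            fh.write(f"{rsid}\t\tTrait{i + 1}\tGCST{9000 + i}\n")
        for i, sym in enumerate(gwas_genes):
            fh.write(f"\t{sym}\tTrait{100 + i}\tGCST{9500 + i}\n")

    sharing_ids = [genes[gi][0] for gi in sharing_gene_idx]
    other_ids = [g[0] for g in genes if g[0] not in sharing_ids]
    housekeeping = sorted(sharing_ids + other_ids[:1])
    top_expressed = sorted(sharing_ids + other_ids[1:3])
    hk_path = out / "genesets" / "housekeeping.txt"
    hk_path.write_text("".join(f"{g}\n" for g in housekeeping))
    te_path = out / "genesets" / "top_expressed.txt"
    te_path.write_text("".join(f"{g}\n" for g in top_expressed))

    manifest_path = out / "manifest.json"
    manifest = {
        "datasets": [{
            "path": "qtls.tsv",
            "qtl_type": "eQTL",
            "build": "hg19",
            "significance_policy": "fwer_derived",
            "sig_threshold": spec.sig_threshold,
        }],
    }
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")

    truth = {
        "spec": asdict(spec),
        "sig_threshold": spec.sig_threshold,
        "genes": [g[0] for g in genes],
        "studies": [list(s) for s in studies],
        "n_significant_records": n_significant,
        "sharing": truth_sharing,
        "recover_thresholds": [t for t in (0.6, 0.8)
                               if t < spec.ld_block_r2 - 0.05],
        "best": truth_best,
        "housekeeping": housekeeping,
        "top_expressed": top_expressed,
        "distance_log_mu": spec.distance_log_mu,
        "distance_log_sigma": spec.distance_log_sigma,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")

    return FixtureBundle(outdir=out, qtls=qtls_path, genes=genes_path,
                         vcf=vcf_path, ld=ld_path, tads=tads_path,
                         gwas=gwas_path, manifest=manifest_path,
                         housekeeping=hk_path, top_expressed=te_path,
                         truth_path=truth_path, truth=truth)


# ---------------------------------------------------------------------------
# The worked-example store (synthetic stand-in)


def use_case_store():
    """Synthetic in-memory store mirroring the structure of a published
    coronary-artery-disease locus annotation: one index SNP (rs2306374,
    intronic of MRAS) with 31 QTL records over seven genes, of which the 14
    MRAS records are all study-wide significant.

    The numbers are a constructed census, not real data.  Returns a
    :class:`~qtlannot.ingest.QtlStore`.
    """
    from .core import GeneRecord, QtlRecord, StudyKey, VariantKey
    from .ingest import GeneIndex, QtlStore

    mras = GeneRecord.from_1based("ENSG00000158186", "MRAS", "3",
                                  138_066_000, 138_124_000, "-")
    others = [GeneRecord.from_1based(f"ENSG0000000000{i}", f"GENE{i}", "3",
                                     138_300_000 + i * 400_000,
                                     138_350_000 + i * 400_000, "+")
              for i in range(1, 7)]
    gene_index = GeneIndex([mras] + others)
    variant = VariantKey(rsid="rs2306374", chrom="3", pos=138_119_952)

    tissues = ["Artery-Aorta", "Artery-Tibial", "Heart-Atrial appendage",
               "Heart", "Artery-Coronary", "Adipose", "Lung"]
    sources = ["GTEx", "Haploreg", "Franzen"]
    store = QtlStore(gene_index=gene_index)

    def add(gene, source, tissue, p, beta):
        study = StudyKey(source=source, study=f"{source}Study", tissue=tissue)
        store.records.append(QtlRecord(
            variant=variant, gene=gene, study=study, p_value=p, beta=beta,
            effect_allele="C", non_effect_allele="T"))
        store.thresholds.setdefault((source, f"{source}Study"), 1e-12)

    # 14 study-wide-significant MRAS records over distinct (source, tissue)
    n = 0
    for source in sources:
        for tissue in tissues:
            if n >= 14:
                break
            add(mras, source, tissue, p=10.0 ** -(13 + n % 5),
                beta=0.4 if n % 2 == 0 else -0.4)
            n += 1
    # 17 further, non-significant records across the six other genes
    census = [3, 3, 3, 3, 3, 2]
    for gene, count in zip(others, census):
        for j in range(count):
            add(gene, sources[j % len(sources)], tissues[(j * 2) % len(tissues)],
                p=10.0 ** -(2 + j), beta=0.1)
    return store
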