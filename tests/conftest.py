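from __future__ import annotations

import numpy as np
import pytest

from qtlannot.core import GeneRecord, QtlRecord, StudyKey, VariantKey
from qtlannot.ingest import GeneIndex, QtlStore
from qtlannot.ld import LdStore
from qtlannot.synth import FixtureSpec, generate, use_case_store


def make_gene(gene_id="GENE1", symbol="G1", chrom="1", start1=1_000_000,
              end1=1_050_000, strand="+", synonyms=()):
    return GeneRecord.from_1based(gene_id, symbol, chrom, start1, end1,
                                  strand, synonyms)


def make_record(rsid="rs1", chrom="1", pos=1_000_500, gene=None,
                source="SrcA", study="StudyA", tissue="Liver", p=1e-5,
                beta=None, **kw):
    gene = gene or make_gene()
    return QtlRecord(
        variant=VariantKey(rsid=rsid, chrom=chrom, pos=pos),
        gene=gene,
        study=StudyKey(source=source, study=study, tissue=tissue, **kw),
        p_value=p, beta=beta)


def random_store(rng: np.random.Generator, n_records=200, n_variants=30,
                 n_genes=8, n_sources=3, n_tissues=3,
                 threshold=1e-12) -> tuple[QtlStore, LdStore]:
    """A random in-memory store plus a random LD store, for oracle checks."""
    genes = [make_gene(f"G{i:03d}", f"SYM{i}", chrom="1",
                       start1=1_000_000 + i * 2_000_000,
                       end1=1_050_000 + i * 2_000_000)
             for i in range(n_genes)]
    variants = [VariantKey(rsid=f"rs{i}", chrom="1", pos=100_000 + i * 1000)
                for i in range(n_variants)]
    combos = [(v, g, s, t)
              for v in range(n_variants) for g in range(n_genes)
              for s in range(n_sources) for t in range(n_tissues)]
    idx = rng.choice(len(combos), size=min(n_records, len(combos)),
                     replace=False)
    store = QtlStore(gene_index=GeneIndex(genes))
    for i in sorted(idx):
        v, g, s, t = combos[i]
        p = float(10 ** rng.uniform(-16, 0))
        store.records.append(QtlRecord(
            variant=variants[v], gene=genes[g],
            study=StudyKey(source=f"Src{s}", study=f"Study{s}",
                           tissue=f"Tissue{t}"),
            p_value=p))
        store.thresholds.setdefault((f"Src{s}", f"Study{s}"), threshold)
    ld = LdStore()
    keys = [v.key for v in variants]
    for _ in range(n_variants * 3):
        i, j = rng.choice(n_variants, size=2, replace=False)
        ld.add_pair(keys[i], keys[j], float(rng.uniform(0, 1)),
                    float(rng.uniform(0, 1)))
    return store, ld


@pytest.fixture(scope="session")
def usecase_store():
    return use_case_store()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic bundle, shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    return generate(FixtureSpec(seed=11), out)


@pytest.fixture(scope="session")
def annotated_bundle(bundle):
    """The bundle's store, fully annotated through the public pipeline."""
    from qtlannot.annotate import annotate_store
    from qtlannot.ingest import (ingest_manifest, read_genes,
                                 read_gwas_catalog, read_tads)

    gene_index = read_genes(str(bundle.genes))
    store = ingest_manifest(str(bundle.manifest), gene_index)
    tads, _ = read_tads(str(bundle.tads))
    gwas, _ = read_gwas_catalog(str(bundle.gwas))
    ld = LdStore.from_tsv(str(bundle.ld))
    annotated = annotate_store(store, ld_store=ld, tad_set=tads,
                               gwas_catalog=gwas)
    return annotated, store, ld, tads, gwas
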