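"""Explorative analyses over an annotated store.

Two reusable pipeline stages:

* **eQTL-gene distance** — per tissue-specific study (source/tissue pair) and
  gene, the distance from the gene start to the position of the best (lowest
  P) study-wide-significant eQTL, summarized as mean/median in kb and
  stratified by cis/trans.

* **Cross-study sharing** — per gene, the best study-wide-significant eQTL of
  every tissue-specific study is pooled and grouped into LD blocks by
  single-linkage clustering over pairwise r² at a series of thresholds
  (> 0.6, > 0.8, > 0.9, > 0.95, = 1, and "no LD" where every variant is its
  own block); the gene is assigned the block covering the maximum number of
  tissue-specific studies.  The top-k genes by that count are then tested for
  overlap with reference gene sets (housekeeping, top-expressed) with a
  one-sided hypergeometric test and Benjamini-Hochberg adjustment across the
  threshold x set family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import AnnotatedQtl, QtlAnnotError
from .ld import LdStore

__all__ = [
    "SHARING_THRESHOLDS",
    "DistanceSummary",
    "SharingResult",
    "EnrichmentResult",
    "best_eqtl_distances",
    "sharing_analysis",
    "rank_and_enrich",
    "sharing_to_frame",
    "enrichment_to_frame",
    "hypergeometric_enrichment",
    "top_fraction_expressed",
    "distance_histogram",
]

# "no LD" (None) is the strictest grouping; r²=1 links only perfect proxies.
SHARING_THRESHOLDS: tuple[float | None, ...] = (0.6, 0.8, 0.9, 0.95, 1.0, None)


def _best_significant_per_study(annotated: list[AnnotatedQtl]):
    """Minimal-P study-wide-significant record per (gene, source, tissue).

    Exact P ties resolve to the lexicographically smallest variant key so the
    analyses are deterministic and order-independent.
    """
    best: dict[tuple[str, str, str], AnnotatedQtl] = {}
    for a in annotated:
        if not a.is_sw_significant:
            continue
        r = a.record
        key = (r.gene.gene_id, r.study.source, r.study.tissue)
        cur = best.get(key)
        if cur is None or (r.p_value, r.variant.key) < \
                (cur.record.p_value, cur.record.variant.key):
            best[key] = a
    return best


# ---------------------------------------------------------------------------
# Distance analysis


@dataclass
class DistanceSummary:
    """Distances from gene start to the best significant eQTL, per study.

    ``entries`` rows: (gene_id, source, tissue, distance_bp or None,
    colocalization).  Distance is signed in bp (positive: eQTL past the gene
    start); records on another chromosome have no distance and only appear in
    the trans stratum counts.  Summary statistics use absolute distances, in kb.
    """

    entries: list[tuple[str, str, str, float | None, str]] = \
        field(default_factory=list)

    def _abs_kb(self, stratum: str | None = None) -> np.ndarray:
        vals = [abs(d) / 1000.0 for (_g, _s, _t, d, c) in self.entries
                if d is not None and (stratum is None or c == stratum)]
        return np.asarray(vals, dtype=float)

    def mean_kb(self, stratum: str | None = None) -> float:
        v = self._abs_kb(stratum)
        return float(v.mean()) if v.size else float("nan")

    def median_kb(self, stratum: str | None = None) -> float:
        v = self._abs_kb(stratum)
        return float(np.median(v)) if v.size else float("nan")

    def count(self, stratum: str | None = None) -> int:
        return sum(1 for (_g, _s, _t, _d, c) in self.entries
                   if stratum is None or c == stratum)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["gene_id", "source", "tissue",
                                     "distance_bp", "colocalization"])


def best_eqtl_distances(annotated: list[AnnotatedQtl]) -> DistanceSummary:
    """Distance distribution between gene starts and best significant eQTLs.

    One entry per (gene, source, tissue) with at least one study-wide
    significant record; a store with no significant record yields an empty
    summary.
    """
    best = _best_significant_per_study(annotated)
    summary = DistanceSummary()
    for (gene_id, source, tissue), a in sorted(best.items()):
        r = a.record
        if r.variant.chrom is not None and r.variant.pos is not None \
                and r.variant.chrom == r.gene.chrom:
            dist = float(r.variant.pos - r.gene.start_1based)
        else:
            dist = None
        summary.entries.append((gene_id, source, tissue, dist,
                                a.colocalization))
    return summary


def distance_histogram(summary: DistanceSummary, n_bins: int = 30,
                       stratum: str | None = None) -> pd.DataFrame:
    """Log10-scaled histogram of absolute distances (bp), for plotting export."""
    vals = summary._abs_kb(stratum) * 1000.0
    vals = vals[vals > 0]
    if vals.size == 0:
        return pd.DataFrame(columns=["bin_left_bp", "bin_right_bp", "count"])
    edges = np.logspace(np.log10(vals.min()), np.log10(vals.max() + 1),
                        n_bins + 1)
    counts, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_left_bp": edges[:-1],
                         "bin_right_bp": edges[1:],
                         "count": counts})


# ---------------------------------------------------------------------------
# Sharing analysis


@dataclass(frozen=True)
class SharingResult:
    """Max number of tissue-specific studies over a gene's eQTL LD blocks."""

    gene_id: str
    r2_threshold: float | None  # None = "no LD" (every variant its own block)
    max_block_count: int
    n_studies: int              # tissue-specific studies with a best eQTL
    block_variants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.max_block_count < 1:
            raise QtlAnnotError("a gene in the sharing analysis has >= 1 study")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _linked(r2: float, threshold: float | None) -> bool:
    if threshold is None:
        return False
    if threshold >= 1.0:
        return r2 >= 1.0  # perfect proxies only
    return r2 > threshold


def sharing_analysis(annotated: list[AnnotatedQtl],
                     ld_store: LdStore | None,
                     thresholds: tuple[float | None, ...] = SHARING_THRESHOLDS,
                     ) -> list[SharingResult]:
    """Cross-study eQTL sharing per gene at each LD-grouping threshold.

    Only the best study-wide-significant eQTL per tissue-specific study and
    gene is considered.  Variant pairs without LD data are treated as r² = 0
    (separate blocks).  ``max_block_count`` is non-increasing as the grouping
    gets stricter (0.6 → 0.8 → 0.9 → 0.95 → 1.0 → no LD).
    """
    best = _best_significant_per_study(annotated)
    per_gene: dict[str, dict[tuple[str, str], str]] = {}
    for (gene_id, source, tissue), a in best.items():
        per_gene.setdefault(gene_id, {})[(source, tissue)] = \
            a.record.variant.key
    results: list[SharingResult] = []
    for gene_id in sorted(per_gene):
        study_variant = per_gene[gene_id]
        variants = sorted(set(study_variant.values()))
        for thr in thresholds:
            uf = _UnionFind(variants)
            if thr is not None and ld_store is not None:
                for i, va in enumerate(variants):
                    for vb in variants[i + 1:]:
                        got = ld_store.get(va, vb)
                        r2 = 0.0 if got is None else got[0]
                        if _linked(r2, thr):
                            uf.union(va, vb)
            blocks: dict[str, set[tuple[str, str]]] = {}
            members: dict[str, set[str]] = {}
            for study, v in study_variant.items():
                root = uf.find(v)
                blocks.setdefault(root, set()).add(study)
                members.setdefault(root, set()).add(v)
            top_root = max(blocks, key=lambda rt: (len(blocks[rt]), rt))
            results.append(SharingResult(
                gene_id=gene_id, r2_threshold=thr,
                max_block_count=len(blocks[top_root]),
                n_studies=len(study_variant),
                block_variants=frozenset(members[top_root])))
    return results


def sharing_to_frame(results: list[SharingResult]) -> pd.DataFrame:
    rows = [{"gene_id": r.gene_id,
             "r2_threshold": "none" if r.r2_threshold is None
             else r.r2_threshold,
             "max_block_count": r.max_block_count,
             "n_studies": r.n_studies,
             "block_variants": ";".join(sorted(r.block_variants))}
            for r in results]
    return pd.DataFrame(rows, columns=["gene_id", "r2_threshold",
                                       "max_block_count", "n_studies",
                                       "block_variants"])


# ---------------------------------------------------------------------------
# Enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap of the top-k shared genes with a reference set."""

    r2_threshold: float | None
    reference_set: str
    k: int
    overlap: int
    universe_size: int
    reference_in_universe: int
    p_value: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > min(self.k, self.reference_in_universe):
            raise QtlAnnotError("overlap exceeds min(k, |reference|)")
        if not (0.0 < self.p_value <= 1.0):
            raise QtlAnnotError("hypergeometric P must be in (0,1]")


def hypergeometric_enrichment(universe: int, reference_in_universe: int,
                              drawn: int, overlap: int) -> float:
    """One-sided upper-tail hypergeometric P: P(X >= overlap).

    X counts reference genes among ``drawn`` genes sampled without replacement
    from a universe containing ``reference_in_universe`` reference genes.
    """
    if drawn > universe or reference_in_universe > universe:
        raise QtlAnnotError("hypergeometric arguments inconsistent")
    return float(hypergeom.sf(overlap - 1, universe, reference_in_universe,
                              drawn))


def rank_and_enrich(sharing: list[SharingResult],
                    reference_sets: dict[str, set[str]],
                    k: int = 100,
                    thresholds: tuple[float | None, ...] | None = None,
                    ) -> list[EnrichmentResult]:
    """Top-k genes by max sharing count, tested against each reference set.

    The universe is the set of genes with at least one best study-wide
    significant eQTL (every gene appearing in the sharing results).  Ranking
    ties at the k-th count are broken deterministically by gene_id.  BH
    adjustment runs across the whole (threshold x reference set) family.
    """
    if thresholds is None:
        thresholds = tuple(sorted({r.r2_threshold for r in sharing},
                                  key=lambda t: (-1.0 if t is None else t)))
    universe = sorted({r.gene_id for r in sharing})
    if not universe:
        return []
    results: list[EnrichmentResult] = []
    for thr in thresholds:
        counts = {r.gene_id: r.max_block_count for r in sharing
                  if r.r2_threshold == thr}
        ranked = sorted(counts, key=lambda g: (-counts[g], g))
        top = set(ranked[:k])
        n_drawn = len(top)
        for name, ref in sorted(reference_sets.items()):
            ref_in = len(ref & set(universe))
            overlap = len(top & ref)
            p = hypergeometric_enrichment(len(universe), ref_in, n_drawn,
                                          overlap)
            results.append(EnrichmentResult(
                r2_threshold=thr, reference_set=name, k=n_drawn,
                overlap=overlap, universe_size=len(universe),
                reference_in_universe=ref_in, p_value=p))
    if results:
        _rej, p_adj, _a, _b = multipletests(
            [r.p_value for r in results], method="fdr_bh")
        results = [EnrichmentResult(
            r2_threshold=r.r2_threshold, reference_set=r.reference_set,
            k=r.k, overlap=r.overlap, universe_size=r.universe_size,
            reference_in_universe=r.reference_in_universe,
            p_value=r.p_value, p_adjusted=float(q))
            for r, q in zip(results, p_adj)]
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [{"r2_threshold": "none" if r.r2_threshold is None
             else r.r2_threshold,
             "reference_set": r.reference_set, "k": r.k,
             "overlap": r.overlap, "universe": r.universe_size,
             "reference_in_universe": r.reference_in_universe,
             "p": r.p_value, "p_adjusted": r.p_adjusted}
            for r in results]
    return pd.DataFrame(rows)


def top_fraction_expressed(expression: pd.DataFrame,
                           fraction: float = 0.1) -> set[str]:
    """Helper: top-fraction genes by mean expression across tissues.

    ``expression`` is a genes x tissues matrix indexed by gene_id.  Returns the
    gene ids whose mean expression is in the top ``fraction`` (ties broken by
    gene_id for determinism).
    """
    if not (0.0 < fraction <= 1.0):
        raise QtlAnnotError("fraction must be in (0, 1]")
    means = expression.mean(axis=1)
    order = sorted(means.index, key=lambda g: (-means[g], str(g)))
    n = max(1, int(round(fraction * len(order))))
    return set(order[:n])
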