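"""Independent brute-force oracles used to check the package's computations.

Everything here is deliberately naive — explicit 2x2 haplotype counting,
O(n²) loops over records, exhaustive subset enumeration — and shares no code
path with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def oracle_ld(a, b) -> tuple[float, float]:
    """r² and D′ from an explicit 2x2 haplotype count table."""
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for x, y in zip(a, b):
        if x == 1 and y == 1:
            n11 += 1
        elif x == 1 and y == 0:
            n10 += 1
        elif x == 0 and y == 1:
            n01 += 1
        else:
            n00 += 1
    p_a = (n11 + n10) / n
    p_b = (n11 + n01) / n
    p_ab = n11 / n
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    return r2, d_prime


def oracle_flags(records, thresholds, ld_r2_lookup, r2_threshold=0.2,
                 same_gene=True):
    """Recompute all flags for a list of QtlRecords with O(n²) loops.

    ``ld_r2_lookup(a, b)`` returns the stored pairwise r² or 0.0.  Returns a
    list of dicts parallel to ``records``.
    """
    out = []
    for r in records:
        thr = thresholds.get((r.study.source, r.study.study), 1e-12)
        if r.study.significance_policy == "source_provided" \
                and r.source_significant is not None:
            sw = bool(r.source_significant)
        else:
            sw = r.p_value <= thr
        study_group = [x for x in records
                       if x.study.source == r.study.source
                       and x.study.tissue == r.study.tissue]
        best = all(r.p_value <= x.p_value for x in study_group)
        candidates = []
        for x in study_group:
            if same_gene and x.gene.gene_id != r.gene.gene_id:
                continue
            if x.variant.key == r.variant.key \
                    or ld_r2_lookup(r.variant.key, x.variant.key) > r2_threshold:
                candidates.append(x)
        best_in_group = all(r.p_value <= x.p_value for x in candidates)
        out.append({"is_sw_significant": sw, "is_best": best,
                    "is_best_in_ld_group": best_in_group})
    return out


def oracle_counts(records, flags):
    """Recompute n_occ / n_best / n_sw_significant / n_qtls by direct loops."""
    out = []
    for r in records:
        vg_pairs = set()
        best_pairs = set()
        sig_pairs = set()
        n_qtls = 0
        for x, f in zip(records, flags):
            ts = (x.study.source, x.study.tissue)
            if x.variant.key == r.variant.key \
                    and x.gene.gene_id == r.gene.gene_id:
                vg_pairs.add(ts)
                if f["is_best"]:
                    best_pairs.add(ts)
                if f["is_sw_significant"]:
                    sig_pairs.add(ts)
            if x.gene.gene_id == r.gene.gene_id \
                    and ts == (r.study.source, r.study.tissue):
                n_qtls += 1
        out.append({"n_occ": len(vg_pairs), "n_best": len(best_pairs),
                    "n_sw_significant": len(sig_pairs), "n_qtls": n_qtls})
    return out


def oracle_same_tad(tads, chrom_a, pos0_a, chrom_b, pos0_b) -> bool:
    """Any single interval containing both positions (explicit loop)."""
    for (chrom, start, end) in tads:
        if chrom == chrom_a == chrom_b \
                and start <= pos0_a < end and start <= pos0_b < end:
            return True
    return False


def oracle_hypergeom_upper(universe: int, n_ref: int, drawn: int,
                           overlap: int) -> float:
    """P(X >= overlap) by exact combinatorial summation."""
    total = comb(universe, drawn)
    hits = sum(comb(n_ref, x) * comb(universe - n_ref, drawn - x)
               for x in range(overlap, min(n_ref, drawn) + 1))
    return hits / total


def oracle_hypergeom_enumerate(universe_ids, ref_ids, drawn_ids) -> float:
    """P(X >= observed overlap) by enumerating every same-size draw.

    Only feasible for universes <= 20; this is the exhaustive check.
    """
    ref = set(ref_ids)
    observed = len(set(drawn_ids) & ref)
    k = len(drawn_ids)
    hits = total = 0
    for subset in combinations(sorted(universe_ids), k):
        total += 1
        if len(set(subset) & ref) >= observed:
            hits += 1
    return hits / total
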