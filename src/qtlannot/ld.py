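"""Linkage-disequilibrium engine.

Computes pairwise r² and D′ from phased haplotypes by direct 2x2 haplotype
counting (no EM — inputs are phased, as in reference-panel data), or loads a
precomputed pairwise LD table.  On top of the pairwise store it builds LD
groups (seed + all variants with r² > 0.2 against the seed, strictly pairwise,
not a transitive closure) and proxy sets for query expansion (threshold
applied with >=, by r² or D′).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import QtlAnnotError, VariantKey, normalize_chrom

__all__ = [
    "MonomorphicVariantError",
    "HaplotypePanel",
    "LdGroup",
    "LdStore",
    "ld_stats",
    "ld_stats_vectors",
]

DEFAULT_LD_GROUP_R2 = 0.2
DEFAULT_LD_WINDOW_BP = 1_000_000


class MonomorphicVariantError(QtlAnnotError):
    """LD is undefined for a monomorphic variant; callers may skip the pair."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes: matrix of 0/1 alleles, haplotypes x variants."""

    haplotypes: np.ndarray            # shape (n_hap, n_var), dtype int8, 0/1
    variant_ids: list[str]
    positions: np.ndarray | None = None   # 1-based, parallel to variant_ids
    chroms: list[str] | None = None
    population: str = "EUR"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 2:
            raise QtlAnnotError("panel needs >= 2 haplotypes")
        if self.haplotypes.shape[1] != len(self.variant_ids):
            raise QtlAnnotError("variant index does not match matrix width")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise QtlAnnotError("haplotype matrix must be biallelic 0/1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def column(self, variant: str) -> np.ndarray:
        try:
            return self.haplotypes[:, self._index[variant]]
        except KeyError:
            raise QtlAnnotError(f"variant {variant!r} not in panel") from None

    @classmethod
    def from_vcf(cls, path: str, samples: list[str] | None = None,
                 population: str = "EUR") -> "HaplotypePanel":
        """Read phased GT fields from a VCF; biallelic records only.

        ``samples`` optionally restricts to a population subset (e.g. the
        European samples of a reference panel).
        """
        from cyvcf2 import VCF

        vcf = VCF(path, samples=samples, gts012=False)
        cols: list[np.ndarray] = []
        ids: list[str] = []
        positions: list[int] = []
        chroms: list[str] = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                continue  # biallelic only
            gts = rec.genotype.array()
            alleles = gts[:, :2].reshape(-1)
            if (alleles < 0).any():
                continue  # no missing entries allowed after filtering
            cols.append(alleles.astype(np.int8))
            ids.append(rec.ID if rec.ID not in (None, ".") else
                       f"{normalize_chrom(rec.CHROM)}:{rec.POS}")
            positions.append(rec.POS)
            chroms.append(normalize_chrom(rec.CHROM))
        if not cols:
            raise QtlAnnotError(f"no usable phased biallelic records in {path}")
        mat = np.stack(cols, axis=1)
        return cls(haplotypes=mat, variant_ids=ids,
                   positions=np.asarray(positions), chroms=chroms,
                   population=population)


def ld_stats_vectors(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """r² and D′ for two phased 0/1 haplotype vectors.

    Standard definitions from haplotype frequencies:
    D = p_AB − p_A·p_B;  r² = D² / (p_A(1−p_A) p_B(1−p_B));  D′ = |D|/D_max.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise QtlAnnotError("haplotype vectors must be 1-D and equal length")
    n = a.size
    p_a = a.sum() / n
    p_b = b.sum() / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicVariantError("LD undefined for monomorphic variant")
    p_ab = float(a @ b) / n
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))
    if d >= 0:
        d_max = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    # clip numerical overshoot at the boundaries
    return min(max(r2, 0.0), 1.0), min(max(d_prime, 0.0), 1.0)


def ld_stats(panel: HaplotypePanel, variant_a: str,
             variant_b: str) -> tuple[float, float]:
    """Pairwise (r², D′) between two panel variants; symmetric in arguments."""
    return ld_stats_vectors(panel.column(variant_a), panel.column(variant_b))


@dataclass(frozen=True)
class LdGroup:
    """A seed variant plus all variants with pairwise r² above the threshold.

    Membership is strictly pairwise-to-seed (no transitive closure) and uses a
    strict inequality, matching the definition used for the
    ``is_best_in_ld_group`` flag (default threshold 0.2).
    """

    seed: str
    members: frozenset[str]
    threshold: float = DEFAULT_LD_GROUP_R2
    no_ld_data: bool = False

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise QtlAnnotError("LD group must contain its seed")


class LdStore:
    """Symmetric pairwise r²/D′ lookup with per-variant adjacency."""

    def __init__(self, population: str = "EUR") -> None:
        self.population = population
        self._pairs: dict[tuple[str, str], tuple[float, float]] = {}
        self._adj: dict[str, set[str]] = {}
        self._known: set[str] = set()

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_pair(self, a: str, b: str, r2: float, d_prime: float) -> None:
        if a == b:
            return
        if not (0.0 <= r2 <= 1.0 and 0.0 <= d_prime <= 1.0):
            raise QtlAnnotError(f"LD metrics out of [0,1] for {a}/{b}")
        self._pairs[self._key(a, b)] = (float(r2), float(d_prime))
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)
        self._known.update((a, b))

    def add_variant(self, v: str) -> None:
        """Register a variant as covered by the LD reference (possibly isolated)."""
        self._known.add(v)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, variant: str) -> bool:
        return variant in self._known

    def get(self, a: str, b: str) -> tuple[float, float] | None:
        if a == b:
            return (1.0, 1.0)
        return self._pairs.get(self._key(a, b))

    def r2(self, a: str, b: str, default: float = 0.0) -> float:
        got = self.get(a, b)
        return default if got is None else got[0]

    def neighbors(self, v: str) -> dict[str, tuple[float, float]]:
        return {u: self._pairs[self._key(v, u)] for u in self._adj.get(v, ())}

    # ---- construction -----------------------------------------------------

    @classmethod
    def from_panel(cls, panel: HaplotypePanel,
                   window_bp: int | None = DEFAULT_LD_WINDOW_BP,
                   min_r2: float = 0.0) -> "LdStore":
        """All-pairs LD within a window (default 1 Mb) to bound computation.

        Monomorphic variants are skipped (LD undefined).  Pairs with
        r² < ``min_r2`` are not stored, which keeps desk-scale stores sparse;
        absent pairs read back as r² = 0.
        """
        store = cls(population=panel.population)
        mat = panel.haplotypes.astype(np.float64)
        freqs = mat.mean(axis=0)
        poly = (freqs > 0.0) & (freqs < 1.0)
        ids = panel.variant_ids
        for v, ok in zip(ids, poly):
            if ok:
                store.add_variant(v)
        n = panel.n_variants
        for i in range(n):
            if not poly[i]:
                continue
            for j in range(i + 1, n):
                if not poly[j]:
                    continue
                if window_bp is not None and panel.positions is not None:
                    same_chrom = (panel.chroms is None
                                  or panel.chroms[i] == panel.chroms[j])
                    if not same_chrom:
                        continue
                    if abs(int(panel.positions[i]) - int(panel.positions[j])) > window_bp:
                        continue
                r2, dp = ld_stats_vectors(mat[:, i], mat[:, j])
                if r2 >= min_r2 and r2 > 0.0:
                    store.add_pair(ids[i], ids[j], r2, dp)
        return store

    @classmethod
    def from_tsv(cls, path: str, population: str = "EUR") -> "LdStore":
        """Load a precomputed pairwise table: ``variant_a variant_b r2 dprime``."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"variant_a", "variant_b", "r2", "dprime"}
        missing = required - set(df.columns)
        if missing:
            raise QtlAnnotError(
                f"LD table {path} lacks columns: {sorted(missing)}")
        store = cls(population=population)
        for a, b, r2, dp in zip(df["variant_a"], df["variant_b"],
                                df["r2"].astype(float),
                                df["dprime"].astype(float)):
            store.add_pair(str(a), str(b), r2, dp)
        return store

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2, dp)
                for (a, b), (r2, dp) in sorted(self._pairs.items())]
        return pd.DataFrame(rows,
                            columns=["variant_a", "variant_b", "r2", "dprime"])

    # ---- group / proxy operations ----------------------------------------

    def build_ld_group(self, seed: str,
                       r2_threshold: float = DEFAULT_LD_GROUP_R2) -> LdGroup:
        """The seed plus every variant with pairwise r² strictly above threshold.

        A seed absent from the LD reference yields a singleton group flagged
        ``no_ld_data`` (conservative: such variants are their own group).
        """
        if seed not in self._known:
            return LdGroup(seed=seed, members=frozenset([seed]),
                           threshold=r2_threshold, no_ld_data=True)
        members = {seed}
        for other, (r2, _dp) in self.neighbors(seed).items():
            if r2 > r2_threshold:
                members.add(other)
        return LdGroup(seed=seed, members=frozenset(members),
                       threshold=r2_threshold)

    def find_proxies(self, seed: str, metric: str = "r2",
                     threshold: float = 0.8) -> list[tuple[str, float, float]]:
        """Proxy variants of a seed at metric >= threshold, sorted descending.

        Returns (variant, r2, d_prime) triples; the seed itself is excluded.
        Proxy sets are antitone in the threshold (higher cutoff, subset).
        """
        if metric not in ("r2", "dprime"):
            raise QtlAnnotError(f"unknown LD metric {metric!r}")
        if not (0.0 <= threshold <= 1.0):
            raise QtlAnnotError("proxy threshold must be in [0, 1]")
        idx = 0 if metric == "r2" else 1
        hits = [(v, r2, dp) for v, (r2, dp) in self.neighbors(seed).items()
                if (r2, dp)[idx] >= threshold]
        hits.sort(key=lambda t: (-t[1 + idx], t[0]))
        return hits
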