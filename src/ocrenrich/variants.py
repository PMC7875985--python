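"""Variants, haplotype panels, LD (r²), proxy expansion and locus filters.

r² is computed from phased haplotypes: with allele frequencies pA, pB and
joint frequency pAB over haplotypes,

    D = pAB − pA·pB,    r² = D² / (pA(1−pA) pB(1−pB)).

A *risk locus* is a genome-wide-significant index variant together with all
proxies at r² above a threshold (default 0.8, strict) within a window
(default 1 Mb, index-to-proxy distance, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

#: Extended MHC region excluded in sensitivity analyses (unusual LD).
MHC_REGION: tuple[str, int, int] = ("chr6", 26_000_000, 34_000_000)


class LDUndefinedError(ValueError):
    """r² requested for a monomorphic variant (undefined LD)."""


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError("maf must lie in [0, 0.5]")


@dataclass
class RiskLocus:
    """An index variant plus its LD proxies and the spanning interval."""

    index: Variant
    proxies: list[Variant]
    span: GenomicInterval

    def __post_init__(self) -> None:
        if any(p.id == self.index.id for p in self.proxies):
            raise ValueError("index must not appear among its own proxies")

    @property
    def positions(self) -> np.ndarray:
        return np.array(
            [self.index.pos] + [p.pos for p in self.proxies], dtype=np.int64
        )

    @property
    def chrom(self) -> str:
        return self.index.chrom


@dataclass
class GeneAnnotation:
    """Per-chromosome sorted transcription start site positions."""

    tss_positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.tss_positions.items():
            arr = np.sort(np.asarray(pos, dtype=np.int64))
            if len(arr) and arr[0] < 0:
                raise ValueError("TSS positions must be non-negative")
            clean[chrom] = arr
        self.tss_positions = clean

    @classmethod
    def from_table(cls, path) -> "GeneAnnotation":
        """Read a 2-column (chrom, tss) or BED table (start used as TSS)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        by_chrom: dict[str, list[int]] = {}
        for chrom, tss in zip(df[0], df[1]):
            by_chrom.setdefault(str(chrom), []).append(int(tss))
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.tss_positions):
                for tss in self.tss_positions[chrom]:
                    fh.write(f"{chrom}\t{int(tss)}\n")


class HaplotypePanel:
    """Phased binary haplotype matrix (haplotypes × variants)."""

    def __init__(self, alleles: np.ndarray, variants: Sequence[Variant]):
        alleles = np.asarray(alleles, dtype=np.uint8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if alleles.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if alleles.shape[1] != len(variants):
            raise ValueError("column count must equal variant count")
        if alleles.max(initial=0) > 1:
            raise ValueError("allele entries must be 0 or 1")
        self.alleles = alleles
        freq = alleles.mean(axis=0)
        maf = np.minimum(freq, 1.0 - freq)
        self.variants: list[Variant] = [
            Variant(v.id, v.chrom, v.pos, float(m))
            for v, m in zip(variants, maf)
        ]
        self._id_index = {v.id: i for i, v in enumerate(self.variants)}
        self.chroms = np.array([v.chrom for v in self.variants])
        self.positions = np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def maf(self) -> np.ndarray:
        freq = self.alleles.mean(axis=0)
        return np.minimum(freq, 1.0 - freq)

    def column(self, variant_id: str) -> int:
        try:
            return self._id_index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_files(cls, matrix_path, variants_path) -> "HaplotypePanel":
        """Load a 0/1 matrix (rows = haplotypes) plus a variant table.

        The variant table is tab-separated with columns id, chrom, pos
        (0-based) and optionally maf (recomputed from the matrix anyway).
        """
        alleles = np.loadtxt(matrix_path, dtype=np.uint8)
        vdf = pd.read_csv(variants_path, sep="\t")
        variants = [
            Variant(str(r.id), str(r.chrom), int(r.pos))
            for r in vdf.itertuples()
        ]
        return cls(np.atleast_2d(alleles), variants)

    def write(self, matrix_path, variants_path) -> None:
        np.savetxt(matrix_path, self.alleles, fmt="%d", delimiter="\t")
        pd.DataFrame(
            {
                "id": [v.id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "maf": [v.maf for v in self.variants],
            }
        ).to_csv(variants_path, sep="\t", index=False, float_format="%.6g")


def compute_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared LD correlation r² between panel columns ``i`` and ``j``."""
    a = panel.alleles[:, i].astype(float)
    b = panel.alleles[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise LDUndefinedError("r2 undefined for a monomorphic variant")
    pab = (a * b).mean()
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return float(min(1.0, max(0.0, r2)))


def _r2_vector(panel: HaplotypePanel, col: int, cand: np.ndarray) -> np.ndarray:
    """r² of column ``col`` against candidate columns, vectorized."""
    h = panel.n_haplotypes
    a = panel.alleles[:, col].astype(np.float64)
    x = panel.alleles[:, cand].astype(np.float64)
    pa = a.mean()
    pb = x.mean(axis=0)
    pab = a @ x / h
    d = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    return np.clip(r2, 0.0, 1.0)


def find_proxies(
    panel: HaplotypePanel,
    index: Variant | str,
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> RiskLocus:
    """Expand an index variant into a RiskLocus of LD proxies.

    Proxies are all other panel variants on the index chromosome within
    ``window`` bases whose r² with the index strictly exceeds
    ``r2_threshold``. The span covers index and proxies.
    """
    vid = index if isinstance(index, str) else index.id
    col = panel.column(vid)
    v = panel.variants[col]
    if v.maf == 0.0:
        raise LDUndefinedError(f"index variant {vid!r} is monomorphic")
    cand = np.flatnonzero(
        (panel.chroms == v.chrom)
        & (np.abs(panel.positions - v.pos) <= window)
    )
    cand = cand[cand != col]
    proxies: list[Variant] = []
    if len(cand):
        r2 = _r2_vector(panel, col, cand)
        hit = cand[np.nan_to_num(r2) > r2_threshold]
        proxies = [panel.variants[k] for k in np.sort(hit)]
    pos = [v.pos] + [p.pos for p in proxies]
    span = GenomicInterval(v.chrom, int(min(pos)), int(max(pos)) + 1)
    return RiskLocus(index=v, proxies=proxies, span=span)


def all_risk_loci(
    panel: HaplotypePanel,
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> list[RiskLocus]:
    """Build the RiskLocus of every polymorphic panel variant.

    Uses one covariance pass per chromosome; equivalent to calling
    :func:`find_proxies` per variant but much faster for control pools.
    """
    loci: list[RiskLocus] = [None] * panel.n_variants  # type: ignore
    h = panel.n_haplotypes
    for chrom in np.unique(panel.chroms):
        cols = np.flatnonzero(panel.chroms == chrom)
        x = panel.alleles[:, cols].astype(np.float64)
        p = x.mean(axis=0)
        pab = x.T @ x / h
        d = pab - np.outer(p, p)
        denom = np.outer(p * (1 - p), p * (1 - p))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, d * d / denom, 0.0)
        pos = panel.positions[cols]
        near = np.abs(pos[:, None] - pos[None, :]) <= window
        hit = (r2 > r2_threshold) & near
        np.fill_diagonal(hit, False)
        for a, col in enumerate(cols):
            v = panel.variants[col]
            proxies = [panel.variants[cols[b]] for b in np.flatnonzero(hit[a])]
            ps = [v.pos] + [q.pos for q in proxies]
            span = GenomicInterval(chrom, int(min(ps)), int(max(ps)) + 1)
            loci[col] = RiskLocus(index=v, proxies=proxies, span=span)
    return [l for l in loci if l is not None]


def distance_to_nearest_gene(v: Variant, genes: GeneAnnotation) -> float:
    """Minimal |pos − TSS| on the variant's chromosome; +inf if none."""
    tss = genes.tss_positions.get(v.chrom)
    if tss is None or len(tss) == 0:
        return float("inf")
    i = np.searchsorted(tss, v.pos)
    best = np.inf
    if i < len(tss):
        best = min(best, abs(int(tss[i]) - v.pos))
    if i > 0:
        best = min(best, abs(int(tss[i - 1]) - v.pos))
    return float(best)


def filter_mhc(
    loci: Sequence[RiskLocus],
    region: tuple[str, int, int] = MHC_REGION,
) -> list[RiskLocus]:
    """Drop loci whose *index* lies in the half-open region; idempotent."""
    chrom, lo, hi = region
    return [
        l
        for l in loci
        if not (l.index.chrom == chrom and lo <= l.index.pos < hi)
    ]
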