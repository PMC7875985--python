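"""Synthetic study generator: genome, peaks with planted motifs, an
LD-structured haplotype panel, risk loci with a controllable planted
enrichment effect, matched-control pools and negative-control variant sets.

The generator emulates, at desk scale, the shape of a GWAS-vs-open-chromatin
enrichment study: a small diploid-free genome (i.i.d. bases with tunable GC),
disjoint ATAC-seq-like peaks, a phased haplotype panel with founder-derived
LD blocks and a realistic (uniform-frequency, MAF-filtered) allele-frequency
spectrum, and index-variant sets. ``effect`` is the fraction of index loci
resampled conditional on their locus (index or LD proxy) overlapping a
designated target annotation — the planted enrichment; ``effect = 0`` gives
calibration/negative-control sets. Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import MatchingBins
from .intervals import GenomicInterval, IntervalSet
from .motifs import BASES, PWM, reverse_complement
from .variants import (
    GeneAnnotation,
    HaplotypePanel,
    RiskLocus,
    Variant,
    all_risk_loci,
)


class SimulationError(RuntimeError):
    """The requested synthetic configuration could not be realized."""


_DEFAULT_MOTIFS = ("GCAGCTGC", "GGATTACA")


@dataclass
class SyntheticConfig:
    """Study conditions of the scaled synthetic analysis.

    Defaults define a 2-chromosome × 2 Mb genome with 500 peaks, a
    200-haplotype / 2,000-variant panel with 20 kb founder blocks, 60 risk
    loci and two negative-control variant sets.
    """

    seed: int = 20210210
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    gc_content: float = 0.41
    n_peaks: int = 500
    peak_length_mean: int = 500
    motif_consensi: tuple = _DEFAULT_MOTIFS
    plant_rate: float = 0.45
    n_haplotypes: int = 200
    n_variants: int = 2000
    block_length: int = 10_000
    n_founders: tuple = (2, 4)  # inclusive range per block
    mutation_rate: float = 0.02
    maf_min: float = 0.05
    n_loci: int = 60
    effect: float = 0.0
    n_control_sets: int = 2
    n_genes: int = 40
    n_decoy_annotations: int = 2
    r2_threshold: float = 0.8
    ld_window: int = 1_000_000

    def __post_init__(self) -> None:
        for frac in (self.gc_content, self.plant_rate, self.mutation_rate,
                     self.maf_min, self.effect):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        for n in (self.n_chrom, self.chrom_length, self.n_peaks,
                  self.peak_length_mean, self.n_haplotypes, self.n_variants,
                  self.block_length, self.n_loci, self.n_genes):
            if n <= 0:
                raise ValueError("lengths and counts must be positive")

    @property
    def motif_set(self) -> list[PWM]:
        return [
            PWM.from_consensus(f"planted_{c}", c)
            for c in self.motif_consensi
        ]

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


# -- genome and peaks -----------------------------------------------------


def gen_genome(cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """i.i.d. genome with the configured GC content, as base-code arrays."""
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        name: rng.choice(4, size=cfg.chrom_length, p=p).astype(np.int8)
        for name in cfg.chrom_names()
    }


def _place_disjoint(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    n: int,
    label: str,
    name_prefix: str,
) -> IntervalSet:
    per_chrom = np.full(cfg.n_chrom, n // cfg.n_chrom)
    per_chrom[: n % cfg.n_chrom] += 1
    intervals: list[GenomicInterval] = []
    idx = 0
    for chrom, want in zip(cfg.chrom_names(), per_chrom):
        placed: list[tuple[int, int]] = []
        for _round in range(100):
            if len(placed) >= want:
                break
            need = want - len(placed)
            lengths = np.clip(
                rng.gamma(4.0, cfg.peak_length_mean / 4.0, size=need),
                60,
                None,
            ).astype(int)
            starts = rng.integers(0, cfg.chrom_length - lengths.max(), need)
            cand = sorted(placed + list(zip(starts, starts + lengths)))
            keep: list[tuple[int, int]] = []
            last_end = -1
            for s, e in cand:
                if s > last_end:  # strict: keep peaks non-bookended too
                    keep.append((int(s), int(e)))
                    last_end = e
            placed = keep[:want]
        else:
            raise SimulationError(
                f"could not place {want} disjoint intervals on {chrom}"
            )
        for s, e in sorted(placed):
            intervals.append(GenomicInterval(chrom, s, e, f"{name_prefix}{idx:05d}"))
            idx += 1
    return IntervalSet(intervals, label=label, _normalized=True)


def gen_peaks(cfg: SyntheticConfig, rng: np.random.Generator) -> IntervalSet:
    return _place_disjoint(cfg, rng, cfg.n_peaks, "peaks", "peak_")


def plant_motif_peaks(
    cfg: SyntheticConfig,
    genome: dict,
    peaks: IntervalSet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Write exact consensus instances into a ``plant_rate`` fraction of peaks.

    One instance per (peak, motif), at a uniform internal offset and random
    strand, avoiding previously planted windows in the same peak. Mutates
    ``genome`` in place; returns the truth table (peak, motif, offset,
    strand) with peak-relative offsets.
    """
    peak_list = list(peaks)
    records = []
    occupied: dict[str, list[tuple[int, int]]] = {iv.name: [] for iv in peak_list}
    for pwm in cfg.motif_set:
        consensus = pwm.consensus()
        w = len(consensus)
        n_plant = int(round(cfg.plant_rate * len(peak_list)))
        chosen = rng.choice(len(peak_list), size=n_plant, replace=False)
        for pi in sorted(chosen):
            iv = peak_list[pi]
            if len(iv) < w:
                continue
            placed = None
            for _try in range(20):
                off = int(rng.integers(0, len(iv) - w + 1))
                if all(
                    off + w <= a or off >= b for a, b in occupied[iv.name]
                ):
                    placed = off
                    break
            if placed is None:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            inst = consensus if strand == "+" else reverse_complement(consensus)
            codes = np.array([BASES.index(b) for b in inst], dtype=np.int8)
            genome[iv.chrom][iv.start + placed:iv.start + placed + w] = codes
            occupied[iv.name].append((placed, placed + w))
            records.append(
                {
                    "peak": iv.name,
                    "motif": pwm.name,
                    "offset": placed,
                    "strand": strand,
                }
            )
    return pd.DataFrame(records, columns=["peak", "motif", "offset", "strand"])


def decode_genome(genome: dict) -> dict[str, str]:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return {
        name: lut[arr.astype(np.intp)].tobytes().decode()
        for name, arr in genome.items()
    }


# -- haplotype panel ------------------------------------------------------


def gen_haplotype_panel(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> HaplotypePanel:
    """Founder-block panel: within each ``block_length`` block, haplotypes
    descend from 2–4 founders with per-site mutation, giving high
    within-block and low between-block r². Monomorphic and MAF <
    ``maf_min`` columns are dropped; candidate sites are oversampled so the
    retained panel holds ``n_variants`` common variants (fewer only when the
    MAF spectrum is too sparse).
    """
    h = cfg.n_haplotypes
    n_sites = int(np.ceil(cfg.n_variants * 1.7))
    per_chrom = np.full(cfg.n_chrom, n_sites // cfg.n_chrom)
    per_chrom[: n_sites % cfg.n_chrom] += 1
    cols: list[np.ndarray] = []
    variants: list[Variant] = []
    vid = 0
    for chrom, m in zip(cfg.chrom_names(), per_chrom):
        pos = np.sort(
            rng.choice(cfg.chrom_length, size=m, replace=False)
        ).astype(np.int64)
        block_ids = pos // cfg.block_length
        alleles = np.zeros((h, m), dtype=np.uint8)
        for b in np.unique(block_ids):
            sel = np.flatnonzero(block_ids == b)
            lo_f, hi_f = cfg.n_founders
            nf = int(rng.integers(lo_f, hi_f + 1))
            founders = rng.integers(0, 2, size=(nf, len(sel))).astype(np.uint8)
            assign = rng.integers(0, nf, size=h)
            block = founders[assign]
            flips = rng.random((h, len(sel))) < cfg.mutation_rate
            alleles[:, sel] = block ^ flips.astype(np.uint8)
        for j in range(m):
            variants.append(Variant(f"var_{vid:05d}", chrom, int(pos[j])))
            vid += 1
        cols.append(alleles)
    alleles = np.concatenate(cols, axis=1)
    freq = alleles.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    keep = np.flatnonzero(maf >= cfg.maf_min)
    if len(keep) == 0:
        raise SimulationError(
            "no polymorphic variants survive the MAF filter; raise "
            "n_haplotypes or lower maf_min/mutation_rate"
        )
    if len(keep) > cfg.n_variants:
        keep = np.sort(rng.choice(keep, size=cfg.n_variants, replace=False))
    return HaplotypePanel(
        alleles[:, keep],
        [variants[int(k)] for k in keep],
    )


def gen_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> GeneAnnotation:
    per_chrom = np.full(cfg.n_chrom, cfg.n_genes // cfg.n_chrom)
    per_chrom[: cfg.n_genes % cfg.n_chrom] += 1
    return GeneAnnotation(
        {
            chrom: np.sort(rng.integers(0, cfg.chrom_length, size=n))
            for chrom, n in zip(cfg.chrom_names(), per_chrom)
        }
    )


# -- risk loci with planted enrichment ------------------------------------


def _greedy_independent(
    candidates: np.ndarray,
    n: int,
    loci: list[RiskLocus],
    rng: np.random.Generator,
    taken: set[int],
    chosen_ids: set[str] | None = None,
) -> list[int]:
    """Pick n candidate columns, skipping LD partners of earlier picks.

    Greedy over a random candidate order; retries fresh orders (bounded)
    when one order strands too many candidates behind LD partners.
    """
    chosen_ids = set() if chosen_ids is None else chosen_ids
    best: list[int] | None = None
    for _attempt in range(10):
        order = rng.permutation(candidates)
        chosen: list[int] = []
        ids = set(chosen_ids)
        for c in order:
            if len(chosen) == n:
                break
            if c in taken:
                continue
            locus = loci[c]
            if locus.index.id in ids or any(
                p.id in ids for p in locus.proxies
            ):
                continue
            chosen.append(int(c))
            ids.add(locus.index.id)
            ids.update(p.id for p in locus.proxies)
        if best is None or len(chosen) > len(best):
            best = chosen
        if len(best) == n:
            chosen_ids.update(
                {loci[c].index.id for c in best}
                | {p.id for c in best for p in loci[c].proxies}
            )
            return best
    raise SimulationError(
        f"only {len(best)} LD-independent eligible index variants, need {n}"
    )


def gen_risk_loci(
    cfg: SyntheticConfig,
    panel: HaplotypePanel,
    target: IntervalSet,
    genes: GeneAnnotation,
    bins: MatchingBins | None = None,
    rng: np.random.Generator | None = None,
):
    """Index-variant sets with a planted enrichment toward ``target``.

    A fraction ``cfg.effect`` of the ``n_loci`` study indices is drawn only
    from variants whose locus (index or proxy) overlaps the target
    annotation; the remainder is drawn unconditionally. Index variants are
    restricted to matching bins that can supply ``bins.min_controls``
    controls, and chosen LD-independent of each other; study and control
    draws are conditioned identically, so effect = 0 is an exchangeable
    null. Returns (study loci, control pool, control variant sets).
    """
    if bins is None:
        bins = MatchingBins.scaled_default()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not target.is_normalized:
        target = target.normalize()

    from .variants import distance_to_nearest_gene  # local to avoid cycle

    loci = all_risk_loci(panel, cfg.r2_threshold, cfg.ld_window)
    n = len(loci)
    overlap = np.array(
        [
            target.contains_positions(l.chrom, l.positions).any()
            for l in loci
        ]
    )
    keys = [
        bins.assign(
            len(l.proxies),
            l.index.maf,
            distance_to_nearest_gene(l.index, genes),
        )
        for l in loci
    ]
    occupancy: dict[tuple, int] = {}
    for k in keys:
        occupancy[k] = occupancy.get(k, 0) + 1
    # A variant is an eligible index when its bin can still supply controls
    # after excluding itself, its LD partners, and other study indices that
    # may land in the same bin (margin).
    margin = 15
    eligible = np.array(
        [
            occupancy[k] - 1 - len(l.proxies) >= bins.min_controls + margin
            for k, l in zip(keys, loci)
        ]
    )
    n_eff = int(round(cfg.effect * cfg.n_loci))
    eff_candidates = np.flatnonzero(eligible & overlap)
    if len(eff_candidates) < n_eff:
        raise SimulationError(
            f"only {len(eff_candidates)} eligible target-overlapping "
            f"variants, need {n_eff}; enlarge the target or lower effect"
        )
    taken: set[int] = set()
    ids: set[str] = set()
    chosen = _greedy_independent(
        eff_candidates, n_eff, loci, rng, taken, ids
    )
    taken.update(chosen)
    rest = _greedy_independent(
        np.flatnonzero(eligible), cfg.n_loci - n_eff, loci, rng, taken, ids
    )
    study_cols = chosen + rest
    study = [loci[c] for c in study_cols]
    pool = [loci[c] for c in range(n) if c not in set(study_cols)]

    control_sets: list[list[RiskLocus]] = []
    for _ in range(cfg.n_control_sets):
        cols = _greedy_independent(
            np.flatnonzero(eligible), cfg.n_loci, loci, rng, set()
        )
        control_sets.append([loci[c] for c in cols])
    return study, pool, control_sets


# -- orchestration --------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    genome: dict[str, str]
    annotations: list[IntervalSet]  # element 0 is the peak set
    peak_sequences: dict[str, str]
    truth: pd.DataFrame
    target_subset: IntervalSet  # peaks carrying the first planted motif
    panel: HaplotypePanel
    genes: GeneAnnotation
    loci: list[RiskLocus]
    pool: list[RiskLocus]
    control_sets: list[list[RiskLocus]]
    bins: MatchingBins

    @property
    def peaks(self) -> IntervalSet:
        return self.annotations[0]


def simulate_study(
    cfg: SyntheticConfig,
    bins: MatchingBins | None = None,
    sequences: bool = True,
) -> SyntheticStudy:
    """Generate the full fixture bundle for one seed.

    With ``sequences=False`` the genome/motif-planting stage is skipped
    (peaks are placed but carry no sequence) — sufficient for enrichment
    calibration runs; the planted-enrichment target then defaults to the
    full peak set.
    """
    if bins is None:
        bins = MatchingBins.scaled_default()
    rng = np.random.default_rng(cfg.seed)
    peaks = gen_peaks(cfg, rng)
    annotations = [peaks] + [
        _place_disjoint(cfg, rng, cfg.n_peaks, f"decoy_{i + 1}", f"d{i + 1}_")
        for i in range(cfg.n_decoy_annotations)
    ]
    if sequences:
        genome_codes = gen_genome(cfg, rng)
        truth = plant_motif_peaks(cfg, genome_codes, peaks, rng)
        genome = decode_genome(genome_codes)
        first = cfg.motif_set[0].name
        carriers = set(truth.loc[truth.motif == first, "peak"])
        target_subset = IntervalSet(
            [iv for iv in peaks if iv.name in carriers],
            label=f"{first}-truth-subset",
            _normalized=True,
        )
        from .seqio import extract_sequences

        peak_sequences = extract_sequences(genome, peaks)
    else:
        genome = {}
        truth = pd.DataFrame(columns=["peak", "motif", "offset", "strand"])
        target_subset = peaks
        peak_sequences = {}
    panel = gen_haplotype_panel(cfg, rng)
    genes = gen_genes(cfg, rng)
    target = target_subset if len(target_subset) else peaks
    loci, pool, control_sets = gen_risk_loci(
        cfg, panel, target, genes, bins=bins, rng=rng
    )
    return SyntheticStudy(
        config=cfg,
        genome=genome,
        annotations=annotations,
        peak_sequences=peak_sequences,
        truth=truth,
        target_subset=target_subset,
        panel=panel,
        genes=genes,
        loci=loci,
        pool=pool,
        control_sets=control_sets,
        bins=bins,
    )


def known_motif_library(cfg: SyntheticConfig) -> list[PWM]:
    """A small known-motif library: the planted motifs plus fixed decoys."""
    decoys = [
        PWM.from_consensus("decoy_TTTTCCCC", "TTTTCCCC"),
        PWM.from_consensus("decoy_GAGAGAGA", "GAGAGAGA"),
        PWM.from_consensus("decoy_CCCTTAGG", "CCCTTAGG"),
    ]
    return [
        PWM.from_consensus(f"known_{c}", c) for c in cfg.motif_consensi
    ] + decoys


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write every fixture file in plain-text formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from .seqio import write_fasta, write_motif_library

    if study.genome:
        write_fasta(out / "genome.fa", study.genome)
    for ann in study.annotations:
        ann.to_bed(out / f"{ann.label}.bed")
    study.target_subset.to_bed(out / "target_subset.bed")
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    study.panel.write(out / "haplotypes.tsv", out / "variants.tsv")
    study.genes.to_table(out / "genes.tsv")
    pd.DataFrame(
        {
            "id": [l.index.id for l in study.loci],
            "chrom": [l.index.chrom for l in study.loci],
            "pos": [l.index.pos for l in study.loci],
            "n_proxies": [len(l.proxies) for l in study.loci],
        }
    ).to_csv(out / "index_variants.tsv", sep="\t", index=False)
    for i, cs in enumerate(study.control_sets):
        pd.DataFrame(
            {
                "id": [l.index.id for l in cs],
                "chrom": [l.index.chrom for l in cs],
                "pos": [l.index.pos for l in cs],
            }
        ).to_csv(out / f"control_set_{i + 1}.tsv", sep="\t", index=False)
    write_motif_library(out / "known_motifs.txt", known_motif_library(study.config))
    cfg_dict = asdict(study.config)
    (out / "config.json").write_text(
        json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n"
    )
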