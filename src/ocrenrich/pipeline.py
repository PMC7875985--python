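"""End-to-end workflow: stage 1 annotation enrichment, stage 2 motif
discovery and peak subsetting within the top dual-significant annotation,
stage 3 per-subset enrichment, plus negative-control variant sets.

Stage 1 runs both enrichment tests (locus-shift permutation and
matched-control Poisson-binomial) on every annotation set, Bonferroni factor
= number of annotation sets; an annotation is dual-significant when both
adjusted p-values fall below alpha. Stage 2 discovers enriched k-mers in the
top dual-significant annotation's peak sequences against per-sequence
shuffled backgrounds, scans them back (optionally via best-matched known
motifs), and subsets the peaks (including the noMotif negative-control
subset, with an exclusion log). Stage 3 re-runs both tests per subset,
Bonferroni factor = number of subsets actually tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import (
    EnrichmentResult,
    MatchingBins,
    dual_significant,
    locus_shift_test,
    matched_control_test,
)
from .intervals import IntervalSet
from .motifs import (
    BackgroundModel,
    KmerMotif,
    MotifOccurrence,
    PWM,
    discover_enriched_kmers,
    match_to_known_motifs,
    scan_sequences,
    subset_peaks_by_motif,
)
from .simulate import (
    SyntheticConfig,
    SyntheticStudy,
    known_motif_library,
    simulate_study,
)
from .variants import GeneAnnotation, RiskLocus, filter_mhc


@dataclass
class AnalysisConfig:
    """Workflow parameters. Defaults are the full-scale analysis settings;
    :meth:`scaled_synthetic` returns the preset sized for the synthetic
    fixture (fewer permutations, smaller control and subset minima)."""

    seed: int = 0
    r2_threshold: float = 0.8
    ld_window: int = 1_000_000
    n_perm: int = 10_000
    scan_p: float = 1e-4
    min_subset: int = 1000
    exclude_mhc: bool = False
    alpha: float = 0.05
    mode: str = "denovo"  # "denovo" | "known"
    k_range: tuple = (6, 7, 8)
    e_threshold: float = 0.05
    max_motifs: int = 25
    similarity_min: float = 0.8
    bins: MatchingBins = field(default_factory=MatchingBins)
    synthetic: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("denovo", "known"):
            raise ValueError("mode must be 'denovo' or 'known'")
        for p in (self.scan_p, self.alpha, self.e_threshold):
            if not (0.0 < p <= 1.0):
                raise ValueError("thresholds must lie in (0, 1]")

    @classmethod
    def scaled_synthetic(
        cls, seed: int, effect: float = 0.0, **overrides
    ) -> "AnalysisConfig":
        synth = SyntheticConfig(seed=seed, effect=effect)
        return cls(
            seed=seed,
            n_perm=overrides.pop("n_perm", 1000),
            min_subset=overrides.pop("min_subset", 50),
            bins=overrides.pop("bins", MatchingBins.scaled_default()),
            synthetic=synth,
            **overrides,
        )


@dataclass
class WorkflowReport:
    stage1: pd.DataFrame
    stage2_motifs: pd.DataFrame | None
    exclusions: list[tuple[str, str]]
    stage3: pd.DataFrame | None
    control_stage1: dict[str, pd.DataFrame]
    control_stage3: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.6g")
        self.stage1.to_csv(out / "stage1_annotations.tsv", **kw)
        if self.stage2_motifs is not None:
            self.stage2_motifs.to_csv(out / "stage2_motifs.tsv", **kw)
        with open(out / "stage2_exclusions.tsv", "w") as fh:
            fh.write("motif\trule\n")
            for motif, rule in self.exclusions:
                fh.write(f"{motif}\t{rule}\n")
        if self.stage3 is not None:
            self.stage3.to_csv(out / "stage3_subsets.tsv", **kw)
        for name, df in self.control_stage1.items():
            df.to_csv(out / f"{name}_stage1.tsv", **kw)
        for name, df in self.control_stage3.items():
            df.to_csv(out / f"{name}_stage3.tsv", **kw)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str)
            + "\n"
        )


def _test_annotations(
    loci: Sequence[RiskLocus],
    annotations: Sequence[IntervalSet],
    pool: Sequence[RiskLocus],
    bins: MatchingBins,
    genes: GeneAnnotation,
    cfg: AnalysisConfig,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Both enrichment tests per annotation, Bonferroni over the batch."""
    n_tests = len(annotations)
    rows = []
    for ann, seed in zip(annotations, seeds):
        ann = ann.normalize() if not ann.is_normalized else ann
        ls = locus_shift_test(
            loci, ann, n_perm=cfg.n_perm, seed=int(seed)
        ).with_bonferroni(n_tests)
        mc = matched_control_test(loci, ann, pool, bins, genes).with_bonferroni(
            n_tests
        )
        rows.append(
            {
                "annotation": ann.label,
                "n_intervals": len(ann),
                "observed_proportion": ls.observed,
                "n_overlap": ls.n_overlap,
                "locus_shift_p_raw": ls.p_raw,
                "locus_shift_p_adj": ls.p_adjusted,
                "matched_control_p_raw": mc.p_raw,
                "matched_control_p_adj": mc.p_adjusted,
                "n_tests": n_tests,
                "dual_significant": dual_significant(
                    ls.p_adjusted, mc.p_adjusted, cfg.alpha
                ),
            }
        )
    return pd.DataFrame(rows)


def _shuffle_sequences(
    seqs: dict[str, str], rng: np.random.Generator
) -> list[str]:
    """Per-sequence base shuffle: preserves each sequence's composition."""
    out = []
    for s in seqs.values():
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out.append(arr.tobytes().decode())
    return out


def _discover_and_subset(
    study: SyntheticStudy,
    annotation: IntervalSet,
    cfg: AnalysisConfig,
    rng: np.random.Generator,
):
    """Stage 2: k-mer discovery, (optional) known-motif matching, scanning
    and peak subsetting within one annotation. Returns
    (motif table, occurrences per motif, PeakSubsets)."""
    from .seqio import extract_sequences

    seqs = (
        study.peak_sequences
        if annotation is study.peaks
        else extract_sequences(study.genome, annotation)
    )
    background = _shuffle_sequences(seqs, rng)
    motifs = discover_enriched_kmers(
        list(seqs.values()),
        background,
        k_range=cfg.k_range,
        e_threshold=cfg.e_threshold,
        max_motifs=cfg.max_motifs,
    )
    bg = BackgroundModel.from_sequences(seqs.values())
    library = known_motif_library(study.config)

    occurrences: dict[str, list[MotifOccurrence]] = {}
    matched: set[str] = set()
    rows = []
    scanned: set[str] = set()
    for km in motifs:
        matches = match_to_known_motifs(km, library)
        best = matches[0] if matches else None
        has_match = best is not None and best.score >= cfg.similarity_min
        if cfg.mode == "denovo":
            key, pwm = km.pattern, km.to_pwm()
        else:
            if not has_match:
                # keep the de novo name so the exclusion log can cite it
                key, pwm = km.pattern, None
            else:
                key, pwm = best.motif.name, best.motif
        if has_match:
            matched.add(key)
        rows.append(
            {
                "pattern": km.pattern,
                "subset_key": key,
                "n_target_pos": km.n_target_pos,
                "n_bg_pos": km.n_bg_pos,
                "p_fisher": km.p_fisher,
                "e_value": km.e_value,
                "best_known_match": best.motif.name if best else "",
                "match_score": best.score if best else np.nan,
            }
        )
        if key in scanned:
            continue
        scanned.add(key)
        if pwm is None:
            occurrences[key] = []
        else:
            occurrences[key] = scan_sequences(
                seqs, pwm, bg, p_threshold=cfg.scan_p
            )
    subsets = subset_peaks_by_motif(
        annotation,
        occurrences,
        min_subset=cfg.min_subset,
        require_known_match=(cfg.mode == "known"),
        matched=frozenset(matched),
    )
    return pd.DataFrame(rows), occurrences, subsets


def run_workflow(cfg: AnalysisConfig, study: SyntheticStudy | None = None):
    """Run the full analysis; returns (WorkflowReport, SyntheticStudy).

    ``study`` may be supplied (e.g. loaded from files); otherwise it is
    generated from ``cfg.synthetic``. Deterministic given cfg and seed.
    """
    if study is None:
        if cfg.synthetic is None:
            raise ValueError("need either a study or cfg.synthetic")
        study = simulate_study(cfg.synthetic, bins=cfg.bins)
    master = np.random.default_rng(cfg.seed)
    manifest: dict = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
        "n_loci": len(study.loci),
        "n_annotations": len(study.annotations),
        "pool_size": len(study.pool),
    }
    loci = study.loci
    control_sets = study.control_sets
    if cfg.exclude_mhc:
        before = len(loci)
        loci = filter_mhc(loci)
        control_sets = [filter_mhc(cs) for cs in control_sets]
        manifest["mhc_excluded_loci"] = before - len(loci)

    annotations = [
        a if a.is_normalized else a.normalize() for a in study.annotations
    ]

    # Stage 1 — annotation-level enrichment.
    seeds = master.integers(2**31, size=len(annotations))
    stage1 = _test_annotations(
        loci, annotations, study.pool, study.bins, study.genes, cfg, seeds
    )
    dual = stage1[stage1.dual_significant]
    stage2_motifs = None
    exclusions: list[tuple[str, str]] = []
    stage3 = None
    control_stage3: dict[str, pd.DataFrame] = {}
    subsets_list: list[IntervalSet] = []

    if len(dual) == 0:
        manifest["stage2"] = (
            "skipped: no annotation dual-significant in stage 1"
        )
    else:
        top_label = dual.sort_values(
            ["matched_control_p_adj", "locus_shift_p_adj"]
        ).iloc[0]["annotation"]
        manifest["stage2_annotation"] = top_label
        # use the original (named) set: normalization drops peak names
        top_ann = next(
            a for a in study.annotations if a.label == top_label
        )
        rng2 = np.random.default_rng(int(master.integers(2**31)))
        stage2_motifs, occurrences, subsets = _discover_and_subset(
            study, top_ann, cfg, rng2
        )
        exclusions = subsets.exclusions
        manifest["stage2_n_motifs"] = len(stage2_motifs)
        manifest["stage2_n_subsets"] = len(subsets.subsets)

        # Stage 3 — subset-level enrichment (noMotif included when non-empty).
        subsets_list = list(subsets.subsets.values())
        if len(subsets.no_motif):
            subsets_list.append(subsets.no_motif)
        if subsets_list:
            seeds3 = master.integers(2**31, size=len(subsets_list))
            stage3 = _test_annotations(
                loci, subsets_list, study.pool, study.bins, study.genes,
                cfg, seeds3,
            )
        else:
            manifest["stage3"] = "skipped: no subsets to test"

    # Negative-control variant sets through the identical stages.
    control_stage1: dict[str, pd.DataFrame] = {}
    for i, cs in enumerate(control_sets):
        name = f"control_{i + 1}"
        seeds_c = master.integers(2**31, size=len(annotations))
        control_stage1[name] = _test_annotations(
            cs, annotations, study.pool, study.bins, study.genes, cfg, seeds_c
        )
        if subsets_list:
            seeds_c3 = master.integers(2**31, size=len(subsets_list))
            control_stage3[name] = _test_annotations(
                cs, subsets_list, study.pool, study.bins, study.genes, cfg,
                seeds_c3,
            )

    report = WorkflowReport(
        stage1=stage1,
        stage2_motifs=stage2_motifs,
        exclusions=exclusions,
        stage3=stage3,
        control_stage1=control_stage1,
        control_stage3=control_stage3,
        manifest=manifest,
    )
    return report, study
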