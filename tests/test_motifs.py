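"""PWM exact score calibration, scanning, k-mer discovery, known-motif
matching and peak subsetting."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ocrenrich.intervals import GenomicInterval, IntervalSet
from ocrenrich.motifs import (
    BackgroundModel,
    KmerMotif,
    MotifOccurrence,
    PWM,
    RULE_NO_KNOWN_MATCH,
    RULE_NO_OCCURRENCES,
    RULE_TOO_SMALL,
    discover_enriched_kmers,
    exact_score_pvalues,
    match_to_known_motifs,
    reverse_complement,
    scan_sequences,
    subset_peaks_by_motif,
)


def random_pwm(rng, width):
    p = rng.dirichlet(np.ones(4) * 0.7, size=width) + 1e-4
    return PWM("rand", p / p.sum(axis=1, keepdims=True))


def enumerate_tail(dist, width):
    """Brute-force 4^w enumeration on the same discretized score scale."""
    imat = dist.int_matrix
    scores = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for k in range(width):
        scores = (scores[:, None] + imat[k][None, :]).ravel()
        probs = (probs[:, None] * np.full(4, 0.25)[None, :]).ravel()
    return scores, probs


class TestExactScorePvalues:
    def test_sharp_width2_max_word(self):
        # near-deterministic A then C: P(max score word) = 1/16 under
        # uniform background
        pwm = PWM.from_consensus("ac", "AC", certainty=0.997)
        dist = exact_score_pvalues(pwm, BackgroundModel.uniform())
        max_int = dist.int_matrix.max(axis=1).sum()
        assert dist.pvalue_of_int(max_int)[0] == pytest.approx(1 / 16)

    def test_uniform_pwm_degenerate(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        dist = exact_score_pvalues(pwm, BackgroundModel.uniform())
        assert dist.pvalue_of_int(0)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [2, 3, 5])
    def test_dp_equals_exhaustive_enumeration(self, width, rng):
        pwm = random_pwm(rng, width)
        bg = BackgroundModel.uniform()
        dist = exact_score_pvalues(pwm, bg)
        scores, probs = enumerate_tail(dist, width)
        for s in np.unique(scores):
            tail = probs[scores >= s].sum()
            assert dist.pvalue_of_int(s)[0] == pytest.approx(tail, abs=1e-12)

    def test_pvalues_monotone_nonincreasing(self, rng):
        dist = exact_score_pvalues(random_pwm(rng, 6), BackgroundModel.uniform())
        assert np.all(np.diff(dist.pvals) <= 1e-15)
        assert dist.pvals[0] == pytest.approx(1.0)

    def test_invalid_precision(self, rng):
        with pytest.raises(ValueError):
            exact_score_pvalues(
                random_pwm(rng, 3), BackgroundModel.uniform(), precision=0
            )


class TestScanSequences:
    @staticmethod
    def planted_sequence(rng, motif, offset, length=100, rc=False):
        seq = "".join(rng.choice(list("ACGT"), length))
        inst = reverse_complement(motif) if rc else motif
        return seq[:offset] + inst + seq[offset + len(motif):]

    def test_planted_consensus_recovered_forward(self, rng):
        pwm = PWM.from_consensus("m", "GGATTACA")
        seq = self.planted_sequence(rng, "GGATTACA", 17)
        occ = scan_sequences({"s": seq}, pwm, BackgroundModel.uniform())
        plus = [o for o in occ if o.strand == "+"]
        assert any(o.offset == 17 for o in plus)

    def test_reverse_complement_found_on_minus_strand(self, rng):
        pwm = PWM.from_consensus("m", "GGATTACA")
        seq = self.planted_sequence(rng, "GGATTACA", 17, rc=True)
        occ = scan_sequences({"s": seq}, pwm, BackgroundModel.uniform())
        assert any(o.offset == 17 and o.strand == "-" for o in occ)

    def test_all_a_sequence_no_hits(self):
        pwm = PWM.from_consensus("c", "CCCCCC")
        occ = scan_sequences({"s": "A" * 200}, pwm, BackgroundModel.uniform())
        assert occ == []

    def test_sequence_shorter_than_motif(self):
        pwm = PWM.from_consensus("m", "GGATTACA")
        assert scan_sequences({"s": "ACG"}, pwm, BackgroundModel.uniform()) == []

    def test_n_windows_skipped(self, rng):
        pwm = PWM.from_consensus("m", "GGATTACA")
        seq = self.planted_sequence(rng, "GGATTACA", 10)
        seq = seq[:12] + "N" + seq[13:]  # N inside the planted window
        occ = scan_sequences({"s": seq}, pwm, BackgroundModel.uniform())
        assert not any(o.offset == 10 for o in occ)

    def test_threshold_monotonicity(self, rng):
        pwm = random_pwm(rng, 6)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(5)
        }
        loose = scan_sequences(seqs, pwm, p_threshold=1e-2)
        tight = scan_sequences(seqs, pwm, p_threshold=1e-3)
        loose_keys = {(o.seq_id, o.offset, o.strand) for o in loose}
        tight_keys = {(o.seq_id, o.offset, o.strand) for o in tight}
        assert tight_keys <= loose_keys

    def test_matches_brute_force_scanner(self, rng):
        """Hit set equals scoring every window against the exhaustive
        4^w p-value table."""
        pwm = random_pwm(rng, 4)
        bg = BackgroundModel.uniform()
        seq = "".join(rng.choice(list("ACGT"), 400))
        thr = 5e-2
        occ = scan_sequences({"s": seq}, pwm, bg, p_threshold=thr)
        got = {(o.offset, o.strand) for o in occ}
        dist = exact_score_pvalues(pwm, bg)
        scores, probs = enumerate_tail(dist, 4)
        tail = {
            s: probs[scores >= s].sum() for s in np.unique(scores)
        }
        expected = set()
        for strand, imat in (
            ("+", dist.int_matrix),
            ("-", dist.int_matrix[::-1, ::-1]),
        ):
            for off in range(len(seq) - 4 + 1):
                window = seq[off:off + 4]
                s = sum(imat[k, "ACGT".index(b)] for k, b in enumerate(window))
                if tail[s] <= thr:
                    expected.add((off, strand))
        assert got == expected


class TestDiscoverKmers:
    def test_planted_motif_tops_ranking(self, rng):
        mk = lambda: "".join(rng.choice(list("ACGT"), 60))
        targets = [mk() for _ in range(100)]
        for i in range(50):
            targets[i] = targets[i][:20] + "CAGCTG" + targets[i][26:]
        background = [mk() for _ in range(100)]
        res = discover_enriched_kmers(targets, background, k_range=(6,))
        assert res[0].pattern in ("CAGCTG", reverse_complement("CAGCTG"))
        assert res[0].e_value < 1e-10

    def test_toy_counts_match_hypergeometric_oracle(self):
        # 5/10 targets vs 0/10 background: one-sided Fisher equals the
        # hypergeometric tail P(X >= 5) with margins (10,10;5,15)
        expected = sum(
            stats.hypergeom.pmf(k, 20, 5, 10) for k in range(5, 6)
        )
        fisher = stats.fisher_exact(
            [[5, 5], [0, 10]], alternative="greater"
        ).pvalue
        targets = ["GGATTACA" + "A" * 10] * 5 + ["C" * 18] * 5
        background = ["C" * 18] * 10
        res = discover_enriched_kmers(
            targets, background, k_range=(8,), e_threshold=1.0, max_motifs=100
        )
        top = {m.pattern: m for m in res}
        key = min("GGATTACA", reverse_complement("GGATTACA"))
        assert key in top
        assert top[key].p_fisher == pytest.approx(expected)
        assert top[key].p_fisher == pytest.approx(fisher)

    def test_no_planting_rarely_yields_motifs(self, rng):
        hits = 0
        reps = 10
        for _ in range(reps):
            seqs = [
                "".join(rng.choice(list("ACGT"), 80)) for _ in range(60)
            ]
            bg = [
                "".join(rng.choice(list("ACGT"), 80)) for _ in range(60)
            ]
            if discover_enriched_kmers(seqs, bg, k_range=(6, 7, 8)):
                hits += 1
        assert hits <= 1  # >=90% of replicates find nothing

    def test_empty_k_range_rejected(self):
        with pytest.raises(ValueError):
            discover_enriched_kmers(["ACGTAC"], ["ACGTAC"], k_range=())

    def test_hamming_neighbors_deduplicated(self):
        targets = ["TTGGATTACATT"] * 30 + ["TTGGATAACATT"] * 30
        background = ["C" * 12] * 60
        res = discover_enriched_kmers(
            targets, background, k_range=(8,), e_threshold=1.0
        )
        pats = [m.pattern for m in res]
        for i, a in enumerate(pats):
            for b in pats[i + 1:]:
                if len(a) == len(b):
                    ham = sum(x != y for x, y in zip(a, b))
                    ham_rc = sum(
                        x != y for x, y in zip(reverse_complement(a), b)
                    )
                    assert min(ham, ham_rc) > 1


class TestMatchToKnown:
    def test_self_match_is_perfect(self, rng):
        lib = [random_pwm(rng, w) for w in (6, 8, 10)]
        for i, q in enumerate(lib):
            ranked = match_to_known_motifs(q, lib)
            assert ranked[0].motif is lib[i]
            assert ranked[0].score == pytest.approx(1.0)

    def test_reverse_complement_flagged_minus(self, rng):
        lib = [random_pwm(rng, 8)]
        ranked = match_to_known_motifs(lib[0].reverse_complement(), lib)
        assert ranked[0].score == pytest.approx(1.0)
        assert ranked[0].orientation == "-"

    def test_subcolumns_recover_true_offset(self, rng):
        lib_pwm = random_pwm(rng, 8)
        query = PWM("q", lib_pwm.probs[1:7])
        ranked = match_to_known_motifs(query, [lib_pwm])
        assert ranked[0].offset == 1
        assert ranked[0].score == pytest.approx(1.0)

    def test_kmer_query_converted(self):
        lib = [PWM.from_consensus("e", "CAGCTG", certainty=0.97)]
        km = KmerMotif("CAGCTG", 5, 10, 0, 10, 1e-3, 1e-2)
        ranked = match_to_known_motifs(km, lib)
        assert ranked[0].motif.name == "e"
        assert ranked[0].score > 0.99

    def test_no_overlap_skipped_with_warning(self, rng):
        q = random_pwm(rng, 4)
        lib = [random_pwm(rng, 3)]
        with pytest.warns(UserWarning, match="skipped"):
            out = match_to_known_motifs(q, lib, min_overlap=6)
        assert out == []


def occ(seq_id, offset, width=6, motif="m"):
    return MotifOccurrence(seq_id, offset, "+", 10.0, 1e-5, width, motif)


class TestSubsetPeaks:
    peaks = IntervalSet(
        [
            GenomicInterval("chr1", 0, 100, "p1"),
            GenomicInterval("chr1", 200, 300, "p2"),
            GenomicInterval("chr1", 400, 500, "p3"),
        ],
        label="peaks",
    )

    def test_toy_partition(self):
        res = subset_peaks_by_motif(
            self.peaks,
            {"m": [occ("p1", 10), occ("p3", 50)]},
            min_subset=1,
        )
        assert {iv.name for iv in res.subsets["m"]} == {"p1", "p3"}
        assert {iv.name for iv in res.no_motif} == {"p2"}

    def test_containment_is_strict(self):
        # occurrence extends 1 base past the peak end -> not contained
        res = subset_peaks_by_motif(
            self.peaks, {"m": [occ("p1", 95, width=6)]}, min_subset=1
        )
        assert ("m", RULE_NO_OCCURRENCES) in res.exclusions

    def test_zero_occurrences_excluded(self):
        res = subset_peaks_by_motif(self.peaks, {"m": []}, min_subset=1)
        assert res.exclusions == [("m", RULE_NO_OCCURRENCES)]
        assert len(res.no_motif) == 3

    def test_min_subset_exclusion(self):
        res = subset_peaks_by_motif(
            self.peaks, {"m": [occ("p1", 10)]}, min_subset=2
        )
        assert res.exclusions == [("m", RULE_TOO_SMALL)]

    def test_known_match_requirement(self):
        res = subset_peaks_by_motif(
            self.peaks,
            {"m": [occ("p1", 10)], "k": [occ("p2", 10, motif="k")]},
            min_subset=1,
            require_known_match=True,
            matched={"k"},
        )
        assert ("m", RULE_NO_KNOWN_MATCH) in res.exclusions
        assert set(res.subsets) == {"k"}

    def test_unresolvable_seq_id_raises(self):
        with pytest.raises(KeyError, match="ghost"):
            subset_peaks_by_motif(
                self.peaks, {"m": [occ("ghost", 1)]}, min_subset=1
            )

    def test_subsets_plus_nomotif_cover_and_disjoint(self):
        res = subset_peaks_by_motif(
            self.peaks,
            {"a": [occ("p1", 1), occ("p2", 1)], "b": [occ("p2", 3)]},
            min_subset=1,
        )
        names = {iv.name for s in res.subsets.values() for iv in s}
        no = {iv.name for iv in res.no_motif}
        assert names | no == {"p1", "p2", "p3"}
        assert names & no == set()
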