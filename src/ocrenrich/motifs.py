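"""Motif models: PWM scoring with exact p-value calibration, scanning,
k-mer discovery, known-motif matching and motif-based peak subsetting.

Scores are log-odds in bits against an order-0 background. The exact score
p-value distribution is computed by dynamic programming over positions on a
discretized score scale (default step 0.01 bits); scanning uses the same
discretized per-position scores, so window p-values and the DP distribution
agree exactly.

De novo discovery is a ZOOPS (zero-or-one occurrence per sequence) Fisher
enrichment test over literal k-mers of length 6–8 with reverse-complement
collapsing — a deliberately simple discriminative discovery stage in the
spirit of short-motif discovery tools, without wildcard refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import IntervalSet

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N to 0/1/2/3/-1 (int8)."""
    table = np.full(256, -1, dtype=np.int8)
    for b, c in _CODE.items():
        table[ord(b)] = c
        table[ord(b.lower())] = c
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BackgroundModel:
    """Order-0 background: base probabilities over (A, C, G, T)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=np.float64)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("freqs must be 4 non-negative values summing to 1")
        self.freqs = f

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], pseudocount: float = 1.0
    ) -> "BackgroundModel":
        counts = np.full(4, pseudocount, dtype=np.float64)
        for s in seqs:
            enc = encode(s)
            valid = enc >= 0
            counts += np.bincount(enc[valid], minlength=4)
        return cls(counts / counts.sum())

    def symmetrized(self) -> "BackgroundModel":
        """Average complementary bases so both strands share one model."""
        f = self.freqs
        at = (f[0] + f[3]) / 2
        cg = (f[1] + f[2]) / 2
        return BackgroundModel(np.array([at, cg, cg, at]))


class PWM:
    """Position weight matrix: width × 4 base probabilities over (A,C,G,T)."""

    def __init__(self, name: str, probs, pseudocount: float = 0.0):
        p = np.asarray(probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be a width x 4 matrix")
        if not (1 <= p.shape[0] <= 30):
            raise ValueError("PWM width must lie in [1, 30]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each PWM row must sum to 1")
        if np.any(p <= 0):
            raise ValueError("all PWM entries must be > 0 (apply pseudocount)")
        self.name = name
        self.probs = p
        self.pseudocount = pseudocount

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls, name: str, counts, pseudocount: float = 0.5
    ) -> "PWM":
        c = np.asarray(counts, dtype=np.float64) + pseudocount
        return cls(name, c / c.sum(axis=1, keepdims=True), pseudocount)

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, certainty: float = 0.97
    ) -> "PWM":
        """Sharp PWM from a consensus string; N positions are uniform."""
        rows = []
        off = (1.0 - certainty) / 3.0
        for b in consensus.upper():
            if b == "N":
                rows.append([0.25] * 4)
            else:
                row = [off] * 4
                row[_CODE[b]] = certainty
                rows.append(row)
        return cls(name, np.array(rows))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1], self.pseudocount)

    def log_odds(self, bg: BackgroundModel) -> np.ndarray:
        """Per-position log2(p / bg) score matrix in bits."""
        return np.log2(self.probs / bg.freqs[None, :])


@dataclass(frozen=True)
class MotifOccurrence:
    """One scored motif match within a named sequence (peak)."""

    seq_id: str
    offset: int  # forward-strand 0-based start of the window
    strand: str  # "+" or "-"
    score: float  # log-odds in bits
    pvalue: float
    width: int
    motif: str = ""


@dataclass(frozen=True)
class KmerMotif:
    """A literal k-mer enrichment motif (ZOOPS Fisher test)."""

    pattern: str
    n_target_pos: int
    n_target: int
    n_bg_pos: int
    n_bg: int
    p_fisher: float
    e_value: float

    def __post_init__(self) -> None:
        if not (6 <= len(self.pattern) <= 8):
            raise ValueError("k-mer motifs are 6-8 bp")
        if self.n_target_pos > self.n_target or self.n_bg_pos > self.n_bg:
            raise ValueError("positives cannot exceed totals")
        if self.e_value < self.p_fisher - 1e-12:
            raise ValueError("e_value must be >= p_fisher")

    def to_pwm(self, pseudocount: float = 0.01) -> "PWM":
        """Sharp PWM: planted base 1 − 3·pseudocount, N positions uniform."""
        return PWM.from_consensus(
            self.pattern, self.pattern, certainty=1.0 - 3 * pseudocount
        )


# -- exact score distribution ---------------------------------------------


class ScoreDistribution:
    """Exact distribution of discretized PWM log-odds under the background.

    ``pvalue(score)`` returns P(score' >= score) for a window score in bits;
    monotonically non-increasing in score, and 1 at the minimum score.
    """

    def __init__(self, int_matrix, min_sum, pvals, precision):
        self.int_matrix = int_matrix  # width x 4 integer scores
        self.min_sum = min_sum
        self.pvals = pvals  # tail prob indexed by (int total − min_sum)
        self.precision = precision

    def pvalue_of_int(self, totals) -> np.ndarray:
        t = np.atleast_1d(np.asarray(totals, dtype=np.int64)) - self.min_sum
        t = np.clip(t, 0, len(self.pvals) - 1)
        return self.pvals[t]

    def pvalue(self, score_bits: float) -> float:
        return float(
            self.pvalue_of_int(int(round(score_bits / self.precision)))[0]
        )

    @property
    def scores(self) -> np.ndarray:
        """All achievable discretized scores, in bits, ascending."""
        return (np.arange(len(self.pvals)) + self.min_sum) * self.precision


def exact_score_pvalues(
    pwm: PWM, bg: BackgroundModel, precision: float = 0.01
) -> ScoreDistribution:
    """Exact p-value calibration of PWM scores by dynamic programming.

    Scores are discretized to integer multiples of ``precision`` bits; the
    distribution of the window score of a random background word is built by
    convolving per-position score distributions.
    """
    if precision <= 0:
        raise ValueError("precision must be > 0")
    lo = pwm.log_odds(bg)
    imat = np.rint(lo / precision).astype(np.int64)
    mins = imat.min(axis=1)
    maxs = imat.max(axis=1)
    min_sum = int(mins.sum())
    size = int((maxs - mins).sum()) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    hi = 1  # current support length
    for k in range(pwm.width):
        width_k = int(maxs[k] - mins[k])
        new = np.zeros(hi + width_k)
        for b in range(4):
            shift = int(imat[k, b] - mins[k])
            new[shift:shift + hi] += bg.freqs[b] * dist[:hi]
        hi += width_k
        dist[:hi] = new
        dist[hi:] = 0.0
    pvals = np.minimum(1.0, np.cumsum(dist[::-1])[::-1])
    return ScoreDistribution(imat, min_sum, pvals, precision)


# -- scanning -------------------------------------------------------------


def _window_int_scores(enc: np.ndarray, imat: np.ndarray) -> np.ndarray:
    """Discretized score of every window; invalid (N) windows get int_min."""
    w = imat.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    sums = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for k in range(w):
        col = enc[k:k + n]
        invalid = col < 0
        bad |= invalid
        sums += imat[k, np.where(invalid, 0, col)]
    sums[bad] = np.iinfo(np.int64).min
    return sums


def scan_sequences(
    seqs: Mapping[str, str] | Iterable[tuple[str, str]],
    pwm: PWM,
    bg: BackgroundModel | None = None,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    precision: float = 0.01,
) -> list[MotifOccurrence]:
    """Report every window with exact score p-value <= ``p_threshold``.

    Offsets refer to the forward-strand start of the window; windows
    containing N are skipped; sequences shorter than the motif yield no
    occurrences. When scanning both strands the background is symmetrized
    (A/T, C/G averaged) so one score distribution serves both orientations.
    """
    items = seqs.items() if isinstance(seqs, Mapping) else list(seqs)
    if bg is None:
        bg = BackgroundModel.from_sequences(s for _, s in items)
    if both_strands:
        bg = bg.symmetrized()
    dist = exact_score_pvalues(pwm, bg, precision)
    strands = [("+", dist.int_matrix)]
    if both_strands:
        # RC matrix under a symmetric background: flip positions and bases.
        strands.append(("-", dist.int_matrix[::-1, ::-1]))
    out: list[MotifOccurrence] = []
    int_min = np.iinfo(np.int64).min
    for seq_id, seq in items:
        enc = encode(seq)
        for strand, imat in strands:
            sums = _window_int_scores(enc, imat)
            if len(sums) == 0:
                continue
            pv = dist.pvalue_of_int(np.where(sums == int_min, dist.min_sum, sums))
            hits = np.flatnonzero((pv <= p_threshold) & (sums != int_min))
            for o in hits:
                out.append(
                    MotifOccurrence(
                        seq_id=seq_id,
                        offset=int(o),
                        strand=strand,
                        score=float(sums[o] * precision),
                        pvalue=float(pv[o]),
                        width=pwm.width,
                        motif=pwm.name,
                    )
                )
    out.sort(key=lambda oc: (oc.seq_id, oc.offset, oc.strand))
    return out


# -- k-mer discovery ------------------------------------------------------


def _rc_code_table(k: int) -> np.ndarray:
    """code -> code of the reverse complement, for all 4^k k-mers."""
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _zoops_counts(seqs: Sequence[str], k: int) -> np.ndarray:
    """Per-canonical-k-mer count of sequences containing it (ZOOPS)."""
    rc = _rc_code_table(k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    counts = np.zeros(4 ** k, dtype=np.int64)
    for s in seqs:
        enc = encode(s).astype(np.int64)
        if len(enc) < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = (win >= 0).all(axis=1)
        if not valid.any():
            continue
        codes = win[valid] @ powers
        canon = np.minimum(codes, rc[codes])
        counts[np.unique(canon)] += 1
    return counts


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def discover_enriched_kmers(
    targets: Sequence[str],
    background: Sequence[str],
    k_range: Iterable[int] = (6, 7, 8),
    e_threshold: float = 0.05,
    max_motifs: int = 25,
) -> list[KmerMotif]:
    """Discriminative k-mer discovery by one-sided Fisher enrichment.

    For every canonical k-mer (a pattern and its reverse complement are one
    candidate) present in the targets, the number of target vs background
    sequences containing it (ZOOPS) is tested with a one-sided Fisher exact
    test (hypergeometric tail); E-value = p × number of candidates evaluated
    across all k. Returns up to ``max_motifs`` motifs with E <= threshold,
    ranked ascending, greedily dropping any motif within Hamming distance 1
    of a better-ranked motif of equal length (either orientation).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    if len(targets) == 0 or len(background) == 0:
        raise ValueError("both sequence collections must be non-empty")
    n_t, n_b = len(targets), len(background)

    candidates: list[tuple[float, str, int, int]] = []  # (p, pattern, t, b)
    n_candidates = 0
    for k in ks:
        tc = _zoops_counts(targets, k)
        bc = _zoops_counts(background, k)
        rc = _rc_code_table(k)
        canonical = np.arange(4 ** k) <= rc  # count each pair once
        present = (tc > 0) & canonical
        n_candidates += int(present.sum())
        codes = np.flatnonzero(present)
        # One-sided Fisher exact == hypergeometric upper tail.
        pvals = stats.hypergeom.sf(
            tc[codes] - 1, n_t + n_b, tc[codes] + bc[codes], n_t
        )
        for code, p in zip(codes, pvals):
            candidates.append(
                (float(p), _decode_kmer(int(code), k), int(tc[code]),
                 int(bc[code]))
            )

    ranked = sorted(
        (
            (p * n_candidates, p, pat, t, b)
            for p, pat, t, b in candidates
        ),
        key=lambda r: (r[0], r[2]),
    )
    accepted: list[KmerMotif] = []
    for e, p, pat, t, b in ranked:
        if e > e_threshold or len(accepted) >= max_motifs:
            break
        dup = False
        for acc in accepted:
            if len(acc.pattern) != len(pat):
                continue
            if (
                _hamming(acc.pattern, pat) <= 1
                or _hamming(reverse_complement(acc.pattern), pat) <= 1
            ):
                dup = True
                break
        if dup:
            continue
        accepted.append(
            KmerMotif(
                pattern=pat,
                n_target_pos=t,
                n_target=n_t,
                n_bg_pos=b,
                n_bg=n_b,
                p_fisher=p,
                e_value=min(1.0, e) if e <= 1.0 else e,
            )
        )
    return accepted


# -- known-motif matching -------------------------------------------------


@dataclass(frozen=True)
class MotifMatch:
    motif: PWM
    score: float  # mean per-column Pearson correlation, best alignment
    orientation: str  # "+" or "-"
    offset: int  # query start relative to library motif start


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a - a.mean(), b - b.mean()
    na, nb = np.sqrt((va ** 2).sum()), np.sqrt((vb ** 2).sum())
    if na < 1e-12 or nb < 1e-12:
        return 1.0 if np.allclose(a, b) else 0.0
    return float((va @ vb) / (na * nb))


def match_to_known_motifs(
    query: "PWM | KmerMotif",
    library: Sequence[PWM],
    min_overlap: int = 4,
) -> list[MotifMatch]:
    """Rank library motifs by ungapped alignment similarity to the query.

    For every library motif, the best offset over both orientations is
    scored as the mean per-column Pearson correlation of the probability
    columns over the overlap (minimum ``min_overlap`` columns). Library
    motifs with no valid overlap are skipped with a warning.
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    q = query.to_pwm() if isinstance(query, KmerMotif) else query
    out: list[MotifMatch] = []
    for lib in library:
        best: MotifMatch | None = None
        for orient, qp in (("+", q.probs), ("-", q.reverse_complement().probs)):
            wq, wl = len(qp), lib.width
            for off in range(-(wq - min_overlap), wl - min_overlap + 1):
                lo = max(0, off)
                hi = min(wl, off + wq)
                if hi - lo < min_overlap:
                    continue
                cols = [
                    _column_corr(qp[i - off], lib.probs[i])
                    for i in range(lo, hi)
                ]
                score = float(np.mean(cols))
                if best is None or score > best.score:
                    best = MotifMatch(lib, score, orient, off)
        if best is None:
            warnings.warn(
                f"no >= {min_overlap}-column overlap between query and "
                f"{lib.name}; skipped",
                stacklevel=2,
            )
            continue
        out.append(best)
    out.sort(key=lambda m: (-m.score, m.motif.name))
    return out


# -- peak subsetting ------------------------------------------------------


@dataclass
class PeakSubsets:
    subsets: dict[str, IntervalSet]
    no_motif: IntervalSet
    exclusions: list[tuple[str, str]]  # (motif name, rule)


RULE_NO_OCCURRENCES = "no significant motif occurrences"
RULE_NO_KNOWN_MATCH = "no known motif match"
RULE_TOO_SMALL = "subset smaller than min_subset"


def subset_peaks_by_motif(
    peaks: IntervalSet,
    occurrences: Mapping[str, Sequence[MotifOccurrence]],
    min_subset: int = 1000,
    require_known_match: bool = False,
    matched: frozenset | set = frozenset(),
) -> PeakSubsets:
    """Partition peaks into per-motif subsets plus a noMotif complement.

    A peak belongs to a motif's subset when it contains at least one
    occurrence *fully inside* the peak (occurrence offsets are peak-relative;
    full containment = offset >= 0 and offset + width <= peak length).
    Motifs are excluded — and logged with their rule — when they lack a
    known-motif match (if required), have no occurrences, or their subset is
    smaller than ``min_subset``. noMotif = peaks in no included subset.
    """
    peak_by_name: dict[str, "GenomicInterval"] = {}
    for iv in peaks:
        if iv.name is not None:
            peak_by_name[iv.name] = iv

    subsets: dict[str, IntervalSet] = {}
    exclusions: list[tuple[str, str]] = []
    covered: set[str] = set()
    for motif, occs in occurrences.items():
        if require_known_match and motif not in matched:
            exclusions.append((motif, RULE_NO_KNOWN_MATCH))
            continue
        members: set[str] = set()
        for occ in occs:
            iv = peak_by_name.get(occ.seq_id)
            if iv is None:
                raise KeyError(
                    f"occurrence seq_id {occ.seq_id!r} does not resolve to a "
                    "peak"
                )
            if occ.offset >= 0 and occ.offset + occ.width <= len(iv):
                members.add(occ.seq_id)
        if not members:
            exclusions.append((motif, RULE_NO_OCCURRENCES))
            continue
        if len(members) < min_subset:
            exclusions.append((motif, RULE_TOO_SMALL))
            continue
        subsets[motif] = IntervalSet(
            [peak_by_name[n] for n in sorted(members)],
            label=f"{motif}-subset",
        )
        covered |= members
    no_motif = IntervalSet(
        [iv for iv in peaks if iv.name not in covered],
        label="noMotif",
    )
    return PeakSubsets(subsets=subsets, no_motif=no_motif,
                       exclusions=exclusions)


def occurrences_to_bed(
    occurrences: Sequence[MotifOccurrence],
    path,
    peaks: IntervalSet | None = None,
) -> None:
    """Write occurrences as BED6 (score column = log-odds bits).

    Peak-relative by default; genome-relative when ``peaks`` provides the
    peak coordinates.
    """
    origin = {}
    if peaks is not None:
        origin = {iv.name: (iv.chrom, iv.start) for iv in peaks if iv.name}
    with open(path, "w") as fh:
        for occ in occurrences:
            if peaks is not None:
                chrom, base = origin[occ.seq_id]
            else:
                chrom, base = occ.seq_id, 0
            fh.write(
                f"{chrom}\t{base + occ.offset}\t{base + occ.offset + occ.width}"
                f"\t{occ.motif or occ.seq_id}\t{occ.score:.3f}\t{occ.strand}\n"
            )
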