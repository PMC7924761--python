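"""PWM scanning with exact score p-values.

The scanner mirrors common motif-search practice: each position weight
matrix is scored as a log-odds (bits) against a 0-order background, and the
p-value of a score is the exact tail probability of that score for a single
width-w alignment of background bases. The exact null is computed by
dynamic programming: log-odds entries are rounded to an integer grid of
resolution ``epsilon`` bits and the score pmf is built by column-wise
convolution; tail probabilities follow by suffix summation.

Best-hit semantics: the strongest match per region on either strand, with
its per-alignment p-value (no correction for region length) — regions are
then compared class-wise (opened / closed / unchanged) by ECDF,
two-sample KS, and Fisher exact counts at a well-matched threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PWM:
    """Position probability matrix with background model and pseudocount."""

    motif_id: str
    probs: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a width x 4 matrix with width >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("every PWM column must sum to 1 +/- 1e-6")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1 +/- 1e-6")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def log_odds(self) -> np.ndarray:
        """Pseudocounted log2 odds matrix, width x 4, in bits."""
        p = (self.probs + self.pseudocount * self.background[None, :]) / (
            1.0 + self.pseudocount
        )
        return np.log2(p / self.background[None, :])

    @property
    def consensus(self) -> str:
        """Column-wise argmax base; ties broken alphabetically."""
        return "".join(BASES[int(np.argmax(col))] for col in self.probs)

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass
class ScoreDistribution:
    """Exact null pmf of the log-odds score on an integer grid.

    ``grid_scores[i] * epsilon`` is the score in bits; ``tail[i]`` is
    P(score >= grid_scores[i]) for one width-w alignment of i.i.d.
    background bases.
    """

    motif_id: str
    epsilon: float
    grid_scores: np.ndarray  # ascending integers
    pmf: np.ndarray
    tail: np.ndarray
    int_log_odds: np.ndarray  # width x 4 integer grid matrix

    def pvalue(self, int_score: int) -> float:
        """Tail probability P(score >= int_score) on the integer grid."""
        idx = np.searchsorted(self.grid_scores, int_score, side="left")
        if idx >= len(self.tail):
            return float(self.pmf[-1]) if int_score <= self.grid_scores[-1] else 0.0
        return float(self.tail[idx])


def score_distribution(pwm: PWM, epsilon: float = 0.01) -> ScoreDistribution:
    """Exact score null by column-wise convolution on an integer grid."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    lo = pwm.log_odds()
    int_lo = np.rint(lo / epsilon).astype(np.int64)  # width x 4
    offset = int(int_lo.min(axis=1).sum())
    span = int((int_lo.max(axis=1) - int_lo.min(axis=1)).sum())
    pmf = np.zeros(span + 1)
    pmf[0] = 1.0
    pos = 0  # running minimum already absorbed in offset
    bg = pwm.background
    for k in range(pwm.width):
        col = int_lo[k] - int_lo[k].min()
        width_k = int(col.max())
        new = np.zeros(pos + width_k + 1)
        for b in range(4):
            new[col[b]: col[b] + pos + 1] += bg[b] * pmf[: pos + 1]
        pmf = new
        pos += width_k
    grid_scores = np.arange(span + 1, dtype=np.int64) + offset
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)  # guard fp drift
    return ScoreDistribution(
        motif_id=pwm.motif_id, epsilon=epsilon, grid_scores=grid_scores,
        pmf=pmf, tail=tail, int_log_odds=int_lo,
    )


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to base indices; non-ACGT -> -1 (ambiguous)."""
    seq = sequence.upper()
    out = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(sequence.upper()))


@dataclass
class MotifHitBest:
    """Best (lowest p-value) motif match in one region."""

    region_id: str
    score_bits: float
    pvalue: float
    position: int
    strand: str
    class_label: str | None = None
    n_ambiguous: int = 0
    undefined: bool = False  # sequence shorter than motif width


def _best_score_one_strand(codes: np.ndarray, int_lo: np.ndarray) -> tuple[int, int]:
    """(best integer score, leftmost position) over all alignments.

    Ambiguous bases contribute 0 to the score.
    """
    w = int_lo.shape[0]
    n = len(codes) - w + 1
    # per-position contributions: lookup with ambiguity -> 0
    contrib = np.zeros((len(codes), w), dtype=np.int64)
    for k in range(w):
        valid = codes >= 0
        contrib[valid, k] = int_lo[k][codes[valid]]
    scores = np.zeros(n, dtype=np.int64)
    for k in range(w):
        scores += contrib[k: k + n, k]
    best_pos = int(np.argmax(scores))  # argmax returns leftmost max
    return int(scores[best_pos]), best_pos


def scan_best_hit(
    sequence: str,
    pwm: PWM,
    dist: ScoreDistribution | None = None,
    region_id: str = "",
    class_label: str | None = None,
    length_correct: bool = False,
) -> MotifHitBest:
    """Strongest match to the motif on either strand of one sequence.

    Ties go to the smallest position, then the + strand. A sequence shorter
    than the motif yields p = 1, flagged undefined. Sequences with more
    than 50% ambiguous bases are an error.

    ``length_correct=True`` converts the per-alignment p to a per-region
    p, 1 - (1-p)^(2(L-w+1)); off by default since class comparisons use
    per-alignment best-hit minima on sets of comparable length.
    """
    if dist is None:
        dist = score_distribution(pwm)
    w = pwm.width
    codes = _encode(sequence)
    n_ambig = int((codes < 0).sum())
    if len(sequence) > 0 and n_ambig / len(sequence) > 0.5:
        raise ValueError(f"region {region_id!r}: >50% ambiguous bases")
    if len(sequence) < w:
        return MotifHitBest(region_id, float("-inf"), 1.0, 0, "+",
                            class_label, n_ambig, undefined=True)

    fwd_score, fwd_pos = _best_score_one_strand(codes, dist.int_log_odds)
    rc_codes = _encode(reverse_complement(sequence))
    rev_score, rev_pos_rc = _best_score_one_strand(rc_codes, dist.int_log_odds)
    # position of the reverse-strand hit on the forward sequence
    rev_pos = len(sequence) - w - rev_pos_rc

    if fwd_score > rev_score:
        score, pos, strand = fwd_score, fwd_pos, "+"
    elif rev_score > fwd_score:
        score, pos, strand = rev_score, rev_pos, "-"
    else:  # tie: smallest position, then + strand
        if fwd_pos <= rev_pos:
            score, pos, strand = fwd_score, fwd_pos, "+"
        else:
            score, pos, strand = rev_score, rev_pos, "-"
    pvalue = dist.pvalue(score)
    if length_correct:
        n_alignments = 2 * (len(sequence) - w + 1)
        pvalue = float(-np.expm1(n_alignments * np.log1p(-min(pvalue, 1.0 - 1e-16))))
    return MotifHitBest(
        region_id=region_id,
        score_bits=score * dist.epsilon,
        pvalue=pvalue,
        position=pos,
        strand=strand,
        class_label=class_label,
        n_ambiguous=n_ambig,
    )


def scan_fasta(records: list[tuple[str, str]], pwm: PWM,
               epsilon: float = 0.01) -> list[MotifHitBest]:
    """Best hit per (header, sequence) record; ``class=`` keys in headers
    become class labels."""
    dist = score_distribution(pwm, epsilon)
    hits = []
    for header, seq in records:
        toks = header.split()
        region_id = toks[0]
        label = None
        for tok in toks[1:]:
            if tok.startswith("class="):
                label = tok.split("=", 1)[1]
        hits.append(scan_best_hit(seq, pwm, dist, region_id, label))
    return hits


@dataclass
class ClassComparison:
    """Class-wise comparison of best-hit motif strength."""

    ecdf: dict[str, pd.DataFrame]  # class -> columns (neglog10_p, cumfreq)
    ks: pd.DataFrame  # class_a, class_b, ks_d, ks_p
    counts: pd.DataFrame  # class, n, n_below_threshold
    fisher: pd.DataFrame  # class_a, class_b, odds_ratio, fisher_p
    threshold: float


def class_comparison(hits: list[MotifHitBest],
                     threshold: float = 1e-3) -> ClassComparison:
    """ECDFs of -log10 best p per class, pairwise KS, and Fisher exact
    counts of well-matched motifs (best p < threshold)."""
    by_class: dict[str, np.ndarray] = {}
    for h in hits:
        label = h.class_label if h.class_label is not None else "unlabeled"
        by_class.setdefault(label, [])
        by_class[label].append(h.pvalue)
    if len(by_class) < 2:
        raise ValueError("class comparison needs >= 2 classes")
    for label, ps in by_class.items():
        if len(ps) == 0:
            raise ValueError(f"class {label!r} is empty")
        by_class[label] = np.asarray(ps)

    ecdf = {}
    for label, ps in by_class.items():
        x = np.sort(-np.log10(np.maximum(ps, 1e-300)))
        ecdf[label] = pd.DataFrame(
            {"neglog10_p": x, "cumfreq": np.arange(1, len(x) + 1) / len(x)}
        )

    labels = sorted(by_class)
    ks_rows, fisher_rows = [], []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ks = stats.ks_2samp(by_class[a], by_class[b])
            ks_rows.append({"class_a": a, "class_b": b,
                            "ks_d": ks.statistic, "ks_p": ks.pvalue})
            ka = int((by_class[a] < threshold).sum())
            kb = int((by_class[b] < threshold).sum())
            na, nb = len(by_class[a]), len(by_class[b])
            odds, fp = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])
            fisher_rows.append({"class_a": a, "class_b": b,
                                "odds_ratio": odds, "fisher_p": fp})
    counts = pd.DataFrame(
        [{"class": c, "n": len(by_class[c]),
          "n_below_threshold": int((by_class[c] < threshold).sum())}
         for c in labels]
    )
    return ClassComparison(
        ecdf=ecdf, ks=pd.DataFrame(ks_rows), counts=counts,
        fisher=pd.DataFrame(fisher_rows), threshold=threshold,
    )
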