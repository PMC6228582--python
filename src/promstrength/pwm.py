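"""Position weight matrices for sigma70 promoter hexamers.

This module builds nucleotide count matrices from aligned 6-mers,
converts them to log-odds weight matrices against a GC-content-derived
background with a pseudocount prior, scores hexamers additively, and
computes *exact* score p-values.  The p-value of a score threshold ``t``
is the probability that a hexamer drawn i.i.d. from the background model
scores at least ``t``.  Because a 6-position motif has at most
``4**6 = 4096`` distinct score sums, the null score distribution is
obtained by exact position-wise convolution rather than by sampling or
by a coarse score grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: motif width of the -35 and -10 promoter elements
MOTIF_LENGTH = 6

#: E. coli genomic GC content used for the default background
ECOLI_GC = 0.508

# distinct exact sums of six weights are merged at this resolution when
# convolving the null score distribution (absorbs float addition noise only)
_SCORE_RESOLUTION = 1e-9

# scores this close to a threshold count as meeting it (covers the
# accumulated merge rounding; far below any meaningful weight difference)
_TAIL_SLACK = 1e-6


def clean_sequence(seq: str, length: int | None = MOTIF_LENGTH, label: str | None = None) -> str:
    """Uppercase and validate a DNA string over {A,C,G,T}.

    ``length`` fixes the required length (``None`` disables the check);
    ``label`` identifies the offending record in error messages.
    RNA (U) and IUPAC ambiguity codes are rejected.
    """
    tag = f" in {label}" if label else ""
    s = str(seq).strip().upper()
    if length is not None and len(s) != length:
        raise ValueError(f"expected a {length}-nt sequence{tag}, got {s!r} (length {len(s)})")
    for pos, ch in enumerate(s):
        if ch not in BASE_INDEX:
            raise ValueError(f"invalid character {ch!r} at position {pos}{tag}: {s!r}")
    return s


@dataclass(frozen=True)
class NucleotideBackground:
    """Zeroth-order background model: one probability per base (A, C, G, T)."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr <= 0):
            raise ValueError(f"background frequencies must be positive, got {arr}")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"background frequencies must sum to 1, got {arr.sum()!r}")

    @classmethod
    def from_gc(cls, gc: float = ECOLI_GC) -> "NucleotideBackground":
        """Background with G = C = gc/2 and A = T = (1 - gc)/2."""
        if not 0 < gc < 1:
            raise ValueError("gc must be in (0, 1)")
        at = (1.0 - gc) / 2.0
        return cls(freq_A=at, freq_C=gc / 2.0, freq_G=gc / 2.0, freq_T=at)

    @classmethod
    def uniform(cls) -> "NucleotideBackground":
        return cls(0.25, 0.25, 0.25, 0.25)

    def as_array(self) -> np.ndarray:
        return np.array([self.freq_A, self.freq_C, self.freq_G, self.freq_T])

    def __getitem__(self, base: str) -> float:
        return float(self.as_array()[BASE_INDEX[base.upper()]])


@dataclass
class CountMatrix:
    """Per-position nucleotide counts over a set of aligned hexamers.

    ``counts[i, b]`` is the number of sequences with base ``BASES[b]`` at
    position ``i``; every row sums to ``n_sequences``.
    """

    counts: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"counts must be (positions, 4), got shape {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        row_sums = self.counts.sum(axis=1)
        if not np.allclose(row_sums, self.n_sequences, atol=1e-9):
            raise ValueError(
                f"every position must have {self.n_sequences} counts, got row sums {row_sums}"
            )

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def build_count_matrix(hexamers: Iterable[str], length: int = MOTIF_LENGTH) -> CountMatrix:
    """Tally per-position base counts over aligned fixed-length sequences."""
    counts = np.zeros((length, 4))
    n = 0
    for i, seq in enumerate(hexamers):
        s = clean_sequence(seq, length=length, label=f"record {i}")
        for pos, ch in enumerate(s):
            counts[pos, BASE_INDEX[ch]] += 1
        n += 1
    if n == 0:
        raise ValueError("no sequences")
    return CountMatrix(counts=counts, n_sequences=n)


@dataclass
class ScoreDistribution:
    """Exact distribution of PWM scores under a background model.

    ``support`` is sorted ascending; ``probabilities`` are the matching
    point masses and sum to 1.
    """

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.support.shape != self.probabilities.shape:
            raise ValueError("support and probabilities must align")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def pvalue(self, threshold: float) -> float:
        """P[score >= threshold] under the background model."""
        if not math.isfinite(threshold):
            if threshold == -math.inf:
                return 1.0
            raise ValueError("threshold must be finite")
        if threshold <= self.support[0] + _TAIL_SLACK:
            return 1.0
        mask = self.support >= threshold - _TAIL_SLACK
        return float(min(1.0, self.probabilities[mask].sum()))


@dataclass
class Match:
    """Best PWM hit within a scanned region."""

    hexamer: str
    offset: int
    score: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


@dataclass
class PWM:
    """Log-odds position weight matrix.

    ``weights[i, b]`` is ``log(p_ib / q_b)`` in base ``log_base``, where
    ``p_ib`` is the pseudocounted frequency of base ``b`` at position
    ``i`` and ``q_b`` the background frequency.  A hexamer's score is the
    sum of its per-position weights.
    """

    weights: np.ndarray
    background: NucleotideBackground
    pseudocount_total: float
    log_base: float = 2.0
    _dist: ScoreDistribution | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError(f"weights must be (positions, 4), got shape {self.weights.shape}")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def score(self, hexamer: str) -> float:
        s = clean_sequence(hexamer, length=self.length)
        return float(sum(self.weights[i, BASE_INDEX[ch]] for i, ch in enumerate(s)))

    def probabilities(self) -> np.ndarray:
        """Invert the log-odds transform back to a row-stochastic matrix."""
        q = self.background.as_array()
        return (self.log_base ** self.weights) * q[None, :]

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.weights.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    def score_distribution(self) -> ScoreDistribution:
        """Null score distribution under this PWM's own background (cached)."""
        if self._dist is None:
            self._dist = score_distribution(self)
        return self._dist

    def pvalue(self, score: float) -> float:
        return self.score_distribution().pvalue(score)

    def to_dict(self) -> dict:
        return {
            "background": dict(zip("ACGT", self.background.as_array().tolist())),
            "pseudocount_total": self.pseudocount_total,
            "log_base": self.log_base,
            "base_order": BASES,
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PWM":
        bg = d["background"]
        return cls(
            weights=np.array(d["weights"], dtype=float),
            background=NucleotideBackground(bg["A"], bg["C"], bg["G"], bg["T"]),
            pseudocount_total=float(d["pseudocount_total"]),
            log_base=float(d["log_base"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PWM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def to_log_odds(
    counts: CountMatrix,
    background: NucleotideBackground | None = None,
    pseudocount_total: float = 1.0,
    log_base: float = 2.0,
) -> PWM:
    """Convert a count matrix to a log-odds PWM.

    The pseudocount mass is apportioned to the four bases proportionally
    to the background, so a position whose observed frequencies equal the
    background gets weight exactly 0 for every base:

        w[i, b] = log((c[i, b] + pc * q_b) / (n + pc) / q_b)
    """
    if pseudocount_total <= 0:
        raise ValueError("pseudocount_total must be positive (zero counts give -inf weights)")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    bg = background if background is not None else NucleotideBackground.from_gc()
    q = bg.as_array()
    freqs = (counts.counts + pseudocount_total * q[None, :]) / (
        counts.n_sequences + pseudocount_total
    )
    weights = np.log(freqs / q[None, :]) / np.log(log_base)
    return PWM(
        weights=weights,
        background=bg,
        pseudocount_total=pseudocount_total,
        log_base=log_base,
    )


def score_hexamer(pwm: PWM, hexamer: str) -> float:
    """Additive PWM score of a single hexamer (sum of per-position weights)."""
    return pwm.score(hexamer)


def score_distribution(pwm: PWM, background: NucleotideBackground | None = None) -> ScoreDistribution:
    """Exact null distribution of PWM scores by position-wise convolution.

    Positions are independent under the background model, so the
    distribution of the score sum is the convolution of six 4-point
    distributions.  Equal sums are merged, keeping the support at most
    ``4**length`` values.
    """
    bg = background if background is not None else pwm.background
    q = bg.as_array()
    support = np.zeros(1)
    probs = np.ones(1)
    for i in range(pwm.length):
        sums = support[:, None] + pwm.weights[i][None, :]
        mass = probs[:, None] * q[None, :]
        keys = np.round(sums / _SCORE_RESOLUTION).astype(np.int64)
        uniq, inverse = np.unique(keys.ravel(), return_inverse=True)
        probs = np.bincount(inverse, weights=mass.ravel())
        support = uniq * _SCORE_RESOLUTION
    return ScoreDistribution(support=support, probabilities=probs / probs.sum())


def exact_score_pvalue(
    pwm: PWM, threshold: float, background: NucleotideBackground | None = None
) -> float:
    """P[score(X) >= threshold] for X drawn i.i.d. from the background.

    Non-increasing in ``threshold``; equals 1 at or below the minimum
    achievable score.
    """
    if background is None or background == pwm.background:
        return pwm.score_distribution().pvalue(threshold)
    return score_distribution(pwm, background).pvalue(threshold)


def information_content(
    counts: CountMatrix,
    background: NucleotideBackground | None = None,
    pseudocount_total: float = 0.0,
) -> np.ndarray:
    """Per-position relative entropy (bits) of observed frequencies vs background.

    This is the column height data of a sequence logo.  For a uniform
    background each value lies in [0, 2] bits.  No pseudocount is applied
    by default so that a perfectly conserved column reports the full
    2 bits; pass ``pseudocount_total > 0`` to regularize sparse counts.
    """
    if counts.n_sequences <= 0:
        raise ValueError("count matrix is empty")
    bg = background if background is not None else NucleotideBackground.from_gc()
    q = bg.as_array()
    freqs = (counts.counts + pseudocount_total * q[None, :]) / (
        counts.n_sequences + pseudocount_total
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs / q[None, :]), 0.0)
    return terms.sum(axis=1)


def read_hexamers(path: str | Path, length: int | None = MOTIF_LENGTH) -> list[str]:
    """Read sequences from FASTA (one record each) or plain/TSV text.

    In text mode the first whitespace-separated DNA-looking field of each
    non-empty, non-comment line is taken.
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip()[:1]
    seqs: list[str] = []
    if first == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs.append(clean_sequence(str(rec.seq), length=length, label=rec.id))
        if not seqs:
            raise ValueError("no sequences")
        return seqs
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for fld in line.split():
            if set(fld.upper()) <= set(BASES):
                seqs.append(clean_sequence(fld, length=length, label=f"line {lineno}"))
                break
        else:
            raise ValueError(f"no DNA field on line {lineno}: {line!r}")
    if not seqs:
        raise ValueError("no sequences")
    return seqs
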