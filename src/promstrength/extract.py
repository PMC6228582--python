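"""Best-match extraction of -35/-10 hexamers from 13-nt promoter regions.

Promoter element positions are uncertain by a few bases, so each element
is given as a 13-nt window centred on its nominal position.  A matcher
(a log-odds :class:`~promstrength.pwm.PWM`, or a consensus-string
matcher for the very first pass before any PWM exists) scores every
6-nt window and the best-scoring window is reported together with its
exact background p-value.  Regions whose best hit is not significant are
dropped, yielding the hexamer set from which final PWMs are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pwm import (
    BASES,
    BASE_INDEX,
    MOTIF_LENGTH,
    Match,
    NucleotideBackground,
    PWM,
    ScoreDistribution,
    clean_sequence,
    score_distribution,
)

#: canonical sigma70 consensus hexamers
CONSENSUS_MINUS35 = "TTGACA"
CONSENSUS_MINUS10 = "TATAAT"

REGION_LENGTH = 13

ROLES = ("minus35", "minus10")


@dataclass
class PromoterRegion:
    """A strand-resolved window around a -35 or -10 promoter element."""

    sequence: str
    role: str = "minus35"
    source_id: str = ""
    relaxed: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        length = None if self.relaxed else REGION_LENGTH
        self.sequence = clean_sequence(
            self.sequence, length=length, label=self.source_id or "region"
        )
        if len(self.sequence) < MOTIF_LENGTH:
            raise ValueError(
                f"region {self.source_id or self.sequence!r} shorter than {MOTIF_LENGTH} nt"
            )


class ConsensusMatcher:
    """Mismatch-count scorer against a consensus hexamer.

    Scores ``-(number of mismatches)``: 0 for an exact consensus match,
    -6 for a hexamer differing everywhere.  Used to bootstrap extraction
    before any PWM exists.  Exposes the same ``score``/``pvalue``
    interface as :class:`~promstrength.pwm.PWM`.
    """

    def __init__(
        self, consensus: str, background: NucleotideBackground | None = None
    ) -> None:
        self.consensus = clean_sequence(consensus, length=None)
        self.background = background if background is not None else NucleotideBackground.from_gc()
        self._dist: ScoreDistribution | None = None

    @property
    def length(self) -> int:
        return len(self.consensus)

    def score(self, hexamer: str) -> float:
        s = clean_sequence(hexamer, length=self.length)
        return -float(sum(a != b for a, b in zip(s, self.consensus)))

    def score_distribution(self) -> ScoreDistribution:
        # exact convolution of per-position {0, -1} match indicators
        if self._dist is None:
            probs = np.ones(1)
            for ch in self.consensus:
                p_match = self.background[ch]
                # index k holds P[k mismatches so far]
                nxt = np.zeros(len(probs) + 1)
                nxt[: len(probs)] += probs * p_match
                nxt[1:] += probs * (1.0 - p_match)
                probs = nxt
            support = -np.arange(len(probs))[::-1].astype(float)
            self._dist = ScoreDistribution(support=support, probabilities=probs[::-1])
        return self._dist

    def pvalue(self, score: float) -> float:
        return self.score_distribution().pvalue(score)


def best_match_in_region(matcher: PWM | ConsensusMatcher, region: PromoterRegion | str) -> Match:
    """Maximum-scoring window of the region; ties go to the smallest offset."""
    seq = region.sequence if isinstance(region, PromoterRegion) else clean_sequence(region, length=None)
    width = matcher.length
    if len(seq) < width:
        raise ValueError(f"region of length {len(seq)} is shorter than the motif ({width})")
    scores = [matcher.score(seq[off : off + width]) for off in range(len(seq) - width + 1)]
    offset = int(np.argmax(scores))  # argmax returns the first maximum
    best = float(scores[offset])
    return Match(
        hexamer=seq[offset : offset + width],
        offset=offset,
        score=best,
        p_value=matcher.pvalue(best),
    )


@dataclass
class ExtractionResult:
    """Significant best-match hexamers plus a per-region audit table."""

    hexamers: list[str]
    table: pd.DataFrame  # columns: source_id, hexamer, offset, score, p_value, kept
    n_input: int
    n_kept: int

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def extract_significant_hexamers(
    regions: Sequence[PromoterRegion | str],
    matcher: PWM | ConsensusMatcher,
    alpha: float = 0.05,
) -> ExtractionResult:
    """Best match per region, retained iff its p-value < ``alpha``.

    Output order follows input order.  The audit table records every
    region's best hit and whether it was kept.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    rows = []
    kept: list[str] = []
    for i, region in enumerate(regions):
        m = best_match_in_region(matcher, region)
        keep = m.p_value < alpha
        sid = region.source_id if isinstance(region, PromoterRegion) else f"region_{i}"
        rows.append((sid or f"region_{i}", m.hexamer, m.offset, m.score, m.p_value, keep))
        if keep:
            kept.append(m.hexamer)
    table = pd.DataFrame(
        rows, columns=["source_id", "hexamer", "offset", "score", "p_value", "kept"]
    )
    return ExtractionResult(hexamers=kept, table=table, n_input=len(rows), n_kept=len(kept))


def read_regions(
    path: str | Path, role: str = "minus35", relaxed: bool = False
) -> list[PromoterRegion]:
    """Read promoter regions from FASTA or a TSV with header
    ``source_id<TAB>sequence[<TAB>role]``."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip()[:1] == ">":
        return [
            PromoterRegion(sequence=str(r.seq), role=role, source_id=r.id, relaxed=relaxed)
            for r in SeqIO.parse(str(path), "fasta")
        ]
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ValueError("TSV must have a 'sequence' column (plus optional source_id, role)")
    out = []
    for _, row in df.iterrows():
        out.append(
            PromoterRegion(
                sequence=row["sequence"],
                role=row.get("role", role) if "role" in df.columns else role,
                source_id=str(row["source_id"]) if "source_id" in df.columns else "",
                relaxed=relaxed,
            )
        )
    return out
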