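"""Embedded training data and synthetic sequence generators.

The training set is the 18-member Anderson library of constitutive *tet*
promoter variants with strengths normalized to the strongest member,
together with the published -35/-10 PWM feature scores of each promoter.
The printed scores are shipped verbatim ("fixture scores") because the
exact PWM parameterization that produced them (log base, pseudocount
magnitude) is not recoverable; regression-facing results therefore use
these scores directly, while PWM construction is exercised on synthetic
hexamer sets drawn from realistic sigma70 conservation profiles.

Known data inconsistency: the published prediction for BBa_J23110
(-3.3947) is not reproducible from its own printed feature scores
(4.3854, 5.462 give -1.7428 under the published model); its printed -35
score coincides with TTTACG's score although its -35 hexamer is TTTAGG.
The scores are kept verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pwm import BASES, BASE_INDEX, MOTIF_LENGTH
from .regression import PromoterRecord, feature_table, log_strength

# id, -35 hexamer, -10 hexamer, normalized strength, s35, s10
_ANDERSON = (
    ("BBa_J23100", "TTGACG", "TACAGT", 1.00, 6.5966, 2.398),
    ("BBa_J23101", "TTTACA", "TATTAT", 0.70, 6.9195, 8.089),
    ("BBa_J23102", "TTGACA", "TACTGT", 0.86, 9.1308, 0.402),
    ("BBa_J23104", "TTGACA", "TATTGT", 0.72, 9.1308, 5.025),
    ("BBa_J23105", "TTTACG", "TACTAT", 0.24, 4.3854, 3.465),
    ("BBa_J23106", "TTTACG", "TATAGT", 0.47, 4.3854, 7.022),
    ("BBa_J23107", "TTTACG", "TATTAT", 0.36, 4.3854, 8.089),
    ("BBa_J23108", "CTGACA", "TATAAT", 0.51, 4.5119, 10.086),
    ("BBa_J23109", "TTTACA", "GACTGT", 0.04, 6.9195, -4.474),
    ("BBa_J23110", "TTTAGG", "TACAAT", 0.33, 4.3854, 5.462),
    ("BBa_J23111", "TTGACG", "TATAGT", 0.58, 6.5966, 7.022),
    ("BBa_J23112", "CTGATA", "GATTAT", 0.01, 2.5179, 3.213),
    ("BBa_J23113", "CTGATG", "GATTAT", 0.01, -0.0162, 3.213),
    ("BBa_J23114", "TTTATG", "TACAAT", 0.10, 2.3914, 5.462),
    ("BBa_J23115", "TTTATA", "TACAAT", 0.15, 4.9255, 5.462),
    ("BBa_J23116", "TTGACA", "GACTAT", 0.16, 9.1308, -1.411),
    ("BBa_J23117", "TTGACA", "GATTGT", 0.06, 9.1308, 0.15),
    ("BBa_J23118", "TTGACG", "TATTGT", 0.56, 6.5966, 5.025),
)


@dataclass
class TrainingFixture:
    """The embedded training library: records plus published feature scores."""

    records: list[PromoterRecord]
    scores: pd.DataFrame  # id, s35, s10

    def feature_table(self) -> pd.DataFrame:
        """Regression table using the published scores and y = ln(strength)."""
        y = [log_strength(r.strength) for r in self.records]
        return feature_table(
            [r.id for r in self.records], self.scores["s35"], self.scores["s10"], y
        )

    def strengths(self) -> np.ndarray:
        return np.array([r.strength for r in self.records])

    def score_lookup(self) -> tuple[dict[str, float], dict[str, float]]:
        """Hexamer -> published score maps for the -35 and -10 elements."""
        s35 = {r.hex35: float(s) for r, s in zip(self.records, self.scores["s35"])}
        s10 = {r.hex10: float(s) for r, s in zip(self.records, self.scores["s10"])}
        return s35, s10


def anderson_fixture() -> TrainingFixture:
    """The 18 Anderson library promoters with their published PWM scores."""
    records = [PromoterRecord(i, h35, h10, s) for i, h35, h10, s, _, _ in _ANDERSON]
    scores = pd.DataFrame(
        {
            "id": [row[0] for row in _ANDERSON],
            "s35": [row[4] for row in _ANDERSON],
            "s10": [row[5] for row in _ANDERSON],
        }
    )
    return TrainingFixture(records=records, scores=scores)


@dataclass
class SyntheticMotifProfile:
    """Per-position base probabilities emulating a curated hexamer set.

    Default profiles put literature-typical sigma70 conservation on the
    consensus base at each position and split the remainder equally; the
    default sample sizes match the sizes of the curated -35 and -10
    collections the model was built from.
    """

    probs: np.ndarray  # (6, 4) row-stochastic, base order ACGT
    name: str = "custom"
    sample_size: int = 1000

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (MOTIF_LENGTH, 4):
            raise ValueError(f"probs must be ({MOTIF_LENGTH}, 4)")
        if np.any(self.probs < 0) or not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must be non-negative and sum to 1")
        if self.sample_size <= 0:
            raise ValueError("sample_size must be positive")

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.probs.argmax(axis=1))


def _profile(consensus: str, conservation: tuple[float, ...]) -> np.ndarray:
    probs = np.empty((len(consensus), 4))
    for i, (base, c) in enumerate(zip(consensus, conservation)):
        probs[i, :] = (1.0 - c) / 3.0
        probs[i, BASE_INDEX[base]] = c
    return probs


def minus35_profile(sample_size: int = 1004) -> SyntheticMotifProfile:
    """TTGACA-centred profile with typical per-position conservation."""
    return SyntheticMotifProfile(
        probs=_profile("TTGACA", (0.69, 0.79, 0.61, 0.56, 0.54, 0.54)),
        name="minus35",
        sample_size=sample_size,
    )


def minus10_profile(sample_size: int = 1046) -> SyntheticMotifProfile:
    """TATAAT-centred profile with typical per-position conservation."""
    return SyntheticMotifProfile(
        probs=_profile("TATAAT", (0.77, 0.76, 0.60, 0.61, 0.56, 0.82)),
        name="minus10",
        sample_size=sample_size,
    )


def generate_hexamer_set(profile: SyntheticMotifProfile, n: int | None = None, seed: int = 0) -> list[str]:
    """Sample n hexamers position-independently from the profile."""
    if n is None:
        n = profile.sample_size
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    idx = np.column_stack(
        [rng.choice(4, size=n, p=profile.probs[i]) for i in range(MOTIF_LENGTH)]
    )
    return ["".join(BASES[j] for j in row) for row in idx]


def generate_regions(
    profile: SyntheticMotifProfile,
    n: int | None = None,
    seed: int = 0,
    length: int = 13,
) -> list:
    """13-nt regions with a profile-drawn hexamer embedded at a random
    offset inside uniform background sequence."""
    from .extract import PromoterRegion  # local import avoids a cycle

    if n is None:
        n = profile.sample_size
    rng = np.random.default_rng(seed)
    hexamers = generate_hexamer_set(profile, n=n, seed=int(rng.integers(2**31)))
    role = profile.name if profile.name in ("minus35", "minus10") else "minus35"
    regions = []
    for i, hx in enumerate(hexamers):
        offset = int(rng.integers(0, length - MOTIF_LENGTH + 1))
        flank = "".join(BASES[j] for j in rng.integers(0, 4, size=length - MOTIF_LENGTH))
        seq = flank[:offset] + hx + flank[offset:]
        regions.append(
            PromoterRegion(sequence=seq, role=role, source_id=f"{profile.name}_{i}")
        )
    return regions


def synthetic_feature_table(
    n: int = 18,
    coefficients: tuple[float, float, float] = (-5.1046, 0.4271, 0.2726),
    sigma: float = 0.853,
    seed: int = 0,
    s35_range: tuple[float, float] = (-0.1, 9.2),
    s10_range: tuple[float, float] = (-4.5, 10.1),
) -> pd.DataFrame:
    """Regression table with a known linear truth plus Gaussian noise.

    Defaults mirror the training conditions: n = 18 promoters, true
    coefficients equal to the fitted model's, residual scale equal to the
    training fit's residual standard deviation (0.853), and feature
    ranges spanning the observed score ranges.
    """
    rng = np.random.default_rng(seed)
    a, b35, b10 = coefficients
    s35 = rng.uniform(*s35_range, size=n)
    s10 = rng.uniform(*s10_range, size=n)
    y = a + b35 * s35 + b10 * s10 + rng.normal(0.0, sigma, size=n)
    return feature_table([f"syn_{i}" for i in range(n)], s35, s10, y)
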