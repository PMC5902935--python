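"""COBRA quantification of AluS methylation from gel band intensities.

Combined bisulfite restriction analysis (COBRA) interrogates two CpG loci
in the AluS internal promoter. After bisulfite conversion and PCR, TaqI
cuts only sites that were methylated (the CpG is retained as TCGA), so a
133-bp amplicon resolves into six possible fragments — 133, 90, 75, 58,
43 and 32 bp — whose lane-intensity shares encode the mixture of the four
joint methylation states of the two CpGs:

    uCuC (both unmethylated)  -> 133
    mCuC (first methylated)   -> 90 + 43
    uCmC (second methylated)  -> 75 + 58
    mCmC (both methylated)    -> 43 + 32 + 58

Intensity is proportional to DNA mass (fragment count x length), so
dividing each band's intensity share by its length recovers relative
molar quantities, from which the methylated-locus percentage and the four
pattern percentages are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "FRAGMENT_LENGTHS",
    "BandProfile",
    "StateMixture",
    "MethylationSummary",
    "BlankLaneError",
    "normalize_bands",
    "compute_methylation",
    "forward_profile",
    "add_gel_noise",
]

#: Fragment lengths (bp) in canonical band order.
FRAGMENT_LENGTHS: Tuple[int, ...] = (133, 90, 75, 58, 43, 32)

_SHARE_TOL = 1e-6


class BlankLaneError(ValueError):
    """Raised when a lane carries no usable signal for a denominator."""


@dataclass(frozen=True)
class BandProfile:
    """Lane-intensity shares (percent of lane total) for the six fragments.

    ``shares`` follows :data:`FRAGMENT_LENGTHS` order and sums to 100.
    """

    shares: Tuple[float, ...]
    sample_id: str = ""

    def __post_init__(self):
        shares = tuple(float(s) for s in self.shares)
        if len(shares) != len(FRAGMENT_LENGTHS):
            raise ValueError(f"expected {len(FRAGMENT_LENGTHS)} band shares, got {len(shares)}")
        if any(s < 0 for s in shares):
            raise ValueError(f"band intensities must be non-negative: {shares}")
        if abs(sum(shares) - 100.0) > _SHARE_TOL:
            raise ValueError(f"band shares must sum to 100, got {sum(shares)!r}")
        object.__setattr__(self, "shares", shares)

    @classmethod
    def from_intensities(cls, intensities: Iterable[float], sample_id: str = "") -> "BandProfile":
        """Build a profile from raw (un-normalized) band intensities."""
        x = np.asarray(list(intensities), dtype=float)
        if x.size != len(FRAGMENT_LENGTHS):
            raise ValueError(f"expected {len(FRAGMENT_LENGTHS)} intensities, got {x.size}")
        if np.any(x < 0):
            raise ValueError(f"band intensities must be non-negative: {x.tolist()}")
        total = x.sum()
        if total <= 0:
            raise BlankLaneError(f"lane {sample_id!r} has zero total intensity")
        return cls(shares=tuple(100.0 * x / total), sample_id=sample_id)

    def share(self, length: int) -> float:
        return self.shares[FRAGMENT_LENGTHS.index(length)]


@dataclass(frozen=True)
class StateMixture:
    """Molecule fractions of the four two-CpG methylation states.

    p_uu + p_mu + p_um + p_mm = 1; mu = mCuC, um = uCmC.
    """

    p_uu: float
    p_mu: float
    p_um: float
    p_mm: float

    def __post_init__(self):
        ps = self.as_tuple()
        if any(p < -1e-12 or p > 1 + 1e-12 for p in ps):
            raise ValueError(f"state fractions must lie in [0, 1]: {ps}")
        if abs(sum(ps) - 1.0) > 1e-6:
            raise ValueError(f"state fractions must sum to 1, got {sum(ps)!r}")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.p_uu, self.p_mu, self.p_um, self.p_mm)

    @classmethod
    def normalized(cls, p_uu: float, p_mu: float, p_um: float, p_mm: float) -> "StateMixture":
        total = p_uu + p_mu + p_um + p_mm
        if total <= 0:
            raise ValueError("cannot normalize a non-positive mixture")
        return cls(p_uu / total, p_mu / total, p_um / total, p_mm / total)

    @property
    def methylated_locus_fraction(self) -> float:
        """Fraction of the 2 interrogated CpG loci per molecule that are
        methylated: (p_mu + p_um)/2 + p_mm."""
        return (self.p_mu + self.p_um) / 2.0 + self.p_mm


@dataclass(frozen=True)
class MethylationSummary:
    """Methylation level and pattern percentages for one lane.

    The four pattern percentages share one denominator and sum to 100;
    pct_mC is the percentage of methylated CpG loci (2 per molecule).
    ``molar`` carries the intermediate quantities (A, B, C, D, E, F).
    """

    pct_mC: float
    pct_mCmC: float
    pct_uCmC: float
    pct_mCuC: float
    pct_uCuC: float
    molar: Tuple[float, ...] = field(default=(), compare=False)
    sample_id: str = ""

    def patterns(self) -> Tuple[float, float, float, float]:
        return (self.pct_mCmC, self.pct_uCmC, self.pct_mCuC, self.pct_uCuC)

    def as_dict(self) -> dict:
        return {
            "pct_mC": self.pct_mC,
            "pct_mCmC": self.pct_mCmC,
            "pct_uCmC": self.pct_uCmC,
            "pct_mCuC": self.pct_mCuC,
            "pct_uCuC": self.pct_uCuC,
        }


def normalize_bands(profile: BandProfile) -> Tuple[float, float, float, float, float, float]:
    """Length-normalize band shares into relative molar quantities.

    Returns (A, B, C, D, E, F) = (%133/133, %58/58, %75/75, %90/90,
    %43/43, %32/32) — exactly these six quotients, with no rescaling.
    """
    a = profile.share(133) / 133.0
    b = profile.share(58) / 58.0
    c = profile.share(75) / 75.0
    d = profile.share(90) / 90.0
    e = profile.share(43) / 43.0
    f = profile.share(32) / 32.0
    return (a, b, c, d, e, f)


def compute_methylation(profile: BandProfile) -> MethylationSummary:
    """Evaluate the COBRA estimator for one lane.

    %mC   = 100 (E + B) / (2A + E + B + C + D)
    %mCmC = 100 F / (A + C + D + F)
    %uCmC = 100 C / (A + C + D + F)
    %mCuC = 100 D / (A + C + D + F)
    %uCuC = 100 A / (A + C + D + F)

    The pattern denominator counts each molecule exactly once (133 for
    uCuC, 75 for uCmC, 90 for mCuC, 32 for mCmC), so the four pattern
    percentages always sum to 100. Raises BlankLaneError when either
    denominator vanishes.
    """
    a, b, c, d, e, f = normalize_bands(profile)
    pattern_denom = a + c + d + f
    level_denom = 2 * a + e + b + c + d
    if pattern_denom <= 0 or level_denom <= 0:
        raise BlankLaneError(f"lane {profile.sample_id!r} has no quantifiable bands")
    return MethylationSummary(
        pct_mC=100.0 * (e + b) / level_denom,
        pct_mCmC=100.0 * f / pattern_denom,
        pct_uCmC=100.0 * c / pattern_denom,
        pct_mCuC=100.0 * d / pattern_denom,
        pct_uCuC=100.0 * a / pattern_denom,
        molar=(a, b, c, d, e, f),
        sample_id=profile.sample_id,
    )


def _fragment_counts(mix: StateMixture, digestion_efficiency: float) -> np.ndarray:
    """Expected molar fragment counts per amplicon under (possibly
    incomplete) TaqI digestion.

    Site 1 sits 43 bp from one end, site 2 at 32 bp from the other; a cut
    happens at a methylated site with probability ``digestion_efficiency``.
    """
    eff = float(digestion_efficiency)
    if not 0.0 <= eff <= 1.0:
        raise ValueError("digestion_efficiency must lie in [0, 1]")
    counts = dict.fromkeys(FRAGMENT_LENGTHS, 0.0)
    counts[133] += mix.p_uu
    # mCuC: cut at site 1 -> 43 + 90
    counts[43] += mix.p_mu * eff
    counts[90] += mix.p_mu * eff
    counts[133] += mix.p_mu * (1 - eff)
    # uCmC: cut at site 2 -> 75 + 58
    counts[75] += mix.p_um * eff
    counts[58] += mix.p_um * eff
    counts[133] += mix.p_um * (1 - eff)
    # mCmC: independent cuts at both sites
    counts[43] += mix.p_mm * eff * eff
    counts[58] += mix.p_mm * eff * eff
    counts[32] += mix.p_mm * eff * eff
    counts[43] += mix.p_mm * eff * (1 - eff)
    counts[90] += mix.p_mm * eff * (1 - eff)
    counts[75] += mix.p_mm * (1 - eff) * eff
    counts[58] += mix.p_mm * (1 - eff) * eff
    counts[133] += mix.p_mm * (1 - eff) * (1 - eff)
    return np.array([counts[frag] for frag in FRAGMENT_LENGTHS])


def forward_profile(
    mix: StateMixture,
    sample_id: str = "",
    stain: str = "mass",
    digestion_efficiency: float = 1.0,
) -> BandProfile:
    """Simulate the gel lane produced by a methylation-state mixture.

    Band intensity is mass-proportional by default (fragment count x
    length, matching intercalating-dye staining and hence the
    length-division step of the estimator); ``stain='molar'`` makes
    intensity count-proportional instead. ``digestion_efficiency`` < 1
    models incomplete TaqI digestion (simulator-only; the estimator
    assumes complete digestion).
    """
    counts = _fragment_counts(mix, digestion_efficiency)
    if stain == "mass":
        intensity = counts * np.array(FRAGMENT_LENGTHS, dtype=float)
    elif stain == "molar":
        intensity = counts
    else:
        raise ValueError(f"unknown stain model {stain!r}")
    return BandProfile.from_intensities(intensity, sample_id=sample_id)


def add_gel_noise(profile: BandProfile, cv: float, seed=None) -> BandProfile:
    """Apply multiplicative lognormal noise per band and renormalize.

    The lognormal is mean-one with coefficient of variation ``cv``, so
    cv = 0 is the identity. ``seed`` may be an int or a Generator.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return BandProfile(shares=profile.shares, sample_id=profile.sample_id)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigma = np.sqrt(np.log1p(cv * cv))
    factors = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=len(FRAGMENT_LENGTHS))
    noisy = np.asarray(profile.shares) * factors
    return BandProfile.from_intensities(noisy, sample_id=profile.sample_id)
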