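"""Band matching, Sulston overlap probabilities and clone-coverage analytics.

The overlap test between two restriction fingerprints is the probability of
observing at least ``m`` tolerance-matched bands between two unrelated clones.
With single-band match probability ``p = 2*tolerance/gel_length`` and
``lambda = 1 - (1-p)**n_hi`` (the chance that one band of the smaller profile
finds any partner in the larger one), the score is the exact binomial tail

    S = sum_{k=m}^{n_lo} C(n_lo, k) * lambda**k * (1-lambda)**(n_lo-k)

evaluated in log space.  An overlap is called when ``S <= cutoff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "Method",
    "BandProfile",
    "ScoreParams",
    "LWParams",
    "OverlapCall",
    "match_bands",
    "sulston_score",
    "call_overlap",
    "min_match_threshold",
    "min_informative_band_count",
    "expected_contigs",
    "effective_cutoff",
]

#: HICF composite bands are ``channel * CHANNEL_SPAN + size_unit``; size units
#: are kept away from channel edges so cross-channel bands can never fall
#: within any sane tolerance of each other.
CHANNEL_SPAN = 2000


class Method(str, Enum):
    """Fingerprinting chemistry of a profile."""

    AGAROSE = "AGAROSE"
    HICF = "HICF"


class FingerprintError(ValueError):
    """Raised on invalid band lists or score parameters."""


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the band-match/overlap test.

    tolerance
        Maximum band-position difference (gel units) for two bands to match.
    gel_length
        Number of distinguishable band positions on the gel.
    cutoff
        Maximum Sulston score at which an overlap is accepted.
    """

    tolerance: int = 7
    gel_length: int = 5000
    cutoff: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 < self.tolerance < self.gel_length):
            raise FingerprintError(
                f"tolerance must satisfy 0 < tolerance < gel_length, got "
                f"{self.tolerance} / {self.gel_length}"
            )
        if not (0 < self.cutoff <= 1):
            raise FingerprintError(f"cutoff must be in (0, 1], got {self.cutoff}")

    @property
    def p(self) -> float:
        """Single-band chance match probability, ``2*tolerance/gel_length``."""
        return 2.0 * self.tolerance / self.gel_length


@dataclass(frozen=True)
class LWParams:
    """Lander-Waterman island-count parameters.

    ``G`` (effective genome length in band units) is ``genome_bp/avg_band_bp``;
    ``L`` the average band count per clone, ``N`` the clone count and ``T`` the
    minimum matched bands required to call an overlap.
    """

    genome_bp: float
    avg_band_bp: float
    n_clones: int
    avg_bands: float
    min_match: float

    def __post_init__(self) -> None:
        for name in ("genome_bp", "avg_band_bp", "n_clones", "avg_bands", "min_match"):
            if getattr(self, name) <= 0:
                raise FingerprintError(f"{name} must be positive")
        if self.min_match > self.avg_bands:
            raise FingerprintError("min_match must not exceed avg_bands")


@dataclass
class BandProfile:
    """One clone's scoreable fingerprint bands plus its well address."""

    clone_id: str
    method: Method = Method.AGAROSE
    bands: tuple = ()
    plate: int = 0
    well_row: int = 0
    well_col: int = 0
    batch: int = 0

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        if any(b2 <= b1 for b1, b2 in zip(self.bands, self.bands[1:])):
            raise FingerprintError(
                f"bands of {self.clone_id!r} must be strictly ascending"
            )

    @property
    def n(self) -> int:
        return len(self.bands)

    @property
    def well(self) -> tuple:
        return (self.plate, self.well_row, self.well_col)


@dataclass(frozen=True)
class OverlapCall:
    accepted: bool
    score: float
    match_count: int


def _check_sorted(bands: Sequence, name: str) -> None:
    if any(bands[i] > bands[i + 1] for i in range(len(bands) - 1)):
        raise FingerprintError(f"{name} band list is not sorted ascending")


def match_bands(a: Sequence, b: Sequence, tolerance: int):
    """Maximum tolerance matching between two sorted band lists.

    Returns ``(match_count, pairs)`` where ``pairs`` are disjoint index pairs
    ``(i, j)`` with ``|a[i] - b[j]| <= tolerance``.  The greedy two-pointer
    sweep attains the maximum matching on sorted inputs; ties are broken
    towards the earliest available partner.
    """
    _check_sorted(a, "first")
    _check_sorted(b, "second")
    pairs = []
    i = j = 0
    la, lb = len(a), len(b)
    while i < la and j < lb:
        d = a[i] - b[j]
        if d > tolerance:
            j += 1
        elif d < -tolerance:
            i += 1
        else:
            pairs.append((i, j))
            i += 1
            j += 1
    return len(pairs), pairs


def match_count(a: Sequence, b: Sequence, tolerance: int) -> int:
    """Unchecked fast path of :func:`match_bands` returning only the count."""
    i = j = c = 0
    la, lb = len(a), len(b)
    while i < la and j < lb:
        d = a[i] - b[j]
        if d > tolerance:
            j += 1
        elif d < -tolerance:
            i += 1
        else:
            c += 1
            i += 1
            j += 1
    return c


def _log_binom_tail(n: int, k0: int, lam: float) -> float:
    """log of sum_{k=k0}^{n} C(n,k) lam^k (1-lam)^(n-k), exact terms."""
    if k0 <= 0:
        return 0.0
    if lam >= 1.0:
        return 0.0
    llam = math.log(lam)
    l1m = math.log1p(-lam)
    terms = []
    for k in range(k0, n + 1):
        lc = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        terms.append(lc + k * llam + (n - k) * l1m)
    mx = max(terms)
    return mx + math.log(sum(math.exp(t - mx) for t in terms))


def sulston_score(n_a: int, n_b: int, m: int, params: ScoreParams) -> float:
    """Probability that two unrelated clones share >= ``m`` matching bands.

    The binomial runs over the lower band count; the per-band match chance
    ``lambda`` uses the higher count.  Exact log-space arithmetic — boundary
    cases sit within a few percent of the assembly cutoffs.
    """
    if n_a < 0 or n_b < 0:
        raise FingerprintError("band counts must be non-negative")
    n_lo, n_hi = min(n_a, n_b), max(n_a, n_b)
    if m > n_lo:
        raise FingerprintError(f"m={m} exceeds min(n_a, n_b)={n_lo}")
    if m <= 0:
        return 1.0
    lam = -math.expm1(n_hi * math.log1p(-params.p))
    return min(1.0, math.exp(_log_binom_tail(n_lo, m, lam)))


def call_overlap(
    pa: BandProfile,
    pb: BandProfile,
    params: ScoreParams,
    effective_cutoff: float | None = None,
) -> OverlapCall:
    """Score two same-method profiles and accept iff score <= cutoff.

    Degenerate clones (< 2 bands) are never accepted.
    """
    if pa.method != pb.method:
        raise FingerprintError(
            f"cannot compare {pa.method.value} profile {pa.clone_id!r} with "
            f"{pb.method.value} profile {pb.clone_id!r}"
        )
    cutoff = params.cutoff if effective_cutoff is None else effective_cutoff
    m = match_count(pa.bands, pb.bands, params.tolerance)
    score = sulston_score(pa.n, pb.n, m, params)
    accepted = score <= cutoff and pa.n >= 2 and pb.n >= 2
    return OverlapCall(accepted, score, m)


def min_match_threshold(n: int, params: ScoreParams) -> int | None:
    """Smallest ``j`` with ``sulston_score(n, n, j) <= cutoff``.

    Returns ``None`` when even a perfect match (``j = n``) stays above the
    cutoff.
    """
    if n < 1:
        raise FingerprintError("n must be >= 1")
    for j in range(0, n + 1):
        if sulston_score(n, n, j, params) <= params.cutoff:
            return j
    return None


def min_match_threshold_pair(n_a: int, n_b: int, params: ScoreParams) -> int | None:
    """Smallest ``j`` with ``sulston_score(n_a, n_b, j) <= cutoff`` (or None)."""
    n_lo = min(n_a, n_b)
    for j in range(0, n_lo + 1):
        if sulston_score(n_a, n_b, j, params) <= params.cutoff:
            return j
    return None


def min_informative_band_count(params: ScoreParams, n_max: int = 10_000) -> int:
    """Smallest band count ``n`` at which even an all-band match is callable,
    i.e. ``sulston_score(n, n, n) <= cutoff``."""
    if params.cutoff >= 1:
        raise FingerprintError("cutoff must be < 1 for an informative minimum")
    for n in range(1, n_max + 1):
        # all-match score is lambda(n)**n
        lam = -math.expm1(n * math.log1p(-params.p))
        if n * math.log(lam) <= math.log(params.cutoff):
            return n
    raise FingerprintError(f"no informative band count found up to {n_max}")


def expected_contigs(lw: LWParams) -> float:
    """Lander-Waterman expected contig count ``N*exp(-(L*N/G)*(1-T/L))``."""
    g = lw.genome_bp / lw.avg_band_bp
    exponent = -(lw.avg_bands * lw.n_clones / g) * (1.0 - lw.min_match / lw.avg_bands)
    return lw.n_clones * math.exp(exponent)


def effective_cutoff(
    base: float, shared_evidence: int, floor: float | None = None
) -> float:
    """Relax the cutoff by 2, 3 or 4 denary intervals for 1, 2 or >=3 shared
    evidence markers; optionally capped at a relaxation floor."""
    if shared_evidence < 0:
        raise FingerprintError("shared_evidence must be >= 0")
    if shared_evidence == 0:
        out = base
    else:
        out = base * 10.0 ** (min(shared_evidence, 3) + 1)
    if floor is not None:
        out = min(out, floor)
    return out
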