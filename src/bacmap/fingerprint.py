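"""Restriction-fingerprint data model, band matching, and Sulston overlap scores.

A clone's HICF fingerprint is its sorted list of restriction-fragment sizes,
digitized to integer size-units (default 0.1 bp per unit).  Two clones that
overlap on the genome share the fragments of the shared interval, so the
number of bands matching within a size tolerance measures overlap.  The
Sulston score is the probability of observing at least that many matches
between two *unrelated* fingerprints: the smaller the score, the stronger
the evidence that the clones truly overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "Fingerprint",
    "ScoreParams",
    "SulstonResult",
    "match_bands",
    "sulston_log10",
    "sulston_score",
    "qc_filter",
]


@dataclass(frozen=True)
class Fingerprint:
    """A clone's digitized fingerprint: ascending integer band sizes."""

    clone_id: str
    library: str
    bands: tuple[int, ...]

    def __post_init__(self) -> None:
        bands = tuple(int(b) for b in self.bands)
        if any(b <= 0 for b in bands):
            raise ValueError(f"{self.clone_id}: band sizes must be positive")
        if any(bands[i] > bands[i + 1] for i in range(len(bands) - 1)):
            raise ValueError(f"{self.clone_id}: bands must be sorted ascending")
        object.__setattr__(self, "bands", bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class ScoreParams:
    """Sulston-score parameters.

    tolerance
        Band match tolerance *t* in size-units; two bands match when their
        sizes differ by at most *t*.
    gellen
        *G*, the number of distinct band size-units resolvable by the sizing
        system.  The default 5650 corresponds to sizes 35.0-600.0 bp read at
        0.1 bp resolution.
    cutoff
        Probability threshold below which two clones are considered to
        overlap (1e-80 for a stringent initial build).
    """

    tolerance: int = 3
    gellen: int = 5650
    cutoff: float = 1e-80

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.gellen <= 2 * self.tolerance + 1:
            raise ValueError("gellen must exceed 2*tolerance + 1")
        if not (0.0 < self.cutoff <= 1.0):
            raise ValueError("cutoff must be in (0, 1]")

    @property
    def log10_cutoff(self) -> float:
        return float(np.log10(self.cutoff))

    def with_cutoff(self, cutoff: float) -> "ScoreParams":
        return ScoreParams(self.tolerance, self.gellen, cutoff)


def _as_sorted_array(bands: Sequence[int] | np.ndarray, label: str) -> np.ndarray:
    arr = np.asarray(bands, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError(f"{label}: band list must be one-dimensional")
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise ValueError(f"{label}: band list must be sorted ascending")
    return arr


def match_bands(
    f1: Fingerprint | Sequence[int],
    f2: Fingerprint | Sequence[int],
    tolerance: int,
) -> int:
    """Count bands shared by two fingerprints within ``tolerance`` size-units.

    Greedy ascending matching: walk both sorted lists with two pointers,
    pairing bands whose sizes differ by at most *t*; each band is used at
    most once.  On this interval structure the greedy pairing attains the
    maximum bipartite matching (certified by a property test against
    exhaustive matching), and the count is symmetric in its arguments.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    b1 = _as_sorted_array(f1.bands if isinstance(f1, Fingerprint) else f1, "f1")
    b2 = _as_sorted_array(f2.bands if isinstance(f2, Fingerprint) else f2, "f2")
    i = j = m = 0
    n1, n2 = b1.size, b2.size
    while i < n1 and j < n2:
        d = b1[i] - b2[j]
        if d > tolerance:
            j += 1
        elif d < -tolerance:
            i += 1
        else:
            m += 1
            i += 1
            j += 1
    return m


def _log10_binomial_tail(n_low: int, p: float, m: int) -> float:
    """log10 of P(Binomial(n_low, p) >= m), evaluated stably in log space."""
    if m <= 0:
        return 0.0
    if p >= 1.0:
        return 0.0
    if p <= 0.0:
        return -np.inf
    j = np.arange(m, n_low + 1)
    log_terms = (
        gammaln(n_low + 1)
        - gammaln(j + 1)
        - gammaln(n_low - j + 1)
        + j * np.log(p)
        + (n_low - j) * np.log1p(-p)
    )
    return float(logsumexp(log_terms) / np.log(10.0))


def sulston_log10(
    n1: int, n2: int, matched: int, params: ScoreParams
) -> float:
    """log10 Sulston score for ``matched`` shared bands between fingerprints
    of ``n1`` and ``n2`` bands.

    With nL = min(n1, n2) and nH = max(n1, n2), the chance that one given
    band of the smaller fingerprint matches *some* band of the larger one is
    p = 1 - (1 - (2t+1)/G)**nH, and the score is the binomial upper tail
    P(X >= m) for X ~ Binomial(nL, p).  Empty fingerprints give score 1
    (no evidence).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("band counts must be non-negative")
    n_low, n_high = (n1, n2) if n1 <= n2 else (n2, n1)
    if not 0 <= matched <= n_low:
        raise ValueError("matched count must be in [0, min(n1, n2)]")
    if n_low == 0:
        return 0.0
    window = (2 * params.tolerance + 1) / params.gellen
    p = -np.expm1(n_high * np.log1p(-window))
    return _log10_binomial_tail(n_low, p, matched)


@dataclass(frozen=True)
class SulstonResult:
    matched: int
    log10_score: float

    @property
    def score(self) -> float:
        # underflows to 0.0 below ~1e-308; compare in log space instead
        return float(10.0 ** self.log10_score)


def sulston_score(
    f1: Fingerprint, f2: Fingerprint, params: ScoreParams
) -> SulstonResult:
    """Match two fingerprints and evaluate the Sulston overlap score."""
    m = match_bands(f1, f2, params.tolerance)
    return SulstonResult(m, sulston_log10(f1.n_bands, f2.n_bands, m, params))


def qc_filter(
    fingerprints: Iterable[Fingerprint],
    min_bands: int = 20,
    max_bands: int = 220,
) -> tuple[list[Fingerprint], list[tuple[Fingerprint, str]]]:
    """Split fingerprints into (kept, removed-with-reason).

    A fingerprint is kept iff ``min_bands <= n <= max_bands``.  Empty band
    lists (failed digests, insertless vectors) are removed with reason
    ``"empty"``; others with ``"too-few"`` or ``"too-many"``.
    """
    kept: list[Fingerprint] = []
    removed: list[tuple[Fingerprint, str]] = []
    for fp in fingerprints:
        n = fp.n_bands
        if n == 0:
            removed.append((fp, "empty"))
        elif n < min_bands:
            removed.append((fp, "too-few"))
        elif n > max_bands:
            removed.append((fp, "too-many"))
        else:
            kept.append(fp)
    return kept, removed
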