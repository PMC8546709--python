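"""Alpha-diversity mathematics for a single community.

Shannon's entropy ``H' = -sum(p_i ln p_i)`` blends two distinct aspects of a
community into one number: how many taxa there are (richness, S) and how
uniformly abundance is spread across them (evenness).  This module decomposes
the entropy into those components.  The evenness statistic is the
normalized-median evenness (NME),

    NME = median(-p_i ln p_i) / max(-p_i ln p_i),

the median of the per-taxon surprisal terms scaled by their maximum, so that
a perfectly even community scores exactly 1 and strongly dominated
communities score near 0.  Pielou's J' = H'/ln(S) and the first-order Hill
number exp(H') are provided for comparison.

All functions operate on a 1-D vector of relative abundances (proportions).
They trust the caller on normalization: values are used as given, and
``relative_abundances`` is the explicit normalization step for count data.
Taxa with zero abundance are treated as absent and never contribute a
surprisal term.  Natural logarithms throughout.
"""

from __future__ import annotations

import numpy as np
import numpy.typing as npt

from .exceptions import InvalidInputError, UndefinedResultError

__all__ = [
    "relative_abundances",
    "surprisal_terms",
    "shannon",
    "richness",
    "nme",
    "pielou",
    "hill1",
]


def _validate(values: npt.ArrayLike) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise InvalidInputError(f"expected a 1-D abundance vector, got shape {v.shape}")
    if v.size == 0:
        raise InvalidInputError("abundance vector is empty")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("abundance vector contains non-finite values")
    if np.any(v < 0):
        raise InvalidInputError("abundance vector contains negative values")
    if not np.any(v > 0):
        raise InvalidInputError("abundance vector has no positive entries")
    return v


def relative_abundances(values: npt.ArrayLike) -> np.ndarray:
    """Normalize counts (or proportions) to proportions summing to 1.

    Taxon order is preserved; zeros stay zero.  Input that is already a
    proportion vector is returned unchanged up to floating-point scaling.
    """
    v = _validate(values)
    return v / v.sum()


def surprisal_terms(p: npt.ArrayLike) -> np.ndarray:
    """Per-taxon surprisal terms ``-p_i ln p_i`` for the present taxa.

    Absent taxa (p_i = 0) are excluded, so the result has one entry per
    *present* taxon, in the original taxon order.  The sum of the terms is
    the community's Shannon entropy.
    """
    p = _validate(p)
    if np.any(p > 1.0 + 1e-12):
        raise InvalidInputError(
            "proportions > 1 encountered; pass counts through relative_abundances() first"
        )
    p = p[p > 0]
    return -p * np.log(p)


def shannon(p: npt.ArrayLike) -> float:
    """Shannon entropy H' in nats: ``-sum(p_i ln p_i)`` over present taxa."""
    return float(surprisal_terms(p).sum())


def richness(p: npt.ArrayLike) -> int:
    """Observed richness S: the number of taxa with abundance > 0.

    No extrapolation for unseen rare taxa is attempted.
    """
    return int(np.count_nonzero(_validate(p) > 0))


def nme(p: npt.ArrayLike) -> float:
    """Normalized-median evenness: median surprisal / maximum surprisal.

    Equals 1 for a perfectly even community (every surprisal term identical)
    and approaches 0 as one taxon dominates.  For an even number of present
    taxa the median is the mean of the two central order statistics.

    Raises
    ------
    UndefinedResultError
        For single-taxon communities, where the only surprisal term is 0
        and the ratio is a 0/0 form.
    """
    s = surprisal_terms(p)
    if s.size < 2:
        raise UndefinedResultError(
            "NME is undefined for a single-species community (0/0)"
        )
    return float(np.median(s) / s.max())


def pielou(p: npt.ArrayLike) -> float:
    """Pielou's evenness J' = H' / ln(S).

    Raises
    ------
    UndefinedResultError
        For single-taxon communities (H' = 0 and ln S = 0).
    """
    s = richness(p)
    if s < 2:
        raise UndefinedResultError(
            "Pielou's evenness is undefined for a single-species community (0/0)"
        )
    return shannon(p) / np.log(s)


def hill1(p: npt.ArrayLike) -> float:
    """First-order Hill number ¹D = exp(H'): the effective number of species."""
    return float(np.exp(shannon(p)))
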