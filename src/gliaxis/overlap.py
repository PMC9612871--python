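"""Set-overlap statistics: log-space hypergeometric tests, Jaccard, BH-FDR.

Overlap p-values between large differentially-expressed gene sets routinely
fall far below the double-precision floor (e.g. e^-1008), so the upper-tail
hypergeometric probability is computed and stored entirely in natural-log
space via log-gamma and log-sum-exp; a linear-scale value is derived only for
display.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import GeneSet, OverlapResult

logger = logging.getLogger(__name__)

__all__ = ["log_hypergeom_tail", "overlap_test", "bh_adjust", "jaccard_index"]


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeometric(N, K, n).

    The tail is the probability that two sets of sizes ``K`` and ``n``, drawn
    from a background of ``N`` genes, share at least ``k`` members.  Summation
    runs in log space over the exact pmf terms, so the result is finite for
    any positive tail probability (no underflow to -inf).

    Parameters
    ----------
    k
        Observed overlap (the test is one-sided, upper tail).
    K, n
        Sizes of the two sets.
    N
        Background population size.

    Returns
    -------
    float
        ln P(X >= k); 0.0 when ``k == 0`` (the tail is certain).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if max(K, n) > N:
        raise ValueError(f"set sizes K={K}, n={n} cannot exceed background N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} cannot exceed min(K, n)={min(K, n)}")
    if k == 0:
        return 0.0
    # support of the overlap also has a lower bound max(0, n + K - N)
    i = np.arange(k, min(K, n) + 1)
    log_pmf = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(logsumexp(log_pmf), 0.0))


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; 0.0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def overlap_test(set_a, set_b, background) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    Members outside the background are dropped (with a logged count) before
    testing, so the reported sizes refer to the intersected sets.

    Parameters
    ----------
    set_a, set_b
        Gene sets (:class:`GeneSet` or any iterable of identifiers).
    background
        The population the sets were drawn from, e.g. all genes tested for
        differential expression.
    """
    bg = set(background.members if isinstance(background, GeneSet) else background)
    if not bg:
        raise ValueError("background must be non-empty")
    a = set(set_a.members if isinstance(set_a, GeneSet) else set_a)
    b = set(set_b.members if isinstance(set_b, GeneSet) else set_b)
    dropped = len(a - bg) + len(b - bg)
    if dropped:
        logger.warning("dropping %d set members outside the background", dropped)
    a &= bg
    b &= bg
    k = len(a & b)
    ln_p = log_hypergeom_tail(k, len(a), len(b), len(bg))
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        overlap=k,
        background=len(bg),
        ln_p=ln_p,
        jaccard=jaccard_index(a, b),
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Monotonicity is enforced and values capped at 1; the family is exactly
    the list passed in (callers define one family per comparison table).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
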