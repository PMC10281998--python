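"""Shared statistical primitives: one-sided hypergeometric tail and BH FDR."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper_tail", "bh_adjust", "binom_upper_tail"]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    This is the one-sided overlap-enrichment p-value used throughout:
    population N, K marked elements, n drawn, k or more marked in the draw.
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(_st.hypergeom.sf(k - 1, N, K, n))


def binom_upper_tail(n: int, p: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0,1], got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(_st.binom.sf(k - 1, n, p))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()
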