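"""Exact posterior enumeration for tiny problem instances.

For complete data with N small and the feature count truncated at
``max_k``, the posterior over binary feature matrices can be enumerated
directly: sum the IBP class prior times the collapsed marginal likelihood
over every multiset of at most ``max_k`` nonzero membership columns.  This
serves as an independent cross-check of the Gibbs sampler's stationary
distribution — it shares no code path with the sampler beyond the collapsed
marginal, which the sampler itself never calls.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from scipy.special import gammaln, logsumexp

from .sampler import as_model_data, collapsed_log_marginal, harmonic_number

__all__ = ["enumerate_posterior", "exact_k_posterior"]


def _class_log_prior(patterns: tuple[tuple[int, ...], ...], n: int,
                     alpha: float) -> float:
    """Log IBP probability of the column-multiset equivalence class given by
    ``patterns`` (each a nonzero 0/1 membership tuple of length n)."""
    k = len(patterns)
    hn = harmonic_number(n)
    if k == 0:
        return -alpha * hn
    mult = Counter(patterns)
    lp = k * math.log(alpha) - alpha * hn
    lp -= sum(gammaln(c + 1) for c in mult.values())
    for pat in patterns:
        m = sum(pat)
        lp += gammaln(n - m + 1) + gammaln(m) - gammaln(n + 1)
    return float(lp)


def enumerate_posterior(x, alpha: float, sigma_x: float, sigma_a: float,
                        max_k: int) -> list[tuple[tuple, float]]:
    """All column multisets with at most ``max_k`` features and their
    posterior log weights (unnormalized)."""
    data = as_model_data(x)
    if not data.mask.all():
        raise ValueError("exact enumeration requires complete data")
    n = data.n
    nonzero = [pat for pat in itertools.product((0, 1), repeat=n)
               if any(pat)]
    out = []
    for k in range(max_k + 1):
        for combo in itertools.combinations_with_replacement(nonzero, k):
            z = (np.array(combo, dtype=float).T if k
                 else np.zeros((n, 0)))
            lw = (_class_log_prior(combo, n, alpha)
                  + collapsed_log_marginal(data, z, sigma_x, sigma_a))
            out.append((combo, lw))
    return out


def exact_k_posterior(x, alpha: float, sigma_x: float, sigma_a: float,
                      max_k: int) -> np.ndarray:
    """Posterior P(K = 0..max_k | X) under the truncated model, exactly.

    Returns an array of length ``max_k + 1`` summing to 1.
    """
    weighted = enumerate_posterior(x, alpha, sigma_x, sigma_a, max_k)
    logw_by_k = [[] for _ in range(max_k + 1)]
    for combo, lw in weighted:
        logw_by_k[len(combo)].append(lw)
    logs = np.array([logsumexp(v) if v else -np.inf for v in logw_by_k])
    logs -= logsumexp(logs)
    return np.exp(logs)
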