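"""Closed-form laws of neutral heteroplasmy drift and variant detection.

These expressions are derived directly from the model definitions
(hypergeometric segregation, binomial read sampling) and are independent of
the stochastic simulator; the test suite and the acceptance script use them
as the analytic oracle against Monte-Carlo output.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def segregation_variance(p: float, n_copies: int) -> float:
    """Variance of daughter VAF after strict doubling + random segregation.

    A parent with VAF p and N copies doubles to 2N molecules (2Np mutant) and
    a daughter draws N without replacement, so the daughter's mutant count is
    hypergeometric and Var(VAF) = p(1-p)/(2N-1).
    """
    return p * (1.0 - p) / (2 * n_copies - 1)


def drift_transition_matrix(n_copies: int) -> np.ndarray:
    """Markov transition matrix of the neutral drift chain on mutant counts.

    State k (0..N mutant copies) doubles deterministically to 2k of 2N and a
    daughter receives Hypergeom(2N, 2k, N) mutant copies. States 0 and N are
    absorbing (loss and fixation).
    """
    n = int(n_copies)
    states = np.arange(n + 1)
    mat = np.zeros((n + 1, n + 1))
    for k in states:
        mat[k] = stats.hypergeom.pmf(states, 2 * n, 2 * k, n)
    return mat


def fixation_probability_exact(n_copies: int, k0: int) -> float:
    """Absorption probability at fixation for the neutral drift chain.

    Solved exactly from the absorbing Markov chain; for a neutral variant it
    equals the initial frequency k0/N (martingale argument), which the linear
    solve confirms without assuming it.
    """
    n = int(n_copies)
    if not (0 <= k0 <= n):
        raise ValueError("k0 must be in [0, N]")
    mat = drift_transition_matrix(n)
    interior = np.arange(1, n)
    q = mat[np.ix_(interior, interior)]
    r_fix = mat[interior, n]
    f = np.linalg.solve(np.eye(n - 1) - q, r_fix)
    if k0 == 0:
        return 0.0
    if k0 == n:
        return 1.0
    return float(f[k0 - 1])


def detection_probability(p: float, coverage: int, support_threshold: int) -> float:
    """P(variant called) at fixed coverage: binomial upper tail.

    With zero sequencing error the alt-read count is Binomial(coverage, p);
    the variant is called when at least ``support_threshold`` reads carry it.
    """
    return float(stats.binom.sf(support_threshold - 1, coverage, p))


def expected_mutations_per_replication(mu: float, genome_length: int) -> float:
    """Mean de-novo variants added per replication event: Poisson rate mu*L."""
    return mu * genome_length
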