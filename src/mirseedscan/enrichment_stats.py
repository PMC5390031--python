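"""Over-representation analysis of target-gene annotations.

One hypergeometric upper-tail test per ontology term with at least one
study hit, followed by Benjamini-Hochberg step-up FDR control across the
tested terms. The tail probability is accumulated in log space from
log-binomial coefficients, which keeps tiny p-values stable far below
double underflow of the direct product form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int           # study hits for the term
    n: int           # study size
    K: int           # population hits for the term
    N: int           # population size
    p_value: float
    fdr: float
    flagged: bool


def _log_comb(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed as logsumexp over the log-pmf, so extreme tails do not
    underflow. Raises on inconsistent counts.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    xs = np.arange(k, hi + 1)
    log_pmf = _log_comb(K, xs) + _log_comb(N - K, n - xs) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def enrich(study, annotation: dict, alpha: float = 0.05) -> list[EnrichmentResult]:
    """Term over-representation in a study gene set.

    ``annotation`` maps gene -> iterable of term ids; the population is
    the set of annotated genes. Terms are tested only when hit at least
    once in the study; BH correction spans exactly the tested terms.
    """
    study = [g for g in study]
    if not study:
        warnings.warn("empty study set", stacklevel=2)
        return []
    population = set(annotation)
    study_set = set(study)
    if not study_set <= population:
        raise ValueError("study genes missing from the annotation map")
    N = len(population)
    n = len(study_set)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene, terms in annotation.items():
        in_study = gene in study_set
        for t in set(terms):
            term_pop[t] = term_pop.get(t, 0) + 1
            if in_study:
                term_study[t] = term_study.get(t, 0) + 1
    tested = sorted(term_study)
    pvals = [
        hypergeom_tail(term_study[t], n, term_pop[t], N) for t in tested
    ]
    fdrs = bh_adjust(pvals)
    return [
        EnrichmentResult(
            term_id=t,
            k=term_study[t],
            n=n,
            K=term_pop[t],
            N=N,
            p_value=p,
            fdr=f,
            flagged=f <= alpha,
        )
        for t, p, f in zip(tested, pvals, fdrs)
    ]
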