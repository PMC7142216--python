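"""Gene-set enrichment and tumor-vs-normal differential expression.

Enrichment uses the upper-tail cumulative hypergeometric test: with a
universe of N genes, M of which carry a term, and a query of n genes
overlapping the term in i, the enrichment p-value is P(X ≥ i) for
X ~ Hypergeometric(N, M, n).

Differential expression follows the SAM (significance analysis of
microarrays) scheme: a moderated t-like statistic
``d = (mean_a − mean_b) / (s + s0)`` with a fudge constant s0 guarding
against near-zero variances, and permutation-based q-values estimated
as the median false-call rate over group-label permutations at each |d|
cutoff. A gene is called when q < 0.05 and |log2 fold change| > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("panprog")

__all__ = ["EnrichmentResult", "DEResult", "hypergeom_enrich", "sam_de"]


@dataclass
class EnrichmentResult:
    """One term's overlap statistics and hypergeometric p-value."""

    term_id: str
    N: int        # universe size
    M: int        # term size within the universe
    n: int        # query size within the universe
    i_hit: int    # overlap of query and term
    p: float
    significant: bool


@dataclass
class DEResult:
    gene_id: str
    d_stat: float
    log2_fc: float
    q_value: float
    called: bool


def hypergeom_enrich(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    namespace: str | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    Terms and the query are first intersected with the universe (query
    genes outside it are dropped with a warning). ``namespace`` keeps
    only terms whose id ends in ``|<namespace>`` (e.g. ``"BP"`` for
    biological-process GO terms). Results are sorted by ascending p; the
    significance flag applies ``alpha`` without multiplicity correction.
    """
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    outside = query - universe
    if outside:
        log.warning("hypergeom_enrich: %d query genes outside universe dropped", len(outside))
    q = query & universe
    n = len(q)
    results = []
    for term_id, members in collection.items():
        if namespace is not None:
            if "|" not in term_id or term_id.rsplit("|", 1)[1] != namespace:
                continue
        m_set = members & universe
        M = len(m_set)
        i_hit = len(q & m_set)
        # P(X >= i_hit), X ~ Hypergeom(N, M, n); sf(i-1) is the upper tail
        p = float(stats.hypergeom.sf(i_hit - 1, N, M, n)) if i_hit > 0 else 1.0
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                term_id=term_id, N=N, M=M, n=n, i_hit=i_hit, p=p, significant=p < alpha
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def _sam_d(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """Moderated difference statistic per gene for group matrices a, b."""
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    pooled = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled += ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt(pooled / (na + nb - 2) * (1.0 / na + 1.0 / nb))
    return diff / (s + s0)


def _gene_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[1], b.shape[1]
    pooled = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled += ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt(pooled / (na + nb - 2) * (1.0 / na + 1.0 / nb))


def sam_de(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    q_thresh: float = 0.05,
    fc_thresh: float = 1.0,
    n_perm: int = 200,
    seed: int = 0,
) -> list[DEResult]:
    """SAM-style differential expression between two sample groups.

    ``expr_a`` / ``expr_b`` are gene × sample matrices (un-logged
    expression) sharing gene ids. Per gene the moderated statistic d is
    computed with s0 fixed at the 5th percentile of gene-wise standard
    errors; q-values come from ``n_perm`` group-label permutations as
    the median number of null genes beyond each |d|, divided by the
    observed count and monotonized. log2 fold change uses group means
    with a pseudo-count of 1. A gene is called when q < ``q_thresh`` and
    |log2FC| > ``fc_thresh``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    common = expr_a.index.intersection(expr_b.index)
    if len(common) == 0:
        raise ValueError("no shared gene ids")
    a = expr_a.loc[common].to_numpy(float)
    b = expr_b.loc[common].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two samples")

    s0 = float(np.percentile(_gene_se(a, b), 5))
    d_obs = _sam_d(a, b, s0)
    abs_obs = np.abs(d_obs)

    pooled = np.concatenate([a, b], axis=1)
    rng = np.random.default_rng(seed)
    n_genes = len(common)
    # per-permutation count of null |d| values >= each observed |d|
    order = np.argsort(abs_obs)
    sorted_abs = abs_obs[order]
    exceed = np.zeros((n_perm, n_genes))
    for k in range(n_perm):
        perm = rng.permutation(na + nb)
        pa, pb = pooled[:, perm[:na]], pooled[:, perm[na:]]
        d_null = np.abs(_sam_d(pa, pb, s0))
        # for each observed cutoff, how many null stats lie at/above it
        pos = np.searchsorted(np.sort(d_null), sorted_abs, side="left")
        exceed[k] = n_genes - pos
    med_false = np.median(exceed, axis=0)
    n_called = n_genes - np.arange(n_genes)   # observed genes at/above each sorted cutoff
    q_sorted = med_false / n_called
    # monotonize: q must be non-increasing in the cutoff
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n_genes)
    q[order] = np.clip(q_sorted, 0.0, 1.0)

    log2_fc = np.log2(a.mean(axis=1) + 1.0) - np.log2(b.mean(axis=1) + 1.0)
    results = [
        DEResult(
            gene_id=str(g),
            d_stat=float(d_obs[i]),
            log2_fc=float(log2_fc[i]),
            q_value=float(q[i]),
            called=bool(q[i] < q_thresh and abs(log2_fc[i]) > fc_thresh),
        )
        for i, g in enumerate(common)
    ]
    return results
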