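"""Integrate Bayes factors and select risk genes via Bayesian FDR.

Per gene, the Random Draw BF (from case-only data) and the family-based
trio BF are multiplied after flooring each at 1, so that weak evidence
from one source never down-weights the other. Final BFs are converted to
posterior null probabilities with a prior risk-gene proportion pi1 and to
q-values (cumulative mean of posterior null probabilities down the
BF-ranked list); selection uses q < 0.05 or a Bonferroni rule on p-values
recovered from the q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneResult",
    "combine_bfs",
    "bayesian_fdr",
    "qvalues_to_pvalues",
    "select_genes",
    "count_false_selections",
    "integrate",
    "results_to_frame",
]


@dataclass
class GeneResult:
    """Combined per-gene evidence and selection flags."""

    gene_id: str
    bf_rd: float
    bf_family: float
    bf_final: float
    posterior_null: float = math.nan
    q_value: float = math.nan
    p_value: float = math.nan
    selected_fdr: bool = False
    selected_bonferroni: bool = False


def combine_bfs(bf_rd: float, bf_family: float) -> float:
    """Multiply the two BFs, substituting any BF less than 1 with 1."""
    if not (bf_rd > 0 and bf_family > 0):
        raise ValueError("Bayes factors must be positive")
    return max(1.0, bf_rd) * max(1.0, bf_family)


def bayesian_fdr(
    bfs: Sequence[float], pi1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior null probabilities and Bayesian-FDR q-values.

    posterior_null_i = (1-pi1) / ((1-pi1) + pi1 * BF_i). Genes are ranked
    by BF descending; the q-value at rank k is the mean posterior null
    probability of the top k genes (the expected FDR if the top k are
    declared risk genes). Tied BFs share the q-value of the last tied
    rank. Outputs are returned in the input order.
    """
    if len(bfs) == 0:
        raise ValueError("empty Bayes factor list")
    if not 0.0 < pi1 < 1.0:
        raise ValueError(f"pi1 must lie in (0,1), got {pi1}")
    bfs = np.asarray(bfs, dtype=float)
    pi0 = 1.0 - pi1
    with np.errstate(invalid="ignore"):
        post_null = np.where(
            np.isinf(bfs), 0.0, pi0 / (pi0 + pi1 * bfs)
        )
    order = np.argsort(-bfs, kind="stable")
    q_sorted = np.cumsum(post_null[order]) / np.arange(1, len(bfs) + 1)
    # ties share the q-value of the last tied rank
    sorted_bfs = bfs[order]
    k = len(bfs) - 1
    while k > 0:
        if sorted_bfs[k - 1] == sorted_bfs[k]:
            q_sorted[k - 1] = q_sorted[k]
        k -= 1
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return post_null, q


def qvalues_to_pvalues(q_values: Sequence[float]) -> np.ndarray:
    """Recover p-values from q-values by inverting the BH step-up map.

    On the ranked list, p_(k) = q_(k) * k / m, followed by a running
    maximum to enforce monotonicity (BH loses information, so this is the
    canonical pseudo-inverse, kept isolated here so it can be swapped).
    Returned in input order, capped at 1.
    """
    q = np.asarray(q_values, dtype=float)
    m = len(q)
    order = np.argsort(q, kind="stable")
    p_sorted = q[order] * np.arange(1, m + 1) / m
    p_sorted = np.minimum(np.maximum.accumulate(p_sorted), 1.0)
    p = np.empty_like(p_sorted)
    p[order] = p_sorted
    return p


def select_genes(
    results: Sequence[GeneResult],
    q_cut: float = 0.05,
    bonferroni_alpha: float = 0.05,
) -> list[GeneResult]:
    """Flag genes under the FDR and Bonferroni selection rules (in place)."""
    n = len(results)
    pvals = qvalues_to_pvalues([r.q_value for r in results])
    for r, p in zip(results, pvals):
        r.p_value = float(p)
        r.selected_fdr = r.q_value < q_cut
        r.selected_bonferroni = p < bonferroni_alpha / n
    return list(results)


def count_false_selections(
    selected: Iterable[str], benchmark_positive: Iterable[str]
) -> int:
    """Number of selected genes outside the benchmark-positive set.

    In simulations the benchmark-positive set is the known risk-gene
    truth; averaging this count over replicate datasets gives the
    per-family error rate (PFER).
    """
    return len(set(selected) - set(benchmark_positive))


def integrate(
    rd_bfs: dict[str, float],
    family_bfs: dict[str, float],
    pi1: float = 0.06,
    q_cut: float = 0.05,
    bonferroni_alpha: float = 0.05,
) -> list[GeneResult]:
    """Full integration over the union of genes seen in either source.

    Genes missing from one source contribute BF = 1 from it (no
    evidence). Results are sorted by final BF descending, gene_id as the
    tie-break for reproducibility.
    """
    gene_ids = sorted(set(rd_bfs) | set(family_bfs))
    results = []
    for g in gene_ids:
        bf_rd = rd_bfs.get(g, 1.0)
        bf_family = family_bfs.get(g, 1.0)
        results.append(
            GeneResult(
                gene_id=g,
                bf_rd=bf_rd,
                bf_family=bf_family,
                bf_final=combine_bfs(bf_rd, bf_family),
            )
        )
    post_null, q = bayesian_fdr([r.bf_final for r in results], pi1)
    for r, pn, qv in zip(results, post_null, q):
        r.posterior_null = float(pn)
        r.q_value = float(qv)
    select_genes(results, q_cut=q_cut, bonferroni_alpha=bonferroni_alpha)
    results.sort(key=lambda r: (-r.bf_final, r.gene_id))
    return results


def results_to_frame(results: Sequence[GeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "bf_rd": [r.bf_rd for r in results],
            "bf_family": [r.bf_family for r in results],
            "bf_final": [r.bf_final for r in results],
            "posterior_null": [r.posterior_null for r in results],
            "q_value": [r.q_value for r in results],
            "p_value": [r.p_value for r in results],
            "selected_fdr": [r.selected_fdr for r in results],
            "selected_bonferroni": [r.selected_bonferroni for r in results],
        }
    )
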