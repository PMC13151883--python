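"""The Random Draw model: gene-level Bayes factors from inferred counts.

Each case-only variant in a gene is treated as a random draw from a mixed
pool of de novo and inherited variants. Let I indicate true de novo
status, X the classifier call at the chosen threshold, and D the gene's
risk status. With p1 = P(I=1 | D=1) and p0 = P(I=1 | D=0), p1 > p0 —
a risk gene's baseline mutation rate is multiplied by a relative risk
gamma > 1, so a larger share of its variants is de novo — the observed
composition (x_d likely de novo, x_h likely inherited) is binomial under
either scenario. Classification error is absorbed into the binomial
parameter via the sensitivity w1 = P(X=1|I=1) and specificity
w2 = P(X=0|I=0):

    P(X=1 | D) = w1 * p + (1 - w2) * (1 - p),   p in {p1, p0}.

The Bayes factor contrasting risk and non-risk is the ratio of the two
binomial likelihoods (the binomial coefficients cancel); Beta priors on
p1, p0 give closed-form beta-binomial marginals. All computation is in
natural-log space; reported values are linear-scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betaln

from .classdn import ClassifierPerformance
from .variant_io import GeneCounts, GeneEntry

__all__ = [
    "RDPriors",
    "RDResult",
    "misclassified_param",
    "rd_likelihood",
    "rd_log_bayes_factor",
    "rd_bayes_factor",
    "rd_bayes_factors",
    "rd_log_bf_array",
    "priors_from_mutation_rate",
    "estimate_point_priors",
]


@dataclass
class RDPriors:
    """Priors on the de novo-draw probabilities p1 (risk) and p0 (non-risk).

    ``kind='point'``: p1, p0 are fixed fractions with 0 <= p0 < p1 <= 1.
    ``kind='beta'``: p1 ~ Beta(a1, b1), p0 ~ Beta(a0, b0), integrated out
    analytically in the likelihood.
    """

    kind: str = "point"
    p1: float | None = 0.603
    p0: float | None = 0.026
    a1: float | None = None
    b1: float | None = None
    a0: float | None = None
    b0: float | None = None
    gamma: float | None = None
    derived_from_mu: bool = False

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.p1 is None or self.p0 is None:
                raise ValueError("point priors require p1 and p0")
            # p0 == p1 is allowed as the degenerate no-contrast prior
            # (it yields BF = 1 for all counts)
            if not 0.0 <= self.p0 <= self.p1 <= 1.0:
                raise ValueError(f"need 0 <= p0 <= p1 <= 1, got p0={self.p0}, p1={self.p1}")
        elif self.kind == "beta":
            hyper = (self.a1, self.b1, self.a0, self.b0)
            if any(h is None or h <= 0 for h in hyper):
                raise ValueError("beta priors require positive a1, b1, a0, b0")
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.gamma is not None and not self.gamma > 1:
            raise ValueError("gamma must exceed 1")


@dataclass
class RDResult:
    """Per-gene Random Draw output: BF plus the corrected draw probabilities."""

    gene_id: str
    bf_rd: float
    log_bf_rd: float
    q1: float
    q0: float
    x_d: int
    x_h: int


def misclassified_param(p: float, w1: float, w2: float) -> float:
    """Probability a draw is *called* de novo given the true rate ``p``.

    q = w1*p + (1-w2)*(1-p): true de novo draws are caught with
    sensitivity w1, inherited draws leak in at the false-positive rate
    1-w2. A perfect classifier (w1=w2=1) returns p; an uninformative one
    (w1+w2=1) returns 1-w2 regardless of p.
    """
    for name, v in (("p", p), ("w1", w1), ("w2", w2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {v}")
    return w1 * p + (1.0 - w2) * (1.0 - p)


def _log_binom_point(x_d: int, x_h: int, q: float) -> float:
    """log q^x_d (1-q)^x_h, with the 0^0 = 1 convention."""
    out = 0.0
    if x_d:
        out += -math.inf if q == 0.0 else x_d * math.log(q)
    if x_h:
        out += -math.inf if q == 1.0 else x_h * math.log1p(-q)
    return out


def rd_likelihood(
    x_d: int,
    x_h: int,
    q: float | None = None,
    beta: tuple[float, float] | None = None,
) -> float:
    """Binomial likelihood of the observed draw composition.

    With a point parameter ``q``: C(x_d+x_h, x_d) q^x_d (1-q)^x_h. With
    ``beta=(a, b)``: the beta-binomial marginal, integrating q over
    Beta(a, b).
    """
    if x_d < 0 or x_h < 0:
        raise ValueError("counts must be nonnegative")
    n = x_d + x_h
    log_coef = (
        math.lgamma(n + 1) - math.lgamma(x_d + 1) - math.lgamma(x_h + 1)
    )
    if beta is not None:
        a, b = beta
        return math.exp(log_coef + betaln(a + x_d, b + x_h) - betaln(a, b))
    if q is None:
        raise ValueError("either q or beta must be given")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0,1], got {q}")
    lp = _log_binom_point(x_d, x_h, q)
    return 0.0 if lp == -math.inf else math.exp(log_coef + lp)


def rd_log_bayes_factor(
    x_d: int,
    x_h: int,
    w1: float,
    w2: float,
    priors: RDPriors,
) -> tuple[float, float, float]:
    """Natural-log Bayes factor plus the corrected parameters (q1, q0).

    The binomial coefficients cancel in the ratio. Under Beta priors the
    (w1, w2) correction is applied inside the integral: the marginal of
    each scenario is the beta-binomial in the *corrected* success
    probability, computed by transforming the Beta prior on p through
    q = w1 p + (1-w2)(1-p) via Gauss–Legendre quadrature when the
    correction is active, or analytically when w1 = w2 = 1.

    Degenerate corrected parameters (q in {0, 1}) yield +inf/-inf log-BFs
    with a warning rather than an exception. An anti-informative
    classifier (w1 + w2 < 1) flips the direction of evidence; a warning
    is emitted.
    """
    if w1 + w2 < 1.0:
        warnings.warn(
            "w1 + w2 < 1: classifier is anti-informative, evidence direction flips",
            stacklevel=2,
        )
    if x_d == 0 and x_h == 0:
        q_pt = misclassified_param(
            priors.p1 if priors.kind == "point" else 0.5, w1, w2
        )
        return 0.0, q_pt, q_pt

    if priors.kind == "point":
        q1 = misclassified_param(priors.p1, w1, w2)
        q0 = misclassified_param(priors.p0, w1, w2)
        log_l1 = _log_binom_point(x_d, x_h, q1)
        log_l0 = _log_binom_point(x_d, x_h, q0)
        if math.isinf(log_l0) or math.isinf(log_l1):
            warnings.warn(
                f"degenerate corrected parameter (q1={q1}, q0={q0}) with counts "
                f"(x_d={x_d}, x_h={x_h}): Bayes factor is 0 or infinite",
                stacklevel=2,
            )
            if math.isinf(log_l1) and math.isinf(log_l0):
                return 0.0, q1, q0  # both scenarios impossible: no evidence
            return (-math.inf if math.isinf(log_l1) else math.inf), q1, q0
        return log_l1 - log_l0, q1, q0

    # Beta priors
    if w1 == 1.0 and w2 == 1.0:
        log_l1 = betaln(priors.a1 + x_d, priors.b1 + x_h) - betaln(priors.a1, priors.b1)
        log_l0 = betaln(priors.a0 + x_d, priors.b0 + x_h) - betaln(priors.a0, priors.b0)
        q1 = priors.a1 / (priors.a1 + priors.b1)
        q0 = priors.a0 / (priors.a0 + priors.b0)
        return float(log_l1 - log_l0), q1, q0
    log_l1, q1 = _beta_marginal_corrected(x_d, x_h, priors.a1, priors.b1, w1, w2)
    log_l0, q0 = _beta_marginal_corrected(x_d, x_h, priors.a0, priors.b0, w1, w2)
    return log_l1 - log_l0, q1, q0


def _beta_marginal_corrected(
    x_d: int, x_h: int, a: float, b: float, w1: float, w2: float, n_nodes: int = 120
) -> tuple[float, float]:
    """Marginal log-likelihood integrating p ~ Beta(a,b) through the
    misclassification map.

    Gauss–Jacobi quadrature with the Beta density's endpoint weights
    p^(a-1) (1-p)^(b-1) folded into the rule, so hyperparameters below 1
    (integrable endpoint singularities) are handled exactly.
    """
    from scipy.special import roots_jacobi

    nodes, weights = roots_jacobi(n_nodes, b - 1.0, a - 1.0)
    p = 0.5 * (nodes + 1.0)
    q = w1 * p + (1.0 - w2) * (1.0 - p)
    with np.errstate(divide="ignore"):
        log_pmf = x_d * np.log(q) + x_h * np.log1p(-q)
    # ∫ p^(a-1)(1-p)^(b-1) f(p) dp = 2^(1-a-b) Σ w_i f(p_i)
    log_scale = (1.0 - a - b) * math.log(2.0) - betaln(a, b)
    val = float(np.sum(weights * np.exp(log_pmf)))
    q_mean = misclassified_param(a / (a + b), w1, w2)
    if val <= 0.0:
        return -math.inf, q_mean
    return log_scale + math.log(val), q_mean


def rd_bayes_factor(
    counts: GeneCounts,
    perf: ClassifierPerformance,
    priors: RDPriors,
) -> RDResult:
    """Random Draw Bayes factor for one gene.

    Genes with no classified variants carry no draw evidence and receive
    BF = 1.
    """
    log_bf, q1, q0 = rd_log_bayes_factor(
        counts.x_d, counts.x_h, perf.w1, perf.w2, priors
    )
    if math.isinf(log_bf):
        bf = math.inf if log_bf > 0 else 0.0
    else:
        bf = math.exp(log_bf)
    return RDResult(
        gene_id=counts.gene_id,
        bf_rd=bf,
        log_bf_rd=log_bf,
        q1=q1,
        q0=q0,
        x_d=counts.x_d,
        x_h=counts.x_h,
    )


def rd_bayes_factors(
    counts: Sequence[GeneCounts],
    perf: ClassifierPerformance,
    priors: RDPriors,
) -> list[RDResult]:
    return [rd_bayes_factor(c, perf, priors) for c in counts]


def rd_log_bf_array(
    x_d: np.ndarray,
    x_h: np.ndarray,
    w1: float,
    w2: float,
    priors: RDPriors,
) -> np.ndarray:
    """Vectorized point-prior log Bayes factor over many genes.

    Same quantity as :func:`rd_log_bayes_factor` with point priors,
    evaluated for arrays of counts (used by the simulation studies, where
    tens of thousands of genes are scored per replicate). Genes with no
    classified variants get log BF = 0.
    """
    if priors.kind != "point":
        raise ValueError("vectorized path supports point priors only")
    x_d = np.asarray(x_d, dtype=float)
    x_h = np.asarray(x_h, dtype=float)
    q1 = misclassified_param(priors.p1, w1, w2)
    q0 = misclassified_param(priors.p0, w1, w2)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_bf = x_d * (np.log(q1) - np.log(q0)) + x_h * (
            np.log1p(-q1) - np.log1p(-q0)
        )
    return np.where((x_d == 0) & (x_h == 0), 0.0, log_bf)


def priors_from_mutation_rate(
    gene: GeneEntry,
    gamma: float,
    inherited_rate: float,
) -> RDPriors:
    """Map a gene's mutation rate to point priors via competing rates.

    De novo variants arrive at rate mu (non-risk) or gamma*mu (risk);
    inherited variants at a per-gene rate ``inherited_rate`` (nu). The
    probability that a random draw is de novo is the rate ratio
    p = dn / (dn + nu), so p0 = mu/(mu+nu) and p1 = gamma*mu/(gamma*mu+nu);
    gamma > 1 guarantees p1 > p0, and jointly rescaling mu and nu leaves
    both unchanged.
    """
    if not gamma > 1:
        raise ValueError("gamma must exceed 1")
    if not inherited_rate > 0:
        raise ValueError("inherited_rate must be positive")
    mu = gene.mu
    p0 = mu / (mu + inherited_rate)
    p1 = gamma * mu / (gamma * mu + inherited_rate)
    return RDPriors(kind="point", p1=p1, p0=p0, gamma=gamma, derived_from_mu=True)


def estimate_point_priors(
    n_dn_risk: int,
    n_total_risk: int,
    n_dn_nonrisk: int,
    n_total_nonrisk: int,
) -> RDPriors:
    """Point priors from labeled family data: risk-stratified de novo fractions."""
    if n_total_risk <= 0 or n_total_nonrisk <= 0:
        raise ValueError("totals must be positive")
    p1 = n_dn_risk / n_total_risk
    p0 = n_dn_nonrisk / n_total_nonrisk
    return RDPriors(kind="point", p1=p1, p0=p0)
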