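"""Null (PFER) and power simulation studies for the Random Draw model.

Two designs probe the method end to end on synthetic gene tables:

* **Null**: case variants carry no association signal — every gene's
  variants are de novo at the background (non-risk) rate regardless of
  risk status. Family-based BFs still carry real signal, so the question
  is whether adding Random Draw evidence from null case data inflates the
  number of false gene selections (the per-family error rate, PFER).
* **Power**: the de novo fraction of each gene's case variants is set by
  its risk status (0.603 for risk genes, 0.026 otherwise), and the mean
  number of q < 0.05 discoveries is compared with the family-only count.

In both designs each variant receives a raw Gaussian de novo score —
Normal(0.6, 0.1) for de novo, Normal(0.2, 0.1) for inherited — and is
called likely de novo when the score strictly exceeds the threshold c.
Because the score distributions are known, the sensitivity w1 and
specificity w2 at any threshold follow analytically from the two normal
tails; the published operating points at c in {0.3, 0.5, 0.7, 0.9} are
(0.829, 0.624), (0.624, 0.829), (0.376, 0.943) and (0.171, 0.987).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gene_discovery import bayesian_fdr, qvalues_to_pvalues
from .random_draw import RDPriors, rd_log_bf_array
from .synthetic_data import ScoreModel, round_half_away
from .variant_io import GeneEntry

__all__ = [
    "SimulationConfig",
    "SimulationReport",
    "analytic_w1_w2",
    "simulate_power_rep",
    "run_power_study",
    "simulate_null_rep",
    "run_null_study",
    "family_only_discoveries",
]


@dataclass
class SimulationConfig:
    """Shared knobs for the null and power studies."""

    thresholds: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    n_reps: int = 100
    score_model: ScoreModel = field(default_factory=ScoreModel)
    dn_fraction_risk: float = 0.603
    dn_fraction_nonrisk: float = 0.026
    pi1: float = 0.06
    q_cut: float = 0.05
    bonferroni_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.thresholds:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"threshold {c} outside [0,1]")
        for name in ("dn_fraction_risk", "dn_fraction_nonrisk", "pi1", "q_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class SimulationReport:
    """Per-threshold summary of a simulation study."""

    table: pd.DataFrame  # columns: c, w1, w2, and the study's metrics
    family_only_discoveries: int | None = None
    family_only_pfer_bonferroni: float | None = None
    family_only_pfer_qvalue: float | None = None


def analytic_w1_w2(c: float, model: ScoreModel | None = None) -> tuple[float, float]:
    """Sensitivity and specificity of thresholding Gaussian scores at c.

    w1 = P(score > c | de novo) = 1 - Phi((c - m_dn)/sd_dn) and
    w2 = P(score <= c | inherited) = Phi((c - m_inh)/sd_inh).
    """
    model = model or ScoreModel()
    w1 = float(norm.sf(c, loc=model.dn_mean, scale=np.sqrt(model.dn_var)))
    w2 = float(norm.cdf(c, loc=model.inh_mean, scale=np.sqrt(model.inh_var)))
    return w1, w2


def _gene_arrays(
    genes: Sequence[GeneEntry],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts = np.array(
        [0 if g.case_variant_count is None else g.case_variant_count for g in genes]
    )
    risk = np.array([bool(g.risk_label) for g in genes])
    fbf = np.array(
        [1.0 if g.family_bf is None else g.family_bf for g in genes]
    )
    return counts, risk, fbf


def _classified_counts(
    n_dn: np.ndarray,
    n_inh: np.ndarray,
    model: ScoreModel,
    c: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a Gaussian score per variant and tally calls per gene.

    Scores are raw (unclamped) normals; a variant is called likely de
    novo iff its score strictly exceeds c.
    """
    n_genes = len(n_dn)
    gene_of_dn = np.repeat(np.arange(n_genes), n_dn)
    gene_of_inh = np.repeat(np.arange(n_genes), n_inh)
    s_dn = rng.normal(model.dn_mean, np.sqrt(model.dn_var), size=len(gene_of_dn))
    s_inh = rng.normal(model.inh_mean, np.sqrt(model.inh_var), size=len(gene_of_inh))
    x_d = np.bincount(gene_of_dn[s_dn > c], minlength=n_genes) + np.bincount(
        gene_of_inh[s_inh > c], minlength=n_genes
    )
    total = n_dn + n_inh
    return x_d, total - x_d


def _combined_qvalues(
    x_d: np.ndarray,
    x_h: np.ndarray,
    fbf: np.ndarray,
    c: float,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """RD log-BFs at the analytic (w1, w2), floored combination, q and p."""
    w1, w2 = analytic_w1_w2(c, cfg.score_model)
    priors = RDPriors(
        kind="point", p1=cfg.dn_fraction_risk, p0=cfg.dn_fraction_nonrisk
    )
    bf_rd = np.exp(rd_log_bf_array(x_d, x_h, w1, w2, priors))
    bf_final = np.maximum(1.0, bf_rd) * np.maximum(1.0, fbf)
    _, q = bayesian_fdr(bf_final, cfg.pi1)
    p = qvalues_to_pvalues(q)
    return q, p


def simulate_power_rep(
    genes: Sequence[GeneEntry],
    cfg: SimulationConfig,
    c: float,
    seed: int,
) -> int:
    """One power replicate: number of q < q_cut discoveries at threshold c.

    Per gene, the number of de novo case variants is the de novo fraction
    (by risk status) times the gene's case variant count, rounded half
    away from zero and lower-bounded by zero; the remainder is inherited.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    counts, risk, fbf = _gene_arrays(genes)
    frac = np.where(risk, cfg.dn_fraction_risk, cfg.dn_fraction_nonrisk)
    n_dn = np.minimum(round_half_away(frac * counts), counts)
    n_inh = counts - n_dn
    rng = np.random.default_rng(seed)
    x_d, x_h = _classified_counts(n_dn, n_inh, cfg.score_model, c, rng)
    q, _ = _combined_qvalues(x_d, x_h, fbf, c, cfg)
    return int(np.sum(q < cfg.q_cut))


def family_only_discoveries(
    genes: Sequence[GeneEntry], cfg: SimulationConfig
) -> int:
    """Discoveries from family-based BFs alone (floored at 1)."""
    _, _, fbf = _gene_arrays(genes)
    _, q = bayesian_fdr(np.maximum(1.0, fbf), cfg.pi1)
    return int(np.sum(q < cfg.q_cut))


def run_power_study(
    genes: Sequence[GeneEntry], cfg: SimulationConfig
) -> SimulationReport:
    """Mean discoveries over replicates at each threshold."""
    rows = []
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = ss.generate_state(cfg.n_reps * len(cfg.thresholds)) % (2**31)
    k = 0
    for c in cfg.thresholds:
        w1, w2 = analytic_w1_w2(c, cfg.score_model)
        disc = []
        for _ in range(cfg.n_reps):
            disc.append(simulate_power_rep(genes, cfg, c, int(rep_seeds[k])))
            k += 1
        rows.append(
            {"c": c, "w1": w1, "w2": w2, "mean_discoveries": float(np.mean(disc))}
        )
    return SimulationReport(
        table=pd.DataFrame(rows),
        family_only_discoveries=family_only_discoveries(genes, cfg),
    )


def simulate_null_rep(
    genes: Sequence[GeneEntry],
    cfg: SimulationConfig,
    c: float,
    seed: int,
    force_rd_to_one: bool = False,
) -> tuple[int, int]:
    """One null replicate: false selections under (Bonferroni, q-value).

    The null case data carry no signal: every gene's variants are de novo
    at the background fraction, independent of risk status. Family BFs
    retain their (real) signal; false selections are selected genes
    outside the risk-gene truth set. ``force_rd_to_one`` disables the RD
    contribution, recovering the family-only benchmark.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    counts, risk, fbf = _gene_arrays(genes)
    rng = np.random.default_rng(seed)
    n_dn = rng.binomial(counts, cfg.dn_fraction_nonrisk)
    n_inh = counts - n_dn
    x_d, x_h = _classified_counts(n_dn, n_inh, cfg.score_model, c, rng)
    if force_rd_to_one:
        x_d = np.zeros_like(x_d)
        x_h = np.zeros_like(x_h)
    q, p = _combined_qvalues(x_d, x_h, fbf, c, cfg)
    n = len(genes)
    sel_bonf = p < cfg.bonferroni_alpha / n
    sel_q = q < cfg.q_cut
    false_bonf = int(np.sum(sel_bonf & ~risk))
    false_q = int(np.sum(sel_q & ~risk))
    return false_bonf, false_q


def run_null_study(
    genes: Sequence[GeneEntry],
    cfg: SimulationConfig,
    force_rd_to_one: bool = False,
) -> SimulationReport:
    """Mean PFER over replicates at each threshold, plus the family-only
    benchmark PFERs."""
    counts, risk, fbf = _gene_arrays(genes)
    # family-only benchmark: RD plays no part, so it is replicate-free
    _, q0 = bayesian_fdr(np.maximum(1.0, fbf), cfg.pi1)
    p0 = qvalues_to_pvalues(q0)
    fam_bonf = int(np.sum((p0 < cfg.bonferroni_alpha / len(genes)) & ~risk))
    fam_q = int(np.sum((q0 < cfg.q_cut) & ~risk))
    rows = []
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = ss.generate_state(cfg.n_reps * len(cfg.thresholds)) % (2**31)
    k = 0
    for c in cfg.thresholds:
        w1, w2 = analytic_w1_w2(c, cfg.score_model)
        bonf, qv = [], []
        for _ in range(cfg.n_reps):
            fb, fq = simulate_null_rep(
                genes, cfg, c, int(rep_seeds[k]), force_rd_to_one=force_rd_to_one
            )
            bonf.append(fb)
            qv.append(fq)
            k += 1
        rows.append(
            {
                "c": c,
                "w1": w1,
                "w2": w2,
                "mean_pfer_bonferroni": float(np.mean(bonf)),
                "mean_pfer_qvalue": float(np.mean(qv)),
            }
        )
    return SimulationReport(
        table=pd.DataFrame(rows),
        family_only_pfer_bonferroni=float(fam_bonf),
        family_only_pfer_qvalue=float(fam_q),
    )
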