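"""Synthetic cohorts with the statistical structure the method assumes.

Real SPARK/ASC family and case cohorts are not redistributable, so this
module generates stand-ins: labeled family-based variant tables (known
inheritance class), unlabeled case-only tables with hidden truth, Gaussian
de novo scores, and per-gene tables with mutation rates, family-based
Bayes factors and risk status.

The class-conditional covariate distributions reproduce the qualitative
separation seen in real trio data: relative to inherited variants, de novo
variants have lower population allele frequency, lower LOEUF (more
constrained genes), higher CCR, lower FDR_TADA_DD (stronger prior
DD/NDD-risk evidence), lower observed LoF counts and higher expected LoF
counts. The parametric families are chosen for support-correctness (each
covariate stays inside its legal range); only the direction of separation
is constrained by the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .variant_io import (
    GeneEntry,
    InheritanceLabel,
    PredictedClass,
    VariantRecord,
)

__all__ = [
    "CovariateParams",
    "CovariateModel",
    "ScoreModel",
    "round_half_away",
    "generate_family_variants",
    "generate_case_only_variants",
    "draw_scores",
    "generate_gene_table",
    "separable_covariate_model",
]


def round_half_away(x) -> np.ndarray | int:
    """Round half away from zero, lower-bounded by zero.

    De novo counts derived from fractions are "rounded to the nearest
    integer, and lower bounded by zero"; the half-case convention is fixed
    here (0.5 -> 1) for reproducibility.
    """
    arr = np.asarray(x, dtype=float)
    out = np.maximum(0, np.sign(arr) * np.floor(np.abs(arr) + 0.5)).astype(int)
    return int(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class CovariateParams:
    """Class-conditional distribution parameters for the six covariates.

    af: point mass at 0 (absent from gnomAD) with probability ``af_zero``,
    else log-uniform on [af_lo, af_hi). loeuf: normal(mean, sd) truncated
    to [0, 2]. ccr: point mass at 0 with probability ``ccr_zero``, else
    uniform on (0, 100]. fdr_tada_dd: Beta(a, b). obs_lof: Poisson(lam).
    exp_lof: gamma(shape, scale).
    """

    af_zero: float
    af_lo: float
    af_hi: float
    loeuf_mean: float
    loeuf_sd: float
    ccr_zero: float
    fdr_a: float
    fdr_b: float
    obs_lam: float
    exp_shape: float
    exp_scale: float

    def draw(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        af = np.exp(
            rng.uniform(np.log(self.af_lo), np.log(self.af_hi), size=n)
        )
        af[rng.random(n) < self.af_zero] = 0.0
        a = (0.0 - self.loeuf_mean) / self.loeuf_sd
        b = (2.0 - self.loeuf_mean) / self.loeuf_sd
        loeuf = stats.truncnorm.rvs(
            a, b, loc=self.loeuf_mean, scale=self.loeuf_sd, size=n, random_state=rng
        )
        ccr = rng.uniform(0.0, 100.0, size=n)
        ccr[rng.random(n) < self.ccr_zero] = 0.0
        fdr = rng.beta(self.fdr_a, self.fdr_b, size=n)
        obs = rng.poisson(self.obs_lam, size=n).astype(float)
        exp = rng.gamma(self.exp_shape, self.exp_scale, size=n)
        return {
            "af": af,
            "loeuf": loeuf,
            "ccr": ccr,
            "fdr_tada_dd": fdr,
            "obs_lof": obs,
            "exp_lof": exp,
        }


def _default_de_novo() -> CovariateParams:
    return CovariateParams(
        af_zero=0.70, af_lo=1e-6, af_hi=1e-3,
        loeuf_mean=0.45, loeuf_sd=0.40,
        ccr_zero=0.35,
        fdr_a=0.8, fdr_b=1.5,
        obs_lam=5.0, exp_shape=5.0, exp_scale=4.0,
    )


def _default_inherited() -> CovariateParams:
    return CovariateParams(
        af_zero=0.45, af_lo=1e-6, af_hi=1e-3,
        loeuf_mean=0.85, loeuf_sd=0.45,
        ccr_zero=0.55,
        fdr_a=1.5, fdr_b=1.0,
        obs_lam=10.0, exp_shape=4.0, exp_scale=3.5,
    )


@dataclass
class CovariateModel:
    """Pair of class-conditional covariate distributions plus a seed."""

    de_novo: CovariateParams = field(default_factory=_default_de_novo)
    inherited: CovariateParams = field(default_factory=_default_inherited)
    seed: int = 0


def separable_covariate_model(seed: int = 0) -> CovariateModel:
    """A model whose two classes have disjoint LOEUF/exp_lof supports.

    Useful for tests: any reasonable learner separates the classes almost
    perfectly.
    """
    dn = replace(_default_de_novo(), loeuf_mean=0.15, loeuf_sd=0.05,
                 exp_shape=400.0, exp_scale=0.25)  # loeuf ~ [0, 0.4], exp ~ 100
    inh = replace(_default_inherited(), loeuf_mean=1.6, loeuf_sd=0.05,
                  exp_shape=100.0, exp_scale=0.05)  # loeuf ~ [1.4, 2], exp ~ 5
    return CovariateModel(de_novo=dn, inherited=inh, seed=seed)


@dataclass
class ScoreModel:
    """Gaussian de novo score model used in the validation simulations.

    Scores for de novo variants are Normal(dn_mean, dn_var) and for
    inherited variants Normal(inh_mean, inh_var); defaults follow the
    validation setting (means 0.6 / 0.2, common variance 0.1). Raw draws
    are kept unclamped; thresholding happens at classification.
    """

    dn_mean: float = 0.6
    dn_var: float = 0.1
    inh_mean: float = 0.2
    inh_var: float = 0.1

    def __post_init__(self) -> None:
        if not (self.dn_var > 0 and self.inh_var > 0):
            raise ValueError("score variances must be positive")
        if not self.dn_mean > self.inh_mean:
            raise ValueError("de novo score mean must exceed inherited mean")


def _make_records(
    covs: dict[str, np.ndarray],
    genes: np.ndarray,
    labels: Sequence[InheritanceLabel],
    prefix: str,
    start: int = 0,
) -> list[VariantRecord]:
    return [
        VariantRecord(
            variant_id=f"{prefix}{start + i:06d}",
            gene_id=str(genes[i]),
            af=float(covs["af"][i]),
            loeuf=float(covs["loeuf"][i]),
            ccr=float(covs["ccr"][i]),
            fdr_tada_dd=float(covs["fdr_tada_dd"][i]),
            obs_lof=float(covs["obs_lof"][i]),
            exp_lof=float(covs["exp_lof"][i]),
            inheritance_label=labels[i],
            predicted_class=PredictedClass.UNSET,
        )
        for i in range(len(genes))
    ]


def generate_family_variants(
    n_de_novo: int,
    n_inherited: int,
    model: CovariateModel,
    genes: Sequence[GeneEntry],
    seed: int | None = None,
    risk_gamma: float = 20.0,
) -> list[VariantRecord]:
    """Generate a labeled family-based cohort.

    De novo variants are assigned to genes proportionally to the baseline
    mutation rate mu, multiplied by ``risk_gamma`` for risk genes — in an
    affected cohort, de novo hits concentrate in risk genes because the
    relative risk gamma scales their mutation contribution to liability.
    Inherited variants are assigned uniformly. A realistic cohort has
    roughly thirty times more rare inherited than de novo variants.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    if n_de_novo < 0 or n_inherited < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    gene_ids = np.array([g.gene_id for g in genes])
    mu = np.array([g.mu for g in genes])
    risk = np.array([bool(g.risk_label) for g in genes])
    w = mu * np.where(risk, risk_gamma, 1.0)
    dn_genes = rng.choice(gene_ids, size=n_de_novo, p=w / w.sum())
    inh_genes = rng.choice(gene_ids, size=n_inherited)
    dn_covs = model.de_novo.draw(n_de_novo, rng)
    inh_covs = model.inherited.draw(n_inherited, rng)
    records = _make_records(
        dn_covs, dn_genes, [InheritanceLabel.DE_NOVO] * n_de_novo, "fam"
    )
    records += _make_records(
        inh_covs,
        inh_genes,
        [InheritanceLabel.INHERITED] * n_inherited,
        "fam",
        start=n_de_novo,
    )
    return records


def generate_case_only_variants(
    n_variants: int,
    de_novo_fraction: float,
    model: CovariateModel,
    genes: Sequence[GeneEntry],
    seed: int | None = None,
    risk_fractions: tuple[float, float] | None = None,
) -> tuple[list[VariantRecord], list[InheritanceLabel]]:
    """Generate an unlabeled case-only cohort plus its hidden truth.

    Records carry ``inheritance_label=unknown``; the true labels are
    returned alongside for evaluation. In the default (global) mode
    exactly ``round_half_away(n_variants * de_novo_fraction)`` variants
    are de novo. When ``risk_fractions=(f_risk, f_nonrisk)`` is given and
    the gene table carries risk labels, variants are assigned to genes
    first and each gene receives ``round_half_away(f * n_gene)`` de novo
    variants with f chosen by its risk status — mirroring the power
    simulation design (risk fraction 0.603, non-risk 0.026).
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    if not 0.0 <= de_novo_fraction <= 1.0:
        raise ValueError("de_novo_fraction must lie in [0,1]")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    gene_ids = np.array([g.gene_id for g in genes])
    assigned = rng.choice(len(genes), size=n_variants)
    is_dn = np.zeros(n_variants, dtype=bool)
    if risk_fractions is None:
        n_dn = round_half_away(n_variants * de_novo_fraction)
        if n_dn > 0:
            is_dn[rng.choice(n_variants, size=n_dn, replace=False)] = True
    else:
        f_risk, f_nonrisk = risk_fractions
        for gi in np.unique(assigned):
            members = np.flatnonzero(assigned == gi)
            frac = f_risk if genes[gi].risk_label else f_nonrisk
            k = min(round_half_away(frac * len(members)), len(members))
            if k > 0:
                is_dn[rng.choice(members, size=k, replace=False)] = True
    hidden = [
        InheritanceLabel.DE_NOVO if d else InheritanceLabel.INHERITED for d in is_dn
    ]
    n_dn_total = int(is_dn.sum())
    dn_covs = model.de_novo.draw(n_dn_total, rng)
    inh_covs = model.inherited.draw(n_variants - n_dn_total, rng)
    covs = {}
    for key in dn_covs:
        col = np.empty(n_variants)
        col[is_dn] = dn_covs[key]
        col[~is_dn] = inh_covs[key]
        covs[key] = col
    records = _make_records(
        covs,
        gene_ids[assigned],
        [InheritanceLabel.UNKNOWN] * n_variants,
        "case",
    )
    return records, hidden


def draw_scores(
    labels: Sequence[InheritanceLabel],
    model: ScoreModel,
    seed: int,
) -> np.ndarray:
    """Draw raw Gaussian de novo scores conditional on true labels."""
    rng = np.random.default_rng(seed)
    labels = np.asarray([lab == InheritanceLabel.DE_NOVO for lab in labels])
    scores = np.empty(len(labels))
    scores[labels] = rng.normal(
        model.dn_mean, np.sqrt(model.dn_var), size=int(labels.sum())
    )
    scores[~labels] = rng.normal(
        model.inh_mean, np.sqrt(model.inh_var), size=int((~labels).sum())
    )
    return scores


def generate_gene_table(
    n_genes: int,
    risk_fraction: float,
    mu_model: tuple[float, float] = (np.log(2e-6), 1.0),
    bf_model: dict | None = None,
    seed: int = 0,
    mean_case_variants: float = 0.75,
) -> list[GeneEntry]:
    """Generate a per-gene table with mutation rates, family BFs and risk.

    ``round_half_away(n_genes * risk_fraction)`` genes are flagged as risk
    genes. Mutation rates are log-normal (parameters on the log scale,
    default centred on a typical per-gene PTV rate of ~2e-6). Family-based
    Bayes factors are log-normal with a much larger location for risk
    genes, so that a strong minority of risk genes clears genome-wide
    evidence thresholds, as in real trio cohorts. ``case_variant_count``
    is Poisson with mean ``mean_case_variants`` (about 0.75 case PTVs per
    gene matches an exome-wide cohort of ~13k ultra-rare PTVs over ~18k
    genes).
    """
    if not 0.0 <= risk_fraction <= 1.0:
        raise ValueError("risk_fraction must lie in [0,1]")
    bf = {"risk_logmean": 3.0, "risk_logsd": 2.0,
          "nonrisk_logmean": -0.5, "nonrisk_logsd": 0.8}
    if bf_model:
        bf.update(bf_model)
    rng = np.random.default_rng(seed)
    n_risk = round_half_away(n_genes * risk_fraction)
    risk = np.zeros(n_genes, dtype=bool)
    risk[:n_risk] = True
    rng.shuffle(risk)
    mu = rng.lognormal(mu_model[0], mu_model[1], size=n_genes)
    fbf = np.where(
        risk,
        rng.lognormal(bf["risk_logmean"], bf["risk_logsd"], size=n_genes),
        rng.lognormal(bf["nonrisk_logmean"], bf["nonrisk_logsd"], size=n_genes),
    )
    counts = rng.poisson(mean_case_variants, size=n_genes)
    return [
        GeneEntry(
            gene_id=f"G{i:05d}",
            mu=float(mu[i]),
            family_bf=float(fbf[i]),
            risk_label=bool(risk[i]),
            case_variant_count=int(counts[i]),
        )
        for i in range(n_genes)
    ]
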