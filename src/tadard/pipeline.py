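"""End-to-end orchestration of the two analysis pipelines.

Pipeline one trains ClassDn on a labeled family-based cohort and learns
its operating characteristics (w1, w2) at the chosen threshold on a
disjoint labeled test cohort. Pipeline two scores case-only variants,
classifies them, aggregates likely-de-novo / likely-inherited counts per
gene, computes Random Draw Bayes factors, combines them with family-based
BFs, and selects risk genes by Bayesian FDR. Every run writes a manifest
recording the configuration hash, seed, inputs and package version, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classdn import (
    classify_records,
    evaluate,
    score_records,
    threshold_sweep,
    train,
)
from .gene_discovery import integrate, results_to_frame
from .random_draw import RDPriors, estimate_point_priors, rd_bayes_factors
from .variant_io import (
    InheritanceLabel,
    PredictedClass,
    aggregate_gene_counts,
    filter_ultra_rare,
    read_gene_table,
    read_variant_table,
    write_variant_table,
)

logger = logging.getLogger("tadard")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for a full run."""

    train_path: str
    test_path: str
    case_path: str
    gene_path: str
    out_dir: str
    algorithm: str = "rusboost"
    threshold_c: float = 0.7
    n_estimators: int = 100
    base_learner_depth: int = 3
    af_max: float = 0.001
    pi1: float = 0.06
    q_cut: float = 0.05
    bonferroni_alpha: float = 0.05
    seed: int = 0
    # point priors for the RD model; None means estimate from the
    # labeled family data by risk-stratified de novo fractions
    p1: float | None = None
    p0: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_c <= 1.0:
            raise ValueError("threshold_c must lie in [0,1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - report stage + cause
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def _estimate_priors(train_records, genes) -> RDPriors:
    """Risk-stratified de novo fractions from the labeled family cohort.

    Genes with a family BF above 1 (or an explicit risk label) form the
    risk stratum; the de novo fraction of variants falling in each
    stratum gives (p1, p0). If the stratified estimate is degenerate
    (p1 <= p0, e.g. too little labeled data), the defaults (0.603, 0.026)
    are used instead with a warning.
    """
    risk_genes = {
        g.gene_id
        for g in genes
        if (g.risk_label is True)
        or (g.risk_label is None and g.family_bf is not None and g.family_bf > 1)
    }
    dn_r = tot_r = dn_n = tot_n = 0
    for r in train_records:
        is_dn = r.inheritance_label is InheritanceLabel.DE_NOVO
        if r.gene_id in risk_genes:
            tot_r += 1
            dn_r += is_dn
        else:
            tot_n += 1
            dn_n += is_dn
    try:
        return estimate_point_priors(dn_r, max(tot_r, 1), dn_n, max(tot_n, 1))
    except ValueError:
        logger.warning(
            "risk-stratified prior estimate degenerate (p1 <= p0); "
            "falling back to default point priors"
        )
        return RDPriors()


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full workflow; returns paths of the written artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    @_stage("load")
    def load():
        train_rec = filter_ultra_rare(read_variant_table(cfg.train_path), cfg.af_max)
        test_rec = filter_ultra_rare(read_variant_table(cfg.test_path), cfg.af_max)
        case_rec = filter_ultra_rare(read_variant_table(cfg.case_path), cfg.af_max)
        genes = read_gene_table(cfg.gene_path)
        return train_rec, test_rec, case_rec, genes

    train_rec, test_rec, case_rec, genes = load()

    @_stage("train")
    def fit():
        return train(
            train_rec,
            algorithm=cfg.algorithm,
            n_estimators=cfg.n_estimators,
            base_learner_depth=cfg.base_learner_depth,
            seed=cfg.seed,
        )

    model = fit()

    @_stage("evaluate")
    def perf_table():
        grid = [round(0.05 * k, 2) for k in range(1, 20)]
        if cfg.threshold_c not in grid:
            grid = sorted(set(grid) | {cfg.threshold_c})
        sweep = threshold_sweep(model, test_rec, grid)
        df = pd.DataFrame(
            {
                "threshold_c": [p.threshold_c for p in sweep],
                "w1": [p.w1 for p in sweep],
                "w2": [p.w2 for p in sweep],
                "n_de_novo_eval": [p.n_de_novo_eval for p in sweep],
                "n_inherited_eval": [p.n_inherited_eval for p in sweep],
            }
        )
        path = out / "performance.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        chosen = next(p for p in sweep if p.threshold_c == cfg.threshold_c)
        return chosen, path

    perf, perf_path = perf_table()
    artifacts["performance"] = perf_path

    @_stage("score")
    def score_cases():
        scored = score_records(model, case_rec)
        classified = classify_records(scored, cfg.threshold_c)
        path = out / "scored_case_variants.tsv"
        write_variant_table(classified, path)
        return classified, path

    classified, scored_path = score_cases()
    artifacts["scored_case_variants"] = scored_path

    @_stage("random_draw")
    def rd():
        counts = aggregate_gene_counts(classified)
        if cfg.p1 is not None and cfg.p0 is not None:
            priors = RDPriors(kind="point", p1=cfg.p1, p0=cfg.p0)
        else:
            priors = _estimate_priors(train_rec, genes)
        results = rd_bayes_factors(counts, perf, priors)
        df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in results],
                "x_d": [r.x_d for r in results],
                "x_h": [r.x_h for r in results],
                "bf_rd": [r.bf_rd for r in results],
                "log_bf_rd": [r.log_bf_rd for r in results],
            }
        )
        path = out / "rd_bf.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return {r.gene_id: r.bf_rd for r in results}, priors, path

    rd_bfs, priors, rd_path = rd()
    artifacts["rd_bf"] = rd_path

    @_stage("integrate")
    def combine():
        family_bfs = {
            g.gene_id: g.family_bf for g in genes if g.family_bf is not None
        }
        results = integrate(
            rd_bfs,
            family_bfs,
            pi1=cfg.pi1,
            q_cut=cfg.q_cut,
            bonferroni_alpha=cfg.bonferroni_alpha,
        )
        path = out / "gene_results.tsv"
        results_to_frame(results).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
        return results, path

    results, results_path = combine()
    artifacts["gene_results"] = results_path

    @_stage("manifest")
    def manifest():
        payload = {
            "package": "tadard",
            "version": __version__,
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "inputs": {
                "train": cfg.train_path,
                "test": cfg.test_path,
                "case": cfg.case_path,
                "genes": cfg.gene_path,
            },
            "priors": {"kind": priors.kind, "p1": priors.p1, "p0": priors.p0},
            "performance_at_threshold": {
                "threshold_c": perf.threshold_c,
                "w1": perf.w1,
                "w2": perf.w2,
            },
            "n_selected_fdr": int(sum(bool(r.selected_fdr) for r in results)),
            "n_selected_bonferroni": int(
                sum(bool(r.selected_bonferroni) for r in results)
            ),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    artifacts["manifest"] = manifest()
    return artifacts
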