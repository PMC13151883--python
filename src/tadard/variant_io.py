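"""Reading, validation, filtering and aggregation of annotated variant tables.

The package consumes pre-annotated, tab-separated tables: one row per
offspring variant carrying the six covariates used for inheritance-class
inference (allele frequency, LOEUF, CCR, FDR_TADA_DD, obs_lof, exp_lof),
plus per-gene tables with baseline mutation rates and, optionally,
family-based Bayes factors. Everything downstream consumes the types
defined here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "InheritanceLabel",
    "PredictedClass",
    "VariantRecord",
    "GeneEntry",
    "GeneCounts",
    "COVARIATES",
    "DEFAULT_SCHEMA",
    "SchemaError",
    "RowParseError",
    "read_variant_table",
    "write_variant_table",
    "variants_to_frame",
    "frame_to_variants",
    "read_gene_table",
    "write_gene_table",
    "filter_ultra_rare",
    "aggregate_gene_counts",
]

#: Covariates used by the inheritance-class classifier, in canonical order.
COVARIATES = ("af", "loeuf", "ccr", "fdr_tada_dd", "obs_lof", "exp_lof")


class InheritanceLabel(str, enum.Enum):
    """True inheritance class of a variant (indicator I: 1 = de novo)."""

    DE_NOVO = "de_novo"
    INHERITED = "inherited"
    UNKNOWN = "unknown"


class PredictedClass(str, enum.Enum):
    """Classifier-predicted inheritance class (indicator X)."""

    LIKELY_DE_NOVO = "likely_de_novo"
    LIKELY_INHERITED = "likely_inherited"
    UNSET = "unset"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowParseError(ValueError):
    """A cell in a data row could not be parsed."""


@dataclass
class VariantRecord:
    """One offspring variant with the six classifier covariates.

    Missing covariates are represented as ``nan`` (``af`` missing means
    the variant is absent from the population reference and is treated as
    frequency 0 by the ultra-rare filter).
    """

    variant_id: str
    gene_id: str
    af: float = math.nan
    loeuf: float = math.nan
    ccr: float = math.nan
    fdr_tada_dd: float = math.nan
    obs_lof: float = math.nan
    exp_lof: float = math.nan
    inheritance_label: InheritanceLabel = InheritanceLabel.UNKNOWN
    de_novo_score: float | None = None
    predicted_class: PredictedClass = PredictedClass.UNSET

    def __post_init__(self) -> None:
        if not math.isnan(self.af) and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"af out of [0,1] for {self.variant_id}: {self.af}")
        if not math.isnan(self.ccr) and not 0.0 <= self.ccr <= 100.0:
            raise ValueError(f"ccr out of [0,100] for {self.variant_id}: {self.ccr}")
        if not math.isnan(self.fdr_tada_dd) and not 0.0 <= self.fdr_tada_dd <= 1.0:
            raise ValueError(
                f"fdr_tada_dd out of [0,1] for {self.variant_id}: {self.fdr_tada_dd}"
            )
        if self.de_novo_score is not None and not 0.0 <= self.de_novo_score <= 1.0:
            raise ValueError(
                f"de_novo_score out of [0,1] for {self.variant_id}: {self.de_novo_score}"
            )
        if (
            self.predicted_class is not PredictedClass.UNSET
            and self.de_novo_score is None
        ):
            raise ValueError(
                f"predicted_class set without de_novo_score for {self.variant_id}"
            )

    def with_score(
        self, score: float, predicted: PredictedClass | None = None
    ) -> "VariantRecord":
        return replace(
            self,
            de_novo_score=score,
            predicted_class=predicted if predicted is not None else self.predicted_class,
        )


@dataclass
class GeneEntry:
    """Per-gene annotation: baseline mutation rate and optional evidence.

    ``mu`` is the gene's baseline probability of a de novo mutation per
    offspring; ``family_bf`` is the gene's Bayes factor from family-based
    (trio) analysis; ``risk_label`` houses the risk indicator D used in
    simulations; ``case_variant_count`` is the number of case-only
    variants observed in the gene.
    """

    gene_id: str
    mu: float
    family_bf: float | None = None
    risk_label: bool | None = None
    case_variant_count: int | None = None

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive for {self.gene_id}: {self.mu}")
        if self.family_bf is not None and not self.family_bf > 0:
            raise ValueError(
                f"family_bf must be positive for {self.gene_id}: {self.family_bf}"
            )


@dataclass
class GeneCounts:
    """Per-gene counts of likely-de-novo (x_d) and likely-inherited (x_h)."""

    gene_id: str
    x_d: int
    x_h: int

    def __post_init__(self) -> None:
        if self.x_d < 0 or self.x_h < 0:
            raise ValueError(f"negative counts for {self.gene_id}")

    @property
    def total(self) -> int:
        return self.x_d + self.x_h


DEFAULT_SCHEMA: Mapping[str, str] = {
    "variant_id": "variant_id",
    "gene_id": "gene_id",
    "af": "af",
    "loeuf": "loeuf",
    "ccr": "ccr",
    "fdr_tada_dd": "fdr_tada_dd",
    "obs_lof": "obs_lof",
    "exp_lof": "exp_lof",
    "inheritance_label": "inheritance_label",
}

_OPTIONAL_FIELDS = ("inheritance_label",)


def _parse_float(value, column: str, line: int) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    if isinstance(value, str) and value.strip() in ("", "NA", "na", "NaN", "nan", "."):
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowParseError(
            f"unparseable numeric value {value!r} in column {column!r} at line {line}"
        ) from None


def read_variant_table(
    path, schema: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Read a tab-separated variant table into :class:`VariantRecord` rows.

    ``schema`` maps canonical field names to the column names used in the
    file; omitted entries fall back to :data:`DEFAULT_SCHEMA`. The
    ``inheritance_label`` column is optional (missing means all-unknown)
    and parsed case-insensitively. Missing covariate cells become ``nan``.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld, col in colmap.items():
        if fld in _OPTIONAL_FIELDS:
            continue
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} (field {fld!r}) missing")
    label_col = colmap["inheritance_label"]
    has_label = label_col in df.columns
    has_score = "de_novo_score" in df.columns
    has_pred = "predicted_class" in df.columns
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        row = row._asdict()
        label = InheritanceLabel.UNKNOWN
        if has_label:
            raw = str(row[label_col]).strip().lower()
            if raw in ("", "na", "nan", "unknown"):
                label = InheritanceLabel.UNKNOWN
            elif raw in ("de_novo", "denovo", "dn", "1"):
                label = InheritanceLabel.DE_NOVO
            elif raw in ("inherited", "inh", "0"):
                label = InheritanceLabel.INHERITED
            else:
                raise RowParseError(
                    f"unrecognized inheritance label {raw!r} at line {line}"
                )
        score = None
        if has_score:
            s = _parse_float(row["de_novo_score"], "de_novo_score", line)
            score = None if math.isnan(s) else s
        pred = PredictedClass.UNSET
        if has_pred:
            raw = str(row["predicted_class"]).strip().lower()
            if raw not in ("", "na", "nan", "unset"):
                pred = PredictedClass(raw)
        records.append(
            VariantRecord(
                variant_id=str(row[colmap["variant_id"]]),
                gene_id=str(row[colmap["gene_id"]]),
                af=_parse_float(row[colmap["af"]], colmap["af"], line),
                loeuf=_parse_float(row[colmap["loeuf"]], colmap["loeuf"], line),
                ccr=_parse_float(row[colmap["ccr"]], colmap["ccr"], line),
                fdr_tada_dd=_parse_float(
                    row[colmap["fdr_tada_dd"]], colmap["fdr_tada_dd"], line
                ),
                obs_lof=_parse_float(row[colmap["obs_lof"]], colmap["obs_lof"], line),
                exp_lof=_parse_float(row[colmap["exp_lof"]], colmap["exp_lof"], line),
                inheritance_label=label,
                de_novo_score=score,
                predicted_class=pred,
            )
        )
    return records


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame in the canonical column order."""
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "gene_id": [r.gene_id for r in records],
            **{c: [getattr(r, c) for r in records] for c in COVARIATES},
            "inheritance_label": [r.inheritance_label.value for r in records],
            "de_novo_score": [
                math.nan if r.de_novo_score is None else r.de_novo_score
                for r in records
            ],
            "predicted_class": [r.predicted_class.value for r in records],
        }
    )


def frame_to_variants(df: pd.DataFrame) -> list[VariantRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        score = d.get("de_novo_score")
        if score is not None and isinstance(score, float) and math.isnan(score):
            score = None
        records.append(
            VariantRecord(
                variant_id=str(d["variant_id"]),
                gene_id=str(d["gene_id"]),
                **{c: float(d[c]) for c in COVARIATES},
                inheritance_label=InheritanceLabel(d.get("inheritance_label", "unknown")),
                de_novo_score=score,
                predicted_class=PredictedClass(d.get("predicted_class", "unset")),
            )
        )
    return records


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    """Write records as TSV; round-trips all finite fields bit-identically."""
    df = variants_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_table(path) -> list[GeneEntry]:
    """Read a per-gene TSV with columns gene_id, mu and optional extras."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "mu"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from gene table")
    entries = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        fbf = d.get("family_bf")
        if fbf is not None and isinstance(fbf, float) and math.isnan(fbf):
            fbf = None
        risk = d.get("risk_label")
        if risk is not None:
            risk = None if (isinstance(risk, float) and math.isnan(risk)) else bool(risk)
        cvc = d.get("case_variant_count")
        if cvc is not None:
            cvc = None if (isinstance(cvc, float) and math.isnan(cvc)) else int(cvc)
        entries.append(
            GeneEntry(
                gene_id=str(d["gene_id"]),
                mu=float(d["mu"]),
                family_bf=None if fbf is None else float(fbf),
                risk_label=risk,
                case_variant_count=cvc,
            )
        )
    return entries


def write_gene_table(entries: Sequence[GeneEntry], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in entries],
            "mu": [g.mu for g in entries],
            "family_bf": [g.family_bf for g in entries],
            "risk_label": [
                "" if g.risk_label is None else int(g.risk_label) for g in entries
            ],
            "case_variant_count": [
                "" if g.case_variant_count is None else g.case_variant_count
                for g in entries
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def filter_ultra_rare(
    records: Iterable[VariantRecord], af_max: float = 0.001
) -> list[VariantRecord]:
    """Keep variants with population allele frequency strictly below ``af_max``.

    A missing frequency means the variant is absent from the population
    reference — the strongest rarity evidence — and is treated as 0
    (kept). Order is preserved; the filter is idempotent.
    """
    if not 0.0 < af_max <= 1.0:
        raise ValueError(f"af_max must lie in (0, 1], got {af_max}")
    return [r for r in records if (0.0 if math.isnan(r.af) else r.af) < af_max]


def aggregate_gene_counts(records: Iterable[VariantRecord]) -> list[GeneCounts]:
    """Tally likely-de-novo / likely-inherited predictions per gene.

    Every record must carry a prediction; genes are reported in first-seen
    order. The totals over genes conserve the number of input records.
    """
    counts: dict[str, list[int]] = {}
    for r in records:
        if r.predicted_class is PredictedClass.UNSET:
            raise ValueError(f"variant {r.variant_id} has no predicted class")
        c = counts.setdefault(r.gene_id, [0, 0])
        if r.predicted_class is PredictedClass.LIKELY_DE_NOVO:
            c[0] += 1
        else:
            c[1] += 1
    return [GeneCounts(g, xd, xh) for g, (xd, xh) in counts.items()]
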