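"""Expression-validation statistics: fold change, Welch's t-test, stars.

Fold change is the ratio of mean wild-type (KT2442) expression to mean
cbrB-mutant (MPO401) expression for a gene under one condition, reported to
one decimal.  Group comparison uses the unpaired t-test without assuming
equal variances (Welch), two-sided.  Significance stars follow
``*: p<0.05; **: p<0.01; ***: p<0.005``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError

logger = logging.getLogger("regulonminer")

WT_STRAIN = "KT2442"
MUT_STRAIN = "MPO401"

#: Default replicate count when only summary statistics are given
#: (three biological replicates, each in triplicate).
DEFAULT_N = 9

STAR_THRESHOLDS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ExpressionGroup:
    """Replicate expression values (or their summary) for one gene x strain."""

    gene_id: str
    strain: str
    condition: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"{self.gene_id}/{self.strain}: n must be >= 2")
        if self.sd < 0:
            raise ValidationError(f"{self.gene_id}/{self.strain}: sd must be >= 0")

    @classmethod
    def from_values(
        cls, gene_id: str, strain: str, condition: str, values: list[float]
    ) -> "ExpressionGroup":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"{gene_id}/{strain}: need >= 2 replicates")
        return cls(
            gene_id, strain, condition, float(arr.mean()), float(arr.std(ddof=1)), arr.size
        )


@dataclass(frozen=True)
class ValidationResult:
    """Fold change + Welch test outcome for one gene."""

    gene_id: str
    fold_change: float          # rounded to 1 decimal for reporting
    fold_change_raw: float
    t: float
    df: float
    p: float
    stars: str
    call: str                   # activated | repressed | no_difference


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def fold_change(wt_mean: float, mut_mean: float) -> float:
    """Wild-type over mutant mean, rounded half-up to one decimal.

    Both means must be strictly positive; a non-positive mean signals a
    degenerate qPCR summary and raises :class:`ValidationError`.
    """
    if wt_mean <= 0 or mut_mean <= 0:
        raise ValidationError("fold change requires strictly positive means")
    return _round1(wt_mean / mut_mean)


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, degrees of freedom and 2-sided p.

    With both standard deviations zero: equal means return ``(0, nan, 1)``
    by convention; differing means are an error (no variability to test
    against).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("welch_t requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if math.isclose(mean1, mean2):
            return 0.0, float("nan"), 1.0
        raise ValidationError("zero variance in both groups with differing means")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def stars(p: float) -> str:
    """Significance stars: ``***`` p<0.005, ``**`` p<0.01, ``*`` p<0.05."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    for threshold, symbol in STAR_THRESHOLDS:
        if p < threshold:
            return symbol
    return ""


def _call(fc_raw: float, p: float, alpha: float = 0.05) -> str:
    if p < alpha and fc_raw > 1:
        return "activated"
    if p < alpha and fc_raw < 1:
        return "repressed"
    return "no_difference"


def load_expression_table(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV (summary or replicate layout).

    Summary layout: ``gene_id  strain  condition  mean  sd  [n]``.
    Replicate layout: ``gene_id  strain  condition  value`` with one row per
    replicate measurement.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "strain", "condition"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    if not ({"mean", "sd"} <= set(df.columns) or "value" in df.columns):
        raise ValidationError(f"{path}: need mean/sd columns or a value column")
    return df


def groups_from_table(df: pd.DataFrame, default_n: int = DEFAULT_N) -> list[ExpressionGroup]:
    """Collapse a loaded expression table into :class:`ExpressionGroup` records."""
    groups: list[ExpressionGroup] = []
    if "value" in df.columns:
        for (gene, strain, cond), sub in df.groupby(
            ["gene_id", "strain", "condition"], sort=True
        ):
            groups.append(
                ExpressionGroup.from_values(
                    str(gene), str(strain), str(cond), sub["value"].astype(float).tolist()
                )
            )
    else:
        for row in df.itertuples(index=False):
            n_val = getattr(row, "n", None)
            n = default_n if n_val is None or pd.isna(n_val) else int(n_val)
            groups.append(
                ExpressionGroup(
                    gene_id=str(row.gene_id),
                    strain=str(row.strain),
                    condition=str(row.condition),
                    mean=float(row.mean),
                    sd=float(row.sd),
                    n=n,
                )
            )
    return groups


def validate_targets(
    groups: list[ExpressionGroup],
    wt_strain: str = WT_STRAIN,
    mut_strain: str = MUT_STRAIN,
) -> list[ValidationResult]:
    """Pair wild-type and mutant groups per gene/condition and test each gene.

    Unpaired genes are skipped with a warning.  Results are ordered by
    gene_id (then condition) for deterministic output.
    """
    by_key: dict[tuple[str, str, str], ExpressionGroup] = {}
    for g in groups:
        by_key[(g.gene_id, g.condition, g.strain)] = g

    results: list[ValidationResult] = []
    seen = sorted({(g.gene_id, g.condition) for g in groups})
    for gene, cond in seen:
        wt = by_key.get((gene, cond, wt_strain))
        mut = by_key.get((gene, cond, mut_strain))
        if wt is None or mut is None:
            logger.warning("gene %s (%s): missing %s data, skipped",
                           gene, cond, wt_strain if wt is None else mut_strain)
            continue
        fc_raw = wt.mean / mut.mean if wt.mean > 0 and mut.mean > 0 else float("nan")
        if not math.isfinite(fc_raw):
            raise ValidationError(f"gene {gene}: non-positive mean in summary")
        t, df, p = welch_t(wt.mean, wt.sd, wt.n, mut.mean, mut.sd, mut.n)
        results.append(
            ValidationResult(
                gene_id=gene,
                fold_change=_round1(fc_raw),
                fold_change_raw=fc_raw,
                t=t,
                df=df,
                p=p,
                stars=stars(p),
                call=_call(fc_raw, p),
            )
        )
    return results


def results_table(results: list[ValidationResult]) -> pd.DataFrame:
    """Tabular rendering of validation results."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "fold_change": [r.fold_change for r in results],
            "t": [round(r.t, 3) for r in results],
            "df": [round(r.df, 2) for r in results],
            "p": [f"{r.p:.3g}" for r in results],
            "stars": [r.stars for r in results],
            "call": [r.call for r in results],
        }
    )


def validation_summary_path() -> Path:
    """Path to the packaged RT-qPCR summary table (wild type vs cbrB mutant,
    oxaloacetate minimal medium)."""
    return Path(resources.files("regulonminer") / "data" / "rtqpcr_validation_oaa.tsv")
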