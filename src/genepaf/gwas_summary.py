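"""Reading GWAS summary statistics and recovering score-scale quantities.

A GWAS report typically prints, per variant, the risk-allele frequency, the
per-allele odds ratio with a 95% CI and/or p-value, and the study size.  That
is enough to recover (i) the standard error of the log-OR, (ii) the signed
score statistic ST ~= beta / se(beta), and (iii) the implied trait-genotype
correlation Corr(Y, X) ~= ST / sqrt(N) — the inputs the Monte-Carlo joint
estimator needs.  The module also applies the classical odds-ratio ->
relative-risk correction RR = OR / (1 - P0 + OR*P0) for non-rare diseases,
with P0 the risk in the unexposed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_paf import VariantSummary, RelativeRisk

__all__ = [
    "EffectWithSE",
    "ScoreStatistic",
    "read_summary_table",
    "write_summary_table",
    "read_ld_matrix",
    "se_from_ci",
    "effect_from_summary",
    "score_stat",
    "or_to_rr",
]

logger = logging.getLogger(__name__)

_REQUIRED = ("variant_id", "raf", "or")
_OR_ALIASES = ("or", "or_point", "odds_ratio")
_OPTIONAL = {
    "ci_low": float, "ci_high": float, "p": float, "p_value": float,
    "n_cases": int, "n_controls": int, "effect_model": str,
}


@dataclass(frozen=True)
class EffectWithSE:
    """Log odds ratio and its standard error (both on the log-OR scale)."""

    log_or: float
    se_log_or: float

    def __post_init__(self) -> None:
        if not (self.se_log_or > 0) or not math.isfinite(self.se_log_or):
            raise ValueError(f"se must be positive, got {self.se_log_or}")


@dataclass(frozen=True)
class ScoreStatistic:
    """Signed score statistic and the trait-genotype correlation it implies."""

    st: float
    n_total: int
    y_bar: float | None = None

    @property
    def corr_yx(self) -> float:
        return self.st / math.sqrt(self.n_total)


def read_summary_table(path, delimiter: str | None = None) -> list[VariantSummary]:
    """Read a delimited summary-statistics table into VariantSummary records.

    The contract is a minimal one-line-header TSV/CSV with mandatory columns
    ``variant_id``, ``raf`` and ``or`` (aliases ``or_point``/``odds_ratio``),
    plus optional ``ci_low``, ``ci_high``, ``p``/``p_value``, ``n_cases``,
    ``n_controls`` and ``effect_model``.  Malformed rows raise with their
    1-based line number.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python")
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty summary table", stacklevel=2)
        return []
    df.columns = [str(c).strip().lower() for c in df.columns]
    or_col = next((c for c in _OR_ALIASES if c in df.columns), None)
    missing = [c for c in ("variant_id", "raf") if c not in df.columns]
    if or_col is None:
        missing.append("or")
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}; "
                         f"found {list(df.columns)}")
    if df.empty:
        warnings.warn(f"{path}: summary table has a header but no rows", stacklevel=2)
        return []

    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        kwargs = {"variant_id": str(row["variant_id"]),
                  "raf": float(row["raf"]), "or_point": float(row[or_col])}
        for col, typ in _OPTIONAL.items():
            if col in df.columns and pd.notna(row[col]):
                key = {"p": "p_value"}.get(col, col)
                kwargs[key] = typ(row[col])
        try:
            records.append(VariantSummary(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return records


def write_summary_table(variants, path, delimiter: str = "\t") -> None:
    """Write VariantSummary records back to a delimited table."""
    rows = []
    for v in variants:
        rows.append({"variant_id": v.variant_id, "raf": v.raf, "or": v.or_point,
                     "ci_low": v.ci_low, "ci_high": v.ci_high, "p": v.p_value,
                     "n_cases": v.n_cases, "n_controls": v.n_controls,
                     "effect_model": v.effect_model})
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_ld_matrix(path, delimiter: str | None = None) -> tuple[list[str], np.ndarray]:
    """Read a square pairwise LD matrix (r-squared) with variant IDs as the
    header row and first column; returns (ids, matrix)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, engine="python")
    ids = [str(c) for c in df.columns]
    if list(map(str, df.index)) != ids:
        raise ValueError(f"{path}: LD matrix row and column labels differ")
    mat = df.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{path}: LD matrix is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise ValueError(f"{path}: LD matrix diagonal must be 1")
    return ids, mat


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error of the log-OR from a reported 95% CI of the OR.

    se = (log(upper) - log(lower)) / (2 * 1.96); invariant under allele
    re-orientation since reciprocating both bounds only swaps them.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_low > ci_high:
        raise ValueError(f"ci_low {ci_low} exceeds ci_high {ci_high}")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * 1.96)


def effect_from_summary(vs: VariantSummary) -> EffectWithSE:
    """Recover (log-OR, se) from a summary record.

    The CI-derived se wins when both a CI and a p-value are present; the
    p-value then only serves as a consistency check (a >20% disagreement in
    the implied statistic triggers a warning).
    """
    log_or = math.log(vs.or_point)
    se_ci = se_from_ci(vs.ci_low, vs.ci_high) if vs.ci_low is not None else None
    se_p = None
    if vs.p_value is not None:
        z = stats.norm.isf(vs.p_value / 2.0)
        if z > 0:
            se_p = abs(log_or) / z
    if se_ci is not None and se_ci > 0:
        if se_p is not None and se_p > 0 and abs(se_ci / se_p - 1.0) > 0.20:
            warnings.warn(
                f"{vs.variant_id}: CI-derived se {se_ci:.4g} and p-value-derived "
                f"se {se_p:.4g} disagree by more than 20%; using the CI",
                stacklevel=2,
            )
        return EffectWithSE(log_or, se_ci)
    if se_p is not None and se_p > 0:
        return EffectWithSE(log_or, se_p)
    raise ValueError(
        f"{vs.variant_id}: cannot recover a standard error (need a 95% CI, or a "
        "p-value with a non-unit OR)"
    )


def score_stat(effect: EffectWithSE | None = None, n_total: int | None = None, *,
               p_value: float | None = None, sign: float = 1.0,
               y_bar: float | None = None) -> ScoreStatistic:
    """Signed score statistic ST ~= beta/se and implied Corr(Y, X) = ST/sqrt(N).

    Either ``effect`` (log-OR with se) or a two-sided ``p_value`` plus the
    ``sign`` of the effect must be given.  The Wald, score and likelihood-ratio
    chi-squares are asymptotically equivalent, so either source is acceptable.
    """
    if n_total is None or n_total <= 0:
        raise ValueError("n_total must be a positive sample size")
    if effect is not None:
        st = effect.log_or / effect.se_log_or
    elif p_value is not None:
        if not (0.0 < p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]; p=0 gives an infinite statistic")
        st = math.copysign(stats.norm.isf(p_value / 2.0), sign)
    else:
        raise ValueError("supply either an EffectWithSE or a p-value with a sign")
    stat = ScoreStatistic(st=float(st), n_total=int(n_total), y_bar=y_bar)
    if abs(stat.corr_yx) >= 1.0:
        raise ValueError(f"implied |Corr(Y,X)| = {abs(stat.corr_yx):.3f} >= 1; "
                         "inconsistent effect and sample size")
    return stat


def or_to_rr(odds_ratio: float, baseline_risk: float) -> RelativeRisk:
    """Approximate the per-allele RR from an OR when the disease is not rare.

    RR = OR / (1 - P0 + OR*P0); exact for a binary exposure, an approximation
    per allele since log-linearity in OR does not imply log-linearity in RR.
    The correction always shrinks the OR toward 1.
    """
    if odds_ratio <= 0:
        raise ValueError("OR must be positive")
    if not (0.0 <= baseline_risk < 1.0):
        raise ValueError("baseline risk must lie in [0, 1)")
    return RelativeRisk(odds_ratio / (1.0 - baseline_risk + odds_ratio * baseline_risk))
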