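"""Association between copy-number calls and clinicopathological covariates.

Per-sample deletion calls from one or two assays are merged (OR / AND),
cross-tabulated against categorical covariates, and tested with the usual
2x2 machinery: cross-product odds ratio with a Wald log-scale confidence
interval, Pearson chi-square (optional Yates correction), two-sided
Fisher's exact test, and the Cochran-Armitage trend test for ordered
groups.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InputError

__all__ = [
    "MergeMode",
    "ContingencyTable2x2",
    "TrendTable",
    "CALL_COLUMNS",
    "COVARIATE_LEVELS",
    "merge_calls",
    "odds_ratio",
    "fisher_exact",
    "chi_square",
    "cochran_armitage_trend",
    "build_contingency",
    "validate_call_table",
]

#: Boolean call columns a CallTable DataFrame may carry.
CALL_COLUMNS = ("call_p16light", "call_p14", "call_or", "call_and")

#: Declared vocabularies for the clinical covariates (missing values allowed).
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<60", ">=60"),
    "sex": ("male", "female"),
    "location": ("cardiac", "noncardiac"),
    "differentiation": ("poor", "well_moderate"),
    "stage": ("I-II", "III", "IV"),
    "invasion": ("T1-2", "T3", "T4"),
    "lymph_metastasis": ("negative", "positive"),
    "distant_metastasis": ("negative", "positive"),
}


class MergeMode(str, enum.Enum):
    OR = "or"
    AND = "and"


def merge_calls(call_a, call_b, mode: MergeMode | str = MergeMode.OR):
    """Merge two boolean call vectors (or scalars) by logical OR / AND."""
    mode = MergeMode(mode)
    if isinstance(call_a, (pd.Series, np.ndarray)):
        a = np.asarray(call_a, dtype=bool)
        b = np.asarray(call_b, dtype=bool)
        return a | b if mode is MergeMode.OR else a & b
    return bool(call_a) or bool(call_b) if mode is MergeMode.OR else bool(call_a) and bool(call_b)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: a = exposed & outcome-positive, b = exposed & negative,
    c = unexposed & positive, d = unexposed & negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be non-negative")
        if self.total == 0:
            raise InputError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str  # "wald" or "wald_haldane"
    degenerate: bool = False  # a zero cell made the OR 0 or infinite


def odds_ratio(
    table: ContingencyTable2x2, haldane: bool = False
) -> OddsRatioResult:
    """Cross-product odds ratio (a*d)/(b*c) with a Wald 95% CI.

    A zero cell yields an infinite or zero OR flagged ``degenerate`` unless
    ``haldane`` applies the Haldane-Anscombe +0.5 correction to every cell.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    method = "wald"
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "wald_haldane"
    if b * c == 0 or a * d == 0:
        est = math.inf if b * c == 0 else 0.0
        return OddsRatioResult(est, math.nan, math.nan, method, degenerate=True)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return OddsRatioResult(
        est,
        math.exp(math.log(est) - z * se),
        math.exp(math.log(est) + z * se),
        method,
    )


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: hypergeometric probabilities no larger than
    the observed table's are summed (point-probability rule)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided").pvalue)


def fisher_exact_doubling(table: ContingencyTable2x2) -> float:
    """Alternative two-sided rule: twice the smaller one-sided p, capped at 1."""
    less = stats.fisher_exact(table.as_array(), alternative="less").pvalue
    greater = stats.fisher_exact(table.as_array(), alternative="greater").pvalue
    return float(min(1.0, 2.0 * min(less, greater)))


def chi_square(
    table: ContingencyTable2x2, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square with 1 df; ``yates`` applies the continuity
    correction.  A zero row or column margin is an error."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise AnalysisError("chi-square undefined: zero margin")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TrendTable:
    """Ordered groups for the trend test: per-group positives, totals and
    integer scores (defaults 0, 1, 2, ...)."""

    positives: tuple[int, ...]
    totals: tuple[int, ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.positives) < 3 or len(self.positives) != len(self.totals):
            raise InputError("trend test needs >= 3 ordered groups")
        if any(p < 0 or p > n for p, n in zip(self.positives, self.totals)):
            raise InputError("positives must lie in [0, n] per group")
        if self.scores is not None and len(self.scores) != len(self.positives):
            raise InputError("one score per group required")

    def effective_scores(self) -> np.ndarray:
        if self.scores is None:
            return np.arange(len(self.positives), dtype=float)
        return np.asarray(self.scores, dtype=float)


def cochran_armitage_trend(table: TrendTable) -> tuple[float, float]:
    """Cochran-Armitage test for a linear trend in proportions.

    Z = sum_i s_i (r_i - n_i p) / sqrt(p (1-p) [sum s_i^2 n_i - (sum s_i n_i)^2 / N])

    with p the pooled proportion; two-sided p from the standard normal.
    Zero variance (all groups identical in score or a degenerate pooled
    proportion) gives z = 0, p = 1.
    """
    r = np.asarray(table.positives, dtype=float)
    n = np.asarray(table.totals, dtype=float)
    s = table.effective_scores()
    N = n.sum()
    pbar = r.sum() / N
    var = pbar * (1 - pbar) * (np.sum(s * s * n) - np.sum(s * n) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = float(np.sum(s * (r - n * pbar)) / math.sqrt(var))
    return z, float(2 * stats.norm.sf(abs(z)))


def validate_call_table(calls: pd.DataFrame) -> None:
    """Check sample-id uniqueness and covariate vocabularies."""
    if "sample_id" not in calls.columns:
        raise InputError("call table needs a sample_id column")
    if calls["sample_id"].duplicated().any():
        raise InputError("duplicate sample_ids in call table")
    for cov, levels in COVARIATE_LEVELS.items():
        if cov in calls.columns:
            observed = set(calls[cov].dropna().unique())
            unknown = observed - set(levels)
            if unknown:
                raise InputError(f"unknown levels for {cov}: {sorted(unknown)}")


def build_contingency(
    calls: pd.DataFrame,
    exposure: str,
    outcome: str,
    positive_level: str,
) -> tuple[ContingencyTable2x2, int]:
    """Cross-tabulate a boolean call column against a covariate level.

    Rows are the outcome (covariate == ``positive_level`` vs any other
    level), columns the exposure call, so
    ``a = outcome+/call+``, ``b = outcome+/call-``, ``c = outcome-/call+``,
    ``d = outcome-/call-``.  Samples with a missing covariate are dropped;
    the dropped count is returned alongside the table.
    """
    if calls.empty:
        raise AnalysisError("empty call table")
    if exposure not in calls.columns:
        raise InputError(f"unknown call column: {exposure}")
    if outcome not in calls.columns:
        raise InputError(f"unknown covariate: {outcome}")
    sub = calls[[exposure, outcome]].dropna(subset=[outcome])
    n_dropped = len(calls) - len(sub)
    levels = set(sub[outcome].unique())
    if positive_level not in levels:
        raise InputError(f"level {positive_level!r} absent from {outcome}")
    if len(levels) < 2:
        raise AnalysisError(f"covariate {outcome} has a single level; table degenerate")
    exp = sub[exposure].astype(bool)
    pos = sub[outcome] == positive_level
    a = int((pos & exp).sum())
    b = int((pos & ~exp).sum())
    c = int((~pos & exp).sum())
    d = int((~pos & ~exp).sum())
    return ContingencyTable2x2(a, b, c, d), n_dropped
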