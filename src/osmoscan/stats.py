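"""The statistical procedure: QC gate, normality-gated paired tests, linear
index-vs-covariate models, and age-stratified reference intervals.

The paired-comparison procedure mirrors common clinical-laboratory practice:
a Shapiro-Wilk test on the paired differences decides between the paired
Student t-test (differences compatible with normality) and the Wilcoxon
signed-rank test.  Linear models are ordinary least squares with gender as a
two-level factor.  Reference intervals are central percentile intervals per
stratum with an explicit, bit-reproducible quantile rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import CollinearityError, InsufficientDataError, SchemaError

__all__ = [
    "StatResult",
    "ReferenceInterval",
    "qc_filter",
    "choose_paired_test",
    "paired_compare",
    "fit_index_model",
    "reference_interval",
    "HYPOCHROMIC_LIMIT",
]

HYPOCHROMIC_LIMIT = 5.0  # % hypochromic RBC; at or above indicates iron deficiency


@dataclass(frozen=True)
class StatResult:
    """One test or coefficient: estimate, 95% CI (where defined), p, n."""

    test_name: str  # paired_t | wilcoxon_signed_rank | ols_t | anova_F
    estimate: float
    ci_lo: float | None
    ci_hi: float | None
    p_value: float
    n: int
    term: str = ""

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name, "term": self.term, "estimate": self.estimate,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "p_value": self.p_value, "n": self.n,
        }


@dataclass(frozen=True)
class ReferenceInterval:
    """Central percentile interval for one stratum; undefined if n < min_n."""

    stratum: str
    lo: float | None
    hi: float | None
    n: int
    method: str = "percentile"
    flag: str | None = None  # "LOW_N" when the stratum is too small


def qc_filter(cohort: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop donors with >= 5% hypochromic red cells (iron-deficiency sign).

    Returns the filtered table and the ids (or row indices) of dropped rows.
    """
    if "hypochromic_pct" not in cohort.columns:
        raise SchemaError("cohort table lacks required column 'hypochromic_pct'")
    bad = cohort["hypochromic_pct"] >= HYPOCHROMIC_LIMIT
    if "donor_id" in cohort.columns:
        flags = cohort.loc[bad, "donor_id"].astype(str).tolist()
    else:
        flags = [str(i) for i in cohort.index[bad]]
    return cohort.loc[~bad].copy(), flags


def _paired_diffs(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be 1-D arrays of equal length")
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 pairs, got {x.size}")
    return x - y


def choose_paired_test(x, y, alpha: float = 0.05) -> str:
    """Normality gate: Shapiro-Wilk on the paired differences.

    p >= alpha selects ``paired_t``, otherwise ``wilcoxon_signed_rank``.
    Constant differences are degenerate for Shapiro-Wilk; the rank test is
    returned with a warning.
    """
    d = _paired_diffs(x, y)
    if np.ptp(d) == 0.0:
        warnings.warn("paired differences are constant; defaulting to the signed-rank test", stacklevel=2)
        return "wilcoxon_signed_rank"
    p = sps.shapiro(d).pvalue
    return "paired_t" if p >= alpha else "wilcoxon_signed_rank"


def paired_compare(x, y, alpha: float = 0.05, test: str | None = None) -> StatResult:
    """Gated paired comparison of x vs y; estimate is oriented as x - y.

    The t branch reports the mean difference with its 95% CI; the Wilcoxon
    branch reports the median difference (no CI).  Identical samples return
    estimate 0 and p = 1 by convention.
    """
    d = _paired_diffs(x, y)
    name = test or choose_paired_test(x, y, alpha)
    n = d.size
    if np.all(d == 0.0):
        return StatResult(name, 0.0, None, None, 1.0, n)
    if name == "paired_t":
        res = sps.ttest_rel(x, y)
        lo, hi = res.confidence_interval(0.95)
        return StatResult("paired_t", float(d.mean()), float(lo), float(hi), float(res.pvalue), n)
    if name == "wilcoxon_signed_rank":
        res = sps.wilcoxon(d, alternative="two-sided")
        return StatResult("wilcoxon_signed_rank", float(np.median(d)), None, None, float(res.pvalue), n)
    raise InsufficientDataError(f"unknown test {name!r}")


def fit_index_model(
    cohort: pd.DataFrame, index_name: str, covariates: tuple[str, ...] = ("age", "gender")
) -> tuple[list[StatResult], StatResult]:
    """OLS of one Lorrca index on donor covariates.

    Gender (or any non-numeric column) is coded as a two-level factor.
    Returns per-coefficient t results (intercept included) and the overall
    ANOVA F of the model.
    """
    missing = [c for c in (index_name, *covariates) if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table lacks columns {missing}")
    n = len(cohort)
    if n <= len(covariates) + 2:
        raise InsufficientDataError(f"need n > {len(covariates) + 2} rows, got {n}")
    X = pd.DataFrame(index=cohort.index)
    for c in covariates:
        col = cohort[c]
        if col.dtype.kind in "OUSb" or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise CollinearityError(f"factor column {c!r} has a single level")
            for lev in levels[1:]:
                X[f"{c}[{lev}]"] = (col.astype(str) == lev).astype(float)
        else:
            X[c] = col.astype(float)
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise CollinearityError(f"design matrix is rank deficient over columns {list(X.columns)}")
    model = sm.OLS(cohort[index_name].astype(float), X).fit()
    ci = model.conf_int(alpha=0.05)
    coefs = [
        StatResult("ols_t", float(model.params[t]), float(ci.loc[t, 0]), float(ci.loc[t, 1]),
                   float(model.pvalues[t]), n, term=t)
        for t in X.columns
    ]
    overall = StatResult("anova_F", float(model.fvalue), None, None, float(model.f_pvalue), n, term="model")
    return coefs, overall


def _quantile(values: np.ndarray, q: float) -> float:
    # linear interpolation at rank h = (n-1)q + 1 (numpy's default rule),
    # pinned explicitly so intervals are bit-reproducible
    return float(np.quantile(values, q, method="linear"))


def reference_interval(
    values, strata_labels, lo_q: float = 0.025, hi_q: float = 0.975, min_n: int = 20
) -> list[ReferenceInterval]:
    """Central percentile reference interval per stratum.

    Strata with fewer than ``min_n`` observations are reported with
    undefined bounds and a LOW_N flag rather than dropped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(strata_labels)
    if values.shape != labels.shape:
        raise SchemaError("values and strata_labels must align")
    if not np.all(np.isfinite(values)):
        raise SchemaError("values must be finite")
    out = []
    for stratum in pd.unique(labels):
        v = values[labels == stratum]
        if v.size < min_n:
            out.append(ReferenceInterval(str(stratum), None, None, int(v.size), flag="LOW_N"))
        else:
            out.append(ReferenceInterval(str(stratum), _quantile(v, lo_q), _quantile(v, hi_q), int(v.size)))
    return out
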