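"""Log-scale crossover ANOVA, descriptive statistics, and the BE decision.

The primary engine fits the fixed-effects general linear model

    ln y = mu + sequence + subject(sequence) + period + treatment + eps

to the per-subject endpoints of a 2x2 crossover by least squares on an
effect-coded (sum-to-zero) design matrix.  The treatment effect on the log
scale exponentiates to the geometric-mean-ratio point estimate (fed A vs
fasted B); its 90% confidence interval is the classical t-interval with
n1+n2-2 residual degrees of freedom; the intra-subject CV is recovered from
the residual mean square as 100*sqrt(exp(MSE)-1).  Average bioequivalence is
declared when the 90% CI lies inside 80.00-125.00%.

With complete balanced data this fixed-subject least-squares fit coincides
with the mixed-model (random-subject) analysis; subjects missing either
treatment are dropped (complete-case) with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptiveStats",
    "AnovaResult",
    "BE_LIMITS_DEFAULT",
    "descriptive_stats",
    "fit_crossover_anova",
    "ci_from_summary",
    "be_decision",
    "round_half_up",
]

BE_LIMITS_DEFAULT = (80.0, 125.0)
"""Regulatory average-bioequivalence acceptance window, percent."""


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed PK tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# descriptive statistics (summary-table shape)


@dataclass(frozen=True)
class DescriptiveStats:
    """Eight-number summary of one endpoint in one arm."""

    endpoint: str
    geometric_mean: float
    arithmetic_mean: float
    sd: float
    cv_percent: float
    minimum: float
    maximum: float
    median: float
    n: int


def descriptive_stats(values, endpoint: str) -> DescriptiveStats:
    """Geometric/arithmetic mean, SD, CV%, range, median and n.

    All values must be positive (the geometric mean is defined as
    exp(mean(ln x))).  For n == 1 the SD and CV are reported as 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("descriptive_stats needs at least one value")
    bad = np.nonzero(x <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{endpoint}: non-positive value(s) at position(s) {bad.tolist()}; "
            "geometric statistics undefined"
        )
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return DescriptiveStats(
        endpoint=endpoint,
        geometric_mean=float(np.exp(np.mean(np.log(x)))),
        arithmetic_mean=mean,
        sd=sd,
        cv_percent=100.0 * sd / mean,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        median=float(np.median(x)),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# the 2x2 crossover GLM-ANOVA


@dataclass(frozen=True)
class AnovaResult:
    """Geometric-mean-ratio inference for one endpoint (A fed vs B fasted)."""

    endpoint: str
    point_estimate_percent: float
    ci_lower_percent: float
    ci_upper_percent: float
    alpha: float               # per one-sided test; CI level is 1 - 2*alpha
    mse_log: float             # residual mean square, natural-log scale
    df_resid: int
    intra_cv_percent: float    # 100*sqrt(exp(mse_log) - 1)
    be_decision: bool
    n1: int                    # subjects in sequence AB
    n2: int                    # subjects in sequence BA

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float, float]:
        """(PE, lower, upper, CV) rounded half-up, as printed in reports."""
        return (
            round_half_up(self.point_estimate_percent, ndigits),
            round_half_up(self.ci_lower_percent, ndigits),
            round_half_up(self.ci_upper_percent, ndigits),
            round_half_up(self.intra_cv_percent, ndigits),
        )


def _design_matrix(sub: pd.DataFrame) -> np.ndarray:
    """Effect-coded (sum-to-zero) full-rank design for the crossover GLM.

    Column 1 is the treatment contrast coded +1/2 (A) / -1/2 (B), so its
    coefficient is directly the A-B difference of log means.
    """
    n_rows = len(sub)
    trt = np.where(sub["treatment"].to_numpy() == "A", 0.5, -0.5)
    per = np.where(sub["period"].to_numpy() == 1, 0.5, -0.5)
    seq = np.where(sub["sequence"].to_numpy() == "AB", 0.5, -0.5)
    cols = [np.ones(n_rows), trt, per, seq]
    # subject within sequence: effect coding per sequence group
    for seq_label in ("AB", "BA"):
        in_seq = sub["sequence"].to_numpy() == seq_label
        subjects = sorted(sub.loc[in_seq, "subject_id"].unique())
        reference = subjects[-1]
        for s in subjects[:-1]:
            col = np.zeros(n_rows)
            col[sub["subject_id"].to_numpy() == s] = 1.0
            col[(sub["subject_id"].to_numpy() == reference) & in_seq] = -1.0
            cols.append(col)
    return np.column_stack(cols)


def fit_crossover_anova(
    data: pd.DataFrame,
    value_col: str,
    endpoint: str | None = None,
    alpha: float = 0.05,
    limits: tuple[float, float] = BE_LIMITS_DEFAULT,
) -> AnovaResult:
    """Fit the log-scale crossover GLM and test average bioequivalence.

    ``data`` needs columns ``subject_id``, ``sequence`` ("AB"/"BA"),
    ``period`` (1/2), ``treatment`` ("A"/"B") and ``value_col`` with positive
    endpoint values (logs are taken here).  Returns the point estimate and
    100(1-2*alpha)% CI in percent, the residual mean square and df, the
    intra-subject CV, and the containment decision against ``limits``.
    """
    required = {"subject_id", "sequence", "period", "treatment", value_col}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)}")
    sub = data.copy()

    counts = sub.groupby("subject_id")["treatment"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        warnings.warn(
            f"excluding subject(s) without both treatments: {incomplete}",
            UserWarning,
            stacklevel=2,
        )
        sub = sub[~sub["subject_id"].isin(incomplete)]
    if sub.empty:
        raise ValueError("no complete subjects to analyse")
    y_raw = sub[value_col].to_numpy(dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError(f"{value_col}: non-positive values; log-ANOVA undefined")

    seq_sizes = sub.groupby("sequence")["subject_id"].nunique()
    n1 = int(seq_sizes.get("AB", 0))
    n2 = int(seq_sizes.get("BA", 0))
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 complete subjects per sequence")

    y = np.log(y_raw)
    X = _design_matrix(sub)
    n_rows, n_params = X.shape
    df_resid = n_rows - n_params
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    mse = rss / df_resid
    delta = float(beta[1])                     # A - B on the log scale
    se = math.sqrt(max(mse, 0.0) * xtx_inv[1, 1])

    tcrit = stats.t.ppf(1.0 - alpha, df_resid)
    pe = 100.0 * math.exp(delta)
    lo = 100.0 * math.exp(delta - tcrit * se)
    hi = 100.0 * math.exp(delta + tcrit * se)
    intra_cv = 100.0 * math.sqrt(math.exp(mse) - 1.0)
    return AnovaResult(
        endpoint=endpoint or value_col,
        point_estimate_percent=pe,
        ci_lower_percent=lo,
        ci_upper_percent=hi,
        alpha=alpha,
        mse_log=mse,
        df_resid=df_resid,
        intra_cv_percent=intra_cv,
        be_decision=be_decision((lo, hi), limits),
        n1=n1,
        n2=n2,
    )


def ci_from_summary(
    point_estimate_percent: float,
    intra_cv_percent: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Reconstruct the 100(1-2*alpha)% CI from (PE, intra-CV, group sizes).

    The closed-form bridge between the three columns of a crossover BE table:
    s_w = sqrt(ln(1+(CV/100)^2)), SE = s_w*sqrt((1/n1+1/n2)/2), and the bounds
    are PE*exp(-+ t(1-alpha, n1+n2-2)*SE).  Exact inverse of the CI computed
    by :func:`fit_crossover_anova` on complete balanced data.
    """
    if point_estimate_percent <= 0 or intra_cv_percent < 0:
        raise ValueError("point estimate must be positive, CV non-negative")
    if min(n1, n2) < 2:
        raise ValueError("need n1, n2 >= 2")
    s_w = math.sqrt(math.log1p((intra_cv_percent / 100.0) ** 2))
    se = s_w * math.sqrt((1.0 / n1 + 1.0 / n2) / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha, n1 + n2 - 2)
    margin = tcrit * se
    return (
        point_estimate_percent * math.exp(-margin),
        point_estimate_percent * math.exp(margin),
    )


def be_decision(
    ci_percent: tuple[float, float],
    limits: tuple[float, float] = BE_LIMITS_DEFAULT,
) -> bool:
    """Containment test: CI inside the acceptance window (closed interval)."""
    lo, hi = ci_percent
    if lo > hi:
        raise ValueError("CI lower bound exceeds upper bound")
    if limits[0] > limits[1]:
        raise ValueError("invalid acceptance limits")
    return limits[0] <= lo and hi <= limits[1]
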