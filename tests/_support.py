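"""Shared test helpers: data builders and independent oracles.

Everything here is deliberately written from scratch against the math rather
than by calling the package's own code paths, so tests compare two routes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

SCHEDULE = np.array(
    [0, 0.5, 1, 2, 2.5, 3, 3.5, 4, 4.5, 5, 6, 8, 12, 24, 36, 48, 72], float
)


def balanced_frame(rng: np.random.Generator, n_per_seq: int = 6,
                   delta: float = 0.1, sigma: float = 0.2) -> pd.DataFrame:
    """Random complete balanced 2x2 endpoint data (lognormal values)."""
    rows = []
    for i in range(2 * n_per_seq):
        seq = "AB" if i % 2 == 0 else "BA"
        subj_eff = rng.normal(0, 0.3)
        for period in (1, 2):
            trt = seq[period - 1]
            mu = (delta / 2 if trt == "A" else -delta / 2) + (
                0.05 if period == 1 else -0.05
            )
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "sequence": seq,
                    "period": period,
                    "treatment": trt,
                    "value": math.exp(mu + subj_eff + rng.normal(0, sigma)),
                }
            )
    return pd.DataFrame(rows)


def anova_2x2_summary(frame: pd.DataFrame, value_col: str = "value"):
    """Closed-form balanced-2x2 ANOVA from period differences.

    For complete data: delta_hat = mean(d_AB) - mean(d_BA) with
    d = (ln p1 - ln p2)/2 signed so the result is A - B; MSE = 2 * pooled
    var(d); SE = sqrt(MSE*(1/n1+1/n2)/2); df = n1+n2-2.  Independent of the
    design-matrix solve in the package.
    """
    d = {"AB": [], "BA": []}
    for _, grp in frame.groupby("subject_id"):
        by_p = grp.set_index("period")[value_col]
        seq = grp["sequence"].iloc[0]
        d[seq].append((math.log(by_p.loc[1]) - math.log(by_p.loc[2])) / 2.0)
    d_ab, d_ba = np.asarray(d["AB"]), np.asarray(d["BA"])
    n1, n2 = d_ab.size, d_ba.size
    delta = d_ab.mean() - d_ba.mean()
    pooled = ((n1 - 1) * d_ab.var(ddof=1) + (n2 - 1) * d_ba.var(ddof=1)) / (
        n1 + n2 - 2
    )
    mse = 2.0 * pooled
    se = math.sqrt(mse * (1.0 / n1 + 1.0 / n2) / 2.0)
    return delta, se, mse, n1 + n2 - 2


def simulate_tost_decisions(
    rng: np.random.Generator,
    n_trials: int,
    gmr: float,
    cv_percent: float,
    n_total: int,
    alpha: float = 0.05,
    limits: tuple[float, float] = (0.80, 1.25),
) -> np.ndarray:
    """Vectorised 2x2 TOST simulation on the exact sufficient statistics.

    For lognormal endpoints the fitted log-ratio is N(ln gmr, se^2) and the
    residual MS is sigma^2 * chi2_df / df, independent; the CI-containment
    decision depends only on these.  Their equivalence with the full
    design-matrix fit is asserted separately (test_anova_matches_summary).
    """
    from scipy import stats

    s_w = math.sqrt(math.log1p((cv_percent / 100.0) ** 2))
    se_true = s_w * math.sqrt(2.0 / n_total)
    df = n_total - 2
    delta_hat = rng.normal(math.log(gmr), se_true, n_trials)
    s2 = s_w**2 * rng.chisquare(df, n_trials) / df
    se_hat = np.sqrt(s2 * (2.0 / n_total))
    tcrit = stats.t.ppf(1 - alpha, df)
    lo = np.exp(delta_hat - tcrit * se_hat)
    hi = np.exp(delta_hat + tcrit * se_hat)
    return (lo >= limits[0]) & (hi <= limits[1])


def endpoint_log_mean(config, fed: bool, n_draws: int,
                      rng: np.random.Generator):
    """Monte-Carlo E[ln Cmax] and E[ln AUC(0-72h)] under the generative model.

    Re-implements the simulator's noise structure (lognormal subject and
    period effects on CL/V/ka, time jitter, multiplicative assay error,
    trapezoid truncated at exactly 72 h) as one vectorised computation with
    its own kinetic formula — the estimand oracle for parameter-recovery and
    coverage checks.  Returns (mean ln cmax, mean ln auc, per-draw SDs).
    """
    t_nom = np.asarray(config.schedule)
    m = n_draws
    cl0 = config.clearance
    ka0 = config.ka_fasted * (config.ka_fed_multiplier if fed else 1.0)
    f = config.f_fed_multiplier if fed else 1.0
    cl = cl0 * np.exp(rng.normal(0, config.bsv_cl, m) + rng.normal(0, config.wsv_cl, m))
    v1 = config.v_over_f * np.exp(rng.normal(0, config.bsv_v, m))
    ka = ka0 * np.exp(rng.normal(0, config.bsv_ka, m) + rng.normal(0, config.wsv_ka, m))

    jit = np.clip(rng.normal(0, config.time_jitter_sd, (m, t_nom.size)), -0.08, 0.08)
    jit[:, -1] = np.abs(jit[:, -1])
    t = t_nom[None, :] + jit
    t[:, 0] = 0.0

    alpha = math.log(2) / config.distribution_half_life
    beta = config.ke
    k21 = config.k21
    k12 = alpha + beta - k21 - alpha * beta / k21
    k10 = cl / v1
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4 * k10 * k21)
    al = (s + disc) / 2
    be = (s - disc) / 2
    a = (k21 - al) / ((ka - al) * (be - al))
    bb = (k21 - be) / ((ka - be) * (al - be))
    c = (k21 - ka) / ((al - ka) * (be - ka))
    amp = f * config.dose * 1000.0 * ka / v1
    conc = amp[:, None] * (
        a[:, None] * np.exp(-al[:, None] * t)
        + bb[:, None] * np.exp(-be[:, None] * t)
        + c[:, None] * np.exp(-ka[:, None] * t)
    )
    conc = conc * np.exp(rng.normal(0, config.assay_cv, conc.shape))
    conc[:, 0] = 0.0

    ln_cmax = np.log(conc.max(axis=1))
    # trapezoid truncated/interpolated at exactly 72 h (only the last
    # segment can straddle, since jitter keeps the last time >= 72)
    c72 = conc[:, -2] + (conc[:, -1] - conc[:, -2]) * (
        (72.0 - t[:, -2]) / (t[:, -1] - t[:, -2])
    )
    core = np.trapezoid(conc[:, :-1], t[:, :-1], axis=1)
    ln_auc = np.log(core + 0.5 * (conc[:, -2] + c72) * (72.0 - t[:, -2]))
    return ln_cmax, ln_auc
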