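"""End-to-end orchestration: trial -> NCA -> ANOVA -> nonparametric -> tables.

:func:`run_analyze` ties the pipeline together and returns an
:class:`AnalysisBundle` holding everything a study report prints: per-subject
endpoints, the summary-statistics table per endpoint and arm, the ratio /
90% CI / intra-CV table for AUC(0-72h) and Cmax with the bioequivalence
decision, and the Hodges-Lehmann shift for tmax.  Plotting produces linear
and semilogarithmic mean concentration-time profiles of the two arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .crossover_anova import (
    BE_LIMITS_DEFAULT,
    AnovaResult,
    DescriptiveStats,
    descriptive_stats,
    fit_crossover_anova,
    round_half_up,
)
from .nca import compute_endpoints, endpoints_frame
from .nonparam_tmax import NonparametricResult, tmax_shift_analysis
from .trial_io import TrialDataset

__all__ = ["AnalysisBundle", "run_analyze", "plot_mean_profiles"]

_ENDPOINT_LABELS = {
    "auc_0_72": "AUC(0-72h) [ng*h/mL]",
    "cmax": "Cmax [ng/mL]",
    "tmax": "tmax [h]",
}
_ARM_LABELS = {"A": "A (fed)", "B": "B (fasted)"}


@dataclass(frozen=True)
class AnalysisBundle:
    """All computed results of one food-effect crossover analysis."""

    endpoints: pd.DataFrame
    descriptive: dict[tuple[str, str], DescriptiveStats]  # (endpoint, arm)
    anova: dict[str, AnovaResult]                          # auc_0_72, cmax
    tmax_nonparametric: NonparametricResult
    alpha: float
    limits: tuple[float, float]

    def descriptive_frame(self) -> pd.DataFrame:
        """Summary-statistics table (one row per endpoint x arm)."""
        rows = []
        for (endpoint, arm), d in sorted(self.descriptive.items()):
            rows.append(
                {
                    "treatment": _ARM_LABELS[arm],
                    "endpoint": _ENDPOINT_LABELS[endpoint],
                    "geometric_mean": round_half_up(d.geometric_mean, 3),
                    "arithmetic_mean": round_half_up(d.arithmetic_mean, 3),
                    "sd": round_half_up(d.sd, 3),
                    "cv_percent": round_half_up(d.cv_percent, 1),
                    "min": round_half_up(d.minimum, 3),
                    "max": round_half_up(d.maximum, 3),
                    "median": round_half_up(d.median, 3),
                    "n": d.n,
                }
            )
        return pd.DataFrame(rows)

    def ratio_frame(self) -> pd.DataFrame:
        """Ratio table: PE, CI bounds, intra-CV (percent, 2 dp) and decision."""
        rows = []
        for endpoint in ("auc_0_72", "cmax"):
            r = self.anova[endpoint]
            pe, lo, hi, cv = r.rounded(2)
            rows.append(
                {
                    "endpoint": _ENDPOINT_LABELS[endpoint],
                    "method": "ANOVA-log",
                    "point_estimate_percent": pe,
                    "ci_lower_percent": lo,
                    "ci_upper_percent": hi,
                    "intra_cv_percent": cv,
                    "bioequivalent": r.be_decision,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-ready dictionary of every computed number (full precision)."""
        hl = self.tmax_nonparametric
        return {
            "alpha": self.alpha,
            "limits_percent": list(self.limits),
            "anova": {
                name: {
                    "endpoint": r.endpoint,
                    "point_estimate_percent": r.point_estimate_percent,
                    "ci_lower_percent": r.ci_lower_percent,
                    "ci_upper_percent": r.ci_upper_percent,
                    "mse_log": r.mse_log,
                    "df_resid": r.df_resid,
                    "intra_cv_percent": r.intra_cv_percent,
                    "be_decision": r.be_decision,
                    "n1": r.n1,
                    "n2": r.n2,
                }
                for name, r in self.anova.items()
            },
            "tmax_hodges_lehmann": {
                "estimate_h": hl.hl_estimate,
                "ci_lower_h": hl.ci_lower,
                "ci_upper_h": hl.ci_upper,
                "confidence": hl.confidence,
                "achieved_confidence": hl.achieved_confidence,
                "n1": hl.n1,
                "n2": hl.n2,
            },
            "descriptive": {
                f"{endpoint}|{arm}": {
                    "geometric_mean": d.geometric_mean,
                    "arithmetic_mean": d.arithmetic_mean,
                    "sd": d.sd,
                    "cv_percent": d.cv_percent,
                    "min": d.minimum,
                    "max": d.maximum,
                    "median": d.median,
                    "n": d.n,
                }
                for (endpoint, arm), d in sorted(self.descriptive.items())
            },
        }


def run_analyze(
    trial: TrialDataset,
    alpha: float = 0.05,
    limits: tuple[float, float] = BE_LIMITS_DEFAULT,
    confidence_tmax: float = 0.90,
) -> AnalysisBundle:
    """Run the complete food-effect analysis on one crossover trial."""
    endpoints = compute_endpoints(trial)
    frame = endpoints_frame(endpoints)

    descriptive: dict[tuple[str, str], DescriptiveStats] = {}
    for endpoint in ("auc_0_72", "cmax", "tmax"):
        for arm in ("A", "B"):
            values = frame.loc[frame["treatment"] == arm, endpoint]
            descriptive[(endpoint, arm)] = descriptive_stats(
                values, f"{endpoint}|{arm}"
            )

    anova = {
        endpoint: fit_crossover_anova(
            frame, endpoint, endpoint=endpoint, alpha=alpha, limits=limits
        )
        for endpoint in ("auc_0_72", "cmax")
    }
    hl = tmax_shift_analysis(frame, confidence=confidence_tmax)
    return AnalysisBundle(
        endpoints=frame,
        descriptive=descriptive,
        anova=anova,
        tmax_nonparametric=hl,
        alpha=alpha,
        limits=limits,
    )


def plot_mean_profiles(trial: TrialDataset, outdir: str | Path,
                       title: str = "Synthetic trial") -> list[Path]:
    """Linear and semilog mean concentration-time plots by arm (PNG files).

    BLQ samples enter the mean as 0 (they are pre-dose in simulated data).
    Plots are labelled synthetic: this generator's output, not measured data.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = trial.to_frame()
    df["concentration_ng_ml"] = df["concentration_ng_ml"].astype(float).fillna(0.0)
    mean = (
        df.groupby(["treatment", "nominal_time_h"])["concentration_ng_ml"]
        .mean()
        .reset_index()
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for scale, fname in (("linear", "mean_profiles_linear.png"),
                         ("log", "mean_profiles_semilog.png")):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for arm, label in _ARM_LABELS.items():
            sel = mean[mean["treatment"] == arm]
            ax.plot(sel["nominal_time_h"], sel["concentration_ng_ml"],
                    marker="o", ms=3, label=label)
        if scale == "log":
            ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("mean concentration (ng/mL)")
        ax.set_title(f"{title} — mean profiles ({scale}), synthetic data")
        ax.legend()
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
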