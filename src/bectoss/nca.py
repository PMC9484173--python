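"""Model-independent (non-compartmental) endpoints: AUC(0-72h), Cmax, tmax.

AUC uses the linear trapezoidal rule on the *actual* sampling times, truncated
or interpolated at exactly t_end = 72 h.  Cmax/tmax are the highest measured
concentration and its time; ties take the earliest time.  BLQ convention:
a BLQ sample before the first quantifiable sample contributes 0; BLQ samples
embedded between or trailing quantifiable ones are excluded, letting the
trapezoid span the gap.  (The study situation — BLQ only at pre-dose — is
insensitive to this choice.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_io import ConcentrationRecord, SequenceGroup, Treatment, TrialDataset

__all__ = [
    "SubjectEndpoints",
    "AucTruncationWarning",
    "trapezoid_auc",
    "cmax_tmax",
    "compute_endpoints",
    "endpoints_frame",
]

T_END_DEFAULT = 72.0


class AucTruncationWarning(UserWarning):
    """Last quantifiable sample precedes t_end; AUC truncated, not extrapolated."""


@dataclass(frozen=True)
class SubjectEndpoints:
    """NCA results for one subject under one treatment."""

    subject_id: str
    sequence: SequenceGroup
    period: int
    treatment: Treatment
    auc_0_72: float   # ng*h/mL
    cmax: float       # ng/mL
    tmax: float       # h, an actual sampling time


def _check_profile(times: np.ndarray, concs: np.ndarray) -> None:
    if times.size != concs.size:
        raise ValueError("times and concentrations differ in length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(concs < 0):
        raise ValueError("negative concentration")


def trapezoid_auc(times, concs, t_end: float = T_END_DEFAULT,
                  log_down: bool = False) -> float:
    """Linear trapezoidal AUC from time 0 to ``t_end`` (ng*h/mL).

    If the last sample falls before ``t_end`` the area is truncated there
    (with an :class:`AucTruncationWarning`); if a sampling interval straddles
    ``t_end`` the concentration is linearly interpolated to exactly ``t_end``.
    ``log_down=True`` switches declining segments to the log-trapezoid
    (lin-up/log-down) rule; the default is the plain linear rule.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two samples for an AUC")
    if times[0] != 0.0:
        raise ValueError("profile must start at time 0")
    _check_profile(times, concs)

    if times[-1] < t_end:
        warnings.warn(
            f"last sample at {times[-1]} h precedes t_end={t_end} h; "
            "AUC truncated at the last sample",
            AucTruncationWarning,
            stacklevel=2,
        )
    elif times[-1] > t_end:
        # interpolate the straddling segment to exactly t_end
        c_end = float(np.interp(t_end, times, concs))
        keep = times < t_end
        times = np.append(times[keep], t_end)
        concs = np.append(concs[keep], c_end)

    total = 0.0
    for (t0, t1), (c0, c1) in zip(
        zip(times[:-1], times[1:]), zip(concs[:-1], concs[1:])
    ):
        if log_down and c1 < c0 and c1 > 0:
            total += (c0 - c1) * (t1 - t0) / np.log(c0 / c1)
        else:
            total += 0.5 * (c0 + c1) * (t1 - t0)
    return float(total)


def cmax_tmax(times, concs) -> tuple[float, float]:
    """Highest measured concentration and the earliest time achieving it."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    _check_profile(times, concs)
    post = concs[times > 0]
    if post.size == 0 or np.all(post <= 0):
        raise ValueError("no quantifiable post-dose sample; Cmax/tmax undefined")
    idx = int(np.argmax(concs))  # argmax returns the first maximiser
    return float(concs[idx]), float(times[idx])


def _usable_profile(records: tuple[ConcentrationRecord, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ convention and return (actual_times, concentrations)."""
    first_quant = next((i for i, r in enumerate(records) if not r.blq), None)
    times, concs = [], []
    for i, r in enumerate(records):
        if r.blq:
            if first_quant is not None and i < first_quant:
                times.append(r.actual_time_h)
                concs.append(0.0)
            # embedded/trailing BLQ: excluded, segment spans the gap
        else:
            times.append(r.actual_time_h)
            concs.append(float(r.concentration))
    return np.asarray(times), np.asarray(concs)


def compute_endpoints(
    trial: TrialDataset, t_end: float = T_END_DEFAULT
) -> list[SubjectEndpoints]:
    """One :class:`SubjectEndpoints` per (subject, treatment), on actual times.

    Subjects missing an entire period contribute only the period they have
    (logged as a warning); the downstream crossover analysis is complete-case.
    """
    out: list[SubjectEndpoints] = []
    for subject_id in trial.subjects:
        for treatment in (Treatment.A_FED, Treatment.B_FASTED):
            records = trial.profile(subject_id, treatment)
            if not records:
                warnings.warn(
                    f"subject {subject_id} has no {treatment.value} period; "
                    "excluded from that arm",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            times, concs = _usable_profile(records)
            auc = trapezoid_auc(times, concs, t_end=t_end)
            cmax, tmax = cmax_tmax(times, concs)
            out.append(
                SubjectEndpoints(
                    subject_id=subject_id,
                    sequence=records[0].sequence,
                    period=records[0].period,
                    treatment=treatment,
                    auc_0_72=auc,
                    cmax=cmax,
                    tmax=tmax,
                )
            )
    return out


def endpoints_frame(endpoints: list[SubjectEndpoints]) -> pd.DataFrame:
    """Tidy DataFrame of per-subject endpoints (one row per subject x arm)."""
    return pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "sequence": e.sequence.value,
                "period": e.period,
                "treatment": e.treatment.value,
                "auc_0_72": e.auc_0_72,
                "cmax": e.cmax,
                "tmax": e.tmax,
            }
            for e in endpoints
        ]
    )
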