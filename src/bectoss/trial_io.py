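"""Canonical data model and I/O for long-format crossover concentration tables.

The on-disk format is a plain CSV with one assay measurement per row:

    subject_id, sequence, period, treatment, nominal_time_h, actual_time_h,
    concentration_ng_ml

``sequence`` is ``AB`` or ``BA`` (period-1 treatment then period-2 treatment),
``treatment`` is ``A`` (fed) or ``B`` (fasted), times are decimal hours, and
below-quantification-limit cells carry the literal token ``BLQ``.  Numeric
concentrations below the assay's lower limit of quantification (LLOQ) are
coerced to BLQ with a warning, mirroring how bioanalytical labs report them.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "Treatment",
    "SequenceGroup",
    "ConcentrationRecord",
    "TrialDataset",
    "TrialFormatError",
    "TrialIntegrityError",
    "DEFAULT_LLOQ",
    "CSV_COLUMNS",
    "read_trial",
    "write_trial",
    "write_results",
]

DEFAULT_LLOQ = 0.25
"""Lower limit of quantification of the drospirenone assay, ng/mL."""

CSV_COLUMNS = (
    "subject_id",
    "sequence",
    "period",
    "treatment",
    "nominal_time_h",
    "actual_time_h",
    "concentration_ng_ml",
)

BLQ_TOKEN = "BLQ"


class TrialFormatError(ValueError):
    """The file does not follow the declared column/value contract."""


class TrialIntegrityError(ValueError):
    """The table is well-formed but internally inconsistent."""


class Treatment(str, enum.Enum):
    """Study arm: A = test taken 30 min after a high-fat breakfast, B = fasted."""

    A_FED = "A"
    B_FASTED = "B"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SequenceGroup(str, enum.Enum):
    """Randomised treatment order across the two periods."""

    AB = "AB"
    BA = "BA"

    def treatment_in_period(self, period: int) -> Treatment:
        if period not in (1, 2):
            raise ValueError(f"period must be 1 or 2, got {period!r}")
        first, second = self.value
        return Treatment(first if period == 1 else second)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _time_tolerance(nominal_time_h: float) -> float:
    # ±10% of nominal or ±6 min, whichever is larger.
    return max(0.1 * nominal_time_h, 0.1)


@dataclass(frozen=True)
class ConcentrationRecord:
    """One assay measurement: who, when, which arm, and how much.

    ``concentration`` is ``None`` exactly when ``blq`` is true; a BLQ sample
    carries no number (not zero and not the LLOQ).
    """

    subject_id: str
    sequence: SequenceGroup
    period: int
    treatment: Treatment
    nominal_time_h: float
    actual_time_h: float
    concentration: float | None
    blq: bool = False

    def __post_init__(self) -> None:
        if self.period not in (1, 2):
            raise TrialIntegrityError(
                f"subject {self.subject_id}: period must be 1 or 2, got {self.period}"
            )
        if self.sequence.treatment_in_period(self.period) is not self.treatment:
            raise TrialIntegrityError(
                f"subject {self.subject_id}: sequence {self.sequence.value} implies "
                f"treatment {self.sequence.treatment_in_period(self.period).value} in "
                f"period {self.period}, got {self.treatment.value}"
            )
        if self.nominal_time_h < 0 or self.actual_time_h < 0:
            raise TrialIntegrityError(
                f"subject {self.subject_id}: negative sampling time"
            )
        if self.blq:
            if self.concentration is not None:
                raise TrialIntegrityError(
                    f"subject {self.subject_id}: BLQ record must not carry a value"
                )
        else:
            if self.concentration is None or self.concentration < 0:
                raise TrialIntegrityError(
                    f"subject {self.subject_id}: quantifiable record needs a "
                    "non-negative concentration"
                )
        if abs(self.actual_time_h - self.nominal_time_h) > _time_tolerance(
            self.nominal_time_h
        ):
            raise TrialIntegrityError(
                f"subject {self.subject_id}: actual time {self.actual_time_h} h too "
                f"far from nominal {self.nominal_time_h} h"
            )


@dataclass(frozen=True)
class TrialDataset:
    """A validated long-format 2x2 crossover concentration table."""

    records: tuple[ConcentrationRecord, ...]
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        seen: set[tuple[str, int, float]] = set()
        seq_of: dict[str, SequenceGroup] = {}
        for r in self.records:
            key = (r.subject_id, r.period, r.nominal_time_h)
            if key in seen:
                raise TrialIntegrityError(
                    f"duplicate sample for subject {r.subject_id}, period "
                    f"{r.period}, nominal time {r.nominal_time_h} h"
                )
            seen.add(key)
            prev = seq_of.setdefault(r.subject_id, r.sequence)
            if prev is not r.sequence:
                raise TrialIntegrityError(
                    f"subject {r.subject_id} appears in both sequences"
                )

    # -- convenience views -------------------------------------------------

    @property
    def subjects(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.records:
            if r.subject_id not in out:
                out.append(r.subject_id)
        return tuple(sorted(out))

    @property
    def subjects_per_sequence(self) -> dict[SequenceGroup, int]:
        seq_of = {r.subject_id: r.sequence for r in self.records}
        counts = {SequenceGroup.AB: 0, SequenceGroup.BA: 0}
        for seq in seq_of.values():
            counts[seq] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame mirroring the CSV contract, sorted canonically."""
        rows = [
            {
                "subject_id": r.subject_id,
                "sequence": r.sequence.value,
                "period": r.period,
                "treatment": r.treatment.value,
                "nominal_time_h": r.nominal_time_h,
                "actual_time_h": r.actual_time_h,
                "concentration_ng_ml": r.concentration,
                "blq": r.blq,
            }
            for r in self.records
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["subject_id", "period", "nominal_time_h"], kind="mergesort"
        ).reset_index(drop=True)

    def profile(
        self, subject_id: str, treatment: Treatment
    ) -> tuple[ConcentrationRecord, ...]:
        """All records for one subject under one treatment, in time order."""
        recs = [
            r
            for r in self.records
            if r.subject_id == subject_id and r.treatment is treatment
        ]
        return tuple(sorted(recs, key=lambda r: r.actual_time_h))


def _parse_concentration(raw: object, lloq: float, where: str) -> tuple[float | None, bool]:
    if isinstance(raw, str) and raw.strip().upper() == BLQ_TOKEN:
        return None, True
    try:
        value = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise TrialFormatError(
            f"{where}: concentration {raw!r} is neither numeric nor '{BLQ_TOKEN}'"
        ) from exc
    if value < lloq:
        warnings.warn(
            f"{where}: concentration {value} ng/mL below LLOQ {lloq} ng/mL "
            "coerced to BLQ",
            UserWarning,
            stacklevel=3,
        )
        return None, True
    return value, False


def read_trial(path: str | Path, lloq: float = DEFAULT_LLOQ) -> TrialDataset:
    """Read and validate a long-format concentration-time CSV.

    BLQ cells (token ``BLQ`` or any numeric value below ``lloq``) become
    BLQ-flagged records.  Row order in the file is irrelevant to every
    downstream statistic.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing required column(s) {missing}")
    records: list[ConcentrationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path.name}:{i}"
        try:
            sequence = SequenceGroup(str(row.sequence).strip())
            treatment = Treatment(str(row.treatment).strip())
        except ValueError as exc:
            raise TrialFormatError(f"{where}: {exc}") from exc
        conc, blq = _parse_concentration(row.concentration_ng_ml, lloq, where)
        records.append(
            ConcentrationRecord(
                subject_id=str(row.subject_id).strip(),
                sequence=sequence,
                period=int(row.period),
                treatment=treatment,
                nominal_time_h=float(row.nominal_time_h),
                actual_time_h=float(row.actual_time_h),
                concentration=conc,
                blq=blq,
            )
        )
    return TrialDataset(records=tuple(records), lloq=lloq)


def write_trial(trial: TrialDataset, path: str | Path) -> Path:
    """Write a trial back to the canonical CSV (inverse of :func:`read_trial`)."""
    path = Path(path)
    df = trial.to_frame()
    out = df[list(CSV_COLUMNS)].copy()
    conc = [
        BLQ_TOKEN if b else _fmt(v)
        for v, b in zip(df["concentration_ng_ml"], df["blq"])
    ]
    out["concentration_ng_ml"] = conc
    out["nominal_time_h"] = [_fmt(v) for v in out["nominal_time_h"]]
    out["actual_time_h"] = [_fmt(v) for v in out["actual_time_h"]]
    out.to_csv(path, index=False)
    return path


def _fmt(value: float) -> str:
    """12-significant-digit decimal text; round-trips every value we emit."""
    return format(float(value), ".12g")


# ---------------------------------------------------------------------------
# result bundle output


def write_results(bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the analysis bundle as CSV tables plus a machine-readable JSON.

    Emits ``endpoints.csv`` (per subject x treatment), ``descriptive.csv``
    (summary-statistics table), ``ratios.csv`` (point estimate / 90% CI /
    intra-subject CV per endpoint) and ``results.json``.  Rereading
    ``endpoints.csv`` and recomputing the summary tables reproduces them
    bit-identically.
    """
    from .report import AnalysisBundle  # local import to avoid a cycle

    if not isinstance(bundle, AnalysisBundle):
        raise TypeError("write_results expects an AnalysisBundle")
    if bundle.endpoints.empty:
        raise ValueError("refusing to write an empty endpoint set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}

    endpoints = bundle.endpoints.copy()
    for col in ("auc_0_72", "cmax", "tmax"):
        endpoints[col] = endpoints[col].map(_fmt)
    paths["endpoints"] = outdir / "endpoints.csv"
    endpoints.to_csv(paths["endpoints"], index=False)

    paths["descriptive"] = outdir / "descriptive.csv"
    bundle.descriptive_frame().to_csv(paths["descriptive"], index=False)

    paths["ratios"] = outdir / "ratios.csv"
    bundle.ratio_frame().to_csv(paths["ratios"], index=False)

    paths["json"] = outdir / "results.json"
    with open(paths["json"], "w") as fh:
        json.dump(bundle.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
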