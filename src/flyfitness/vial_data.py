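"""Vial-level data model and record preprocessing.

One *vial* holds a cohort of female flies reared with a single microbial
treatment.  Twice a week the adults are moved onto fresh diet for an 18-h
egg-laying window; the pupae that later form in the spent vial are counted
and normalised to the number of live females at the start of the window.
Deaths and transfer losses are tallied per interval.  This module defines
the record types for those measurements, CSV readers/writers, the weekly
contamination filter, and the two per-interval derived quantities — the
per-female fecundity ``f`` (extrapolated from the 18-h window to the full
3- or 4-day age class) and the fractional survival ``s`` between classes —
that feed the Leslie matrix downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "IntervalMeasurement",
    "VialRecord",
    "ContaminationLog",
    "SurvivalRecord",
    "ValidationError",
    "SchemaError",
    "read_vial_table",
    "write_vial_table",
    "contamination_filter",
    "per_class_fecundity",
    "interval_survival",
    "to_survival_records",
    "survival_records_to_frame",
]


class ValidationError(ValueError):
    """A record violates a count or ordering invariant."""


class SchemaError(ValueError):
    """An input table is missing mandatory columns."""


VIALS_COLUMNS = ["vial_id", "treatment", "experiment_day", "replicate"]
INTERVALS_COLUMNS = [
    "vial_id",
    "start_day",
    "class_length_days",
    "laying_window_hours",
    "pupae_count",
    "females_at_start",
    "female_deaths",
    "females_censored",
]
CONTAMINATION_COLUMNS = ["vial_id", "week", "cfu_per_fly", "unexpected_morphology"]


@dataclass(frozen=True)
class IntervalMeasurement:
    """One twice-weekly measurement window for a vial.

    ``start_day`` counts days since egg collection.  ``pupae_count`` is the
    number of F1 pupae formed from the 18-h laying window opening the
    interval; female counts track the P-generation cohort.
    """

    start_day: float
    class_length_days: float
    laying_window_hours: float
    pupae_count: int
    females_at_start: int
    female_deaths: int
    females_censored: int

    def validate(self) -> None:
        for name in ("pupae_count", "females_at_start", "female_deaths", "females_censored"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.female_deaths + self.females_censored > self.females_at_start:
            raise ValidationError(
                "female_deaths + females_censored exceeds females_at_start "
                f"({self.female_deaths} + {self.females_censored} > {self.females_at_start})"
            )
        if self.class_length_days <= 0:
            raise ValidationError("class_length_days must be positive")
        if self.laying_window_hours <= 0 or self.laying_window_hours > 24 * self.class_length_days:
            raise ValidationError(
                "laying_window_hours must be in (0, 24 * class_length_days]"
            )

    @property
    def end_day(self) -> float:
        return self.start_day + self.class_length_days

    @property
    def females_at_end(self) -> int:
        return self.females_at_start - self.female_deaths - self.females_censored


@dataclass
class VialRecord:
    """One vial: treatment labels plus its ordered interval measurements.

    ``initial_egg_count`` is back-computed as the total number of females
    ever observed (alive at the end plus all deaths and losses), under the
    assumption of complete egg-to-adult survival — the count of females at
    the first transfer is taken as the count of female eggs laid.
    """

    vial_id: str
    treatment: str
    experiment_day: int
    replicate: int
    intervals: list[IntervalMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start_day)

    @property
    def initial_egg_count(self) -> int:
        if not self.intervals:
            return 0
        return self.intervals[0].females_at_start

    @property
    def experiment_end_day(self) -> float:
        return self.intervals[-1].end_day if self.intervals else 0.0

    def validate(self) -> None:
        if not (1 <= self.experiment_day <= 3):
            raise ValidationError(
                f"vial {self.vial_id}: experiment_day must be 1-3, got {self.experiment_day}"
            )
        prev_end = None
        prev = None
        for iv in self.intervals:
            iv.validate()
            if prev_end is not None:
                if iv.start_day < prev_end - 1e-9:
                    raise ValidationError(
                        f"vial {self.vial_id}: interval at day {iv.start_day} overlaps "
                        f"the previous interval ending day {prev_end}"
                    )
                if prev is not None and iv.females_at_start != prev.females_at_end:
                    raise ValidationError(
                        f"vial {self.vial_id}: females_at_start={iv.females_at_start} at day "
                        f"{iv.start_day} does not match {prev.females_at_end} carried over"
                    )
            prev_end = iv.end_day
            prev = iv


@dataclass(frozen=True)
class ContaminationLog:
    """One weekly CFU plating check of F1 offspring from a spent vial."""

    vial_id: str
    week: int
    cfu_per_fly: float
    unexpected_morphology: bool


@dataclass(frozen=True)
class SurvivalRecord:
    """One female fly's lifespan observation.

    ``event`` is 1 for an observed death and 0 for a censored fly (lost in
    a transfer or still alive when the experiment ended); ``time_days``
    counts from egg collection.
    """

    vial_id: str
    treatment: str
    time_days: float
    event: int


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_vial_table(vials_path, intervals_path) -> list[VialRecord]:
    """Read vials.csv + intervals.csv into validated :class:`VialRecord` s.

    Both files are comma-separated UTF-8 with a mandatory header row.
    Malformed rows raise :class:`ValidationError` naming the offending row.
    An empty vials table yields an empty list with a warning.
    """
    vials_df = pd.read_csv(vials_path)
    if vials_df.empty:
        warnings.warn(f"{vials_path}: no vials found", stacklevel=2)
        return []
    _require_columns(vials_df, VIALS_COLUMNS, vials_path)
    intervals_df = pd.read_csv(intervals_path)
    _require_columns(intervals_df, INTERVALS_COLUMNS, intervals_path)

    by_vial: dict[str, list[IntervalMeasurement]] = {}
    for idx, row in intervals_df.iterrows():
        iv = IntervalMeasurement(
            start_day=float(row.start_day),
            class_length_days=float(row.class_length_days),
            laying_window_hours=float(row.laying_window_hours),
            pupae_count=int(row.pupae_count),
            females_at_start=int(row.females_at_start),
            female_deaths=int(row.female_deaths),
            females_censored=int(row.females_censored),
        )
        try:
            iv.validate()
        except ValidationError as exc:
            raise ValidationError(f"{intervals_path} row {idx + 2}: {exc}") from exc
        by_vial.setdefault(str(row.vial_id), []).append(iv)

    records = []
    for idx, row in vials_df.iterrows():
        rec = VialRecord(
            vial_id=str(row.vial_id),
            treatment=str(row.treatment),
            experiment_day=int(row.experiment_day),
            replicate=int(row.replicate),
            intervals=by_vial.get(str(row.vial_id), []),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{vials_path} row {idx + 2}: {exc}") from exc
        records.append(rec)
    unknown = set(by_vial) - {r.vial_id for r in records}
    if unknown:
        raise ValidationError(f"{intervals_path}: intervals reference unknown vial(s) {sorted(unknown)}")
    return records


def write_vial_table(records: list[VialRecord], vials_path, intervals_path) -> None:
    """Write the two-table CSV representation read by :func:`read_vial_table`."""
    vials_df = pd.DataFrame(
        [
            {
                "vial_id": r.vial_id,
                "treatment": r.treatment,
                "experiment_day": r.experiment_day,
                "replicate": r.replicate,
            }
            for r in records
        ],
        columns=VIALS_COLUMNS,
    )
    rows = []
    for r in records:
        for iv in r.intervals:
            rows.append(
                {
                    "vial_id": r.vial_id,
                    "start_day": iv.start_day,
                    "class_length_days": iv.class_length_days,
                    "laying_window_hours": iv.laying_window_hours,
                    "pupae_count": iv.pupae_count,
                    "females_at_start": iv.females_at_start,
                    "female_deaths": iv.female_deaths,
                    "females_censored": iv.females_censored,
                }
            )
    pd.DataFrame(rows, columns=INTERVALS_COLUMNS).to_csv(intervals_path, index=False)
    vials_df.to_csv(vials_path, index=False)


def read_contamination_log(path) -> list[ContaminationLog]:
    df = pd.read_csv(path)
    _require_columns(df, CONTAMINATION_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        out.append(
            ContaminationLog(
                vial_id=str(row.vial_id),
                week=int(row.week),
                cfu_per_fly=float(row.cfu_per_fly),
                unexpected_morphology=bool(row.unexpected_morphology),
            )
        )
    return out


def write_contamination_log(logs: list[ContaminationLog], path) -> None:
    pd.DataFrame(
        [
            {
                "vial_id": l.vial_id,
                "week": l.week,
                "cfu_per_fly": l.cfu_per_fly,
                "unexpected_morphology": l.unexpected_morphology,
            }
            for l in logs
        ],
        columns=CONTAMINATION_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing rules


def contamination_filter(
    vials: list[VialRecord],
    logs: list[ContaminationLog],
    threshold_cfu: float = 200.0,
    consecutive_weeks: int = 2,
) -> tuple[list[VialRecord], list[str]]:
    """Remove vials with sustained unexpected bacterial growth.

    A vial is removed from all downstream analyses when its weekly F1
    plating shows an unexpected colony morphology at >= ``threshold_cfu``
    CFU per fly in ``consecutive_weeks`` back-to-back weeks.

    Returns ``(kept_vials, removed_vial_ids)``.
    """
    known = {v.vial_id for v in vials}
    flagged_weeks: dict[str, set[int]] = {}
    for log in logs:
        if log.vial_id not in known:
            raise ValidationError(f"contamination log references unknown vial {log.vial_id!r}")
        if log.unexpected_morphology and log.cfu_per_fly >= threshold_cfu:
            flagged_weeks.setdefault(log.vial_id, set()).add(log.week)

    removed = []
    for vial_id, weeks in flagged_weeks.items():
        run = 0
        best = 0
        for w in range(min(weeks), max(weeks) + 1):
            run = run + 1 if w in weeks else 0
            best = max(best, run)
        if best >= consecutive_weeks:
            removed.append(vial_id)
    removed_set = set(removed)
    kept = [v for v in vials if v.vial_id not in removed_set]
    return kept, sorted(removed_set)


def per_class_fecundity(
    pupae_count: int,
    females_at_start: int,
    laying_window_hours: float = 18.0,
    class_length_days: float = 3.5,
) -> float:
    """Offspring per female for one age class.

    The pupae count from the ``laying_window_hours`` window is normalised
    per live female and linearly rate-extrapolated to the full class:

        f = (pupae / females) * (24 * class_length_days / laying_window_hours)

    A vial with no females and no pupae gets f = 0 (with a warning); pupae
    without females is an inconsistency and raises.
    """
    if females_at_start == 0:
        if pupae_count > 0:
            raise ValidationError("pupae counted in an interval with zero females at start")
        warnings.warn("zero females at interval start; fecundity defined as 0", stacklevel=2)
        return 0.0
    scale = 24.0 * class_length_days / laying_window_hours
    return (pupae_count / females_at_start) * scale


def interval_survival(
    females_at_start: int,
    female_deaths: int,
    females_censored: int = 0,
) -> float:
    """Fractional survival of females across one age class.

    Censored (lost-in-transfer) flies are treated as non-informative and
    removed from numerator and denominator:

        s = (start - deaths - censored) / (start - censored)

    Raises if the vial is already empty (the schedule truncates upstream).
    """
    if females_at_start == 0:
        raise ValidationError("interval_survival undefined with zero females at start")
    if female_deaths + females_censored > females_at_start:
        raise ValidationError("deaths + censored exceed females at start")
    denom = females_at_start - females_censored
    if denom == 0:
        # every fly was lost: no informative exposure, treat as full survival
        return 1.0
    return (females_at_start - female_deaths - females_censored) / denom


def to_survival_records(vials: list[VialRecord]) -> list[SurvivalRecord]:
    """Expand vial interval tallies into one lifespan record per female.

    Deaths contribute ``event=1`` at the end of their interval, transfer
    losses ``event=0`` at the end of theirs, and every female still alive
    at the last interval's end contributes ``event=0`` there.  The number
    of records per vial equals its initial female count.
    """
    records: list[SurvivalRecord] = []
    for vial in vials:
        vial.validate()
        if not vial.intervals:
            continue
        end = vial.experiment_end_day
        alive = None
        for iv in vial.intervals:
            alive = iv.females_at_start if alive is None else alive
            for _ in range(iv.female_deaths):
                records.append(SurvivalRecord(vial.vial_id, vial.treatment, iv.end_day, 1))
            for _ in range(iv.females_censored):
                records.append(SurvivalRecord(vial.vial_id, vial.treatment, iv.end_day, 0))
            alive = iv.females_at_end
        for _ in range(alive):
            records.append(SurvivalRecord(vial.vial_id, vial.treatment, end, 0))
    return records


def survival_records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "vial_id": r.vial_id,
                "treatment": r.treatment,
                "time_days": r.time_days,
                "event": r.event,
            }
            for r in records
        ],
        columns=["vial_id", "treatment", "time_days", "event"],
    )
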