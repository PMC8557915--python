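"""Leslie-matrix fitness: vital schedules, matrix assembly and the dominant
eigenvalue lambda.

A vial's fitness is summarised as the dominant eigenvalue of a Leslie
matrix whose first row holds the per-class fecundities ``f`` and whose
subdiagonal holds the between-class survival fractions ``s``.  Schedules
built from vial records carry three boundary conventions: a pre-adult
class with f = 0 and assumed complete survival (s = 1), one class per
measured interval, and a terminal class with f = 0 so the model does not
extrapolate never-ending low-level reproduction.  The Euler-Lotka root
``sum_x l_x f_x lambda^-x = 1`` provides an independent scalar oracle for
the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .vial_data import ValidationError, VialRecord, interval_survival, per_class_fecundity

__all__ = [
    "VitalSchedule",
    "LeslieMatrix",
    "FitnessValue",
    "assemble_schedule",
    "build_leslie",
    "dominant_eigenvalue",
    "euler_lotka_lambda",
    "vial_fitness",
]

#: absolute tolerance on the imaginary residual of the dominant root
IMAG_TOL = 1e-9


@dataclass(frozen=True)
class VitalSchedule:
    """Per-class fecundities ``f`` (length k) and survivals ``s`` (length k-1).

    ``s[i]`` is the fraction surviving the transition out of 1-based class
    ``i+1``'s predecessor — i.e. from class i+1 to class i+2 in 0-based
    terms ``f[i]`` belongs to class i+1.
    """

    f: tuple[float, ...]
    s: tuple[float, ...]
    class_labels: tuple[str, ...] = ()

    def __post_init__(self):
        f = tuple(float(x) for x in self.f)
        s = tuple(float(x) for x in self.s)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "s", s)
        if len(f) < 2:
            raise ValidationError("a schedule needs at least 2 classes")
        if len(s) != len(f) - 1:
            raise ValidationError(
                f"survival vector length {len(s)} != n_classes - 1 = {len(f) - 1}"
            )
        if any(x < 0 for x in f):
            raise ValidationError("fecundities must be nonnegative")
        if any(not (0.0 <= x <= 1.0) for x in s):
            raise ValidationError("survival fractions must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.f)

    def cumulative_survival(self) -> np.ndarray:
        """l_x: probability of surviving from class 1 to class x (l_1 = 1)."""
        return np.concatenate([[1.0], np.cumprod(self.s)])


@dataclass(frozen=True)
class LeslieMatrix:
    entries: np.ndarray
    class_labels: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("Leslie matrix must be square")
        mask = np.ones_like(m, dtype=bool)
        mask[0, :] = False
        k = m.shape[0]
        mask[np.arange(1, k), np.arange(0, k - 1)] = False
        if np.any(m[mask] != 0):
            raise ValidationError("off-structure entries must be exactly zero")
        if np.any(m < 0):
            raise ValidationError("Leslie matrix entries must be nonnegative")

    @property
    def k(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class FitnessValue:
    vial_id: str
    lam: float
    imag_residual: float


def assemble_schedule(
    vial: VialRecord,
    extrapolation: str = "rate",
    censoring: str = "remove",
) -> VitalSchedule:
    """Build a vial's vital schedule with the three boundary conventions.

    Classes: [pre-adult f=0, s=1] + one per measured interval + [terminal
    f=0].  Once the cohort is extinct the remaining classes keep f = 0 and
    s = 0, preserving a uniform matrix dimension across vials.

    ``extrapolation``: "rate" scales the 18-h pupae count to the full
    class window; "raw" uses the window count as the class value.
    ``censoring``: "remove" drops lost flies from both terms of s;
    "death" counts them as deaths.
    """
    if extrapolation not in ("rate", "raw"):
        raise ValueError(f"unknown extrapolation mode {extrapolation!r}")
    if censoring not in ("remove", "death"):
        raise ValueError(f"unknown censoring mode {censoring!r}")
    if not vial.intervals or vial.intervals[0].females_at_start == 0:
        raise ValidationError(f"vial {vial.vial_id} has no measurable intervals")

    f = [0.0]
    s = [1.0]
    labels = [f"egg-to-day-{vial.intervals[0].start_day:g}"]
    for iv in vial.intervals:
        labels.append(f"day-{iv.start_day:g}-to-{iv.end_day:g}")
        if iv.females_at_start == 0:
            f.append(0.0)
            s.append(0.0)
            continue
        if extrapolation == "rate":
            f.append(
                per_class_fecundity(
                    iv.pupae_count,
                    iv.females_at_start,
                    iv.laying_window_hours,
                    iv.class_length_days,
                )
            )
        else:
            f.append(iv.pupae_count / iv.females_at_start)
        if censoring == "remove":
            s.append(interval_survival(iv.females_at_start, iv.female_deaths, iv.females_censored))
        else:
            s.append(interval_survival(iv.females_at_start, iv.female_deaths + iv.females_censored, 0))
    f.append(0.0)
    labels.append("terminal")
    return VitalSchedule(f=tuple(f), s=tuple(s), class_labels=tuple(labels))


def build_leslie(schedule: VitalSchedule) -> LeslieMatrix:
    """Place f on the first row and s on the subdiagonal."""
    k = schedule.n_classes
    m = np.zeros((k, k))
    m[0, :] = schedule.f
    m[np.arange(1, k), np.arange(0, k - 1)] = schedule.s
    return LeslieMatrix(entries=m, class_labels=schedule.class_labels)


def dominant_eigenvalue(matrix: LeslieMatrix, vial_id: str = "") -> FitnessValue:
    """Fitness lambda: the largest-modulus eigenvalue, real by
    Perron-Frobenius for a nonnegative Leslie matrix.

    An imprimitive matrix (reproduction concentrated in one late class)
    has complex eigenvalues tied in modulus with the real root; the real
    member of the tie is returned.  Exceeding the imaginary-residual
    tolerance raises with diagnostics.
    """
    eigs = np.linalg.eigvals(matrix.entries)
    radius = np.max(np.abs(eigs))
    if radius == 0.0:
        return FitnessValue(vial_id=vial_id, lam=0.0, imag_residual=0.0)
    tied = eigs[np.abs(np.abs(eigs) - radius) <= 1e-9 * (1.0 + radius)]
    best = tied[np.argmin(np.abs(tied.imag))]
    residual = abs(best.imag)
    if residual >= IMAG_TOL * max(1.0, radius):
        raise ArithmeticError(
            f"dominant eigenvalue has imaginary residual {residual:.3e} "
            f"(spectral radius {radius:.6g}, eigenvalues {eigs})"
        )
    return FitnessValue(vial_id=vial_id, lam=float(max(best.real, 0.0)), imag_residual=float(residual))


def euler_lotka_lambda(schedule: VitalSchedule, rtol: float = 1e-12) -> float:
    """Positive root of sum_x l_x f_x lambda^-x = 1 by bracketed root-finding.

    Independent of the eigen-decomposition route; returns 0 when no
    reproduction is reachable with positive cumulative survival.
    """
    l = schedule.cumulative_survival()
    f = np.asarray(schedule.f)
    w = l * f
    x = np.arange(1, schedule.n_classes + 1, dtype=float)
    keep = w > 0
    if not np.any(keep):
        return 0.0
    w, x = w[keep], x[keep]

    def phi(lam: float) -> float:
        return float(np.sum(w * lam ** (-x)) - 1.0)

    hi = max(1.0, float(np.max(w))) + 1.0
    while phi(hi) > 0:
        hi *= 2.0
    lo = hi
    while phi(lo) < 0:
        lo /= 2.0
        if lo < 1e-300:
            return 0.0
    if lo == hi:
        return lo
    return float(brentq(phi, lo, hi, xtol=1e-300, rtol=max(rtol, 1e-15)))


def vial_fitness(
    vials: list[VialRecord],
    extrapolation: str = "rate",
    censoring: str = "remove",
) -> "pd.DataFrame":
    """Per-vial fitness table: one row per vial with its lambda."""
    import pandas as pd

    rows = []
    for v in vials:
        sched = assemble_schedule(v, extrapolation=extrapolation, censoring=censoring)
        fv = dominant_eigenvalue(build_leslie(sched), vial_id=v.vial_id)
        rows.append(
            {
                "vial_id": v.vial_id,
                "treatment": v.treatment,
                "experiment_day": v.experiment_day,
                "replicate": v.replicate,
                "lambda": fv.lam,
            }
        )
    return pd.DataFrame(rows, columns=["vial_id", "treatment", "experiment_day", "replicate", "lambda"])
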