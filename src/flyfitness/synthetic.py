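"""Synthetic vial-study generator.

Emulates the measurement process of the gnotobiotic vial assay: cohorts
of 30-60 female flies per vial, reared with one microbial treatment, with
eight twice-weekly 18-h fecundity windows over four weeks and interval
mortality under a treatment-specific daily hazard.  Treatments follow two
life-history archetypes — acetic-acid-bacteria-like (early fecundity
peak, higher late-life hazard, "fast") and lactic-acid-bacteria-like
(late peak, low hazard, "slow") — plus neutral controls, an axenic
treatment and one pathogen-like treatment with depressed fecundity and
high mortality.

Per-female daily fecundity follows a gamma-shaped kernel of adult age a:

    m(a) = amplitude * (a / peak)^shape * exp(shape * (1 - a / peak))

with mode at ``peak`` (days post-eclosion) and maximum ``amplitude``
(offspring per female per day).  Pupae counts are negative-binomial
(overdispersed) around ``females * m(a) * window/24``; interval deaths are
binomial under the phase hazard; transfer losses exercise the censoring
rules.  The per-treatment "truth" lambda comes from the expected vital
schedule pushed through the Euler-Lotka solver, so every downstream stage
can be tested against an analytic target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .leslie import VitalSchedule, euler_lotka_lambda
from .vial_data import ContaminationLog, IntervalMeasurement, VialRecord
from .mgwa import OGMatrix

__all__ = [
    "TreatmentArchetype",
    "StudyDesign",
    "default_archetypes",
    "default_design",
    "fecundity_rate",
    "expected_schedule",
    "simulate_vial",
    "simulate_study",
    "simulate_og_matrix",
]

#: fly age (days since egg collection) at which adults have all eclosed and
#: transfers begin for the latest-staggered experiment
ECLOSION_DAY = 8.0

#: interval start offsets (days after first transfer) and lengths for the
#: twice-weekly, 4-week design
BASE_STARTS = (10.0, 13.0, 17.0, 20.0, 24.0, 27.0, 31.0, 34.0)
BASE_LENGTHS = (3.0, 4.0, 3.0, 4.0, 3.0, 4.0, 3.0, 4.0)


@dataclass(frozen=True)
class TreatmentArchetype:
    """Life-history parameters for one microbial treatment.

    ``fecundity_peak_day`` is the adult age (days post-eclosion) of peak
    laying; ``fecundity_amplitude`` the peak per-female daily offspring;
    ``daily_hazard_by_phase`` maps fly-age ranges (days since egg
    collection) to per-day death probabilities.
    """

    name: str
    fecundity_peak_day: float
    fecundity_amplitude: float
    fecundity_shape: float = 3.0
    daily_hazard_by_phase: tuple[tuple[float, float, float], ...] = ((0.0, 60.0, 0.01),)
    maturity_days: float = 2.0
    pathogen_like: bool = False

    def daily_hazard(self, day: float) -> float:
        for start, end, h in self.daily_hazard_by_phase:
            if start <= day < end:
                return h
        return 0.0


@dataclass(frozen=True)
class StudyDesign:
    treatments: tuple[TreatmentArchetype, ...]
    n_experiments: int = 3
    vials_per_experiment: int = 3
    flies_per_vial: tuple[int, int] = (30, 60)
    n_intervals: int = 8
    interval_pattern_days: tuple[float, ...] = BASE_LENGTHS
    laying_window_hours: float = 18.0
    loss_probability: float = 0.01
    dispersion: float = 20.0
    contamination_rate: float = 0.0
    seed: int = 0


def default_archetypes() -> tuple[TreatmentArchetype, ...]:
    """Fifteen treatments spanning the fast-slow continuum.

    Five AAB-like strains peak 4-6 days post-eclosion (12.5-14.5 days from
    egg collection) with elevated late-life hazard; six LAB-like strains
    peak 10-13 days post-eclosion (up to ~21 days from egg collection)
    with low flat hazard; two neutral controls and an axenic treatment sit
    between; the pathogen-like treatment has depressed fecundity and high
    mortality throughout.
    """
    aab_hazard = ((0.0, 22.0, 0.012), (22.0, 60.0, 0.055))
    lab_hazard = ((0.0, 60.0, 0.008),)
    mid_hazard = ((0.0, 24.0, 0.010), (24.0, 60.0, 0.030))
    return (
        TreatmentArchetype("aab_1", 5.0, 2.4, 3.5, aab_hazard),
        TreatmentArchetype("aab_2", 5.5, 2.2, 3.5, aab_hazard),
        TreatmentArchetype("aab_3", 5.5, 2.4, 3.5, ((0.0, 22.0, 0.015), (22.0, 60.0, 0.06))),
        TreatmentArchetype("aab_4", 6.0, 2.1, 3.5, aab_hazard),
        TreatmentArchetype("aab_5", 6.5, 2.2, 3.5, ((0.0, 22.0, 0.010), (22.0, 60.0, 0.05))),
        TreatmentArchetype("lab_1", 10.0, 1.5, 3.0, lab_hazard),
        TreatmentArchetype("lab_2", 11.0, 1.4, 3.0, lab_hazard),
        TreatmentArchetype("lab_3", 12.0, 1.5, 3.0, ((0.0, 60.0, 0.006),)),
        TreatmentArchetype("lab_4", 12.5, 1.3, 3.0, lab_hazard),
        TreatmentArchetype("lab_5", 13.0, 1.4, 3.0, ((0.0, 60.0, 0.007),)),
        TreatmentArchetype("lab_6", 13.0, 1.2, 3.0, lab_hazard),
        TreatmentArchetype("control_1", 8.0, 1.7, 3.2, mid_hazard),
        TreatmentArchetype("control_2", 9.0, 1.6, 3.2, mid_hazard),
        TreatmentArchetype("axenic", 9.5, 1.5, 3.0, mid_hazard),
        TreatmentArchetype(
            "pathogen",
            5.0,
            0.5,
            3.5,
            ((0.0, 14.0, 0.03), (14.0, 60.0, 0.12)),
            pathogen_like=True,
        ),
    )


def default_design(seed: int = 0) -> StudyDesign:
    return StudyDesign(treatments=default_archetypes(), seed=seed)


def fecundity_rate(archetype: TreatmentArchetype, day: float) -> float:
    """Per-female daily offspring at fly age ``day`` (days since egg
    collection); zero before eclosion."""
    a = day - ECLOSION_DAY - archetype.maturity_days
    if a <= 0:
        return 0.0
    peak = archetype.fecundity_peak_day - archetype.maturity_days
    t = a / peak
    k = archetype.fecundity_shape
    return archetype.fecundity_amplitude * t**k * math.exp(k * (1.0 - t))


def _interval_grid(design: StudyDesign, experiment_day: int):
    """Fly-age interval starts for one experiment.

    Experiments are staggered on consecutive days but share transfer
    dates, so later experiments' flies are younger at each transfer.
    """
    shift = float(experiment_day - 1)
    starts = tuple(s - shift for s in BASE_STARTS[: design.n_intervals])
    lengths = design.interval_pattern_days[: design.n_intervals]
    return starts, lengths


def _interval_survival_prob(archetype: TreatmentArchetype, start: float, length: float) -> float:
    p = 1.0
    d = start
    while d < start + length - 1e-9:
        step = min(1.0, start + length - d)
        p *= (1.0 - archetype.daily_hazard(d)) ** step
        d += step
    return p


def expected_schedule(
    archetype: TreatmentArchetype, design: StudyDesign, experiment_day: int = 1
) -> VitalSchedule:
    """The noise-free vital schedule implied by an archetype.

    Expected per-class fecundity equals the daily rate at the window start
    times the class length (the 18-h window and the rate extrapolation
    cancel); survival is the product of daily complements of the hazard.
    """
    starts, lengths = _interval_grid(design, experiment_day)
    f = [0.0]
    s = [1.0]
    for start, length in zip(starts, lengths):
        f.append(fecundity_rate(archetype, start) * length)
        s.append(_interval_survival_prob(archetype, start, length))
    f.append(0.0)
    return VitalSchedule(f=tuple(f), s=tuple(s))


def truth_lambda(archetype: TreatmentArchetype, design: StudyDesign) -> float:
    return euler_lotka_lambda(expected_schedule(archetype, design))


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_vial(
    archetype: TreatmentArchetype,
    n_females: int,
    design: StudyDesign,
    rng: np.random.Generator,
    vial_id: str = "v1",
    experiment_day: int = 1,
    replicate: int = 1,
) -> VialRecord:
    """Simulate one vial's interval table.

    Per interval: deaths ~ Binomial(alive, 1 - interval survival prob),
    transfer losses ~ Binomial(survivors, loss_probability), 18-h pupae
    count ~ NegBin(females * m(start) * window/24, dispersion).
    """
    starts, lengths = _interval_grid(design, experiment_day)
    alive = int(n_females)
    intervals = []
    for start, length in zip(starts, lengths):
        rate = fecundity_rate(archetype, start)
        mean_pupae = alive * rate * design.laying_window_hours / 24.0
        pupae = _negbin(rng, mean_pupae, design.dispersion) if alive > 0 else 0
        surv_p = _interval_survival_prob(archetype, start, length)
        deaths = int(rng.binomial(alive, 1.0 - surv_p)) if alive > 0 else 0
        losses = int(rng.binomial(alive - deaths, design.loss_probability)) if alive - deaths > 0 else 0
        intervals.append(
            IntervalMeasurement(
                start_day=start,
                class_length_days=length,
                laying_window_hours=design.laying_window_hours,
                pupae_count=pupae,
                females_at_start=alive,
                female_deaths=deaths,
                females_censored=losses,
            )
        )
        alive = alive - deaths - losses
    return VialRecord(
        vial_id=vial_id,
        treatment=archetype.name,
        experiment_day=experiment_day,
        replicate=replicate,
        intervals=intervals,
    )


def simulate_study(
    design: StudyDesign,
) -> tuple[list[VialRecord], list[ContaminationLog], dict[str, float]]:
    """Simulate the full study: every treatment x experiment x replicate.

    Returns ``(vials, contamination_log, truth)`` where ``truth`` maps
    treatment name to the analytic lambda of its expected schedule.  With
    ``contamination_rate > 0`` a matching fraction of vials gets two
    consecutive high-CFU weeks injected into the log (and clean weeks
    otherwise), to exercise the contamination filter.
    """
    rng = np.random.default_rng(design.seed)
    vials: list[VialRecord] = []
    logs: list[ContaminationLog] = []
    lo, hi = design.flies_per_vial
    for arch in design.treatments:
        for exp_day in range(1, design.n_experiments + 1):
            for rep in range(1, design.vials_per_experiment + 1):
                vial_id = f"{arch.name}-e{exp_day}r{rep}"
                n = int(rng.integers(lo, hi + 1))
                vials.append(
                    simulate_vial(arch, n, design, rng, vial_id, exp_day, rep)
                )
                contaminated = rng.random() < design.contamination_rate
                onset = int(rng.integers(1, 3)) if contaminated else -1
                for week in range(1, 5):
                    if contaminated and onset <= week <= onset + 1:
                        cfu = float(rng.uniform(250.0, 5000.0))
                        morph = True
                    else:
                        cfu = float(rng.uniform(0.0, 50.0))
                        morph = bool(rng.random() < 0.02)
                    logs.append(ContaminationLog(vial_id, week, cfu, morph))
    truth = {arch.name: truth_lambda(arch, design) for arch in design.treatments}
    return vials, logs, truth


def simulate_og_matrix(
    n_ogs: int,
    strain_ids: list[str],
    planted_pattern,
    effect_delta: float,
    seed: int = 0,
    presence_prob: float = 0.5,
) -> tuple[OGMatrix, dict[str, float]]:
    """OG presence matrix with one planted fitness-associated PDG.

    Background OGs draw i.i.d. Bernoulli(presence_prob) patterns
    (duplicates allowed, giving multi-OG PDGs); one extra OG carries
    ``planted_pattern``.  Returns the matrix and the per-strain fitness
    shift (+effect_delta for strains matching the planted pattern) to add
    to a companion panel's lambda means.
    """
    pattern = tuple(int(x) for x in planted_pattern)
    if len(pattern) != len(strain_ids):
        raise ValueError("planted pattern length must match strain count")
    if sum(pattern) in (0, len(pattern)):
        raise ValueError("planted pattern must be non-degenerate")
    rng = np.random.default_rng(seed)
    presence = (rng.random((n_ogs, len(strain_ids))) < presence_prob).astype(int)
    og_ids = [f"OG{i:05d}" for i in range(1, n_ogs + 1)]
    og_ids.append("OG_planted")
    presence = np.vstack([presence, np.asarray(pattern, dtype=int)])
    shifts = {s: effect_delta * b for s, b in zip(strain_ids, pattern)}
    return OGMatrix(og_ids=og_ids, strain_ids=list(strain_ids), presence=presence), shifts


def simulate_fitness_panel(
    strain_ids: list[str],
    shifts: dict[str, float] | None = None,
    base_lambda: float = 2.0,
    strain_sd: float = 0.0,
    experiment_sd: float = 0.1,
    vial_sd: float = 0.1,
    n_experiments: int = 3,
    vials_per_experiment: int = 3,
    seed: int = 0,
):
    """Direct per-vial fitness panel for association testing.

    lambda_vial = base + strain effect (optional shift, e.g. a planted
    PDG's delta) + a shared random intercept per time-staggered experiment
    + vial noise.  Mirrors the study's layout: each strain measured in
    ``n_experiments`` experiments with ``vials_per_experiment`` vials.
    Returns a DataFrame with columns vial_id, strain_id, experiment,
    lambda.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    shifts = shifts or {}
    exp_effects = rng.normal(0.0, experiment_sd, n_experiments)
    rows = []
    for strain in strain_ids:
        mu = base_lambda + shifts.get(strain, 0.0) + rng.normal(0.0, strain_sd)
        for e in range(n_experiments):
            for r in range(vials_per_experiment):
                rows.append(
                    {
                        "vial_id": f"{strain}-e{e + 1}r{r + 1}",
                        "strain_id": strain,
                        "experiment": e + 1,
                        "lambda": mu + exp_effects[e] + rng.normal(0.0, vial_sd),
                    }
                )
    return pd.DataFrame(rows)
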