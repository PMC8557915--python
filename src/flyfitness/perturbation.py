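"""Per-vial perturbation analysis of survival and fecundity.

The engine scales a single age class's survival or fecundity by a factor
(1/2 down to 1/100000 on the default grid), recomputes each vial's Leslie
lambda, and compares observed against permuted fitness: a Spearman rank
correlation across vials, and a Kruskal-Wallis test (with a B-H-corrected
Dunn post hoc when significant) across treatments on the permuted values.
Pathogen-like treatments are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .leslie import VitalSchedule, build_leslie, dominant_eigenvalue
from .group_stats import GroupedValues, kruskal_wallis, dunn_test, PairwiseResult

__all__ = [
    "PerturbationSpec",
    "PermutationResult",
    "DEFAULT_FACTOR_DENOMINATORS",
    "scale_class",
    "spearman_rho",
    "permutation_grid",
    "results_to_frames",
]

#: the reduction-factor grid: survival/fecundity scaled to 1/d of observed
DEFAULT_FACTOR_DENOMINATORS = (2, 10, 20, 100, 200, 1000, 10000, 100000)


@dataclass(frozen=True)
class PerturbationSpec:
    """What to scale: trait, 1-based age class, and the scale factor <= 1.

    For ``trait="survival"`` the class index addresses the transition OUT
    of that class (scaling class 1 perturbs the assumed pre-adult
    transition; class 2 the first adult class).  For ``trait="fecundity"``
    it addresses the class's own per-female output.
    """

    trait: str
    class_index: int
    factor: float

    def __post_init__(self):
        if self.trait not in ("survival", "fecundity"):
            raise ValueError(f"trait must be 'survival' or 'fecundity', got {self.trait!r}")
        if not (0 < self.factor):
            raise ValueError("factor must be positive")
        if self.class_index < 1:
            raise ValueError("class_index is 1-based")


@dataclass
class PermutationResult:
    spec: PerturbationSpec
    per_vial: pd.DataFrame  # vial_id, treatment, lambda_observed, lambda_permuted
    rho: float
    rho_p: float
    kw_h: float
    kw_p: float
    dunn: PairwiseResult | None = None


def scale_class(schedule: VitalSchedule, spec: PerturbationSpec) -> VitalSchedule:
    """Return a schedule with exactly one entry multiplied by ``spec.factor``.

    All other entries are carried over bit-identically; a scaled survival
    is clamped into [0, 1] (a no-op for factors <= 1).
    """
    i = spec.class_index - 1
    if spec.trait == "fecundity":
        if i >= schedule.n_classes:
            raise IndexError(
                f"fecundity class {spec.class_index} out of range (k={schedule.n_classes})"
            )
        f = list(schedule.f)
        f[i] = f[i] * spec.factor
        return VitalSchedule(f=tuple(f), s=schedule.s, class_labels=schedule.class_labels)
    if i >= len(schedule.s):
        raise IndexError(
            f"survival transition {spec.class_index} out of range (k-1={len(schedule.s)})"
        )
    s = list(schedule.s)
    s[i] = min(1.0, max(0.0, s[i] * spec.factor))
    return VitalSchedule(f=schedule.f, s=tuple(s), class_labels=schedule.class_labels)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks with the t-approximation p.

    Raises on constant input, where the rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def permutation_grid(
    schedules: dict[str, VitalSchedule],
    treatments: dict[str, str],
    trait: str,
    factors=None,
    classes=None,
    exclude_treatments: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> list[PermutationResult]:
    """Run the full (class x factor) perturbation grid for one trait.

    ``schedules`` maps vial_id -> VitalSchedule and ``treatments`` maps
    vial_id -> treatment label.  ``factors`` are scale factors (<= 1), by
    default ``1/d`` over the standard denominator grid.  ``classes`` are
    1-based age-class indices, by default the first adult class (2).
    Vials of excluded treatments (e.g. a pathogen-like strain) are dropped
    before any statistics.
    """
    if factors is None:
        factors = tuple(1.0 / d for d in DEFAULT_FACTOR_DENOMINATORS)
    if classes is None:
        classes = (2,)
    keep = [vid for vid in schedules if treatments[vid] not in set(exclude_treatments)]
    if not keep:
        raise ValueError("no vials left after treatment exclusion")
    keep = sorted(keep)

    observed = {vid: dominant_eigenvalue(build_leslie(schedules[vid]), vid).lam for vid in keep}
    results = []
    for class_index in classes:
        for factor in factors:
            spec = PerturbationSpec(trait=trait, class_index=class_index, factor=factor)
            rows = []
            for vid in keep:
                permuted = dominant_eigenvalue(
                    build_leslie(scale_class(schedules[vid], spec)), vid
                ).lam
                rows.append(
                    {
                        "vial_id": vid,
                        "treatment": treatments[vid],
                        "lambda_observed": observed[vid],
                        "lambda_permuted": permuted,
                    }
                )
            df = pd.DataFrame(rows)
            try:
                rho, rho_p = spearman_rho(df["lambda_observed"], df["lambda_permuted"])
            except ValueError:
                rho, rho_p = float("nan"), float("nan")
            grouped = GroupedValues(
                values=df["lambda_permuted"].tolist(), group_labels=df["treatment"].tolist()
            )
            if grouped.n_groups() >= 2:
                kw_h, kw_p = kruskal_wallis(grouped)
                dunn = dunn_test(grouped) if kw_p < alpha else None
            else:
                kw_h, kw_p, dunn = float("nan"), float("nan"), None
            results.append(
                PermutationResult(
                    spec=spec, per_vial=df, rho=rho, rho_p=rho_p, kw_h=kw_h, kw_p=kw_p, dunn=dunn
                )
            )
    return results


def results_to_frames(results: list[PermutationResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long per-vial table and one-row-per-cell summary table."""
    per_vial = []
    summary = []
    for r in results:
        d = r.per_vial.copy()
        d.insert(0, "trait", r.spec.trait)
        d.insert(1, "class_index", r.spec.class_index)
        d.insert(2, "factor", r.spec.factor)
        per_vial.append(d)
        summary.append(
            {
                "trait": r.spec.trait,
                "class_index": r.spec.class_index,
                "factor": r.spec.factor,
                "rho": r.rho,
                "rho_p": r.rho_p,
                "kw_h": r.kw_h,
                "kw_p": r.kw_p,
            }
        )
    return pd.concat(per_vial, ignore_index=True), pd.DataFrame(summary)
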