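"""Metagenome-wide association of bacterial gene presence with fly fitness.

Ortholog groups (OGs) sharing the exact same strain presence/absence
pattern form one phylogenetic distribution group (PDG) — the unit of
association testing, since OGs with identical patterns are statistically
indistinguishable.  Each testable PDG's presence is regressed against
per-vial fitness lambda with a linear mixed model: presence as the fixed
effect and the time-staggered experiment as a random intercept, fit by
REML with a Wald test on the presence coefficient, Bonferroni-corrected
over the number of testable PDGs.  A pathogen-like strain is excluded by
default so the response stays approximately normal.

The random-intercept REML fit is implemented directly (profiled
likelihood over the variance ratio, Sherman-Morrison block inversion),
which keeps a full scan over hundreds of PDGs fast; it is numerically
equivalent to a general mixed-model routine for this one-random-intercept
design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "OGMatrix",
    "PDG",
    "PDGTable",
    "FitnessPanel",
    "group_pdgs",
    "shapiro_check",
    "fit_pdg_association",
    "run_mgwa",
    "read_og_matrix",
]


@dataclass
class OGMatrix:
    """Binary OG-by-strain presence matrix."""

    og_ids: list[str]
    strain_ids: list[str]
    presence: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=int)
        if self.presence.shape != (len(self.og_ids), len(self.strain_ids)):
            raise ValueError("presence matrix shape does not match og/strain ids")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        if len(set(self.og_ids)) != len(self.og_ids):
            raise ValueError("duplicate og_ids")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain_ids")


@dataclass
class PDG:
    pdg_id: str
    pattern: tuple[int, ...]
    member_ogs: list[str]
    testable: bool = True
    beta: float = float("nan")
    p_raw: float = float("nan")
    p_bonferroni: float = float("nan")
    mean_fitness_present: float = float("nan")
    mean_fitness_absent: float = float("nan")


@dataclass
class PDGTable:
    strain_ids: list[str]
    pdgs: list[PDG]

    @property
    def n_testable(self) -> int:
        return sum(p.testable for p in self.pdgs)

    def to_frame(self, annotations: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for p in self.pdgs:
            present = [s for s, b in zip(self.strain_ids, p.pattern) if b]
            rows.append(
                {
                    "pdg_id": p.pdg_id,
                    "p_raw": p.p_raw,
                    "p_bonferroni": p.p_bonferroni,
                    "beta": p.beta,
                    "mean_fitness_present": p.mean_fitness_present,
                    "mean_fitness_absent": p.mean_fitness_absent,
                    "n_ogs": len(p.member_ogs),
                    "strains_present": ";".join(present),
                    "member_ogs": ";".join(p.member_ogs),
                    "testable": p.testable,
                    "annotations": ";".join(
                        a
                        for a in ((annotations or {}).get(og, "") for og in p.member_ogs)
                        if a
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class FitnessPanel:
    """Per-vial fitness with strain and experiment labels.

    ``data`` columns: vial_id, strain_id, experiment, lambda.  Strains in
    ``exclusions`` (by default the pathogen-like treatment) are dropped
    from every association fit.
    """

    data: pd.DataFrame
    exclusions: tuple[str, ...] = ()

    def __post_init__(self):
        required = {"vial_id", "strain_id", "experiment", "lambda"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"fitness panel missing columns {sorted(missing)}")
        if not np.isfinite(self.data["lambda"]).all():
            raise ValueError("fitness panel contains non-finite lambda")

    def included(self) -> pd.DataFrame:
        return self.data[~self.data["strain_id"].isin(self.exclusions)].reset_index(drop=True)


def read_og_matrix(path) -> OGMatrix:
    """og_matrix.csv: og_id column + one 0/1 column per strain."""
    df = pd.read_csv(path)
    if "og_id" not in df.columns:
        raise ValueError(f"{path}: missing og_id column")
    strains = [c for c in df.columns if c != "og_id"]
    return OGMatrix(
        og_ids=[str(x) for x in df["og_id"]],
        strain_ids=strains,
        presence=df[strains].to_numpy(),
    )


def group_pdgs(og: OGMatrix) -> PDGTable:
    """Collapse OGs into PDGs by exact strain-presence pattern.

    Ordering is lexicographic by pattern for determinism; all-absent and
    all-present patterns are kept but flagged untestable.
    """
    if len(og.og_ids) == 0:
        raise ValueError("empty OG matrix")
    groups: dict[tuple[int, ...], list[str]] = {}
    for og_id, row in zip(og.og_ids, og.presence):
        groups.setdefault(tuple(int(x) for x in row), []).append(og_id)
    pdgs = []
    for i, pattern in enumerate(sorted(groups), start=1):
        n_present = sum(pattern)
        pdgs.append(
            PDG(
                pdg_id=f"PDG{i:04d}",
                pattern=pattern,
                member_ogs=sorted(groups[pattern]),
                testable=0 < n_present < len(pattern),
            )
        )
    return PDGTable(strain_ids=list(og.strain_ids), pdgs=pdgs)


def shapiro_check(lambdas) -> tuple[float, float]:
    """Shapiro-Wilk normality check on the fitness response.

    Logged as a diagnostic before the mixed-model scan, never used as a
    gate.  Raises for n < 3 or a constant vector.
    """
    x = np.asarray(lambdas, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def _reml_random_intercept(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """REML fit of y = b0 + b1*x + u_group + e with one random intercept.

    Profiles the REML log-likelihood over the variance ratio
    r = var(u)/var(e); per-group inverses use the Sherman-Morrison
    identity since V_i = I + r * 11'.  Returns (beta, cov_beta,
    var_u, var_e).
    """
    X = np.column_stack([np.ones_like(y), x])
    n, p = X.shape
    glist = np.unique(groups)
    masks = [groups == g for g in glist]
    parts = [(X[m], y[m], int(m.sum())) for m in masks]

    def components(r: float):
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdetV = 0.0
        for Xi, yi, ni in parts:
            c = r / (1.0 + r * ni)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            XtVX += Xi.T @ Xi - c * np.outer(sx, sx)
            XtVy += Xi.T @ yi - c * sx * sy
            ytVy += yi @ yi - c * sy * sy
            logdetV += np.log1p(r * ni)
        return XtVX, XtVy, ytVy, logdetV

    def neg_restricted_ll(log_r: float) -> float:
        XtVX, XtVy, ytVy, logdetV = components(np.exp(log_r))
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - XtVy @ beta, 1e-300)
        s2 = rss / (n - p)
        return 0.5 * ((n - p) * np.log(s2) + logdetV + logdet_XtVX)

    res = minimize_scalar(neg_restricted_ll, bounds=(-16.0, 12.0), method="bounded")
    # compare against the boundary var_u = 0 (r -> 0)
    r = float(np.exp(res.x))
    if neg_restricted_ll(-50.0) <= res.fun:
        r = 0.0
    XtVX, XtVy, ytVy, _ = components(r)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - XtVy @ beta, 0.0)
    var_e = rss / (n - p)
    cov = var_e * np.linalg.inv(XtVX)
    return beta, cov, r * var_e, var_e


def fit_pdg_association(
    panel: FitnessPanel, pattern, strain_ids: list[str]
) -> tuple[float, float, float, float]:
    """Test one PDG pattern against fitness.

    Returns ``(beta, p_raw, mean_present, mean_absent)``.  ``beta`` is the
    presence effect on lambda from the random-intercept REML fit with a
    two-sided Wald p.  The means pool per-vial lambda over strains
    carrying / lacking the PDG.  A pattern that is constant across the
    panel's (non-excluded) strains is untestable and returns NaNs.
    """
    df = panel.included()
    present_map = dict(zip(strain_ids, pattern))
    unknown = set(df["strain_id"]) - set(strain_ids)
    if unknown:
        raise ValueError(f"panel strains missing from OG matrix: {sorted(unknown)}")
    x = df["strain_id"].map(present_map).to_numpy(dtype=float)
    y = df["lambda"].to_numpy(dtype=float)
    if x.min() == x.max():
        return float("nan"), float("nan"), float("nan"), float("nan")
    beta, cov, _vu, _ve = _reml_random_intercept(y, x, df["experiment"].to_numpy())
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta[1]), p, float(y[x == 1].mean()), float(y[x == 0].mean())


def run_mgwa(
    panel: FitnessPanel,
    og: OGMatrix,
    annotations: dict[str, str] | None = None,
) -> PDGTable:
    """Full scan: PDG grouping, per-PDG mixed-model tests, Bonferroni.

    The Bonferroni multiplier is the number of PDGs actually testable in
    this panel (non-constant presence after exclusions).  The returned
    table is sorted by raw p, untestable PDGs last.
    """
    overlap = set(panel.included()["strain_id"]) & set(og.strain_ids)
    if not overlap:
        raise ValueError("no overlap between panel strains and OG matrix strains")
    table = group_pdgs(og)
    for pdg in table.pdgs:
        if not pdg.testable:
            continue
        beta, p, mp, ma = fit_pdg_association(panel, pdg.pattern, table.strain_ids)
        if not np.isfinite(p):
            pdg.testable = False
            continue
        pdg.beta, pdg.p_raw = beta, p
        pdg.mean_fitness_present, pdg.mean_fitness_absent = mp, ma
    m = table.n_testable
    for pdg in table.pdgs:
        if pdg.testable:
            pdg.p_bonferroni = min(1.0, pdg.p_raw * m)
    table.pdgs.sort(key=lambda p: (not p.testable, p.p_raw if np.isfinite(p.p_raw) else np.inf, p.pdg_id))
    return table
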