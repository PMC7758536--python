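"""Edge-wise general linear models for connectome group inference.

One linear model is fitted per connectome edge across subjects:

    y_ij = x_nc * b_nc + x_non * b_non + x_im * b_im + X_cov * b_cov + e

with three group indicator columns (no intercept; the indicators span it)
and five covariate columns (age, sex, years of education, race code, RMS
motion).  Group differences are tested with t contrasts, e.g.
``c1 = [1, -0.5, -0.5, 0, ...]`` (controls greater than all fighters) and
``c2 = [0, 1, -1, 0, ...]`` (non-impaired greater than impaired); p-values
are one-sided in the contrast direction.  The effect size is Cohen's
``d = c'beta / std_pool`` with ``std_pool = sqrt(RSS / df)`` the pooled
residual standard deviation after covariate adjustment.

The association model replaces the group indicators with an intercept and
a processing-speed (PSS) regressor and tests the PSS slope the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import EdgeStatMap, SubjectRecord, n_edges

__all__ = [
    "DesignMatrix",
    "ContrastSpec",
    "EdgeFit",
    "GROUP_DESIGN_COLUMNS",
    "ASSOCIATION_COLUMNS",
    "build_group_design",
    "build_association_design",
    "fit_edgewise",
    "contrast_map",
    "association_map",
    "contrast_nc_gt_fighters",
    "contrast_non_gt_impaired",
]

log = logging.getLogger(__name__)

GROUP_DESIGN_COLUMNS = ("group_nc", "group_non", "group_im", "age", "sex", "yoe", "race", "motion")
ASSOCIATION_COLUMNS = ("intercept", "pss", "age", "sex", "yoe", "race", "motion")
_COVARIATES = ("age", "sex", "yoe", "race", "motion")


@dataclass
class DesignMatrix:
    """Subjects x predictors design with named columns."""

    values: np.ndarray
    column_roles: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.column_roles):
            raise ValueError("column_roles must match design width")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, role: str) -> np.ndarray:
        return self.values[:, self.column_roles.index(role)]


@dataclass
class ContrastSpec:
    """Named contrast over the design columns (covariate weights zero)."""

    name: str
    coefficients: np.ndarray
    direction: str = "greater"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.direction != "greater":
            raise ValueError("contrasts are one-sided 'greater'; negate coefficients instead")

    def for_design(self, design: DesignMatrix) -> np.ndarray:
        c = self.coefficients
        if c.size > design.p:
            c = c[: design.p]
            if np.any(self.coefficients[design.p:] != 0):
                raise ValueError(f"contrast {self.name!r} weights pruned design columns")
        elif c.size < design.p:
            c = np.concatenate([c, np.zeros(design.p - c.size)])
        return c

    def negated(self) -> "ContrastSpec":
        return ContrastSpec(f"-({self.name})", -self.coefficients)


def contrast_nc_gt_fighters(p: int = 8) -> ContrastSpec:
    c = np.zeros(p)
    c[:3] = [1.0, -0.5, -0.5]
    return ContrastSpec("nc_gt_fighters", c)


def contrast_non_gt_impaired(p: int = 8) -> ContrastSpec:
    c = np.zeros(p)
    c[:3] = [0.0, 1.0, -1.0]
    return ContrastSpec("non_gt_impaired", c)


def _covariate_columns(subjects: list[SubjectRecord]) -> np.ndarray:
    rows = []
    for s in subjects:
        vals = (s.age, float(s.sex), s.yoe, float(s.race), s.rms_motion_mm)
        for name, v in zip(_COVARIATES, vals):
            if not np.isfinite(v):
                raise ValueError(f"subject {s.subject_id}: missing covariate {name}")
        rows.append(vals)
    return np.asarray(rows, dtype=float)


def _prune_degenerate(values: np.ndarray, roles: list[str], protected: int) -> tuple[np.ndarray, tuple]:
    """Drop constant covariate columns (keep the first ``protected`` columns)."""
    keep = []
    for k in range(values.shape[1]):
        if k < protected or np.ptp(values[:, k]) > 0:
            keep.append(k)
        else:
            log.warning("pruning degenerate design column %r", roles[k])
    return values[:, keep], tuple(roles[k] for k in keep)


def build_group_design(subjects: list[SubjectRecord]) -> DesignMatrix:
    """Three group-indicator columns plus the five covariates.

    Race enters as a single integer-coded column so the covariate block
    keeps exactly five columns, matching the model's stated dimensions.
    Constant covariate columns are pruned (they are collinear with the
    group indicators, which sum to the intercept).
    """
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in design")
    groups = np.array([("nc", "non_impaired", "impaired").index(s.group) for s in subjects])
    dummies = np.eye(3)[groups]
    present = dummies.sum(axis=0) > 0
    X = np.hstack([dummies, _covariate_columns(subjects)])
    roles = list(GROUP_DESIGN_COLUMNS)
    if not present.all():  # a cohort may legitimately lack one group
        X = np.hstack([dummies[:, present], _covariate_columns(subjects)])
        roles = [r for r, keep in zip(roles[:3], present) if keep] + list(roles[3:])
    X, roles = _prune_degenerate(X, roles, protected=int(present.sum()))
    return DesignMatrix(X, tuple(roles))


def build_association_design(subjects: list[SubjectRecord]) -> DesignMatrix:
    """Intercept + PSS + covariates, fighters only."""
    for s in subjects:
        if s.group == "nc":
            raise ValueError(f"association model is fighters-only; {s.subject_id} is a control")
    pss = np.array([s.pss for s in subjects], dtype=float)
    if not np.all(np.isfinite(pss)):
        raise ValueError("missing PSS score")
    if np.ptp(pss) == 0:
        raise ValueError("PSS is constant across subjects; slope not identifiable")
    X = np.hstack([np.ones((len(subjects), 1)), pss[:, None], _covariate_columns(subjects)])
    X, roles = _prune_degenerate(X, list(ASSOCIATION_COLUMNS), protected=2)
    return DesignMatrix(X, roles)


@dataclass
class EdgeFit:
    """Per-edge least-squares results shared by all contrasts."""

    betas: np.ndarray  # p x n_edges
    rss: np.ndarray  # n_edges
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    n_roi: int


def fit_edgewise(Y: np.ndarray, design: DesignMatrix, n_roi: int | None = None) -> EdgeFit:
    """Fit the model to every edge column of ``Y`` (subjects x edges)."""
    Y = np.asarray(Y, dtype=float)
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"Y has {Y.shape[0]} rows but design has {X.shape[0]} subjects")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient after pruning")
    if X.shape[0] <= rank:
        raise ValueError(f"{X.shape[0]} subjects cannot identify {rank} parameters with residual df")
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    rss = np.einsum("ij,ij->j", resid, resid)
    if n_roi is None:
        m = Y.shape[1]
        n_roi = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n_edges(n_roi) != Y.shape[1]:
        raise ValueError(f"{Y.shape[1]} columns is not the edge count of an {n_roi}-ROI connectome")
    return EdgeFit(betas, rss, X.shape[0] - rank, design, pinv @ pinv.T, n_roi)


def contrast_map(fit: EdgeFit, contrast: ContrastSpec) -> EdgeStatMap:
    """One-sided t, p and Cohen's d for a contrast at every edge.

    Edges with zero residual variance are degenerate (t undefined) and
    carry NaN; they are excluded from supra-threshold sets downstream.
    """
    c = contrast.for_design(fit.design)
    effect = c @ fit.betas
    sigma2 = fit.rss / fit.df
    cvar = float(c @ fit.xtx_inv @ c)
    degenerate = sigma2 <= 0
    n_deg = int(degenerate.sum())
    if n_deg:
        log.warning("%d degenerate edges (zero residual variance) flagged NaN", n_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        if cvar == 0:  # all-zero contrast: t identically 0
            t = np.where(degenerate, np.nan, 0.0)
            d = np.where(degenerate, np.nan, 0.0)
        else:
            t = np.where(degenerate, np.nan, effect / np.sqrt(sigma2 * cvar))
            d = np.where(degenerate, np.nan, effect / np.sqrt(sigma2))
    p = stats.t.sf(t, fit.df)
    return EdgeStatMap(t, p, d, fit.df, c, fit.n_roi, name=contrast.name)


def association_map(
    Y: np.ndarray, subjects: list[SubjectRecord], n_roi: int | None = None
) -> EdgeStatMap:
    """Edge-wise PSS-slope inference across fighters (positive direction)."""
    design = build_association_design(subjects)
    fit = fit_edgewise(Y, design, n_roi)
    c = np.zeros(design.p)
    c[design.column_roles.index("pss")] = 1.0
    return contrast_map(fit, ContrastSpec("pss_positive", c))
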