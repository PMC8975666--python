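"""Prognostic-variable screening, filtering and discretization.

The clinical catalog holds sixteen candidate variables (twelve discrete,
four continuous: diagnosis age, tumor size, lymph nodes examined, positive
lymph nodes).  Candidates are screened by a Pearson chi-square test against
the binary survival outcome, filtered by a multiple logistic regression
(variables kept at Wald / likelihood-ratio p < 0.05), and surviving
continuous variables are discretized by the equidistant method: the range
[X_min, X_max] is split into r equal intervals of width d = (X_max − X_min)/r,
value x mapping to the level j (0 ≤ j ≤ r−1) with
X_min + j·d < x ≤ X_min + (j+1)·d, and x = X_min mapping to level 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, chi2_contingency

logger = logging.getLogger(__name__)

__all__ = [
    "VariableCatalog",
    "DiscretizationSpec",
    "LogisticFilterResult",
    "default_catalog",
    "equidistant_discretize",
    "chi_square_screen",
    "logistic_filter",
    "odds_ratio",
]

CONTINUOUS_VARIABLES = (
    "diagnosis_age",
    "tumor_size",
    "examined_lymph_nodes",
    "positive_lymph_nodes",
)

DISCRETE_VARIABLES = (
    "gender",
    "marital_status",
    "location",
    "affected_side",
    "pathological_type",
    "histological_grade",
    "tumor_stage",
    "degree_of_transfer",
    "degree_of_diffusion",
    "lymph_node_accumulation",
    "operation_type",
    "radiotherapy",
)


@dataclass
class VariableCatalog:
    """Names, kinds and level counts of the candidate prognostic variables."""

    names: tuple[str, ...]
    kinds: dict[str, str]                      # "discrete" | "continuous"
    levels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.names:
            if self.kinds.get(v) not in ("discrete", "continuous"):
                raise ValueError(f"variable {v!r} needs kind discrete|continuous")
        for v, k in self.levels.items():
            if k < 2:
                raise ValueError(f"discrete variable {v!r} needs ≥ 2 levels")

    @property
    def continuous(self) -> tuple[str, ...]:
        return tuple(v for v in self.names if self.kinds[v] == "continuous")

    @property
    def discrete(self) -> tuple[str, ...]:
        return tuple(v for v in self.names if self.kinds[v] == "discrete")


def default_catalog(levels: dict[str, int] | None = None) -> VariableCatalog:
    """The sixteen-variable clinical catalog (four continuous)."""
    names = DISCRETE_VARIABLES + CONTINUOUS_VARIABLES
    kinds = {v: "discrete" for v in DISCRETE_VARIABLES}
    kinds.update({v: "continuous" for v in CONTINUOUS_VARIABLES})
    cat = VariableCatalog(names, kinds, levels or {})
    assert len(cat.continuous) == 4
    return cat


@dataclass(frozen=True)
class DiscretizationSpec:
    """Equidistant binning of a continuous variable into r equal intervals."""

    x_min: float
    x_max: float
    r: int

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.r < 2:
            raise ValueError("interval count r must be ≥ 2")

    @property
    def d(self) -> float:
        return (self.x_max - self.x_min) / self.r


def equidistant_discretize(values, spec: DiscretizationSpec) -> np.ndarray:
    """Map values in [X_min, X_max] to integer levels 0…r−1.

    Intervals are open below and closed above; the minimum maps to level 0.
    A small relative guard (1e-9 of an interval width) absorbs floating-point
    representation error at interval boundaries.
    """
    x = np.asarray(values, dtype=float)
    tol = 1e-9 * spec.d
    bad = (x < spec.x_min - tol) | (x > spec.x_max + tol)
    if np.any(bad):
        raise ValueError(
            f"value {x[bad].flat[0]} outside [{spec.x_min}, {spec.x_max}]")
    q = (x - spec.x_min) / spec.d
    j = np.ceil(q - 1e-9).astype(int) - 1
    return np.clip(j, 0, spec.r - 1)


def chi_square_screen(cohort: pd.DataFrame, outcome: str, alpha: float = 0.05,
                      specs: dict[str, DiscretizationSpec] | None = None,
                      variables: list[str] | None = None,
                      yates: bool = False) -> tuple[list[str], pd.DataFrame]:
    """Screen variables by Pearson chi-square against a binary outcome.

    Continuous variables must appear in ``specs`` and are pre-binned with
    their equidistant spec before testing.  A variable whose contingency
    table has a zero margin is skipped with a warning.  Returns the kept
    variable names (p < alpha) and a per-variable result table.
    """
    specs = specs or {}
    y = cohort[outcome]
    if y.nunique() < 2:
        raise ValueError("outcome must have at least two observed levels")
    if variables is None:
        variables = [c for c in cohort.columns if c != outcome]
    rows = []
    kept = []
    for v in variables:
        x = cohort[v]
        if v in specs:
            x = pd.Series(equidistant_discretize(x, specs[v]), index=cohort.index)
        table = pd.crosstab(x, y).to_numpy()
        if table.shape[0] < 2 or table.shape[1] < 2 or \
                np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            logger.warning("variable %s skipped: degenerate contingency table", v)
            rows.append({"variable": v, "statistic": np.nan, "df": 0,
                         "p": np.nan, "kept": False})
            continue
        correction = yates and table.shape == (2, 2)
        stat, p, df, _ = chi2_contingency(table, correction=correction)
        keep = bool(p < alpha)
        rows.append({"variable": v, "statistic": float(stat), "df": int(df),
                     "p": float(p), "kept": keep})
        if keep:
            kept.append(v)
    return kept, pd.DataFrame(rows)


@dataclass
class LogisticFilterResult:
    """Per-variable logistic-filter output mirroring a coefficient table.

    For single-degree-of-freedom variables the row carries the coefficient B,
    its standard error, Wald p, exp(B) and the Wald 95% interval for exp(B);
    multi-level categorical variables carry a likelihood-ratio p only.
    """

    table: pd.DataFrame
    retained: list[str]
    converged: bool

    def __post_init__(self) -> None:
        ok = self.table.dropna(subset=["B"])
        expb = np.exp(ok["B"].to_numpy(dtype=float))
        if not np.allclose(expb, ok["exp_b"].to_numpy(dtype=float), rtol=1e-9):
            raise ValueError("exp_b column inconsistent with coefficients")


def _check_separation(x: pd.Series, y: pd.Series, name: str) -> None:
    # complete separation by a single numeric column: the two outcome
    # classes occupy disjoint value ranges
    x = x.astype(float)
    x0, x1 = x[y == y.min()], x[y == y.max()]
    if len(x0) and len(x1) and (x0.max() < x1.min() or x1.max() < x0.min()):
        raise ValueError(f"perfect separation on column {name!r}")


def logistic_filter(cohort: pd.DataFrame, candidates: list[str], outcome: str,
                    alpha: float = 0.05,
                    categorical: list[str] | None = None,
                    maxiter: int = 100) -> LogisticFilterResult:
    """Multiple logistic regression filter of the screened candidates.

    Fits a maximum-likelihood logistic model of the binary outcome on all
    candidates jointly (Newton / IRLS, convergence when the coefficient
    change drops below 1e-8 or after ``maxiter`` iterations).  Variables in
    ``categorical`` with more than two levels are dummy-coded against their
    first level and tested by a likelihood-ratio test; all other variables
    enter as single columns and are tested by their Wald p.  Retained =
    p < alpha.
    """
    y = cohort[outcome].astype(float)
    categorical = categorical or []
    complete = cohort[candidates + [outcome]].dropna()
    n_dropped = len(cohort) - len(complete)
    if n_dropped:
        logger.info("dropped %d rows with missing entries", n_dropped)
    y = complete[outcome].astype(float)

    design_cols: dict[str, list[str]] = {}
    parts = []
    for v in candidates:
        col = complete[v]
        if v in categorical and col.nunique() > 2:
            dummies = pd.get_dummies(col, prefix=v, drop_first=True).astype(float)
            parts.append(dummies)
            design_cols[v] = list(dummies.columns)
        else:
            _check_separation(col, complete[outcome], v)
            parts.append(col.astype(float).rename(v))
            design_cols[v] = [v]
    X = sm.add_constant(pd.concat(parts, axis=1))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, tol=1e-8)
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged:
        logger.warning("logistic filter did not converge; result flagged")

    rows = []
    retained = []
    for v in candidates:
        cols = design_cols[v]
        if len(cols) == 1:
            b = float(fit.params[cols[0]])
            se = float(fit.bse[cols[0]])
            p = float(fit.pvalues[cols[0]])
            lo, hi = np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
            rows.append({"variable": v, "B": b, "std_error": se, "p": p,
                         "exp_b": float(np.exp(b)), "ci_low": float(lo),
                         "ci_high": float(hi)})
        else:
            reduced = X.drop(columns=cols)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit0 = sm.Logit(y, reduced).fit(disp=0, maxiter=maxiter, tol=1e-8)
            lr = 2 * (fit.llf - fit0.llf)
            p = float(chi2.sf(max(lr, 0.0), len(cols)))
            rows.append({"variable": v, "B": np.nan, "std_error": np.nan,
                         "p": p, "exp_b": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan})
        if converged and p < alpha:
            retained.append(v)
    return LogisticFilterResult(pd.DataFrame(rows), retained, converged)


def odds_ratio(coefficient: float) -> float:
    """exp(B): the multiplicative odds change for a one-unit increase."""
    return float(np.exp(coefficient))
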