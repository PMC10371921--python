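"""The five-equation OLS path system and indirect effects.

Equations, all fit by ordinary least squares with classical standard errors on
a single completed dataset (U = the four wave-1 lagged covariates):

1. ``M1 ~ 1 + X + U``            (a1)
2. ``M2 ~ 1 + X + U``            (a2)
3. ``M3 ~ 1 + X + U``            (a3)
4. ``Y  ~ 1 + X + M1 + M2 + M3 + U``   (b1..b3, c')
5. ``Y  ~ 1 + X + U``            (c1, the total effect)

Specific indirect effects are the products ``a_j * b_j``; the total indirect
effect is their sum.  Because all equations are OLS on the same data with
matching covariate sets, the exact decomposition ``c1 = c' + sum_j a_j b_j``
holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import PanelTable

__all__ = [
    "EquationFit",
    "PathCoefficients",
    "IndirectEffects",
    "EQUATION_SPECS",
    "design_columns",
    "fit_equations",
    "compute_indirect_effects",
    "batched_indirect_effects",
    "ParallelMediation",
]

PREDICTOR = "x_t1"
MEDIATORS = ("m1_t2", "m2_t2", "m3_t2")
OUTCOME = "y_t2"
LAGGED = ("u1_t1", "u2_t1", "u3_t1", "u4_t1")

#: equation name -> (outcome, regressors-without-intercept)
EQUATION_SPECS: dict[str, tuple[str, tuple[str, ...]]] = {
    "m1": ("m1_t2", (PREDICTOR,) + LAGGED),
    "m2": ("m2_t2", (PREDICTOR,) + LAGGED),
    "m3": ("m3_t2", (PREDICTOR,) + LAGGED),
    "outcome": (OUTCOME, (PREDICTOR,) + MEDIATORS + LAGGED),
    "total": (OUTCOME, (PREDICTOR,) + LAGGED),
}

#: sensitivity variant: each equation keeps only its own construct's lag
_OWN_LAG_SPECS: dict[str, tuple[str, tuple[str, ...]]] = {
    "m1": ("m1_t2", (PREDICTOR, "u1_t1")),
    "m2": ("m2_t2", (PREDICTOR, "u2_t1")),
    "m3": ("m3_t2", (PREDICTOR, "u3_t1")),
    "outcome": (OUTCOME, (PREDICTOR,) + MEDIATORS + ("u4_t1",)),
    "total": (OUTCOME, (PREDICTOR, "u4_t1")),
}


def design_columns(
    extra_covariates: Sequence[str] = (), covariate_set: str = "all"
) -> dict[str, tuple[str, ...]]:
    """Equation regressor sets, with optional extra covariates in *all* equations.

    ``covariate_set="all"`` (default) enters every lagged covariate in every
    equation, which preserves the exact effect decomposition; ``"own"`` is a
    sensitivity variant where each equation keeps only the lag of its own
    construct.  ``generation`` is expanded to dummy columns by the design
    builder.
    """
    if covariate_set not in ("all", "own"):
        raise ValueError("covariate_set must be 'all' or 'own'")
    specs = EQUATION_SPECS if covariate_set == "all" else _OWN_LAG_SPECS
    extra = tuple(extra_covariates)
    return {name: (spec[0], spec[1] + extra) for name, spec in specs.items()}


@dataclass
class EquationFit:
    """OLS result for one equation: estimates, classical SEs, residual df."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    df_resid: float
    nobs: int

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index,
        )


@dataclass
class PathCoefficients:
    """Estimates for all five equations on one completed dataset."""

    equations: dict[str, EquationFit]
    n: int

    @property
    def a(self) -> np.ndarray:
        return np.array(
            [self.equations[eq].params[PREDICTOR] for eq in ("m1", "m2", "m3")]
        )

    @property
    def b(self) -> np.ndarray:
        return np.array(
            [self.equations["outcome"].params[m] for m in MEDIATORS]
        )

    @property
    def cprime(self) -> float:
        return float(self.equations["outcome"].params[PREDICTOR])

    @property
    def c_total(self) -> float:
        return float(self.equations["total"].params[PREDICTOR])

    def to_frame(self) -> pd.DataFrame:
        """Long-format coefficient table (Model, Coeff, SE, t, df, p)."""
        rows = []
        for name, fit in self.equations.items():
            t = fit.tvalues
            p = fit.pvalues
            for coef in fit.params.index:
                rows.append(
                    {
                        "model": name,
                        "term": coef,
                        "coeff": fit.params[coef],
                        "se": fit.bse[coef],
                        "t": t[coef],
                        "df": fit.df_resid,
                        "p": p[coef],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


@dataclass
class IndirectEffects:
    """Specific products a_j*b_j, their sum, the direct and total effects."""

    specific: np.ndarray  # (3,)
    total_indirect: float
    direct: float
    total: float

    @property
    def labels(self) -> tuple[str, ...]:
        return ("a1b1", "a2b2", "a3b3")

    def as_dict(self) -> dict[str, float]:
        out = {lab: float(v) for lab, v in zip(self.labels, self.specific)}
        out["total_indirect"] = float(self.total_indirect)
        out["direct"] = float(self.direct)
        out["total"] = float(self.total)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _design(
    frame: pd.DataFrame, regressors: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; 'generation' expands to g2/g3 dummies."""
    cols: list[np.ndarray] = [np.ones(len(frame))]
    names = ["const"]
    for r in regressors:
        if r == "generation":
            g = frame["generation"].to_numpy()
            cols.append((np.abs(g - 2.0) < 0.5).astype(float))
            names.append("generation_2")
            cols.append((g >= 2.5).astype(float))
            names.append("generation_3")
        else:
            cols.append(frame[r].to_numpy(dtype=float))
            names.append(r)
    return np.column_stack(cols), names


def fit_equations(
    completed: PanelTable | pd.DataFrame,
    extra_covariates: Sequence[str] = (),
    covariate_set: str = "all",
    robust: bool = False,
) -> PathCoefficients:
    """Fit the five path equations on one completed dataset.

    Requires no missing cells among the analysis variables (and extra
    covariates, if any).  ``robust=True`` switches to HC3 standard errors;
    the default is classical OLS SEs.
    """
    frame = completed.to_frame() if isinstance(completed, PanelTable) else completed
    specs = design_columns(extra_covariates, covariate_set)
    used_cols = {c for _, regs in specs.values() for c in regs} | {
        out for out, _ in specs.values()
    }
    sub = frame[[c for c in frame.columns if c in used_cols or c == "generation"]]
    if sub[list(used_cols)].isna().any().any():
        raise ValueError("completed dataset contains missing cells")

    equations: dict[str, EquationFit] = {}
    for name, (outcome, regressors) in specs.items():
        x, names = _design(frame, regressors)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient design in equation '{name}'")
        model = sm.OLS(frame[outcome].to_numpy(dtype=float), x)
        res = model.fit(cov_type="HC3") if robust else model.fit()
        equations[name] = EquationFit(
            outcome=outcome,
            params=pd.Series(res.params, index=names),
            bse=pd.Series(res.bse, index=names),
            df_resid=float(res.df_resid),
            nobs=int(res.nobs),
        )
    return PathCoefficients(equations=equations, n=len(frame))


def compute_indirect_effects(coeffs: PathCoefficients) -> IndirectEffects:
    """Products a_j*b_j, their sum, c' and c1 from fitted path coefficients."""
    specific = coeffs.a * coeffs.b
    return IndirectEffects(
        specific=specific,
        total_indirect=float(specific.sum()),
        direct=coeffs.cprime,
        total=coeffs.c_total,
    )


# ---------------------------------------------------------------------------
# vectorized bootstrap kernel
# ---------------------------------------------------------------------------


_MAX_CONDITION = 1e10


def _batched_solve(
    design: np.ndarray, rhs: np.ndarray, bad: np.ndarray
) -> np.ndarray:
    """Solve stacked normal equations; mark ill-posed replicates in ``bad``.

    LAPACK solves numerically singular systems without raising, so
    rank-deficiency is detected via the condition number of each Gram matrix.
    """
    gram = np.einsum("bni,bnj->bij", design, design, optimize=True)
    if rhs.ndim == 2:  # (B, n) single target
        target = np.einsum("bni,bn->bi", design, rhs, optimize=True)[..., None]
    else:  # (B, n, k) multi-target
        target = np.einsum("bni,bnk->bik", design, rhs, optimize=True)
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(gram)
    ill = ~np.isfinite(cond) | (cond > _MAX_CONDITION)
    bad |= ill
    safe = gram.copy()
    safe[ill] = np.eye(gram.shape[1])  # placeholder; flagged rows are redrawn
    try:
        sol = np.linalg.solve(safe, target)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        sol = np.full(target.shape, np.nan)
        for i in range(len(safe)):
            try:
                sol[i] = np.linalg.solve(safe[i], target[i])
            except np.linalg.LinAlgError:
                bad[i] = True
    sol[ill] = np.nan
    return sol


def batched_indirect_effects(
    frame: pd.DataFrame,
    indices: np.ndarray,
    extra_covariates: Sequence[str] = (),
    covariate_set: str = "all",
) -> dict[str, np.ndarray]:
    """Indirect/direct effects for many case-resampled replicates at once.

    ``indices`` has shape (B, n); replicate ``b`` uses rows ``indices[b]``.
    Solves the batched normal equations for the mediator system (multi-RHS
    when the mediator equations share a design) and the outcome/total
    equations.  Replicates with a numerically singular design are flagged so
    the caller can redraw them.
    """
    specs = design_columns(extra_covariates, covariate_set)
    y = frame[OUTCOME].to_numpy(dtype=float)
    yb = y[indices]
    bad = np.zeros(len(indices), dtype=bool)

    if covariate_set == "all":
        z1, _ = _design(frame, specs["m1"][1])
        m_mat = frame[list(MEDIATORS)].to_numpy(dtype=float)
        z1b = z1[indices]
        coef1 = _batched_solve(z1b, m_mat[indices], bad)  # (B, p1, 3)
        a = coef1[:, 1, :]
        sol_tot = _batched_solve(z1b, yb, bad)[..., 0]
    else:
        a_cols = []
        for j, eq in enumerate(("m1", "m2", "m3")):
            zj, _ = _design(frame, specs[eq][1])
            mj = frame[MEDIATORS[j]].to_numpy(dtype=float)
            sol = _batched_solve(zj[indices], mj[indices], bad)[..., 0]
            a_cols.append(sol[:, 1])
        a = np.column_stack(a_cols)
        z_tot, _ = _design(frame, specs["total"][1])
        sol_tot = _batched_solve(z_tot[indices], yb, bad)[..., 0]

    z2, _ = _design(frame, specs["outcome"][1])
    sol2 = _batched_solve(z2[indices], yb, bad)[..., 0]

    b = sol2[:, 2:5]
    cprime = sol2[:, 1]
    c_total = sol_tot[:, 1]
    specific = a * b
    with np.errstate(invalid="ignore"):
        nonfinite = ~np.isfinite(specific).all(axis=1)
    bad |= nonfinite
    return {
        "specific": specific,
        "total_indirect": specific.sum(axis=1),
        "direct": cprime,
        "total": c_total,
        "bad": bad,
    }


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class ParallelMediation(BaseEstimator):
    """Parallel multiple-mediation path model on a completed panel.

    scikit-learn style estimator: ``fit(X)`` takes a completed
    :class:`~panelmediate.data_model.PanelTable` or DataFrame and exposes

    - ``paths_`` — :class:`PathCoefficients` for all five equations,
    - ``indirect_`` — :class:`IndirectEffects` (a_j*b_j products, total, c', c1).

    Parameters
    ----------
    extra_covariates : tuple of str
        Demographic covariates appended to every equation (e.g.
        ``("age", "gender", "generation")``; generation expands to dummies).
    robust : bool
        Use HC3 instead of classical standard errors.
    """

    def __init__(self, extra_covariates: tuple = (), robust: bool = False):
        self.extra_covariates = extra_covariates
        self.robust = robust

    def fit(self, X, y=None):
        self.paths_ = fit_equations(
            X, extra_covariates=self.extra_covariates, robust=self.robust
        )
        self.indirect_ = compute_indirect_effects(self.paths_)
        self.n_features_in_ = len(self.paths_.equations["outcome"].params) - 1
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted outcome from the mediator-adjusted equation."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "paths_")
        frame = X.to_frame() if isinstance(X, PanelTable) else X
        regs = (PREDICTOR,) + MEDIATORS + LAGGED + tuple(self.extra_covariates)
        design, names = _design(frame, regs)
        params = self.paths_.equations["outcome"].params
        return design @ params[names].to_numpy()
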