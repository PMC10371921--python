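"""Multiple imputation by joint-normal data augmentation.

The incomplete panel (analysis variables, wave-0 auxiliaries, age and
dummy-coded demographics) is modelled as multivariate normal.  A Gibbs sampler
alternates

* **I-step** — for each row, draw its missing entries from the conditional
  normal given its observed entries and the current ``(mu, Sigma)``.  Rows are
  grouped by missingness pattern and drawn jointly per pattern; the
  conditional moments come from the precision matrix, so one 17x17 inverse per
  iteration plus one small factorization per pattern suffices.
* **P-step** — draw ``(mu, Sigma)`` from the normal-inverse-Wishart posterior
  under the diffuse Jeffreys prior given the completed data:
  ``Sigma ~ IW(n-1, S)``, ``mu | Sigma ~ N(ybar, Sigma/n)``.

Multiple chains from overdispersed starts feed the Gelman-Rubin potential
scale reduction factor (PSRF); imputations are then drawn from a single chain
post burn-in at equal spacing.  Imputed continuous values are clipped to their
scale bounds (never rounded to the Likert grid); dummy-coded categorical
demographics are mapped back to the nearest valid category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import (
    ANALYSIS_VARIABLES,
    AUXILIARY_VARIABLES,
    VARIABLE_BOUNDS,
    PanelTable,
)

__all__ = [
    "ImputationConfig",
    "ConvergenceDiagnostics",
    "ImputationSet",
    "ChainStates",
    "ConvergenceError",
    "run_data_augmentation",
    "compute_psrf",
    "draw_imputations",
    "multiply_impute",
    "fcs_impute",
    "JointNormalImputer",
]

logger = logging.getLogger("panelmediate.imputation")

#: numeric columns entering the imputation model, in canonical order
_CATEGORICAL_DUMMIES = ("gen2", "gen3")
DEFAULT_IMPUTATION_COLUMNS: tuple[str, ...] = (
    ANALYSIS_VARIABLES + AUXILIARY_VARIABLES + ("age", "gender") + _CATEGORICAL_DUMMIES
)


class ConvergenceError(RuntimeError):
    """Raised when the PSRF gate blocks drawing imputations."""


@dataclass
class ImputationConfig:
    """Chain lengths, imputation count and convergence gate.

    Defaults are the full-scale study settings: 5000 burn-in iterations, a
    further 10,000 iterations from which 100 imputations are saved at equal
    spacing, and a PSRF threshold of 1.05 computed across >= 2 chains.
    """

    burn_in: int = 5000
    post_burn_iterations: int = 10_000
    n_imputations: int = 100
    n_chains: int = 2
    psrf_threshold: float = 1.05
    included_variables: tuple[str, ...] | None = None
    ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.post_burn_iterations < self.n_imputations:
            raise ValueError("post_burn_iterations must be >= n_imputations")
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for the PSRF")
        if self.burn_in < 2:
            raise ValueError("burn_in must be at least 2")

    def columns(self) -> tuple[str, ...]:
        return (
            tuple(self.included_variables)
            if self.included_variables is not None
            else DEFAULT_IMPUTATION_COLUMNS
        )


@dataclass
class ConvergenceDiagnostics:
    """Per-parameter PSRF values and the convergence verdict."""

    psrf: pd.Series
    converged: bool
    chain_length: int
    threshold: float

    @property
    def max_psrf(self) -> float:
        return float(self.psrf.max())


@dataclass
class ImputationSet:
    """M completed copies of the panel plus chain diagnostics."""

    completed_tables: list[PanelTable]
    diagnostics: ConvergenceDiagnostics | None
    config: ImputationConfig
    n_regularized: int = 0

    @property
    def m(self) -> int:
        return len(self.completed_tables)


# ---------------------------------------------------------------------------
# matrix <-> panel conversion
# ---------------------------------------------------------------------------


def _panel_to_matrix(table: PanelTable, columns: Sequence[str]) -> np.ndarray:
    frame = table.to_frame()
    out = np.empty((table.n, len(columns)))
    for j, col in enumerate(columns):
        if col == "gen2":
            g = frame["generation"].to_numpy(dtype=float)
            out[:, j] = np.where(np.isnan(g), np.nan, (np.abs(g - 2) < 0.5))
        elif col == "gen3":
            g = frame["generation"].to_numpy(dtype=float)
            out[:, j] = np.where(np.isnan(g), np.nan, (g >= 2.5))
        else:
            out[:, j] = frame[col].to_numpy(dtype=float)
    return out


def _matrix_to_panel(
    template: PanelTable, columns: Sequence[str], completed: np.ndarray
) -> PanelTable:
    """Materialize one completed dataset: clip imputed cells, round categories."""
    frame = template.to_frame()
    cols = list(columns)
    values = completed.copy()
    if "gen2" in cols and "gen3" in cols:
        j2, j3 = cols.index("gen2"), cols.index("gen3")
        scores = np.column_stack(
            [1.0 - values[:, j2] - values[:, j3], values[:, j2], values[:, j3]]
        )
        generation = 1.0 + np.argmax(scores, axis=1)
    else:
        generation = None
    for j, col in enumerate(cols):
        if col in _CATEGORICAL_DUMMIES:
            continue
        if col == "gender":
            vals = np.clip(np.round(values[:, j]), 0, 1)
        else:
            lo, hi = template.bounds.get(col, VARIABLE_BOUNDS[col])
            vals = np.clip(values[:, j], lo, hi)
        observed = template.mask[col].to_numpy()
        original = frame[col].to_numpy(dtype=float)
        frame[col] = np.where(observed, original, vals)
    if generation is not None and "generation" in frame.columns:
        observed = template.mask["generation"].to_numpy()
        frame["generation"] = np.where(
            observed, frame["generation"].to_numpy(dtype=float), generation
        )
    return PanelTable(frame, bounds=template.bounds)


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------


class _Chain:
    """One data-augmentation chain over a fixed missingness layout."""

    __slots__ = ("data", "mu", "sigma", "rng", "n_regularized")

    def __init__(self, data, mu, sigma, rng):
        self.data = data
        self.mu = mu
        self.sigma = sigma
        self.rng = rng
        self.n_regularized = 0


@dataclass
class _PatternGroup:
    """All missingness patterns sharing the same number of missing cells."""

    mis_stack: np.ndarray  # (G, k) missing-column indices per pattern
    row_idx: np.ndarray  # (N,) rows covered by this group
    pat_of_row: np.ndarray  # (N,) pattern index (into mis_stack) per row
    mis_per_row: np.ndarray  # (N, k) missing-column indices per row


@dataclass
class _PatternLayout:
    """Fixed missingness layout of a panel, grouped for batched I-steps."""

    miss: np.ndarray  # (n, p) boolean missing mask
    groups: list[_PatternGroup]

    @property
    def any_missing(self) -> bool:
        return bool(self.miss.any())


@dataclass
class ChainStates:
    """Sampler state after burn-in: chains, PSRF history, pattern layout."""

    chains: list[_Chain]
    history: np.ndarray  # (n_chains, L, K) parameter trajectories
    param_names: list[str]
    layout: _PatternLayout
    columns: tuple[str, ...]
    template: PanelTable
    config: ImputationConfig
    any_missing: bool


def _patterns(miss: np.ndarray) -> _PatternLayout:
    """Group rows by missingness pattern, then patterns by missing count."""
    uniq, inverse = np.unique(miss, axis=0, return_inverse=True)
    by_k: dict[int, list[tuple[int, np.ndarray]]] = {}
    pattern_rows: dict[int, np.ndarray] = {}
    for g, patt in enumerate(uniq):
        mis = np.where(patt)[0]
        if not mis.size:
            continue
        pattern_rows[g] = np.where(inverse == g)[0]
        by_k.setdefault(mis.size, []).append((g, mis))
    groups = []
    for k, members in sorted(by_k.items()):
        mis_stack = np.stack([mis for _, mis in members])  # (G, k)
        row_chunks, pat_chunks = [], []
        for local, (g, _) in enumerate(members):
            rows = pattern_rows[g]
            row_chunks.append(rows)
            pat_chunks.append(np.full(rows.size, local))
        row_idx = np.concatenate(row_chunks)
        pat_of_row = np.concatenate(pat_chunks)
        groups.append(
            _PatternGroup(
                mis_stack=mis_stack,
                row_idx=row_idx,
                pat_of_row=pat_of_row,
                mis_per_row=mis_stack[pat_of_row],
            )
        )
    return _PatternLayout(miss=miss, groups=groups)


def _istep(chain: _Chain, layout: _PatternLayout, ridge: float) -> None:
    """Draw missing cells from their conditional normals given (mu, Sigma).

    Vectorized over rows and over same-size missingness patterns: with the
    precision matrix P, the conditional of the missing block m given the
    observed block o is N(mu_m - P_mm^{-1} P_mo (y_o - mu_o), P_mm^{-1}), and
    ``P_mo (y_o - mu_o)`` for every row at once is one matrix product with the
    observed residuals (missing coordinates zeroed).
    """
    if not layout.groups:
        return
    p = chain.sigma.shape[0]
    try:
        prec = np.linalg.inv(chain.sigma)
    except np.linalg.LinAlgError:
        prec = np.linalg.inv(chain.sigma + ridge * np.eye(p))
        chain.n_regularized += 1
    data, mu, rng = chain.data, chain.mu, chain.rng
    resid = np.where(layout.miss, 0.0, data - mu)  # observed residuals
    big = resid @ prec  # (n, p): big[i, j] = sum_o P[j, o] resid[i, o]
    for grp in layout.groups:
        k = grp.mis_stack.shape[1]
        a = prec[grp.mis_stack[:, :, None], grp.mis_stack[:, None, :]]  # (G,k,k)
        try:
            chol = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            a = a + ridge * np.eye(k)
            chol = np.linalg.cholesky(a)
            chain.n_regularized += 1
        a_rows = a[grp.pat_of_row]  # (N, k, k)
        rhs = big[grp.row_idx[:, None], grp.mis_per_row]  # (N, k)
        shift = np.linalg.solve(a_rows, rhs[..., None])[..., 0]
        cond_mean = mu[grp.mis_per_row] - shift
        z = rng.standard_normal((grp.row_idx.size, k))
        # cov = A^{-1} = L^{-T} L^{-1}; L^{-T} z has exactly that covariance
        lt_rows = np.transpose(chol[grp.pat_of_row], (0, 2, 1))
        draws = cond_mean + np.linalg.solve(lt_rows, z[..., None])[..., 0]
        data[grp.row_idx[:, None], grp.mis_per_row] = draws


def _pstep(chain: _Chain, ridge: float) -> None:
    """Draw (mu, Sigma) from the Jeffreys normal-inverse-Wishart posterior."""
    data, rng = chain.data, chain.rng
    n, p = data.shape
    ybar = data.mean(axis=0)
    centered = data - ybar
    s = centered.T @ centered
    df = n - 1
    if df < p:
        raise ValueError(
            f"too few rows ({n}) for a proper posterior over {p} variables"
        )
    try:
        sigma = stats.invwishart.rvs(df=df, scale=s, random_state=rng)
    except np.linalg.LinAlgError:
        sigma = stats.invwishart.rvs(
            df=df, scale=s + ridge * np.trace(s) * np.eye(p), random_state=rng
        )
        chain.n_regularized += 1
        logger.debug("P-step scale matrix regularized (ridge %g)", ridge)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = sigma + ridge * np.trace(sigma) * np.eye(p)
        chol = np.linalg.cholesky(sigma)
        chain.n_regularized += 1
    chain.sigma = sigma
    chain.mu = ybar + (chol @ rng.standard_normal(p)) / np.sqrt(n)


def _state_vector(chain: _Chain) -> np.ndarray:
    return np.concatenate([chain.mu, np.diag(chain.sigma)])


def run_data_augmentation(table: PanelTable, config: ImputationConfig) -> ChainStates:
    """Run ``n_chains`` independent burn-in chains from overdispersed starts.

    Parameter trajectories (means and variances) over the second half of the
    burn-in are retained for the PSRF.  Deterministic given ``config.seed``.
    """
    columns = config.columns()
    matrix = _panel_to_matrix(table, columns)
    n, p = matrix.shape
    never_observed = np.isnan(matrix).all(axis=0)
    if never_observed.any():
        bad = [columns[j] for j in np.where(never_observed)[0]]
        raise ValueError(f"variables with no observed values: {bad}")

    miss = np.isnan(matrix)
    layout = _patterns(miss)
    col_means = np.nanmean(matrix, axis=0)
    col_sds = np.nanstd(matrix, axis=0, ddof=1)
    col_sds = np.where((col_sds <= 0) | ~np.isfinite(col_sds), 1e-3, col_sds)

    retain = max(min(config.burn_in // 2, config.burn_in - 1), 10)
    retain = min(retain, config.burn_in)
    history = np.empty((config.n_chains, retain, 2 * p))
    chains: list[_Chain] = []
    # overdispersed starts: jittered means, inflated/deflated diagonal starts
    scale_factors = [1.0, 3.0, 0.3, 5.0, 0.2]
    for c in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed), 101, c])
        start = matrix.copy()
        jitter = rng.standard_normal(p) * col_sds * (0.0 if c == 0 else 1.0)
        mu0 = col_means + jitter
        for j in range(p):
            rows = np.where(miss[:, j])[0]
            if rows.size:
                start[rows, j] = mu0[j]
        sigma0 = np.diag(col_sds**2) * scale_factors[c % len(scale_factors)]
        chains.append(_Chain(start, mu0.copy(), sigma0, rng))

    for it in range(config.burn_in):
        for c, chain in enumerate(chains):
            _istep(chain, layout, config.ridge)
            _pstep(chain, config.ridge)
            if it >= config.burn_in - retain:
                history[c, it - (config.burn_in - retain)] = _state_vector(chain)

    param_names = [f"mu[{c}]" for c in columns] + [f"var[{c}]" for c in columns]
    return ChainStates(
        chains=chains,
        history=history,
        param_names=param_names,
        layout=layout,
        columns=columns,
        template=table,
        config=config,
        any_missing=layout.any_missing,
    )


def compute_psrf(states: ChainStates | np.ndarray) -> ConvergenceDiagnostics:
    """Gelman-Rubin potential scale reduction factor per scalar parameter.

    ``PSRF = sqrt(((L-1)/L * W + B/L) / W)`` with W the mean within-chain
    variance and B the between-chain variance of chain means times L.
    Requires >= 2 chains with >= 10 retained iterations; zero within-chain
    variance for a parameter is an error.
    """
    if isinstance(states, ChainStates):
        history = states.history
        names = states.param_names
        threshold = states.config.psrf_threshold
    else:
        history = np.asarray(states, dtype=float)
        names = [f"param[{k}]" for k in range(history.shape[2])]
        threshold = 1.05
    if history.ndim != 3 or history.shape[0] < 2:
        raise ValueError("need trajectories from at least two chains")
    n_chains, length, _ = history.shape
    if length < 10:
        raise ValueError("need at least 10 retained iterations per chain")
    w = history.var(axis=1, ddof=1).mean(axis=0)
    if (w <= 0).any():
        raise ValueError("zero within-chain variance; PSRF undefined")
    chain_means = history.mean(axis=1)
    b = length * chain_means.var(axis=0, ddof=1)
    var_plus = (length - 1) / length * w + b / length
    psrf = pd.Series(np.sqrt(var_plus / w), index=names)
    return ConvergenceDiagnostics(
        psrf=psrf,
        converged=bool(psrf.max() < threshold),
        chain_length=length,
        threshold=threshold,
    )


def draw_imputations(
    states: ChainStates,
    config: ImputationConfig | None = None,
    diagnostics: ConvergenceDiagnostics | None = None,
    force: bool = False,
) -> ImputationSet:
    """Save M completed datasets from chain 0 at equal post-burn-in spacing.

    Blocks (raises :class:`ConvergenceError`) when the PSRF gate failed,
    unless ``force=True`` (the override is logged).
    """
    config = config or states.config
    if diagnostics is None:
        diagnostics = compute_psrf(states)
    # with nothing to impute the gate is vacuous: MI degenerates to copies
    if not diagnostics.converged and states.any_missing:
        if not force:
            raise ConvergenceError(
                f"max PSRF {diagnostics.max_psrf:.3f} >= {diagnostics.threshold}; "
                "pass force=True to draw imputations anyway"
            )
        logger.warning(
            "convergence gate overridden (max PSRF %.3f)", diagnostics.max_psrf
        )
    m = config.n_imputations
    spacing = config.post_burn_iterations // m
    if spacing < 1:
        raise ValueError("requested M exceeds the available post-burn-in spacing")

    chain = states.chains[0]
    completed: list[PanelTable] = []
    if not states.any_missing:
        # degenerate MI: nothing to impute, all tables equal the input
        for _ in range(m):
            completed.append(states.template.copy())
    else:
        for it in range(1, m * spacing + 1):
            _istep(chain, states.layout, config.ridge)
            _pstep(chain, config.ridge)
            if it % spacing == 0:
                completed.append(
                    _matrix_to_panel(states.template, states.columns, chain.data)
                )
    n_reg = sum(c.n_regularized for c in states.chains)
    if n_reg:
        logger.info("%d covariance regularizations applied during sampling", n_reg)
    return ImputationSet(
        completed_tables=completed,
        diagnostics=diagnostics,
        config=config,
        n_regularized=n_reg,
    )


def multiply_impute(
    table: PanelTable, config: ImputationConfig, force: bool = False
) -> ImputationSet:
    """Burn-in + PSRF gate + draw: the full MI front end in one call."""
    states = run_data_augmentation(table, config)
    diagnostics = compute_psrf(states)
    return draw_imputations(states, config, diagnostics, force=force)


# ---------------------------------------------------------------------------
# FCS alternative (sensitivity grid engine)
# ---------------------------------------------------------------------------


def fcs_impute(
    table: PanelTable, config: ImputationConfig, n_cycles: int = 5
) -> ImputationSet:
    """Fully conditional specification via per-variable normal regression.

    Each imputation runs ``n_cycles`` sweeps; in each sweep every incomplete
    variable is regressed on all others (current completed values), with the
    residual variance drawn from its scaled inverse-chi-square posterior and
    coefficients from their normal posterior, then missing cells are drawn
    from the posterior predictive.  A sensitivity-grid alternative to the
    joint data-augmentation engine, not the default.
    """
    columns = config.columns()
    matrix = _panel_to_matrix(table, columns)
    miss = np.isnan(matrix)
    if miss.all(axis=0).any():
        raise ValueError("a variable has no observed values")
    incomplete = [j for j in range(matrix.shape[1]) if miss[:, j].any()]
    completed_tables: list[PanelTable] = []
    for m_idx in range(config.n_imputations):
        rng = np.random.default_rng([int(config.seed), 202, m_idx])
        data = matrix.copy()
        col_means = np.nanmean(matrix, axis=0)
        for j in incomplete:
            data[miss[:, j], j] = col_means[j]
        for _ in range(n_cycles):
            for j in incomplete:
                obs = ~miss[:, j]
                others = [k for k in range(matrix.shape[1]) if k != j]
                x_obs = np.column_stack([np.ones(obs.sum()), data[np.ix_(obs, others)]])
                y_obs = data[obs, j]
                xtx = x_obs.T @ x_obs + config.ridge * np.eye(x_obs.shape[1])
                beta_hat = np.linalg.solve(xtx, x_obs.T @ y_obs)
                resid = y_obs - x_obs @ beta_hat
                dof = max(obs.sum() - x_obs.shape[1], 1)
                sigma2 = resid @ resid / rng.chisquare(dof)
                cov_chol = np.linalg.cholesky(sigma2 * np.linalg.inv(xtx))
                beta = beta_hat + cov_chol @ rng.standard_normal(len(beta_hat))
                x_mis = np.column_stack(
                    [np.ones(miss[:, j].sum()), data[np.ix_(miss[:, j], others)]]
                )
                data[miss[:, j], j] = x_mis @ beta + rng.normal(
                    0.0, np.sqrt(sigma2), size=miss[:, j].sum()
                )
        completed_tables.append(_matrix_to_panel(table, columns, data))
    return ImputationSet(
        completed_tables=completed_tables, diagnostics=None, config=config
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class JointNormalImputer(BaseEstimator, TransformerMixin):
    """scikit-learn style front end to the data-augmentation imputer.

    ``fit(X)`` runs the chains on a :class:`PanelTable` (or a DataFrame with a
    ``subject_id`` column) and exposes

    - ``imputations_`` — list of M completed :class:`PanelTable` objects,
    - ``psrf_`` — per-parameter PSRF series,
    - ``converged_`` — the convergence verdict.

    ``transform(X)`` returns a single completed DataFrame whose imputed cells
    are the across-imputation means (a convenience completion; use
    ``imputations_`` for proper multiple-imputation inference).
    """

    def __init__(
        self,
        n_imputations: int = 100,
        burn_in: int = 5000,
        post_burn_iterations: int = 10_000,
        n_chains: int = 2,
        psrf_threshold: float = 1.05,
        ridge: float = 1e-6,
        force: bool = False,
        random_state: int = 0,
    ):
        self.n_imputations = n_imputations
        self.burn_in = burn_in
        self.post_burn_iterations = post_burn_iterations
        self.n_chains = n_chains
        self.psrf_threshold = psrf_threshold
        self.ridge = ridge
        self.force = force
        self.random_state = random_state

    def _config(self) -> ImputationConfig:
        return ImputationConfig(
            burn_in=self.burn_in,
            post_burn_iterations=self.post_burn_iterations,
            n_imputations=self.n_imputations,
            n_chains=self.n_chains,
            psrf_threshold=self.psrf_threshold,
            ridge=self.ridge,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        table = X if isinstance(X, PanelTable) else PanelTable(X)
        result = multiply_impute(table, self._config(), force=self.force)
        self.imputations_ = result.completed_tables
        self.diagnostics_ = result.diagnostics
        self.psrf_ = result.diagnostics.psrf
        self.converged_ = result.diagnostics.converged
        self.n_features_in_ = len(table.columns)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "imputations_")
        stacked = np.stack(
            [t.data.to_numpy(dtype=float) for t in self.imputations_]
        )
        mean_completion = stacked.mean(axis=0)
        out = self.imputations_[0].to_frame()
        out.loc[:, self.imputations_[0].columns] = mean_completion
        return out
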