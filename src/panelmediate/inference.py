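"""Pooling across imputations and percentile-bootstrap inference.

**Rubin's rules.**  For a scalar parameter estimated on each of M completed
datasets: pooled estimate ``Qbar`` = mean of per-imputation estimates, within
variance ``Wbar`` = mean squared SE, between variance ``B`` (ddof=1), total
variance ``T = Wbar + (1 + 1/M) * B``, with Barnard-Rubin small-sample degrees
of freedom against the complete-data residual df.

**Imputation-then-bootstrap (ITB).**  B case-resampled replicates are drawn
from each of the M completed datasets; the M*B indirect-effect draws are
pooled per effect and 95% percentile intervals taken from the pooled draws.

**Bootstrap-then-imputation (BTI).**  B case resamples of the *incomplete*
table are each imputed a small number of times with short chains; the draw for
each effect is the mean over its per-imputation estimates.

Point estimates are means over imputations of per-imputation products, which
preserves the decomposition ``c1 = c' + sum_j a_j b_j`` at the pooled level.
Percentile bounds use the empirical inverse-CDF quantile convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PanelTable
from .imputation import (
    ImputationConfig,
    ImputationSet,
    _Chain,
    _istep,
    _matrix_to_panel,
    _panel_to_matrix,
    _patterns,
    _pstep,
    multiply_impute,
)
from .path_models import (
    PathCoefficients,
    batched_indirect_effects,
    compute_indirect_effects,
    fit_equations,
)

__all__ = [
    "PooledFit",
    "BootstrapDistribution",
    "CIResult",
    "rubin_pool",
    "pool_indirect_effects",
    "imputation_then_bootstrap",
    "bootstrap_then_imputation",
    "percentile_ci",
    "EFFECT_NAMES",
]

logger = logging.getLogger("panelmediate.inference")

EFFECT_NAMES: tuple[str, ...] = ("a1b1", "a2b2", "a3b3", "total_indirect")

_MAX_REDRAW_ROUNDS = 25


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


def _barnard_rubin_df(lam: float, m: int, df_com: float) -> float:
    """Barnard-Rubin adjusted degrees of freedom (bounded by complete-data df)."""
    nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
    if lam <= 1e-12:
        return nu_obs
    nu_old = (m - 1) / lam**2
    return nu_old * nu_obs / (nu_old + nu_obs)


@dataclass
class PooledFit:
    """Rubin-pooled coefficients for all five equations across M imputations."""

    table: pd.DataFrame  # model, term, estimate, se, t, df, p, within, between
    m: int

    def coefficient(self, model: str, term: str) -> pd.Series:
        row = self.table[(self.table["model"] == model) & (self.table["term"] == term)]
        if row.empty:
            raise KeyError(f"no pooled coefficient for ({model}, {term})")
        return row.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def rubin_pool(fits: Sequence[PathCoefficients]) -> PooledFit:
    """Pool per-equation OLS estimates and SEs across imputations.

    Requires M >= 2 fits with identical equation specifications.  Degenerate
    pooling (identical fits, e.g. no missing data) yields B = 0 and T = Wbar.
    """
    if len(fits) < 2:
        raise ValueError("rubin_pool requires at least two imputations")
    first = fits[0]
    spec = {
        name: tuple(eq.params.index) for name, eq in first.equations.items()
    }
    for f in fits[1:]:
        if {n: tuple(e.params.index) for n, e in f.equations.items()} != spec:
            raise ValueError("inconsistent equation specifications across fits")

    m = len(fits)
    rows = []
    for model, terms in spec.items():
        df_com = first.equations[model].df_resid
        for term in terms:
            q = np.array([f.equations[model].params[term] for f in fits])
            se = np.array([f.equations[model].bse[term] for f in fits])
            qbar = q.mean()
            wbar = (se**2).mean()
            b = q.var(ddof=1)
            t_var = wbar + (1 + 1 / m) * b
            lam = (1 + 1 / m) * b / t_var if t_var > 0 else 0.0
            df = _barnard_rubin_df(lam, m, df_com)
            tstat = qbar / np.sqrt(t_var) if t_var > 0 else np.inf * np.sign(qbar)
            pval = 2 * stats.t.sf(abs(tstat), df) if np.isfinite(tstat) else 0.0
            rows.append(
                {
                    "model": model,
                    "term": term,
                    "estimate": qbar,
                    "se": float(np.sqrt(t_var)),
                    "t": float(tstat),
                    "df": float(df),
                    "p": float(pval),
                    "within": float(wbar),
                    "between": float(b),
                    "total_var": float(t_var),
                }
            )
    return PooledFit(table=pd.DataFrame(rows), m=m)


def pool_indirect_effects(fits: Sequence[PathCoefficients]) -> dict[str, float]:
    """Pooled point estimates of the indirect/direct effects.

    Primary convention: mean over imputations of per-imputation products
    (preserves the pooled decomposition identity).  The product of pooled
    paths is reported alongside for comparison.
    """
    effects = [compute_indirect_effects(f) for f in fits]
    spec = np.array([e.specific for e in effects])  # (M, 3)
    out = {
        "a1b1": float(spec[:, 0].mean()),
        "a2b2": float(spec[:, 1].mean()),
        "a3b3": float(spec[:, 2].mean()),
        "total_indirect": float(spec.sum(axis=1).mean()),
        "direct": float(np.mean([e.direct for e in effects])),
        "total": float(np.mean([e.total for e in effects])),
    }
    a_bar = np.mean([f.a for f in fits], axis=0)
    b_bar = np.mean([f.b for f in fits], axis=0)
    out["product_of_pooled_a2b2"] = float(a_bar[1] * b_bar[1])
    out["product_of_pooled_total"] = float((a_bar * b_bar).sum())
    return out


# ---------------------------------------------------------------------------
# bootstrap distributions
# ---------------------------------------------------------------------------


@dataclass
class BootstrapDistribution:
    """Pooled bootstrap draws of the indirect effects plus point estimates."""

    draws: dict[str, np.ndarray]
    order: str  # "imputation-then-bootstrap" | "bootstrap-then-imputation"
    m: int
    b_per_unit: int
    seed: int
    point_estimates: dict[str, float]
    n_redraws: int = 0

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.draws).to_csv(path, index=False, float_format="%.8g")


def _resample_effects(
    frame: pd.DataFrame,
    n_rep: int,
    rng: np.random.Generator,
    extra_covariates: Sequence[str],
    covariate_set: str = "all",
) -> tuple[dict[str, np.ndarray], int]:
    """n_rep case-resampled effect draws, redrawing singular replicates."""
    n = len(frame)
    idx = rng.integers(0, n, size=(n_rep, n))
    result = batched_indirect_effects(frame, idx, extra_covariates, covariate_set)
    redraws = 0
    rounds = 0
    while result["bad"].any():
        rounds += 1
        if rounds > _MAX_REDRAW_ROUNDS:
            raise RuntimeError("too many rank-deficient bootstrap replicates")
        bad = np.where(result["bad"])[0]
        redraws += bad.size
        retry = batched_indirect_effects(
            frame, rng.integers(0, n, size=(bad.size, n)), extra_covariates, covariate_set
        )
        for key in ("specific", "total_indirect", "direct", "total"):
            result[key][bad] = retry[key]
        result["bad"][bad] = retry["bad"]
    out = {
        "a1b1": result["specific"][:, 0],
        "a2b2": result["specific"][:, 1],
        "a3b3": result["specific"][:, 2],
        "total_indirect": result["total_indirect"],
        "direct": result["direct"],
        "total": result["total"],
    }
    return out, redraws


def imputation_then_bootstrap(
    incomplete: PanelTable,
    imp_config: ImputationConfig,
    B: int,
    seed: int = 0,
    extra_covariates: Sequence[str] = (),
    covariate_set: str = "all",
    imputation_set: ImputationSet | None = None,
    force: bool = False,
) -> BootstrapDistribution:
    """B case-resampled draws from each of M completed datasets, pooled.

    With M imputations this yields exactly ``M * B`` pooled draws per effect.
    Rank-deficient replicates are redrawn (count logged).  Deterministic given
    ``seed``; each imputation has its own child stream so any single
    imputation's draws are reproducible in isolation.
    """
    if imputation_set is None:
        imputation_set = multiply_impute(incomplete, imp_config, force=force)
    m = imputation_set.m
    pooled: dict[str, list[np.ndarray]] = {k: [] for k in EFFECT_NAMES + ("direct", "total")}
    fits = []
    total_redraws = 0
    for i, table in enumerate(imputation_set.completed_tables):
        frame = table.to_frame()
        fits.append(
            fit_equations(
                frame, extra_covariates=extra_covariates, covariate_set=covariate_set
            )
        )
        rng = np.random.default_rng([int(seed), 303, i])
        draws, redraws = _resample_effects(
            frame, B, rng, extra_covariates, covariate_set
        )
        total_redraws += redraws
        for key in pooled:
            pooled[key].append(draws[key])
    if total_redraws:
        logger.info("redrew %d rank-deficient bootstrap replicates", total_redraws)
    point = pool_indirect_effects(fits)
    return BootstrapDistribution(
        draws={k: np.concatenate(v) for k, v in pooled.items()},
        order="imputation-then-bootstrap",
        m=m,
        b_per_unit=B,
        seed=seed,
        point_estimates=point,
        n_redraws=total_redraws,
    )


def _short_chain_impute(
    table: PanelTable, config: ImputationConfig, m: int, rng_key: list[int]
) -> list[pd.DataFrame]:
    """Single-chain DA with a short burn-in, for use inside BTI replicates."""
    columns = config.columns()
    matrix = _panel_to_matrix(table, columns)
    miss = np.isnan(matrix)
    if miss.all(axis=0).any():
        raise ValueError("a variable has no observed values")
    if not miss.any():
        return [table.to_frame() for _ in range(m)]
    layout = _patterns(miss)
    rng = np.random.default_rng(rng_key)
    col_means = np.nanmean(matrix, axis=0)
    col_sds = np.nanstd(matrix, axis=0, ddof=1)
    col_sds = np.where((col_sds <= 0) | ~np.isfinite(col_sds), 1e-3, col_sds)
    start = matrix.copy()
    for j in range(matrix.shape[1]):
        start[miss[:, j], j] = col_means[j]
    chain = _Chain(start, col_means.copy(), np.diag(col_sds**2), rng)
    spacing = 10
    out: list[pd.DataFrame] = []
    for it in range(config.burn_in + m * spacing):
        _istep(chain, layout, config.ridge)
        _pstep(chain, config.ridge)
        if it >= config.burn_in and (it - config.burn_in + 1) % spacing == 0:
            out.append(_matrix_to_panel(table, columns, chain.data).to_frame())
    return out


def bootstrap_then_imputation(
    incomplete: PanelTable,
    imp_config: ImputationConfig,
    B: int,
    m_per_boot: int = 2,
    seed: int = 0,
    extra_covariates: Sequence[str] = (),
    covariate_set: str = "all",
) -> BootstrapDistribution:
    """Case-resample the incomplete table, impute each replicate, average.

    Each of the B resamples of the *incomplete* panel is imputed
    ``m_per_boot`` times with a short single chain (``imp_config.burn_in``
    iterations; pass a reduced configuration — full-length chains per
    replicate are computationally disproportionate).  The draw per effect is
    the mean across the per-imputation estimates, giving B pooled draws.
    A replicate in which some variable has no observed values is redrawn.
    """
    frame = incomplete.to_frame()
    n = incomplete.n
    fully_observed = bool(incomplete.mask.to_numpy().all())
    draws: dict[str, list[float]] = {k: [] for k in EFFECT_NAMES + ("direct", "total")}
    n_redraws = 0
    for b_idx in range(B):
        rng = np.random.default_rng([int(seed), 404, b_idx])
        for attempt in range(_MAX_REDRAW_ROUNDS):
            idx = rng.integers(0, n, size=n)
            boot = frame.iloc[idx].reset_index(drop=True)
            boot["subject_id"] = np.arange(1, n + 1)
            table_b = PanelTable(boot, bounds=incomplete.bounds)
            try:
                if fully_observed:
                    completed = [table_b.to_frame()]
                else:
                    completed = _short_chain_impute(
                        table_b, imp_config, m_per_boot, [int(seed), 405, b_idx, attempt]
                    )
                per_imp = [
                    compute_indirect_effects(
                        fit_equations(
                            c,
                            extra_covariates=extra_covariates,
                            covariate_set=covariate_set,
                        )
                    )
                    for c in completed
                ]
                break
            except (ValueError, np.linalg.LinAlgError):
                n_redraws += 1
                continue
        else:  # pragma: no cover - defensive
            raise RuntimeError("too many invalid bootstrap-then-imputation replicates")
        draws["a1b1"].append(np.mean([e.specific[0] for e in per_imp]))
        draws["a2b2"].append(np.mean([e.specific[1] for e in per_imp]))
        draws["a3b3"].append(np.mean([e.specific[2] for e in per_imp]))
        draws["total_indirect"].append(np.mean([e.total_indirect for e in per_imp]))
        draws["direct"].append(np.mean([e.direct for e in per_imp]))
        draws["total"].append(np.mean([e.total for e in per_imp]))
    if n_redraws:
        logger.info("redrew %d invalid BTI replicates", n_redraws)

    # point estimates from a conventional MI analysis of the original table
    if fully_observed:
        fits = [
            fit_equations(
                frame, extra_covariates=extra_covariates, covariate_set=covariate_set
            )
        ] * 2
    else:
        point_set = multiply_impute(
            incomplete,
            replace(imp_config, n_imputations=max(imp_config.n_imputations, 2)),
            force=True,
        )
        fits = [
            fit_equations(
                t.to_frame(),
                extra_covariates=extra_covariates,
                covariate_set=covariate_set,
            )
            for t in point_set.completed_tables
        ]
    point = pool_indirect_effects(fits)
    return BootstrapDistribution(
        draws={k: np.asarray(v) for k, v in draws.items()},
        order="bootstrap-then-imputation",
        m=m_per_boot,
        b_per_unit=B,
        seed=seed,
        point_estimates=point,
        n_redraws=n_redraws,
    )


# ---------------------------------------------------------------------------
# percentile intervals
# ---------------------------------------------------------------------------


@dataclass
class CIResult:
    """A percentile bootstrap confidence interval for one effect."""

    effect: str
    point: float
    lower: float
    upper: float
    level: float

    @property
    def significant(self) -> bool:
        """True when the interval excludes zero."""
        return not (self.lower <= 0.0 <= self.upper)

    def as_dict(self) -> dict:
        return {
            "effect": self.effect,
            "estimate": self.point,
            "llci": self.lower,
            "ulci": self.upper,
            "level": self.level,
            "significant": self.significant,
        }


def percentile_ci(
    dist: BootstrapDistribution,
    level: float = 0.95,
    effects: Sequence[str] = EFFECT_NAMES,
) -> dict[str, CIResult]:
    """Empirical percentile intervals from the pooled draws.

    Bounds are the alpha/2 and 1-alpha/2 empirical quantiles under the
    inverse-CDF convention (``numpy`` method ``"inverted_cdf"``: the ceil(q*n)-th
    order statistic).  The point estimate is the mean over imputations of the
    per-imputation products, not a bootstrap functional.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    out: dict[str, CIResult] = {}
    alpha = 1.0 - level
    for effect in effects:
        draws = dist.draws[effect]
        if draws.size < 100:
            raise ValueError(
                f"{draws.size} draws are too few for a {level:.0%} percentile interval"
            )
        lo, hi = _inverted_cdf_quantiles(draws, (alpha / 2, 1 - alpha / 2))
        out[effect] = CIResult(
            effect=effect,
            point=float(dist.point_estimates[effect]),
            lower=float(lo),
            upper=float(hi),
            level=level,
        )
    return out


def _inverted_cdf_quantiles(draws: np.ndarray, qs) -> np.ndarray:
    """Empirical inverse-CDF quantiles: the ceil(q*n)-th order statistic.

    Computed directly (with an epsilon guard on ceil) so the convention is
    stable against floating-point noise in q*n at round numbers.
    """
    srt = np.sort(draws)
    n = srt.size
    out = []
    for q in qs:
        k = int(np.ceil(n * q - 1e-9))
        out.append(srt[min(max(k, 1), n) - 1])
    return np.asarray(out)


def ci_table(cis: dict[str, CIResult]) -> pd.DataFrame:
    """Indirect-effects table (Estimate, LLCI, ULCI) in presentation order."""
    rows = [cis[e].as_dict() for e in cis]
    return pd.DataFrame(rows)[["effect", "estimate", "llci", "ulci", "significant"]]


def write_ci_json(cis: dict[str, CIResult], path: str | Path) -> None:
    payload = {e: ci.as_dict() for e, ci in cis.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
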