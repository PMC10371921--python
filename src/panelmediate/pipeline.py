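"""End-to-end orchestration: descriptives, MI, pooling, bootstrap CIs, grid.

``run_full_pipeline`` executes the complete analysis — complete-case
descriptives, multiple imputation behind the PSRF convergence gate,
per-imputation path fits, Rubin pooling, the chosen bootstrap order(s) and
percentile intervals — and writes coefficient and indirect-effect tables plus
a manifest that suffices to replay the run exactly.

``run_sensitivity_grid`` re-runs the analysis over a grid of model variants
(imputation engine x bootstrap order x covariate handling) and summarizes
concordance of the significance verdicts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .data_model import (
    ANALYSIS_VARIABLES,
    MissingnessReport,
    PanelTable,
    read_panel,
    summarize_missingness,
    write_panel,
)
from .imputation import (
    ConvergenceError,
    ImputationConfig,
    ImputationSet,
    compute_psrf,
    draw_imputations,
    fcs_impute,
    run_data_augmentation,
)
from .inference import (
    EFFECT_NAMES,
    BootstrapDistribution,
    CIResult,
    PooledFit,
    _resample_effects,
    bootstrap_then_imputation,
    ci_table,
    imputation_then_bootstrap,
    percentile_ci,
    pool_indirect_effects,
    rubin_pool,
)
from .path_models import fit_equations
from .synthetic_data import SimulationConfig, generate_panel, impose_missingness

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineStageError",
    "DescriptiveTables",
    "PipelineResult",
    "descriptive_tables",
    "run_full_pipeline",
    "run_sensitivity_grid",
    "SensitivityGrid",
    "default_grid",
]

logger = logging.getLogger("panelmediate.pipeline")


class PipelineError(RuntimeError):
    """Configuration-level pipeline failure."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """One full analysis run: input source, MI settings, bootstrap settings."""

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    bootstrap_b: int = 1000
    orders: tuple[str, ...] = ("itb",)
    m_per_boot: int = 2
    bti_burn_in: int = 500
    extra_covariates: tuple[str, ...] = ()
    covariate_set: str = "all"
    level: float = 0.95
    output_dir: str | None = None
    seed: int = 0
    force_convergence: bool = False
    save_draws: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise PipelineError(
                "exactly one of input_path or simulation must be specified"
            )
        bad = [o for o in self.orders if o not in ("itb", "bti")]
        if bad:
            raise PipelineError(f"unknown bootstrap order(s): {bad}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "t1_corr" in sim:
                sim["t1_corr"] = np.asarray(sim["t1_corr"], dtype=float)
            for key in ("true_a", "true_b", "generation_probs"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "u_coefs" in sim:
                sim["u_coefs"] = {k: tuple(v) for k, v in sim["u_coefs"].items()}
            raw["simulation"] = SimulationConfig(**sim)
        if "imputation" in raw and raw["imputation"] is not None:
            raw["imputation"] = ImputationConfig(**raw["imputation"])
        for key in ("orders", "extra_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_master_seed(self, seed: int) -> "PipelineConfig":
        """Derive all stage seeds from one master seed (kept below 2**31)."""
        seed = int(seed) % (2**31 - 10)
        sim = (
            replace(self.simulation, seed=seed + 1)
            if self.simulation is not None
            else None
        )
        imp = replace(self.imputation, seed=seed + 2)
        return replace(self, seed=seed, simulation=sim, imputation=imp)


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


@dataclass
class DescriptiveTables:
    """Complete-case descriptives and bivariate correlations."""

    moments: pd.DataFrame  # variable, mean, sd, pct_missing
    correlations: pd.DataFrame  # long format: var1, var2, r, df, p, stars
    corr_matrix: pd.DataFrame
    n_complete: int
    missingness: MissingnessReport

    def write(self, out_dir: Path) -> None:
        self.moments.to_csv(
            out_dir / "descriptives.csv", index=False, float_format="%.6g"
        )
        self.correlations.to_csv(
            out_dir / "correlations.csv", index=False, float_format="%.6g"
        )


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def descriptive_tables(
    table: PanelTable, variables: Sequence[str] | None = None
) -> DescriptiveTables:
    """Means/SDs, missing percentages and pairwise correlations.

    Moments and correlations are computed on the listwise complete-case
    subset of the analysis variables (missing percentages on the full table).
    Correlations report per-pair df (n-2) and two-sided p, with significance
    stars at the 0.05 / 0.01 thresholds.  A constant variable yields an
    undefined (missing) correlation, logged.
    """
    cols = list(variables) if variables is not None else [
        c for c in ANALYSIS_VARIABLES if c in table.columns
    ]
    missing = summarize_missingness(table, cols)
    cc = table.complete_cases(cols)
    moments = pd.DataFrame(
        {
            "variable": cols,
            "mean": [cc.data[c].mean() for c in cols],
            "sd": [cc.data[c].std(ddof=1) for c in cols],
            "pct_missing": missing.per_variable["pct_missing"].to_numpy(),
        }
    )
    rows = []
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, v1 in enumerate(cols):
        for v2 in cols[i + 1 :]:
            pair = cc.data[[v1, v2]].dropna()
            n_pair = len(pair)
            if n_pair < 3 or pair[v1].std() == 0 or pair[v2].std() == 0:
                logger.warning("correlation undefined for (%s, %s)", v1, v2)
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(pair[v1], pair[v2])
            rows.append(
                {
                    "var1": v1,
                    "var2": v2,
                    "r": r,
                    "df": n_pair - 2,
                    "p": p,
                    "stars": _stars(p),
                }
            )
            mat.loc[v1, v2] = mat.loc[v2, v1] = r
    return DescriptiveTables(
        moments=moments,
        correlations=pd.DataFrame(rows),
        corr_matrix=mat,
        n_complete=cc.n,
        missingness=missing,
    )


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything a run produced, plus the manifest that reproduces it."""

    table: PanelTable
    descriptives: DescriptiveTables
    imputations: ImputationSet
    pooled: PooledFit
    pooled_effects: dict[str, float]
    distributions: dict[str, BootstrapDistribution]
    cis: dict[str, dict[str, CIResult]]
    manifest: dict[str, Any]


def _load_table(config: PipelineConfig) -> PanelTable:
    if config.input_path is not None:
        return read_panel(config.input_path)
    panel = generate_panel(config.simulation)
    if any(r > 0 for r in config.simulation.missing_rates.values()):
        panel = impose_missingness(panel, config.simulation)
    return panel


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Descriptives -> MI (PSRF gate) -> fits -> pooling -> bootstrap CIs.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    a convergence-gate failure propagates as :class:`ConvergenceError` unless
    ``force_convergence`` is set.  Outputs (when ``output_dir`` is set) are
    written with fixed float formats so identical configurations reproduce
    files byte-for-byte.
    """

    def stage(name, fn):
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except ConvergenceError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s: done", name)
        return result

    table = stage("load", lambda: _load_table(config))
    desc = stage("descriptives", lambda: descriptive_tables(table))

    def _impute() -> ImputationSet:
        states = run_data_augmentation(table, config.imputation)
        diagnostics = compute_psrf(states)
        logger.info(
            "max PSRF %.4f (threshold %.2f)",
            diagnostics.max_psrf,
            diagnostics.threshold,
        )
        return draw_imputations(
            states, config.imputation, diagnostics, force=config.force_convergence
        )

    imputations = stage("imputation", _impute)

    def _fit():
        return [
            fit_equations(
                t.to_frame(),
                extra_covariates=config.extra_covariates,
                covariate_set=config.covariate_set,
            )
            for t in imputations.completed_tables
        ]

    fits = stage("estimation", _fit)
    pooled = stage("pooling", lambda: rubin_pool(fits))
    pooled_effects = pool_indirect_effects(fits)

    distributions: dict[str, BootstrapDistribution] = {}
    cis: dict[str, dict[str, CIResult]] = {}
    for order in config.orders:
        if order == "itb":
            dist = stage(
                "bootstrap-itb",
                lambda: imputation_then_bootstrap(
                    table,
                    config.imputation,
                    B=config.bootstrap_b,
                    seed=config.seed,
                    extra_covariates=config.extra_covariates,
                    covariate_set=config.covariate_set,
                    imputation_set=imputations,
                ),
            )
        else:
            dist = stage(
                "bootstrap-bti",
                lambda: bootstrap_then_imputation(
                    table,
                    replace(config.imputation, burn_in=config.bti_burn_in),
                    B=config.bootstrap_b,
                    m_per_boot=config.m_per_boot,
                    seed=config.seed,
                    extra_covariates=config.extra_covariates,
                    covariate_set=config.covariate_set,
                ),
            )
        distributions[order] = dist
        cis[order] = percentile_ci(dist, level=config.level)

    manifest = {
        "seed": config.seed,
        "orders": list(config.orders),
        "bootstrap_b": config.bootstrap_b,
        "m_per_boot": config.m_per_boot,
        "level": config.level,
        "covariate_set": config.covariate_set,
        "extra_covariates": list(config.extra_covariates),
        "imputation": {
            "burn_in": config.imputation.burn_in,
            "post_burn_iterations": config.imputation.post_burn_iterations,
            "n_imputations": config.imputation.n_imputations,
            "n_chains": config.imputation.n_chains,
            "psrf_threshold": config.imputation.psrf_threshold,
            "seed": config.imputation.seed,
        },
        "input": config.input_path
        or {"simulation": _jsonable(config.simulation.to_dict())},
        "n": table.n,
        "n_complete_cases": desc.n_complete,
        "max_psrf": imputations.diagnostics.max_psrf
        if imputations.diagnostics
        else None,
        "converged": imputations.diagnostics.converged
        if imputations.diagnostics
        else None,
        "n_regularized": imputations.n_regularized,
        "bootstrap_redraws": {o: d.n_redraws for o, d in distributions.items()},
        "n_draws": {o: d.n_draws for o, d in distributions.items()},
    }

    result = PipelineResult(
        table=table,
        descriptives=desc,
        imputations=imputations,
        pooled=pooled,
        pooled_effects=pooled_effects,
        distributions=distributions,
        cis=cis,
        manifest=manifest,
    )
    if config.output_dir is not None:
        stage("write", lambda: _write_outputs(result, config))
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.descriptives.write(out)
    result.descriptives.missingness.to_csv(out / "missingness.csv")
    result.pooled.to_csv(out / "pooled_coefficients.csv")
    for order, ci in result.cis.items():
        ci_table(ci).to_csv(
            out / f"indirect_effects_{order}.csv", index=False, float_format="%.6g"
        )
    if config.save_draws:
        for order, dist in result.distributions.items():
            dist.to_csv(out / f"bootstrap_draws_{order}.csv")
    (out / "pooled_indirect_effects.json").write_text(
        json.dumps(_jsonable(result.pooled_effects), indent=2, sort_keys=True)
    )
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(result.manifest), indent=2, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# sensitivity grid
# ---------------------------------------------------------------------------


@dataclass
class SensitivityGrid:
    """Per-variant interval results plus a significance concordance summary."""

    variants: list[dict[str, Any]]
    concordance: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            row = {k: v[k] for k in ("engine", "order", "covariate_set", "demographics")}
            row["seed"] = v["seed"]
            if v.get("error"):
                row["error"] = v["error"]
            else:
                for eff in EFFECT_NAMES:
                    ci = v["cis"][eff]
                    row[f"{eff}_est"] = ci.point
                    row[f"{eff}_llci"] = ci.lower
                    row[f"{eff}_ulci"] = ci.upper
                    row[f"{eff}_sig"] = ci.significant
            rows.append(row)
        return pd.DataFrame(rows)


def default_grid() -> list[dict[str, Any]]:
    """Default variant grid: 2 engines x 2 orders x 2 covariate sets +/- demographics."""
    grid = []
    for engine in ("joint_da", "fcs"):
        for order in ("itb", "bti"):
            for cov in ("all", "own"):
                for demo in (False, True):
                    grid.append(
                        {
                            "engine": engine,
                            "order": order,
                            "covariate_set": cov,
                            "demographics": demo,
                        }
                    )
    grid.append(
        {
            "engine": "complete_case",
            "order": "itb",
            "covariate_set": "all",
            "demographics": False,
        }
    )
    return grid


def _run_variant(
    table: PanelTable, config: PipelineConfig, variant: dict[str, Any]
) -> dict[str, CIResult]:
    extra = ("age", "gender", "generation") if variant["demographics"] else ()
    cov_set = variant["covariate_set"]
    engine = variant["engine"]
    order = variant["order"]
    imp = config.imputation

    if engine == "complete_case":
        cols = list(ANALYSIS_VARIABLES) + [
            c for c in ("age", "gender", "generation") if variant["demographics"]
        ]
        cc = table.complete_cases(cols)
        fit = fit_equations(cc, extra_covariates=extra, covariate_set=cov_set)
        point = pool_indirect_effects([fit, fit])
        rng = np.random.default_rng([int(config.seed), 606])
        draws, _ = _resample_effects(
            cc.to_frame(), config.bootstrap_b, rng, extra, cov_set
        )
        dist = BootstrapDistribution(
            draws={k: np.asarray(v) for k, v in draws.items()},
            order="complete-case-bootstrap",
            m=1,
            b_per_unit=config.bootstrap_b,
            seed=config.seed,
            point_estimates=point,
        )
        return percentile_ci(dist, level=config.level)

    if engine == "fcs":
        imputation_set = fcs_impute(table, imp)
    elif engine == "joint_da":
        imputation_set = None  # let ITB/BTI drive the DA engine
    else:
        raise PipelineError(f"unknown engine: {engine}")

    if order == "itb":
        if imputation_set is None:
            states = run_data_augmentation(table, imp)
            imputation_set = draw_imputations(
                states, imp, compute_psrf(states), force=config.force_convergence
            )
        dist = imputation_then_bootstrap(
            table,
            imp,
            B=config.bootstrap_b,
            seed=config.seed,
            extra_covariates=extra,
            covariate_set=cov_set,
            imputation_set=imputation_set,
        )
    else:
        dist = bootstrap_then_imputation(
            table,
            replace(imp, burn_in=config.bti_burn_in),
            B=config.bootstrap_b,
            m_per_boot=config.m_per_boot,
            seed=config.seed,
            extra_covariates=extra,
            covariate_set=cov_set,
        )
    return percentile_ci(dist, level=config.level)


def run_sensitivity_grid(
    config: PipelineConfig, grid: Sequence[dict[str, Any]] | None = None
) -> SensitivityGrid:
    """Run every model variant; failures are recorded and the grid continues.

    Requires at least two variants.  The concordance summary counts variants
    flagging the private-regard indirect effect and the total indirect effect
    as significant.
    """
    variants = list(grid) if grid is not None else default_grid()
    if len(variants) < 2:
        raise PipelineError("a sensitivity grid needs at least two variants")
    table = _load_table(config)
    results = []
    for variant in variants:
        record = dict(variant)
        record["seed"] = config.seed
        try:
            record["cis"] = _run_variant(table, config, variant)
            record["error"] = None
        except Exception as exc:  # noqa: BLE001 - grid continues on failure
            logger.warning("variant %s failed: %s", variant, exc)
            record["cis"] = None
            record["error"] = str(exc)
        results.append(record)
    ok = [r for r in results if not r["error"]]
    concordance = {
        "n_variants": len(results),
        "n_failed": len(results) - len(ok),
        "n_significant_a2b2": sum(r["cis"]["a2b2"].significant for r in ok),
        "n_significant_total_indirect": sum(
            r["cis"]["total_indirect"].significant for r in ok
        ),
    }
    return SensitivityGrid(variants=results, concordance=concordance)


def write_simulated_panel(
    config: SimulationConfig, path: str | Path, with_missing: bool = True
) -> PanelTable:
    """Generate a panel, write it as CSV plus a JSON sidecar of the config."""
    panel = generate_panel(config)
    if with_missing and any(r > 0 for r in config.missing_rates.values()):
        panel = impose_missingness(panel, config)
    path = Path(path)
    write_panel(panel, path)
    sidecar = path.with_suffix(".config.json")
    sidecar.write_text(json.dumps(_jsonable(config.to_dict()), indent=2, sort_keys=True))
    return panel
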