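"""Synthetic two-wave panel generator with known true paths.

The generator draws the exogenous block (focal predictor, four wave-1 lagged
covariates, four wave-0 auxiliary scores) from a correlated Gaussian whose
latent mean/SD per variable are *calibrated* so that, after truncation to the
response-scale bounds, the realized moments match the study's descriptive
table (predictor mean 4.10, SD 2.71 on a 1-9 scale, etc.).  Wave-2 mediators
and the outcome are then built structurally::

    M_j = i_j + a_j * X + u_j . U + eps_j          (j = 1, 2, 3)
    Y   = i_Y + c' * X + b . M + u_Y . U + eps_Y

with every wave-2 value truncated to its bounds.  Y is generated from the
*truncated* mediators, so the b-paths and c' hold exactly with respect to the
observable data; truncation of a mediator attenuates only its a-path, and only
where the scale ceiling binds (see docs/methods.md).

Missingness is imposed afterwards, either MCAR (independent Bernoulli per
cell) or MAR with masking probability a logistic function of the always
observed wave-0 auxiliaries and demographics, intercept-calibrated to hit the
target rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import (
    ANALYSIS_VARIABLES,
    AUXILIARY_VARIABLES,
    DEFAULT_SCALES,
    VARIABLE_BOUNDS,
    PanelTable,
    ScaleDefinition,
)

__all__ = [
    "SimulationConfig",
    "default_config",
    "generate_panel",
    "impose_missingness",
    "generate_items",
    "estimand_paths",
]

# ---------------------------------------------------------------------------
# Study-condition constants (descriptive moments and path magnitudes as
# printed by the motivating study of immigration-policy impact, ethnic
# identity and self-esteem in early adolescents).
# ---------------------------------------------------------------------------

#: target post-truncation mean/SD of the exogenous wave-1 block
T1_MEANS: dict[str, float] = {
    "x_t1": 4.10,
    "u1_t1": 3.65,
    "u2_t1": 4.29,
    "u3_t1": 3.44,
    "u4_t1": 2.96,
}
T1_SDS: dict[str, float] = {
    "x_t1": 2.71,
    "u1_t1": 0.79,
    "u2_t1": 0.70,
    "u3_t1": 0.83,
    "u4_t1": 0.51,
}

#: latent-scale target mean/SD of the wave-2 endogenous variables
T2_MEANS: dict[str, float] = {"m1_t2": 3.45, "m2_t2": 4.18, "m3_t2": 3.38, "y_t2": 2.99}
T2_SDS: dict[str, float] = {"m1_t2": 0.85, "m2_t2": 0.78, "m3_t2": 0.85, "y_t2": 0.53}

#: correlations of (X, U1..U4) from the study's bivariate table
T1_CORR: np.ndarray = np.array(
    [
        [1.00, 0.18, 0.23, 0.03, -0.12],
        [0.18, 1.00, 0.50, 0.43, 0.26],
        [0.23, 0.50, 1.00, 0.32, 0.25],
        [0.03, 0.43, 0.32, 1.00, 0.28],
        [-0.12, 0.26, 0.25, 0.28, 1.00],
    ]
)

#: stability correlation linking each wave-0 auxiliary to its wave-1 counterpart
AUX_STABILITY: float = 0.55

#: reported missing-data percentages per analysis variable
MISSING_RATES: dict[str, float] = {
    "x_t1": 0.34,
    "m1_t2": 0.38,
    "m2_t2": 0.38,
    "m3_t2": 0.38,
    "y_t2": 0.38,
    "u1_t1": 0.28,
    "u2_t1": 0.28,
    "u3_t1": 0.28,
    "u4_t1": 0.29,
}

#: published path magnitudes used as default true values
TRUE_A: tuple[float, float, float] = (0.019, 0.032, 0.005)
TRUE_B: tuple[float, float, float] = (0.001, 0.117, 0.011)
TRUE_CPRIME: float = -0.004

#: lagged-covariate coefficients (U1..U4) per wave-2 equation
U_COEFS: dict[str, tuple[float, float, float, float]] = {
    "m1_t2": (0.463, 0.104, 0.022, -0.048),
    "m2_t2": (0.109, 0.355, 0.034, 0.173),
    "m3_t2": (0.070, -0.015, 0.310, 0.266),
    "y_t2": (-0.022, -0.029, 0.013, 0.568),
}

_EXO_ORDER = ("x_t1", "u1_t1", "u2_t1", "u3_t1", "u4_t1")
_MEDIATORS = ("m1_t2", "m2_t2", "m3_t2")

# stage tags for deterministic child streams off the master seed
_STAGE_EXOGENOUS = 11
_STAGE_DEMOGRAPHICS = 12
_STAGE_NOISE = 13
_STAGE_MISSING = 14
_STAGE_ITEMS = 15


def _full_latent_corr(t1_corr: np.ndarray, stability: float) -> np.ndarray:
    """9x9 latent correlation for (X, U1..4, A1..4).

    The auxiliary block is constructed as ``A = s*U + sqrt(1-s^2)*E`` with E an
    independent copy sharing the U-block correlation, which keeps the full
    matrix positive definite whenever the 5x5 block is.
    """
    c = t1_corr[1:, 1:]
    full = np.eye(9)
    full[:5, :5] = t1_corr
    full[5:, 5:] = c
    full[5:, 1:5] = stability * c
    full[1:5, 5:] = stability * c.T
    full[5:, 0] = stability * t1_corr[0, 1:]
    full[0, 5:] = stability * t1_corr[0, 1:]
    return full


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic panel.

    Defaults reproduce the study conditions: n = 891 adolescents, predictor
    and lagged-covariate moments from the descriptive table, true paths at the
    published magnitudes, MAR missingness at the reported 28-38% rates driven
    by the always-observed wave-0 auxiliaries and demographics.
    """

    n: int = 891
    true_a: tuple[float, float, float] = TRUE_A
    true_b: tuple[float, float, float] = TRUE_B
    true_cprime: float = TRUE_CPRIME
    u_coefs: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(U_COEFS)
    )
    intercepts: Mapping[str, float] | None = None  # derived from means if None
    t1_means: Mapping[str, float] = field(default_factory=lambda: dict(T1_MEANS))
    t1_sds: Mapping[str, float] = field(default_factory=lambda: dict(T1_SDS))
    t1_corr: np.ndarray = field(default_factory=lambda: T1_CORR.copy())
    t2_means: Mapping[str, float] = field(default_factory=lambda: dict(T2_MEANS))
    t2_sds: Mapping[str, float] = field(default_factory=lambda: dict(T2_SDS))
    resid_sds: Mapping[str, float] | None = None  # derived from t2_sds if None
    aux_stability: float = AUX_STABILITY
    missing_mechanism: str = "MAR"  # "MCAR" | "MAR"
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(MISSING_RATES)
    )
    truncate: bool = True
    item_level: bool = False
    gender_p_male: float = 0.48
    generation_probs: tuple[float, float, float] = (0.14, 0.56, 0.30)
    age_mean: float = 12.09
    age_sd: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.t1_corr, dtype=float)
        if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
            raise ValueError("t1_corr must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("t1_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 1e-10:
            raise ValueError("t1_corr must be positive definite")
        self.t1_corr = corr
        rates = np.array(list(self.missing_rates.values()), dtype=float)
        if ((rates < 0) | (rates >= 1)).any():
            raise ValueError("missing_rates must lie in [0, 1)")
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if self.missing_mechanism.upper() not in {"MCAR", "MAR"}:
            raise ValueError("missing_mechanism must be MCAR or MAR")
        self.missing_mechanism = self.missing_mechanism.upper()

    # -- derived structural quantities -------------------------------------------

    def exogenous_cov(self) -> np.ndarray:
        """Covariance of (X, U1..4) at the target (post-truncation) moments."""
        d = np.array([self.t1_sds[v] for v in _EXO_ORDER])
        return self.t1_corr * np.outer(d, d)

    def betas(self) -> dict[str, np.ndarray]:
        """Per-equation coefficient vector on (X, U1..4) for mediators."""
        return {
            m: np.concatenate(([self.true_a[j]], np.asarray(self.u_coefs[m])))
            for j, m in enumerate(_MEDIATORS)
        }

    def derived_resid_sds(self) -> dict[str, float]:
        """Residual SDs that make latent wave-2 SDs match their targets.

        Closed form under the Gaussian approximation of the exogenous block:
        for each mediator, sigma_j^2 = SD_j^2 - beta' Sigma beta; for the
        outcome the covariance of (X, M1..3, U1..4) is assembled analytically.
        """
        if self.resid_sds is not None:
            return dict(self.resid_sds)
        sig = self.exogenous_cov()
        betas = self.betas()
        out: dict[str, float] = {}
        for m in _MEDIATORS:
            explained = float(betas[m] @ sig @ betas[m])
            resid_var = self.t2_sds[m] ** 2 - explained
            out[m] = float(np.sqrt(max(resid_var, 1e-4)))
        # covariance of (X, U1..4, M1..3)
        big = np.zeros((8, 8))
        big[:5, :5] = sig
        for j, m in enumerate(_MEDIATORS):
            cov_m_exo = sig @ betas[m]
            big[5 + j, :5] = cov_m_exo
            big[:5, 5 + j] = cov_m_exo
            for k, mk in enumerate(_MEDIATORS):
                big[5 + j, 5 + k] = float(betas[m] @ sig @ betas[mk])
            big[5 + j, 5 + j] += out[m] ** 2
        beta_y = np.concatenate(
            (
                [self.true_cprime],
                np.asarray(self.u_coefs["y_t2"]),
                np.asarray(self.true_b),
            )
        )
        explained_y = float(beta_y @ big @ beta_y)
        out["y_t2"] = float(np.sqrt(max(self.t2_sds["y_t2"] ** 2 - explained_y, 1e-4)))
        return out

    def derived_intercepts(self) -> dict[str, float]:
        if self.intercepts is not None:
            return dict(self.intercepts)
        mu = np.array([self.t1_means[v] for v in _EXO_ORDER])
        betas = self.betas()
        out = {m: float(self.t2_means[m] - betas[m] @ mu) for m in _MEDIATORS}
        m_means = np.array([self.t2_means[m] for m in _MEDIATORS])
        out["y_t2"] = float(
            self.t2_means["y_t2"]
            - self.true_cprime * mu[0]
            - np.asarray(self.true_b) @ m_means
            - np.asarray(self.u_coefs["y_t2"]) @ mu[1:]
        )
        return out

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic child stream for a named pipeline stage."""
        return np.random.default_rng([int(self.seed), int(stage)])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "true_a": list(self.true_a),
            "true_b": list(self.true_b),
            "true_cprime": self.true_cprime,
            "u_coefs": {k: list(v) for k, v in self.u_coefs.items()},
            "intercepts": self.derived_intercepts(),
            "t1_means": dict(self.t1_means),
            "t1_sds": dict(self.t1_sds),
            "t1_corr": np.asarray(self.t1_corr).tolist(),
            "t2_means": dict(self.t2_means),
            "t2_sds": dict(self.t2_sds),
            "resid_sds": self.derived_resid_sds(),
            "missing_mechanism": self.missing_mechanism,
            "missing_rates": dict(self.missing_rates),
            "truncate": self.truncate,
            "item_level": self.item_level,
            "seed": self.seed,
        }


def default_config(**overrides) -> SimulationConfig:
    """The study-condition configuration, with keyword overrides."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


# ---------------------------------------------------------------------------
# truncated-normal moment calibration
# ---------------------------------------------------------------------------


def _clipped_moments(mu: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of clip(N(mu, sd), lo, hi) in closed form."""
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    p_lo = stats.norm.cdf(a)
    p_hi = stats.norm.sf(b)
    p_in = max(1.0 - p_lo - p_hi, 0.0)
    if p_in <= 1e-12:
        m = lo * p_lo + hi * p_hi
        return m, float(np.sqrt(lo**2 * p_lo + hi**2 * p_hi - m**2))
    tn = stats.truncnorm(a, b, loc=mu, scale=sd)
    m_in = tn.mean()
    v_in = tn.var()
    mean = lo * p_lo + hi * p_hi + p_in * m_in
    second = lo**2 * p_lo + hi**2 * p_hi + p_in * (v_in + m_in**2)
    return float(mean), float(np.sqrt(max(second - mean**2, 0.0)))


def calibrate_latent_moments(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Latent (mu, sd) whose clipped-to-[lo, hi] moments hit the targets.

    Solved with a 2-D root find on the closed-form clipped-normal moments.
    Raises if the target SD is infeasible for a distribution on [lo, hi].
    """
    max_sd = np.sqrt((target_mean - lo) * (hi - target_mean))
    if not lo < target_mean < hi or target_sd >= max_sd:
        raise ValueError(
            f"targets (mean={target_mean}, sd={target_sd}) infeasible on [{lo}, {hi}]"
        )

    def fun(theta):
        m, s = _clipped_moments(theta[0], np.exp(theta[1]), lo, hi)
        return [m - target_mean, s - target_sd]

    sol = optimize.root(fun, x0=[target_mean, np.log(target_sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"moment calibration failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------


def _clip(values: np.ndarray, col: str, truncate: bool) -> np.ndarray:
    if not truncate:
        return values
    lo, hi = VARIABLE_BOUNDS[col]
    return np.clip(values, lo, hi)


def generate_panel(config: SimulationConfig) -> PanelTable:
    """Draw a fully observed panel from the structural model.

    The master seed fully determines the output; separate deterministic child
    streams drive the exogenous block, demographics, structural noise, and
    (later) missingness.
    """
    n = config.n
    full_corr = _full_latent_corr(np.asarray(config.t1_corr), config.aux_stability)
    if np.linalg.eigvalsh(full_corr).min() <= 1e-10:  # pragma: no cover - defensive
        raise ValueError("latent correlation (with auxiliaries) not positive definite")

    exo_cols = list(_EXO_ORDER) + list(AUXILIARY_VARIABLES)
    # wave-0 auxiliaries share their wave-1 counterpart's target moments
    targets = {
        **{v: (config.t1_means[v], config.t1_sds[v]) for v in _EXO_ORDER},
        **{
            a: (config.t1_means[u], config.t1_sds[u])
            for a, u in zip(AUXILIARY_VARIABLES, _EXO_ORDER[1:])
        },
    }
    mus, sds = [], []
    for col in exo_cols:
        tm, ts = targets[col]
        if config.truncate:
            lo, hi = VARIABLE_BOUNDS[col]
            mu, sd = calibrate_latent_moments(tm, ts, lo, hi)
        else:
            mu, sd = tm, ts
        mus.append(mu)
        sds.append(sd)
    mus_arr, sds_arr = np.array(mus), np.array(sds)

    rng_exo = config.rng(_STAGE_EXOGENOUS)
    z = rng_exo.multivariate_normal(
        np.zeros(9), full_corr, size=n, method="cholesky"
    )
    exo = mus_arr + sds_arr * z
    for j, col in enumerate(exo_cols):
        exo[:, j] = _clip(exo[:, j], col, config.truncate)

    rng_demo = config.rng(_STAGE_DEMOGRAPHICS)
    gender = (rng_demo.random(n) < config.gender_p_male).astype(float)
    generation = rng_demo.choice(
        [1.0, 2.0, 3.0], size=n, p=list(config.generation_probs)
    )
    age = np.clip(
        rng_demo.normal(config.age_mean, config.age_sd, size=n),
        *VARIABLE_BOUNDS["age"],
    )

    x = exo[:, 0]
    u = exo[:, 1:5]
    intercepts = config.derived_intercepts()
    resid = config.derived_resid_sds()
    betas = config.betas()
    rng_noise = config.rng(_STAGE_NOISE)
    med = np.empty((n, 3))
    for j, m in enumerate(_MEDIATORS):
        latent = (
            intercepts[m]
            + betas[m][0] * x
            + u @ betas[m][1:]
            + rng_noise.normal(0.0, resid[m], size=n)
        )
        med[:, j] = _clip(latent, m, config.truncate)
    y_latent = (
        intercepts["y_t2"]
        + config.true_cprime * x
        + med @ np.asarray(config.true_b)
        + u @ np.asarray(config.u_coefs["y_t2"])
        + rng_noise.normal(0.0, resid["y_t2"], size=n)
    )
    y = _clip(y_latent, "y_t2", config.truncate)

    frame = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "x_t1": x,
            "m1_t2": med[:, 0],
            "m2_t2": med[:, 1],
            "m3_t2": med[:, 2],
            "y_t2": y,
            "u1_t1": u[:, 0],
            "u2_t1": u[:, 1],
            "u3_t1": u[:, 2],
            "u4_t1": u[:, 3],
            "aux1_t0": exo[:, 5],
            "aux2_t0": exo[:, 6],
            "aux3_t0": exo[:, 7],
            "aux4_t0": exo[:, 8],
            "gender": gender,
            "generation": generation,
            "age": age,
        }
    )
    if config.item_level:
        frame = _regrid_scores_via_items(frame, config)
    if not config.truncate:
        # latent-scale output: scores may exceed the questionnaire bounds
        bounds = {c: (-np.inf, np.inf) for c in frame.columns if c != "subject_id"}
        return PanelTable(frame, bounds=bounds)
    return PanelTable(frame)


_COL_SCALE = {
    "x_t1": "sb1070",
    "m1_t2": "centrality",
    "m2_t2": "private_regard",
    "m3_t2": "public_regard",
    "y_t2": "self_esteem",
    "u1_t1": "centrality",
    "u2_t1": "private_regard",
    "u3_t1": "public_regard",
    "u4_t1": "self_esteem",
}


def _regrid_scores_via_items(frame: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Replace continuous scores by item-mean scores (adds rounding realism)."""
    from .data_model import score_scale

    rng = config.rng(_STAGE_ITEMS)
    frame = frame.copy()
    for col, scale_name in _COL_SCALE.items():
        scale = DEFAULT_SCALES[scale_name]
        items = generate_items(frame[col].to_numpy(), scale, rng=rng)
        frame[col] = score_scale(items, scale, min_prop_observed=0.0)
    return frame


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

#: MAR linear-predictor weights on standardized [mean(aux), gender, age]
_MAR_SLOPES = np.array([1.0, 0.3, 0.15])


def impose_missingness(table: PanelTable, config: SimulationConfig) -> PanelTable:
    """Mask cells of a fully observed panel per the configured mechanism.

    MCAR masks each target cell independently at its rate.  MAR masks with
    probability ``expit(alpha_v + w_i)`` where ``w`` combines the standardized
    wave-0 auxiliary composite, gender and age, and the per-variable intercept
    ``alpha_v`` is solved so the expected rate equals the target.  Wave-0
    auxiliaries and demographics are never masked.
    """
    if not table.mask.to_numpy().all():
        raise ValueError("impose_missingness expects a fully observed panel")
    rng = config.rng(_STAGE_MISSING)
    frame = table.to_frame()
    data = frame.drop(columns=["subject_id"])

    if config.missing_mechanism == "MAR":
        aux = data[list(AUXILIARY_VARIABLES)]
        if aux.isna().any().any():
            raise ValueError("MAR requires fully observed auxiliary predictors")
        comp = aux.mean(axis=1).to_numpy()
        preds = np.column_stack(
            [
                _standardize(comp),
                _standardize(data["gender"].to_numpy()),
                _standardize(data["age"].to_numpy()),
            ]
        )
        eta = preds @ _MAR_SLOPES

    for col, rate in config.missing_rates.items():
        if rate <= 0 or col not in data.columns:
            continue
        if col in AUXILIARY_VARIABLES or col in ("gender", "generation", "age"):
            raise ValueError(f"refusing to mask always-observed variable {col}")
        if config.missing_mechanism == "MCAR":
            drop = rng.random(table.n) < rate
        else:
            alpha = _solve_intercept(eta, rate)
            p = 1.0 / (1.0 + np.exp(-(alpha + eta)))
            drop = rng.random(table.n) < p
        data.loc[drop, col] = np.nan

    data.insert(0, "subject_id", frame["subject_id"])
    return PanelTable(data, bounds=table.bounds)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _solve_intercept(eta: np.ndarray, rate: float) -> float:
    """Intercept making mean(expit(alpha + eta)) equal the target rate."""

    def gap(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + eta)))) - rate)

    return optimize.brentq(gap, -20.0, 20.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# item generation
# ---------------------------------------------------------------------------


def generate_items(
    scores: np.ndarray,
    scale: ScaleDefinition,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Parallel Likert items consistent with a target reliability.

    Items are ``score + e`` with error variance solved from the
    Spearman-Brown relation ``alpha = k*rho / (1 + (k-1)*rho)`` so that the
    common inter-item correlation ``rho = alpha / (k - alpha*(k-1))`` holds on
    the continuous scale.  Designated reverse items are flipped, then items
    are rounded to the Likert grid and clipped to bounds (which attenuates
    the recovered alpha slightly).
    """
    if not 0.0 < scale.target_alpha < 1.0:
        raise ValueError("target_alpha must be in (0, 1) for item generation")
    if rng is None:
        rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    k = scale.item_count
    rho = scale.target_alpha / (k - scale.target_alpha * (k - 1))
    observed = scores[~np.isnan(scores)]
    sd_t = observed.std(ddof=1) if observed.size > 1 else 1.0
    # rounding to the Likert grid adds ~1/12 variance per item; compensate so
    # the post-rounding inter-item correlation still hits the target
    var_e = max(sd_t**2 * (1.0 - rho) / rho - 1.0 / 12.0, 1e-6)
    items = scores[:, None] + rng.normal(0.0, np.sqrt(var_e), size=(scores.size, k))
    for idx in scale.reverse_items:
        items[:, idx - 1] = scale.response_min + scale.response_max - items[:, idx - 1]
    items = np.clip(np.round(items), scale.response_min, scale.response_max)
    items[np.isnan(scores), :] = np.nan
    return items


# ---------------------------------------------------------------------------
# estimand helper
# ---------------------------------------------------------------------------


def estimand_paths(
    config: SimulationConfig, n: int = 200_000, seed: int = 12345
) -> dict[str, np.ndarray | float]:
    """Large-sample complete-data OLS coefficients under the generator.

    This is the estimand the estimation machinery targets: with truncation the
    population regression coefficients of the *observable* variables differ
    slightly from the latent structural paths (ceiling attenuation of the
    a-paths), and validating imputation/pooling against this benchmark
    isolates the missing-data method from that generator-level attenuation.
    """
    from .path_models import fit_equations

    big = replace(config, n=n, seed=seed, missing_rates={}, missing_mechanism="MCAR")
    panel = generate_panel(big)
    coeffs = fit_equations(panel)
    return {
        "a": coeffs.a.copy(),
        "b": coeffs.b.copy(),
        "cprime": coeffs.cprime,
        "c_total": coeffs.c_total,
    }
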