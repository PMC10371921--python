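"""Panel data structures, scale scoring, reliability and missingness summaries.

The analysis operates on a two-wave (plus auxiliary wave) subject-level panel:

* ``x_t1`` — focal predictor (perceived impact of the immigration law, 1–9),
* ``m1_t2``/``m2_t2``/``m3_t2`` — wave-2 mediators: ethnic centrality (1–5),
  ethnic private regard (1–5) and ethnic public regard (1–4),
* ``y_t2`` — wave-2 outcome, global self-esteem (1–4),
* ``u1_t1``..``u4_t1`` — wave-1 repeated measures of the same four constructs,
  entered as lagged covariates in every equation,
* ``aux1_t0``..``aux4_t0`` — wave-0 auxiliary scores of the same constructs,
  used only to inform imputation,
* ``gender`` (1 = male), ``generation`` (1/2/3 immigrant generation), ``age``.

Every cell may be missing.  Missingness is carried both as ``NaN`` in the data
and as an explicit boolean *observedness* mask; the two must agree cell by cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelValidationError",
    "ScaleDefinition",
    "PanelTable",
    "DEFAULT_SCALES",
    "ANALYSIS_VARIABLES",
    "AUXILIARY_VARIABLES",
    "DEMOGRAPHIC_VARIABLES",
    "VARIABLE_BOUNDS",
    "read_panel",
    "write_panel",
    "score_scale",
    "cronbach_alpha",
    "summarize_missingness",
    "MissingnessReport",
]


class PanelValidationError(ValueError):
    """Raised when a panel violates its schema (ids, columns or bounds)."""


@dataclass(frozen=True)
class ScaleDefinition:
    """A multi-item Likert scale and its scoring rules.

    Parameters
    ----------
    name : str
        Construct label (e.g. ``"private_regard"``).
    item_count : int
        Number of items administered.
    response_min, response_max : float
        Bounds of the per-item response scale.
    reverse_items : tuple of int
        1-based indices of negatively worded items, recoded as
        ``min + max - v`` before averaging.
    target_alpha : float
        Cronbach's alpha the scale is expected (or, for the synthetic item
        generator, calibrated) to attain.
    """

    name: str
    item_count: int
    response_min: float
    response_max: float
    reverse_items: tuple[int, ...] = ()
    target_alpha: float = 0.8

    def __post_init__(self) -> None:
        if self.item_count < 1:
            raise ValueError("item_count must be positive")
        if not self.response_min < self.response_max:
            raise ValueError("response_min must be < response_max")
        bad = [i for i in self.reverse_items if not 1 <= i <= self.item_count]
        if bad:
            raise ValueError(f"reverse_items out of range: {bad}")
        if not 0.0 <= self.target_alpha <= 1.0:
            raise ValueError("target_alpha must be in [0, 1]")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.response_min, self.response_max)


# Default scales.  Private regard is scored on 1-5: the study's printed score
# means (4.18 and 4.29) are only attainable on a range wider than 1-4.
DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    "sb1070": ScaleDefinition("sb1070", 4, 1, 9, target_alpha=0.92),
    "centrality": ScaleDefinition("centrality", 5, 1, 5, target_alpha=0.86),
    "private_regard": ScaleDefinition("private_regard", 3, 1, 5, target_alpha=0.89),
    "public_regard": ScaleDefinition("public_regard", 3, 1, 4, target_alpha=0.81),
    "self_esteem": ScaleDefinition(
        "self_esteem", 10, 1, 4, reverse_items=(3, 5, 8, 9, 10), target_alpha=0.81
    ),
}

ANALYSIS_VARIABLES: tuple[str, ...] = (
    "x_t1",
    "m1_t2",
    "m2_t2",
    "m3_t2",
    "y_t2",
    "u1_t1",
    "u2_t1",
    "u3_t1",
    "u4_t1",
)
AUXILIARY_VARIABLES: tuple[str, ...] = ("aux1_t0", "aux2_t0", "aux3_t0", "aux4_t0")
DEMOGRAPHIC_VARIABLES: tuple[str, ...] = ("gender", "generation", "age")

_CONSTRUCT_OF = {
    "x_t1": "sb1070",
    "m1_t2": "centrality",
    "m2_t2": "private_regard",
    "m3_t2": "public_regard",
    "y_t2": "self_esteem",
    "u1_t1": "centrality",
    "u2_t1": "private_regard",
    "u3_t1": "public_regard",
    "u4_t1": "self_esteem",
    "aux1_t0": "centrality",
    "aux2_t0": "private_regard",
    "aux3_t0": "public_regard",
    "aux4_t0": "self_esteem",
}

#: score-level bounds per column (scale-score bounds for constructs,
#: category/plausible bounds for demographics)
VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    **{
        col: DEFAULT_SCALES[c].bounds for col, c in _CONSTRUCT_OF.items()
    },
    "gender": (0, 1),
    "generation": (1, 3),
    "age": (9, 16),
}

ALL_COLUMNS: tuple[str, ...] = (
    ANALYSIS_VARIABLES + AUXILIARY_VARIABLES + DEMOGRAPHIC_VARIABLES
)


def _bounds_from_schema(
    schema: Sequence[ScaleDefinition] | Mapping[str, tuple[float, float]] | None,
) -> dict[str, tuple[float, float]]:
    if schema is None:
        return dict(VARIABLE_BOUNDS)
    if isinstance(schema, Mapping):
        out = dict(VARIABLE_BOUNDS)
        out.update(schema)
        return out
    by_name = {s.name: s for s in schema}
    out = dict(VARIABLE_BOUNDS)
    for col, construct in _CONSTRUCT_OF.items():
        if construct in by_name:
            out[col] = by_name[construct].bounds
    return out


class PanelTable:
    """Subject-level panel with an explicit observedness mask.

    The mask is ``True`` where a cell is observed.  Invariants enforced at
    construction: unique subject ids, mask/data agreement (missing iff masked
    out), and every observed value within its declared bounds.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        mask: pd.DataFrame | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        if "subject_id" not in data.columns:
            raise PanelValidationError("panel requires a subject_id column")
        data = data.reset_index(drop=True)
        values = data.drop(columns=["subject_id"]).astype(float)
        if mask is None:
            mask = values.notna()
        else:
            mask = mask.reset_index(drop=True).astype(bool)
            if list(mask.columns) != list(values.columns) or len(mask) != len(values):
                raise PanelValidationError("mask shape/columns do not match data")
        self.subject_id = data["subject_id"].reset_index(drop=True)
        self.data = values
        self.mask = mask
        self.bounds = dict(VARIABLE_BOUNDS if bounds is None else bounds)
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        if self.subject_id.duplicated().any():
            dupes = self.subject_id[self.subject_id.duplicated()].tolist()
            raise PanelValidationError(f"duplicate subject ids: {dupes[:5]}")
        observed = self.data.notna()
        if not observed.equals(self.mask):
            raise PanelValidationError("mask and data disagree on missing cells")
        for col in self.data.columns:
            if col not in self.bounds:
                raise PanelValidationError(f"unknown column: {col}")
            lo, hi = self.bounds[col]
            vals = self.data[col].dropna()
            bad = vals[(vals < lo) | (vals > hi)]
            if not bad.empty:
                raise PanelValidationError(
                    f"{col}: {len(bad)} observed value(s) outside [{lo}, {hi}] "
                    f"(first offending value {bad.iloc[0]})"
                )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "PanelTable":
        return PanelTable(
            self.to_frame(), self.mask.copy(), bounds=self.bounds
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "subject_id", self.subject_id)
        return out

    def complete_cases(self, columns: Iterable[str] | None = None) -> "PanelTable":
        cols = list(columns) if columns is not None else self.columns
        keep = self.data[cols].notna().all(axis=1)
        frame = self.to_frame().loc[keep].reset_index(drop=True)
        return PanelTable(frame, bounds=self.bounds)

    def equals(self, other: "PanelTable") -> bool:
        same_ids = self.subject_id.astype(str).equals(other.subject_id.astype(str))
        return bool(
            same_ids
            and self.data.equals(other.data)
            and self.mask.equals(other.mask)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        miss = 100 * (1 - self.mask.to_numpy().mean()) if self.n else 0.0
        return f"PanelTable(n={self.n}, columns={len(self.columns)}, missing={miss:.1f}%)"


def read_panel(
    path: str | Path,
    schema: Sequence[ScaleDefinition] | Mapping[str, tuple[float, float]] | None = None,
    missing_token: str = "",
) -> PanelTable:
    """Read a one-row-per-subject CSV into a validated :class:`PanelTable`.

    ``missing_token`` is the sentinel recorded for missing cells (empty cell by
    default).  Out-of-bounds observed values, duplicate ids and unknown columns
    raise :class:`PanelValidationError`.
    """
    na_values = [missing_token] if missing_token else None
    df = pd.read_csv(
        path, na_values=na_values, keep_default_na=(missing_token == "")
    )
    return PanelTable(df, bounds=_bounds_from_schema(schema))


def write_panel(table: PanelTable, path: str | Path, missing_token: str = "") -> None:
    """Write a panel back to CSV with a stable column order and float format."""
    table.to_frame().to_csv(
        path, index=False, na_rep=missing_token, float_format="%.10g"
    )


# -- scale scoring -----------------------------------------------------------------


def _as_item_matrix(item_responses, scale: ScaleDefinition) -> np.ndarray:
    items = np.asarray(item_responses, dtype=float)
    if items.ndim != 2:
        raise ValueError("item_responses must be 2-D (subjects x items)")
    if items.shape[1] != scale.item_count:
        raise ValueError(
            f"expected {scale.item_count} items for scale '{scale.name}', "
            f"got {items.shape[1]}"
        )
    return items


def score_scale(
    item_responses,
    scale: ScaleDefinition,
    min_prop_observed: float = 0.5,
) -> np.ndarray:
    """Prorated mean score of a multi-item scale.

    Reverse-worded items are recoded ``v -> min + max - v`` first.  The score
    is the mean of non-missing recoded items when the observed fraction is at
    least ``min_prop_observed``; otherwise the score is missing (NaN).
    """
    items = _as_item_matrix(item_responses, scale).copy()
    for idx in scale.reverse_items:
        items[:, idx - 1] = scale.response_min + scale.response_max - items[:, idx - 1]
    observed = ~np.isnan(items)
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.nanmean(np.where(observed, items, np.nan), axis=1)
    prop = n_obs / scale.item_count
    score[(prop < min_prop_observed) | (n_obs == 0)] = np.nan
    return score


def cronbach_alpha(item_responses) -> float:
    """Cronbach's alpha on listwise-complete rows.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(total score))``.
    Requires at least two items and three complete rows; a zero total-score
    variance is an error.
    """
    items = np.asarray(item_responses, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two items")
    complete = items[~np.isnan(items).any(axis=1)]
    if complete.shape[0] < 3:
        raise ValueError("need at least three complete rows")
    k = complete.shape[1]
    item_var = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


# -- missingness -------------------------------------------------------------------


@dataclass
class MissingnessReport:
    """Per-variable missing-data percentages plus the complete-case count."""

    per_variable: pd.DataFrame
    n_complete_cases: int
    n: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n": self.n,
            "n_complete_cases": self.n_complete_cases,
            "per_variable": {
                row["variable"]: {
                    "n_missing": int(row["n_missing"]),
                    "pct_missing": row["pct_missing"],
                }
                for _, row in self.per_variable.iterrows()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        self.per_variable.to_csv(path, index=False, float_format="%.6g")


def summarize_missingness(
    table: PanelTable, variables: Sequence[str] | None = None
) -> MissingnessReport:
    """Percent missing per analysis variable and the listwise-complete count."""
    cols = list(variables) if variables is not None else [
        c for c in ANALYSIS_VARIABLES if c in table.columns
    ]
    n = table.n
    rows = []
    for col in cols:
        n_missing = int((~table.mask[col]).sum())
        rows.append(
            {
                "variable": col,
                "n_missing": n_missing,
                "pct_missing": 100.0 * n_missing / n if n else 0.0,
            }
        )
    complete = int(table.mask[cols].all(axis=1).sum()) if cols else n
    return MissingnessReport(pd.DataFrame(rows), complete, n)
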