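"""Adjusted logistic models, stepwise-AIC selection and interaction tests.

Maximum-likelihood fitting is delegated to :mod:`statsmodels` (Newton
iterations, gradient tolerance 1e-8, at most 100 steps); design matrices
are assembled here so that every coefficient has a predictable name and
the exposure / PRS terms can be located downstream (the genetic-risk-
equivalent computation needs the pair of coefficients plus their
covariance).

Categorical terms enter as treatment (dummy) contrasts against their
first level — for the ordinal exposure that is the lowest-intake
category, for the 5-level PRS stratum the medium category.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "ModelSpec",
    "FittedLogisticModel",
    "ORResult",
    "StepwiseResult",
    "InteractionTest",
    "ConvergenceError",
    "RankDeficiencyError",
    "EmptyCellError",
    "fit_logistic",
    "stepwise_aic",
    "interaction_test",
    "joint_effects",
    "descriptive_table",
]

#: non-default reference levels for treatment coding
_REFERENCE_OVERRIDES = {"prs_category": "medium"}

_PRS_CODINGS = {"percentile": 1.0, "per10": 10.0, "category": None}


class ConvergenceError(RuntimeError):
    """The likelihood maximisation failed (separation or non-convergence)."""


class RankDeficiencyError(ValueError):
    """Aliased model terms; the message names the offending columns."""


class EmptyCellError(ValueError):
    """A required factor-combination cell holds no observations."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one logistic model.

    ``prs`` selects how the polygenic score enters: ``"percentile"``
    (log-odds per percentile), ``"per10"`` (per 10 percentiles),
    ``"category"`` (5-level stratum vs medium) or ``None``.
    ``interactions`` are pairs of term names (``"exposure"``, ``"prs"``
    or any adjustment term); each pair expands to all products of the
    two groups' design columns.
    """

    outcome: str = "case"
    exposure: Optional[str] = "exposure"
    adjust: tuple = ("age", "sex")
    prs: Optional[str] = None
    interactions: tuple = ()

    def __post_init__(self) -> None:
        if self.prs is not None and self.prs not in _PRS_CODINGS:
            raise ValueError(f"unknown prs coding '{self.prs}'")
        for pair in self.interactions:
            if len(pair) != 2:
                raise ValueError("interactions must be term pairs")

    def raw_columns(self) -> list[str]:
        cols = [self.outcome]
        if self.exposure:
            cols.append(self.exposure)
        cols.extend(self.adjust)
        if self.prs in ("percentile", "per10"):
            cols.append("prs_percentile")
        elif self.prs == "category":
            cols.append("prs_category")
        for a, b in self.interactions:
            for t in (a, b):
                if t not in ("exposure", "prs") and t not in cols:
                    cols.append(t)
        return list(dict.fromkeys(cols))


@dataclass(frozen=True)
class ORResult:
    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None


def _dummies(series: pd.Series, name: str) -> tuple[pd.DataFrame, list[str]]:
    """Treatment-coded dummies; reference = first category (or override)."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        levels = list(series.cat.categories)
    else:
        levels = sorted(pd.unique(series.dropna()))
    ref = _REFERENCE_OVERRIDES.get(name, levels[0])
    out = {}
    for lvl in levels:
        if lvl == ref:
            continue
        out[f"{name}[{lvl}]"] = (series == lvl).astype(float)
    frame = pd.DataFrame(out, index=series.index)
    return frame, list(frame.columns)


def _term_design(data: pd.DataFrame, term: str) -> tuple[pd.DataFrame, list[str]]:
    col = data[term]
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        return _dummies(col, term)
    return pd.DataFrame({term: col.astype(float)}), [term]


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Outcome vector, design matrix (with intercept) and term map."""
    y = data[spec.outcome].astype(float)
    parts: list[pd.DataFrame] = []
    term_map: dict[str, list[str]] = {}

    if spec.exposure:
        frame, cols = _dummies(data[spec.exposure], spec.exposure)
        parts.append(frame)
        term_map["exposure"] = cols
    for term in spec.adjust:
        frame, cols = _term_design(data, term)
        parts.append(frame)
        term_map[term] = cols
    if spec.prs in ("percentile", "per10"):
        units = _PRS_CODINGS[spec.prs]
        colname = "prs_percentile" if units == 1.0 else "prs_per10"
        frame = pd.DataFrame(
            {colname: data["prs_percentile"].astype(float) / units})
        parts.append(frame)
        term_map["prs"] = [colname]
    elif spec.prs == "category":
        frame, cols = _dummies(data["prs_category"], "prs_category")
        parts.append(frame)
        term_map["prs"] = cols

    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=data.index)

    for a, b in spec.interactions:
        cols_a = term_map.get(a) or term_map.get("prs" if a == "prs" else a)
        cols_b = term_map.get(b)
        if cols_a is None or cols_b is None:
            raise ValueError(f"interaction pair ({a}, {b}) not in model terms")
        prod_cols = []
        for ca in cols_a:
            for cb in cols_b:
                cname = f"{ca}:{cb}"
                X[cname] = X[ca] * X[cb]
                prod_cols.append(cname)
        term_map[f"{a}:{b}"] = prod_cols

    X.insert(0, "const", 1.0)
    return y, X, term_map


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {arr.shape[1]}; aliased terms: {bad}")


@dataclass
class FittedLogisticModel:
    """A fitted logistic model: coefficients, covariance and term metadata."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    n_used: int
    n_dropped: int
    term_map: dict
    spec: ModelSpec
    prs_percentiles_per_unit: Optional[float] = None
    exposure_counts: Optional[pd.DataFrame] = None

    @property
    def k_params(self) -> int:
        return len(self.params)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def wald_p(self) -> pd.Series:
        z = self.params / self.se()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def or_table(self, ci_level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + ci_level / 2)
        se = self.se()
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": se,
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.params - z * se),
                "ci_high": np.exp(self.params + z * se),
                "p": self.wald_p(),
            }
        )

    def exposure_ors(self, ci_level: float = 0.95) -> list[ORResult]:
        tab = self.or_table(ci_level)
        out = []
        for col in self.term_map.get("exposure", []):
            level = col[col.index("[") + 1:-1]
            n_ca = n_co = None
            if self.exposure_counts is not None and level in self.exposure_counts.index:
                n_ca = int(self.exposure_counts.loc[level, "cases"])
                n_co = int(self.exposure_counts.loc[level, "controls"])
            row = tab.loc[col]
            out.append(ORResult(level, row["OR"], row["ci_low"],
                                row["ci_high"], row["p"], n_ca, n_co))
        return out

    def to_json(self) -> str:
        payload = {
            "params": self.params.to_dict(),
            "cov": {"index": list(self.cov.index),
                    "values": self.cov.to_numpy().tolist()},
            "loglik": self.loglik,
            "aic": self.aic,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "term_map": self.term_map,
            "prs_percentiles_per_unit": self.prs_percentiles_per_unit,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedLogisticModel":
        d = json.loads(text)
        params = pd.Series(d["params"])
        cov = pd.DataFrame(np.asarray(d["cov"]["values"]),
                           index=d["cov"]["index"], columns=d["cov"]["index"])
        return cls(params=params, cov=cov, loglik=d["loglik"], aic=d["aic"],
                   n_used=d["n_used"], n_dropped=d["n_dropped"],
                   term_map=d["term_map"], spec=ModelSpec(exposure=None, adjust=()),
                   prs_percentiles_per_unit=d.get("prs_percentiles_per_unit"))


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> FittedLogisticModel:
    """Maximum-likelihood logistic fit with observed-information covariance.

    Rows missing any involved variable are dropped (complete-case) and
    counted in ``n_dropped``. Separation or failed convergence raises
    :class:`ConvergenceError`; aliased terms raise
    :class:`RankDeficiencyError` naming them.
    """
    cols = spec.raw_columns()
    sub = data[cols].dropna()
    n_dropped = len(data) - len(sub)
    y, X, term_map = build_design(sub, spec)
    if len(sub) < X.shape[1] + 10:
        raise ValueError(
            f"only {len(sub)} complete-case rows for {X.shape[1]} parameters")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome '{spec.outcome}' must be binary 0/1")
    _check_rank(X)

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y.to_numpy(), X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ConvergenceError(f"perfect separation: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("Newton iterations did not converge")

    counts = None
    if spec.exposure:
        ct = pd.crosstab(sub[spec.exposure], y)
        counts = pd.DataFrame({
            "cases": ct.get(1.0, pd.Series(0, index=ct.index)),
            "controls": ct.get(0.0, pd.Series(0, index=ct.index)),
        })
        counts.index = counts.index.astype(str)

    units = _PRS_CODINGS.get(spec.prs) if spec.prs else None
    return FittedLogisticModel(
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        loglik=float(res.llf),
        aic=float(res.aic),
        n_used=len(sub),
        n_dropped=n_dropped,
        term_map=term_map,
        spec=spec,
        prs_percentiles_per_unit=units,
        exposure_counts=counts,
    )


@dataclass
class StepwiseResult:
    spec: ModelSpec
    model: FittedLogisticModel
    history: list = field(default_factory=list)

    @property
    def selected(self) -> tuple:
        forced = self.history[0][1] if self.history else ()
        return tuple(t for t in self.spec.adjust if t not in forced)


def stepwise_aic(
    data: pd.DataFrame,
    forced: Sequence[str],
    candidates: Sequence[str],
    base_spec: Optional[ModelSpec] = None,
) -> StepwiseResult:
    """Greedy bidirectional (forward/backward) AIC search over candidates.

    ``forced`` terms are always retained. At each step every single-term
    addition and deletion is evaluated; the move with the lowest AIC is
    taken if it strictly improves on the current model, else the search
    stops. Candidate models that fail to converge are skipped with a
    warning. Deterministic given the data (ties break on sorted term
    order).
    """
    forced = tuple(forced)
    candidates = tuple(sorted(candidates))
    if set(forced) & set(candidates):
        raise ValueError("candidates must be disjoint from forced terms")
    if base_spec is None:
        base_spec = ModelSpec()
    # rows fixed to complete cases over ALL candidate variables so AICs compare
    all_cols = replace(base_spec, adjust=forced + candidates).raw_columns()
    sub = data[all_cols].dropna()

    def fit_with(sel: tuple):
        spec = replace(base_spec, adjust=forced + sel)
        return spec, fit_logistic(sub, spec)

    selected: tuple = ()
    spec, model = fit_with(selected)
    history = [("start", forced, model.aic)]

    while True:
        best_aic, best_sel, best_move = model.aic, None, None
        moves = [("add", c) for c in candidates if c not in selected]
        moves += [("drop", c) for c in selected]
        for kind, term in moves:
            trial = (tuple(sorted(selected + (term,))) if kind == "add"
                     else tuple(t for t in selected if t != term))
            try:
                _, m = fit_with(trial)
            except (ConvergenceError, RankDeficiencyError) as exc:
                warnings.warn(f"stepwise skipped {kind} '{term}': {exc}")
                continue
            if m.aic < best_aic - 1e-10:
                best_aic, best_sel, best_move = m.aic, trial, (kind, term)
        if best_sel is None:
            break
        selected = best_sel
        spec, model = fit_with(selected)
        history.append((best_move, selected, model.aic))

    return StepwiseResult(spec=spec, model=model, history=history)


@dataclass(frozen=True)
class InteractionTest:
    p_value: float
    df: int
    statistic: float
    method: str


def interaction_test(
    data: pd.DataFrame,
    spec: ModelSpec,
    pair: tuple = ("exposure", "prs"),
    method: str = "lrt",
) -> InteractionTest:
    """Joint test of all cross-product coefficients for a term pair.

    ``method="lrt"`` compares the log-likelihoods of the models with and
    without the product block; ``"wald"`` tests the block against its
    covariance in the expanded model. For two categorical components any
    empty cross-cell raises :class:`EmptyCellError` naming it.
    """
    if method not in ("lrt", "wald"):
        raise ValueError("method must be 'lrt' or 'wald'")
    a, b = pair
    full_spec = replace(spec, interactions=spec.interactions + ((a, b),))
    sub = data[full_spec.raw_columns()].dropna()

    def _component(name):
        if name == "exposure":
            return sub[spec.exposure]
        if name == "prs":
            return sub["prs_category"] if spec.prs == "category" else None
        col = sub[name]
        return col if (isinstance(col.dtype, pd.CategoricalDtype)
                       or col.dtype == object) else None

    ca, cb = _component(a), _component(b)
    if ca is not None and cb is not None:
        ct = pd.crosstab(ca, cb)
        empties = [(str(i), str(j)) for i in ct.index for j in ct.columns
                   if ct.loc[i, j] == 0]
        if empties:
            raise EmptyCellError(f"empty cross-cells for ({a}, {b}): {empties}")

    base = fit_logistic(sub, spec)
    full = fit_logistic(sub, full_spec)
    block = full.term_map[f"{a}:{b}"]
    df = len(block)
    if method == "lrt":
        stat = 2.0 * (full.loglik - base.loglik)
    else:
        beta = full.params[block].to_numpy()
        v = full.cov.loc[block, block].to_numpy()
        stat = float(beta @ np.linalg.solve(v, beta))
    stat = max(stat, 0.0)
    return InteractionTest(
        p_value=float(stats.chi2.sf(stat, df)), df=df,
        statistic=float(stat), method=method)


def joint_effects(
    data: pd.DataFrame,
    adjust: Sequence[str] = ("age", "sex"),
    exposure: str = "exposure",
    prs_col: str = "prs_category",
    reference: tuple = ("medium", "<=1/week"),
    ci_level: float = 0.95,
    outcome: str = "case",
) -> pd.DataFrame:
    """OR grid for all PRS-stratum x exposure cells vs one uniform reference.

    Returns a tidy frame (one row per cell) with counts, OR and CI; the
    reference cell carries OR 1 with a degenerate CI. Any cell without
    observations in both outcome arms raises :class:`EmptyCellError`.
    """
    spec_cols = [outcome, exposure, prs_col, *adjust]
    sub = data[spec_cols].dropna()
    prs_levels = list(sub[prs_col].cat.categories)
    exp_levels = list(sub[exposure].cat.categories)

    cells = sub[prs_col].astype(str) + "|" + sub[exposure].astype(str)
    ref_cell = f"{reference[0]}|{reference[1]}"
    for p in prs_levels:
        for e in exp_levels:
            cell = f"{p}|{e}"
            m = cells == cell
            if not m.any() or sub.loc[m, outcome].nunique() < 2:
                raise EmptyCellError(
                    f"joint-effects cell (PRS {p}, exposure {e}) lacks "
                    "observations in both arms")

    work = sub[[outcome, *adjust]].copy()
    order = [ref_cell] + [f"{p}|{e}" for p in prs_levels for e in exp_levels
                          if f"{p}|{e}" != ref_cell]
    work["cell"] = pd.Categorical(cells, categories=order)
    spec = ModelSpec(outcome=outcome, exposure="cell", adjust=tuple(adjust))
    model = fit_logistic(work, spec)
    tab = model.or_table(ci_level)

    rows = []
    for p in prs_levels:
        for e in exp_levels:
            cell = f"{p}|{e}"
            m = cells == cell
            n_ca = int((sub.loc[m, outcome] == 1).sum())
            n_co = int((sub.loc[m, outcome] == 0).sum())
            if cell == ref_cell:
                orv, lo, hi = 1.0, np.nan, np.nan
            else:
                row = tab.loc[f"cell[{cell}]"]
                orv, lo, hi = row["OR"], row["ci_low"], row["ci_high"]
            rows.append({"prs_category": p, "exposure": e, "n_cases": n_ca,
                         "n_controls": n_co, "OR": orv, "ci_low": lo,
                         "ci_high": hi})
    return pd.DataFrame(rows)


def descriptive_table(
    data: pd.DataFrame,
    characteristics: Optional[Sequence[str]] = None,
    outcome: str = "case",
    matching_factors: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Case/control distributions with Pearson chi-square tests.

    Continuous characteristics are summarised as median (Q1, Q3);
    matching factors are displayed but flagged as not tested; missing
    values are excluded from tests and counted per characteristic.
    """
    if characteristics is None:
        skip = {outcome, "subject_id", "site", "stage",
                "prs_score", "prs_percentile", "prs_true_percentile"}
        characteristics = [c for c in data.columns if c not in skip]
    cases = data[data[outcome] == 1]
    controls = data[data[outcome] == 0]
    rows = []
    for char in characteristics:
        col = data[char]
        is_matching = char in matching_factors
        if pd.api.types.is_float_dtype(col):
            def _fmt(d):
                q = d[char].quantile([0.25, 0.5, 0.75])
                return f"{q[0.5]:.1f} ({q[0.25]:.1f}, {q[0.75]:.1f})"
            rows.append({"characteristic": char, "level": "median (Q1, Q3)",
                         "cases": _fmt(cases), "controls": _fmt(controls),
                         "statistic": np.nan, "p_value": np.nan,
                         "note": ("matching factor, not tested" if is_matching
                                  else "continuous, not tested")})
            continue
        ct = pd.crosstab(col, data[outcome])
        n_ca, n_co = ct.get(1, 0), ct.get(0, 0)
        if ct.shape[0] < 2:
            stat, p, note = np.nan, np.nan, "single level, test skipped"
        elif is_matching:
            stat, p, note = np.nan, np.nan, "matching factor, not tested"
        else:
            stat, p, _, _ = stats.chi2_contingency(
                ct.to_numpy(), correction=False)
            note = ""
        for lvl in ct.index:
            ca, co = int(n_ca.get(lvl, 0)), int(n_co.get(lvl, 0))
            rows.append({
                "characteristic": char, "level": str(lvl),
                "cases": f"{ca} ({100 * ca / max(len(cases), 1):.1f})",
                "controls": f"{co} ({100 * co / max(len(controls), 1):.1f})",
                "statistic": stat, "p_value": p, "note": note})
            stat, p = np.nan, np.nan  # print test once per characteristic
        n_miss_ca = int(cases[char].isna().sum())
        n_miss_co = int(controls[char].isna().sum())
        if n_miss_ca or n_miss_co:
            rows.append({"characteristic": char, "level": "(missing)",
                         "cases": str(n_miss_ca), "controls": str(n_miss_co),
                         "statistic": np.nan, "p_value": np.nan,
                         "note": "excluded from test"})
    return pd.DataFrame(rows)
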