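"""Genetic risk equivalents: exposure effects on the PRS-percentile scale.

The genetic risk equivalent (GRE) of an exposure contrast translates its
log odds ratio into the number of PRS percentiles conferring the same
risk, in direct analogy with risk/rate advancement periods (which use
years of age as the common currency):

    GRE = beta_E / beta_G

where ``beta_E`` is the exposure log-OR and ``beta_G`` the log-odds per
single PRS percentile, both from the same logistic model. A GRE of 20
means the exposure's effect equals that of a PRS 20 percentiles higher.

Confidence intervals for this ratio of coefficients are available three
ways, mutually validating:

* first-order **delta** method (default): symmetric about the point
  estimate, appropriate when the PRS coefficient is estimated precisely;
* **Fieller's** exact-quadratic method: may return an unbounded or
  exclusive region when the denominator is not significantly nonzero;
* parametric **bootstrap** of the coefficient pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "GREResult",
    "FiellerInterval",
    "gre_point",
    "gre_ci_delta",
    "gre_ci_fieller",
    "gre_ci_bootstrap",
    "gre_from_model",
]


@dataclass(frozen=True)
class GREResult:
    """GRE for one exposure contrast, in single-PRS-percentile units."""

    contrast: str
    gre: float
    ci_low: float
    ci_high: float
    method: str
    beta_E: float
    beta_G: float
    var_E: float
    var_G: float
    cov_EG: float
    bounded: bool = True


@dataclass(frozen=True)
class FiellerInterval:
    low: float
    high: float
    #: "interval" (bounded), "complement" (everything outside (low, high)),
    #: or "line" (no information about the ratio at this level)
    kind: str

    @property
    def bounded(self) -> bool:
        return self.kind == "interval"


def _check_inputs(beta_G: float, var_E: float, var_G: float) -> None:
    if beta_G == 0:
        raise ZeroDivisionError(
            "PRS coefficient is zero: the genetic risk equivalent is "
            "undefined (non-informative PRS)")
    if var_E < 0 or var_G < 0:
        raise ValueError("variances must be non-negative")


def gre_point(beta_E: float, beta_G: float) -> float:
    """Ratio of the exposure log-OR to the per-percentile PRS coefficient."""
    _check_inputs(beta_G, 0.0, 0.0)
    return beta_E / beta_G


def gre_ci_delta(
    beta_E: float,
    beta_G: float,
    var_E: float,
    var_G: float,
    cov_EG: float = 0.0,
    level: float = 0.95,
) -> tuple[float, float]:
    """First-order delta-method CI for the coefficient ratio.

    SE^2 = var_E/bG^2 + bE^2 var_G/bG^4 - 2 bE cov/bG^3; the interval is
    symmetric about the point estimate.
    """
    _check_inputs(beta_G, var_E, var_G)
    g = beta_E / beta_G
    se2 = (var_E / beta_G**2
           + beta_E**2 * var_G / beta_G**4
           - 2.0 * beta_E * cov_EG / beta_G**3)
    if se2 < 0:
        raise ValueError(
            f"negative delta-method variance ({se2:.3g}); the covariance "
            "input is inconsistent with the variances")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(se2)
    return g - half, g + half


def gre_ci_fieller(
    beta_E: float,
    beta_G: float,
    var_E: float,
    var_G: float,
    cov_EG: float = 0.0,
    level: float = 0.95,
) -> FiellerInterval:
    """Fieller confidence set for the coefficient ratio.

    Solves (bG^2 - z^2 vG) r^2 - 2 (bE bG - z^2 cov) r + (bE^2 - z^2 vE) = 0.
    A bounded interval exists iff the denominator is significant at the
    level; otherwise the set is the complement of an interval or the
    whole line, reported via :class:`FiellerInterval.kind`.
    """
    _check_inputs(beta_G, var_E, var_G)
    z2 = stats.norm.ppf(0.5 + level / 2) ** 2
    a = beta_G**2 - z2 * var_G
    b = -2.0 * (beta_E * beta_G - z2 * cov_EG)
    c = beta_E**2 - z2 * var_E
    disc = b * b - 4.0 * a * c
    if a > 0:
        # denominator significantly nonzero -> bounded interval; disc >= 0
        # is then guaranteed up to rounding
        sq = math.sqrt(max(disc, 0.0))
        return FiellerInterval((-b - sq) / (2 * a), (-b + sq) / (2 * a),
                               "interval")
    if disc > 0 and a < 0:
        r1, r2 = sorted([(-b - math.sqrt(disc)) / (2 * a),
                         (-b + math.sqrt(disc)) / (2 * a)])
        return FiellerInterval(r1, r2, "complement")
    return FiellerInterval(-math.inf, math.inf, "line")


def gre_ci_bootstrap(
    beta_E: float,
    beta_G: float,
    var_E: float,
    var_G: float,
    cov_EG: float = 0.0,
    level: float = 0.95,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile CI: MVN draws of the coefficient pair."""
    _check_inputs(beta_G, var_E, var_G)
    rng = np.random.default_rng(seed)
    cov = np.array([[var_E, cov_EG], [cov_EG, var_G]])
    draws = rng.multivariate_normal([beta_E, beta_G], cov, size=n_draws,
                                    method="cholesky")
    ratios = draws[:, 0] / draws[:, 1]
    alpha = (1 - level) / 2
    lo, hi = np.quantile(ratios, [alpha, 1 - alpha])
    return float(lo), float(hi)


def gre_from_model(
    model,
    method: str = "delta",
    level: float = 0.95,
    n_draws: int = 10_000,
    seed: int = 0,
) -> list[GREResult]:
    """One GRE per non-reference exposure level of a fitted logistic model.

    The model must carry a *continuous* PRS term; per-10-percentile
    coding is rescaled so results are always in single percentiles.
    ``model`` is a :class:`polygre.regression.FittedLogisticModel`.
    """
    if method not in ("delta", "fieller", "bootstrap"):
        raise ValueError("method must be 'delta', 'fieller' or 'bootstrap'")
    prs_cols = model.term_map.get("prs")
    units = model.prs_percentiles_per_unit
    if not prs_cols or units is None:
        raise ValueError(
            "model lacks a continuous PRS term; the genetic risk "
            "equivalent requires the PRS as a (per-)percentile covariate")
    prs_col = prs_cols[0]
    # per-unit-of-column coefficient -> per-single-percentile
    beta_G = float(model.params[prs_col]) / units
    var_G = float(model.cov.loc[prs_col, prs_col]) / units**2

    results = []
    for col in model.term_map.get("exposure", []):
        contrast = col[col.index("[") + 1:-1]
        beta_E = float(model.params[col])
        var_E = float(model.cov.loc[col, col])
        cov_EG = float(model.cov.loc[col, prs_col]) / units
        point = gre_point(beta_E, beta_G)
        bounded = True
        if method == "delta":
            lo, hi = gre_ci_delta(beta_E, beta_G, var_E, var_G, cov_EG, level)
        elif method == "fieller":
            fi = gre_ci_fieller(beta_E, beta_G, var_E, var_G, cov_EG, level)
            lo, hi, bounded = fi.low, fi.high, fi.bounded
        else:
            lo, hi = gre_ci_bootstrap(beta_E, beta_G, var_E, var_G, cov_EG,
                                      level, n_draws, seed)
        results.append(GREResult(
            contrast=contrast, gre=point, ci_low=lo, ci_high=hi,
            method=method, beta_E=beta_E, beta_G=beta_G, var_E=var_E,
            var_G=var_G, cov_EG=cov_EG, bounded=bounded))
    return results
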