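"""Synthetic case-control cohort generator.

Emulates a population-based case-control study of a gene-environment
question: a 4-level ordinal dietary exposure, a polygenic risk score
(PRS) built from ~140 independent risk loci, binary/categorical
confounders, and a logistic disease model on the PRS *percentile* scale.

Design
------
Subjects are drawn i.i.d. from a super-population (streamed in fixed-size
chunks so that arbitrarily large pools fit in memory). Disease status is
Bernoulli under a logistic model whose intercept is calibrated to a
configurable population prevalence; all cases up to ``n_cases`` and a
random (optionally age-decade x sex frequency-matched) subset of controls
are retained — the classical retrospective sampling scheme under which
logistic odds ratios are preserved.

The subject's "true" PRS percentile is evaluated against the *analytic*
population distribution of the score (exact convolution of the per-locus
dosage distributions), so the generative coefficient
``beta_prs_per_percentile`` has an exactly defined scale independent of
pool size.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from .prs import RiskLociPanel, RiskLocus

__all__ = [
    "EXPOSURE_LEVELS",
    "SITE_LEVELS",
    "STAGE_LEVELS",
    "COVARIATE_REGISTRY",
    "CovariateDef",
    "SimulationConfig",
    "SyntheticDataset",
    "SimulationError",
    "simulate_dosages",
    "simulate_cohort",
    "population_score_percentile_fn",
]

#: ordinal exposure categories, lowest (reference) first
EXPOSURE_LEVELS = ["<=1/week", "multiple/week", "1/day", ">1/day"]

SITE_LEVELS = ["proximal_colon", "distal_colon", "rectum", "unknown"]
STAGE_LEVELS = ["I-III", "IV", "unknown"]

# site/stage mix among cases (generator default, independent of exposure)
_SITE_PROBS = (0.33, 0.26, 0.38, 0.03)
_STAGE_PROBS = (0.82, 0.135, 0.045)

#: control-population exposure distribution (complete-case control counts
#: 469/2444/979/124, normalised)
DEFAULT_EXPOSURE_PREVALENCES = tuple(
    np.array([469.0, 2444.0, 979.0, 124.0]) / 4016.0
)

_CHUNK = 100_000  # super-population streaming chunk; fixed so output is seed-stable


class SimulationError(RuntimeError):
    """The requested cohort cannot be drawn from the configured population."""


@dataclass(frozen=True)
class CovariateDef:
    """A confounder: its levels, control prevalences and default log-ORs.

    ``levels`` of length 2 are emitted as 0/1 integer columns named after
    the covariate; longer ones as ordered categoricals. ``effects`` holds
    one log-OR per non-reference level.
    """

    name: str
    levels: tuple
    prevalences: tuple
    effects: tuple


# Representative confounder panel at control prevalences of a large
# population-based CRC case-control study; default effects are plausible
# adjusted log-ORs, not estimates from any single dataset.
COVARIATE_REGISTRY: dict[str, CovariateDef] = {
    c.name: c
    for c in [
        CovariateDef("education", ("<9y", "9-10y", ">10y"),
                     (0.553, 0.212, 0.235), (-0.20, -0.35)),
        CovariateDef("bmi", ("<25", "25-<30", "30+"),
                     (0.385, 0.457, 0.158), (0.15, 0.35)),
        CovariateDef("smoking", ("never", "former", "current"),
                     (0.506, 0.385, 0.109), (0.10, 0.40)),
        CovariateDef("alcohol_above", (0, 1), (0.774, 0.226), (0.25,)),
        CovariateDef("diabetes", (0, 1), (0.865, 0.135), (0.35,)),
        CovariateDef("family_history", (0, 1), (0.891, 0.109), (0.35,)),
        CovariateDef("colonoscopy", (0, 1), (0.397, 0.603), (-0.70,)),
        CovariateDef("nsaids", (0, 1), (0.620, 0.380), (-0.35,)),
        CovariateDef("statins", (0, 1), (0.776, 0.224), (-0.25,)),
    ]
}

_DEFAULT_COVARIATE_EFFECTS = {
    name: c.effects for name, c in COVARIATE_REGISTRY.items()
}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of the generative world.

    Effect sizes default to the adjusted odds ratios of the exposure in
    the motivating study class (1.19 / 1.41 / 1.73 vs the lowest intake)
    and a PRS log-odds of 0.0131 per percentile; both are free parameters.
    """

    n_cases: int = 2500
    n_controls: int = 2500
    n_loci: int = 140
    risk_allele_freqs: Optional[tuple] = None  # None -> U(0.05, 0.95) at draw time
    beta_prs_per_percentile: float = 0.0131
    beta_exposure: tuple = (
        math.log(1.19), math.log(1.41), math.log(1.73))
    exposure_control_prevalences: tuple = DEFAULT_EXPOSURE_PREVALENCES
    covariate_effects: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS))
    beta_age_per_year: float = 0.03
    beta_male: float = 0.30
    matching: bool = True
    population_prevalence: float = 0.05
    pool_size: Optional[int] = None  # None -> sized from counts/prevalence
    dosage_jitter_sd: float = 0.0
    missing_exposure_rate: float = 0.0
    exposure_confounding: float = 0.0  # latent shift per unit lifestyle score
    age_mean: float = 69.0
    age_sd: float = 10.4
    age_range: tuple = (30.0, 95.0)
    male_fraction: float = 0.614
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        prev = np.asarray(self.exposure_control_prevalences, dtype=float)
        if prev.size != 4 or abs(prev.sum() - 1.0) > 1e-9 or (prev <= 0).any():
            raise ValueError(
                "exposure_control_prevalences must be a positive 4-simplex")
        if len(self.beta_exposure) != 3:
            raise ValueError("beta_exposure needs 3 log-ORs (levels 2-4 vs 1)")
        if not 0 < self.population_prevalence < 1:
            raise ValueError("population_prevalence must be in (0, 1)")
        if self.risk_allele_freqs is not None:
            f = np.asarray(self.risk_allele_freqs, dtype=float)
            if f.size != self.n_loci:
                raise ValueError("risk_allele_freqs length must equal n_loci")
            if (f <= 0).any() or (f >= 1).any():
                raise ValueError("risk allele frequencies must lie in (0, 1)")
        if self.dosage_jitter_sd < 0:
            raise ValueError("dosage_jitter_sd must be >= 0")
        if not 0 <= self.missing_exposure_rate < 1:
            raise ValueError("missing_exposure_rate must be in [0, 1)")
        for name in self.covariate_effects:
            if name not in COVARIATE_REGISTRY:
                raise ValueError(f"unknown covariate '{name}'")
            want = len(COVARIATE_REGISTRY[name].levels) - 1
            got = np.atleast_1d(np.asarray(self.covariate_effects[name])).size
            if got != want:
                raise ValueError(
                    f"covariate '{name}' needs {want} effect(s), got {got}")

    @property
    def true_gre(self) -> tuple:
        """Exposure effects on the PRS-percentile scale implied by the truth.

        NaN when the PRS carries no effect (the ratio is undefined).
        """
        if self.beta_prs_per_percentile == 0:
            return (math.nan,) * len(self.beta_exposure)
        return tuple(b / self.beta_prs_per_percentile for b in self.beta_exposure)


@dataclass
class SyntheticDataset:
    """A simulated study: cohort table, dosage matrix, panel, and the truth."""

    cohort: pd.DataFrame
    dosages: pd.DataFrame
    panel: RiskLociPanel
    truth: SimulationConfig
    truth_extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        n = self.truth.n_cases + self.truth.n_controls
        assert len(self.cohort) == n, "cohort row count mismatch"
        assert len(self.dosages) == len(self.cohort)
        d = self.dosages.to_numpy(dtype=float)
        assert np.nanmin(d) >= -1e-9 and np.nanmax(d) <= 2 + 1e-9
        assert int(self.cohort["case"].sum()) == self.truth.n_cases


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_dosages(rng, n, freqs, jitter_sd):
    # Binomial(2, f) as the sum of two Bernoulli draws: ~8x faster than
    # generic rng.binomial with a per-column p vector
    shape = (n, freqs.size)
    d = np.add(rng.random(shape) < freqs, rng.random(shape) < freqs,
               dtype=np.float64)
    if jitter_sd > 0:
        d = np.clip(d + rng.normal(0.0, jitter_sd, size=d.shape), 0.0, 2.0)
    return d


def simulate_dosages(
    n_subjects: int,
    freqs: Sequence[float],
    seed: Union[int, np.random.Generator, None] = 0,
    jitter_sd: float = 0.0,
    locus_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Hardy-Weinberg dosage matrix: per-locus Binomial(2, f) draws.

    ``jitter_sd`` adds truncated (clipped to [0, 2]) Gaussian noise to
    mimic continuous imputed dosages.
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 1 or f.size == 0 or (f <= 0).any() or (f >= 1).any():
        raise ValueError("allele frequencies must be a vector in (0, 1)")
    rng = _as_rng(seed)
    d = _draw_dosages(rng, int(n_subjects), f, jitter_sd)
    if locus_ids is None:
        locus_ids = [f"L{j + 1:04d}" for j in range(f.size)]
    return pd.DataFrame(d, columns=list(locus_ids))


def _score_pmf(freqs: np.ndarray) -> np.ndarray:
    """Exact pmf of the integer allele-count score: convolution over loci."""
    pmf = np.array([1.0])
    for f in freqs:
        locus = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
        pmf = np.convolve(pmf, locus)
    return pmf


def population_score_percentile_fn(
    freqs: Sequence[float], jitter_sd: float = 0.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Mid-distribution percentile function of the population PRS.

    With integer dosages the score distribution is the exact convolution
    of the per-locus trinomials; percentile(s) = 100 * (P(S < s) +
    P(S = s)/2), the large-sample limit of mean-rank percentiles. With
    dosage jitter the integer pmf is smoothed with the Gaussian jitter of
    the locus sum (clipping at the dosage bounds is ignored, adequate for
    small jitter).
    """
    f = np.asarray(freqs, dtype=float)
    pmf = _score_pmf(f)
    support = np.arange(pmf.size, dtype=float)
    cum_below = np.concatenate([[0.0], np.cumsum(pmf)[:-1]])

    if jitter_sd == 0.0:

        def pct(scores: np.ndarray) -> np.ndarray:
            s = np.rint(np.asarray(scores, dtype=float)).astype(int)
            return 100.0 * (cum_below[s] + 0.5 * pmf[s])

        return pct

    sigma = jitter_sd * math.sqrt(f.size)

    def pct_jitter(scores: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, dtype=float)[:, None]
        return 100.0 * (pmf[None, :] * norm.cdf((s - support[None, :]) / sigma)).sum(axis=1)

    return pct_jitter


def _draw_covariates(rng, n, effects: Mapping) -> tuple[dict, np.ndarray]:
    """Covariate columns at registry prevalences plus their linear predictor."""
    cols: dict = {}
    eta = np.zeros(n)
    for name, cdef in COVARIATE_REGISTRY.items():
        p = np.asarray(cdef.prevalences)
        codes = np.searchsorted(np.cumsum(p[:-1]), rng.random(n), side="right")
        eff = np.concatenate([[0.0], np.atleast_1d(
            np.asarray(effects.get(name, np.zeros(len(cdef.levels) - 1)), dtype=float))])
        eta += eff[codes]
        if len(cdef.levels) == 2:
            cols[name] = codes.astype(np.int64)
        else:
            cols[name] = pd.Categorical.from_codes(
                codes, categories=[str(l) for l in cdef.levels], ordered=True)
    return cols, eta


def _lifestyle_score(cols: dict) -> np.ndarray:
    """Crude lifestyle latent used by the exposure-confounding knob."""
    smoking = np.asarray(pd.Categorical(cols["smoking"]).codes, dtype=float)
    z = smoking + np.asarray(cols["alcohol_above"], dtype=float)
    return z - z.mean() if z.size else z


def _draw_exposure(rng, n, prevalences, confounding, lifestyle) -> np.ndarray:
    """Ordinal exposure codes 0..3 via a latent-logistic threshold model."""
    cuts = logit(np.cumsum(np.asarray(prevalences)[:-1]))
    u = rng.logistic(size=n)
    if confounding != 0.0:
        u = u + confounding * lifestyle
    return np.searchsorted(cuts, u, side="right").astype(np.int64)


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete case-control study from the configured world.

    Raises :class:`SimulationError` (never silently truncates) when the
    super-population cannot supply the requested cases or matched
    controls; the message suggests a larger ``pool_size``.
    """
    rng = np.random.default_rng(config.seed)
    prev = config.population_prevalence

    if config.risk_allele_freqs is None:
        freqs = rng.uniform(0.05, 0.95, size=config.n_loci)
    else:
        freqs = np.asarray(config.risk_allele_freqs, dtype=float)

    pool = config.pool_size or int(math.ceil(
        1.3 * max(config.n_cases / prev, config.n_controls / (1 - prev))))
    # cap retained controls near 4x the request so huge pools stay in memory
    keep_q = min(1.0, 4.0 * config.n_controls / max(1.0, (1 - prev) * pool))

    pct_fn = population_score_percentile_fn(freqs, config.dosage_jitter_sd)
    intercept: Optional[float] = None
    chunks: list[dict] = []
    n_cases_seen = 0

    for start in range(0, pool, _CHUNK):
        n = min(_CHUNK, pool - start)
        a, b = [(x - config.age_mean) / config.age_sd for x in config.age_range]
        age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                            size=n, random_state=rng)
        male = (rng.random(n) < config.male_fraction).astype(np.int64)
        cov_cols, cov_eta = _draw_covariates(rng, n, config.covariate_effects)
        exposure = _draw_exposure(
            rng, n, config.exposure_control_prevalences,
            config.exposure_confounding, _lifestyle_score(cov_cols))
        miss_mask = (rng.random(n) < config.missing_exposure_rate
                     if config.missing_exposure_rate > 0 else np.zeros(n, bool))
        dos = _draw_dosages(rng, n, freqs, config.dosage_jitter_sd)
        score = dos.sum(axis=1)
        percentile = pct_fn(score)

        beta_exp = np.concatenate([[0.0], np.asarray(config.beta_exposure)])
        eta = (config.beta_prs_per_percentile * percentile
               + beta_exp[exposure]
               + cov_eta
               + config.beta_age_per_year * (age - config.age_mean)
               + config.beta_male * male)
        if intercept is None:
            # calibrate once, on the first chunk, to the target prevalence
            lo, hi = -30.0, 30.0
            intercept = float(brentq(
                lambda a0: expit(a0 + eta).mean() - prev, lo, hi, xtol=1e-10))
        p = expit(intercept + eta)
        case = rng.random(n) < p
        n_cases_seen += int(case.sum())
        keep = case | (rng.random(n) < keep_q)
        idx = np.flatnonzero(keep)

        chunk = {
            "case": case[idx].astype(np.int64),
            "age": age[idx],
            "sex": np.where(male[idx] == 1, "male", "female"),
            "exposure_code": exposure[idx],
            "exposure_missing": miss_mask[idx],
            "prs_true_percentile": percentile[idx],
            "_dosages": dos[idx],
        }
        for name, col in cov_cols.items():
            chunk[name] = (col[idx] if isinstance(col, np.ndarray)
                           else col[idx])
        chunks.append(chunk)

    if n_cases_seen < config.n_cases:
        raise SimulationError(
            f"super-population of {pool} yielded only {n_cases_seen} cases "
            f"(need {config.n_cases}); increase pool_size or "
            f"population_prevalence")

    keys = [k for k in chunks[0] if k != "_dosages"]
    data = {k: np.concatenate([c[k] for c in chunks]) for k in keys}
    dosages_all = np.vstack([c["_dosages"] for c in chunks])
    for name, cdef in COVARIATE_REGISTRY.items():
        if len(cdef.levels) > 2:
            data[name] = pd.Categorical(
                data[name], categories=[str(l) for l in cdef.levels], ordered=True)

    case_idx = np.flatnonzero(data["case"] == 1)
    ctrl_idx = np.flatnonzero(data["case"] == 0)
    take_cases = np.sort(rng.choice(case_idx, size=config.n_cases, replace=False))

    if config.matching:
        take_controls = _matched_controls(
            rng, data, take_cases, ctrl_idx, config.n_controls)
    else:
        if ctrl_idx.size < config.n_controls:
            raise SimulationError(
                f"only {ctrl_idx.size} controls retained (need "
                f"{config.n_controls}); increase pool_size")
        take_controls = np.sort(
            rng.choice(ctrl_idx, size=config.n_controls, replace=False))

    take = np.concatenate([take_cases, take_controls])
    order = rng.permutation(take.size)  # shuffle so file order hides status
    take = take[order]

    cohort = pd.DataFrame({k: (v[take] if not isinstance(v, pd.Categorical)
                               else v[take]) for k, v in data.items()})
    cohort["exposure"] = pd.Categorical.from_codes(
        cohort.pop("exposure_code"), categories=EXPOSURE_LEVELS, ordered=True)
    cohort.loc[cohort.pop("exposure_missing").astype(bool), "exposure"] = np.nan
    cohort["sex"] = pd.Categorical(cohort["sex"], categories=["female", "male"])

    # tumour site and stage for cases only
    n_total = len(cohort)
    site = np.full(n_total, None, dtype=object)
    stage = np.full(n_total, None, dtype=object)
    is_case = cohort["case"].to_numpy() == 1
    n_case = int(is_case.sum())
    site[is_case] = rng.choice(SITE_LEVELS, size=n_case, p=_SITE_PROBS)
    stage[is_case] = rng.choice(STAGE_LEVELS, size=n_case, p=_STAGE_PROBS)
    cohort["site"] = pd.Categorical(site, categories=SITE_LEVELS)
    cohort["stage"] = pd.Categorical(stage, categories=STAGE_LEVELS)

    subject_ids = [f"S{i + 1:06d}" for i in range(n_total)]
    cohort.index = pd.Index(subject_ids, name="subject_id")
    cohort.insert(0, "subject_id", subject_ids)

    locus_ids = [f"L{j + 1:04d}" for j in range(freqs.size)]
    dosages = pd.DataFrame(dosages_all[take], columns=locus_ids,
                           index=cohort.index)
    panel = RiskLociPanel(
        [RiskLocus(lid, "A", float(f)) for lid, f in zip(locus_ids, freqs)])

    truth = replace(config, risk_allele_freqs=tuple(freqs), pool_size=pool)
    extras = {
        "intercept": intercept,
        "pool_cases": n_cases_seen,
        "control_keep_probability": keep_q,
        "true_gre": truth.true_gre,
    }
    ds = SyntheticDataset(cohort=cohort, dosages=dosages, panel=panel,
                          truth=truth, truth_extras=extras)
    ds.validate()
    return ds


def _age_stratum(age: np.ndarray) -> np.ndarray:
    # decade bins with merged tails (<=49 and >=80) so sparse extremes
    # never starve the matched sampling
    return np.clip((age // 10).astype(int), 4, 8)


def _matched_controls(rng, data, take_cases, ctrl_idx, n_controls) -> np.ndarray:
    """Frequency-match controls to cases on age decade x sex.

    Per-stratum targets are the case proportions scaled to ``n_controls``
    (largest-remainder rounding); a stratum without enough retained
    controls raises :class:`SimulationError` naming the stratum.
    """
    strat_all = _age_stratum(data["age"]) * 2 + (data["sex"] == "male")
    case_strata = strat_all[take_cases]
    labels, counts = np.unique(case_strata, return_counts=True)
    raw = counts / counts.sum() * n_controls
    targets = np.floor(raw).astype(int)
    short = n_controls - targets.sum()
    if short > 0:
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        targets[order[:short]] += 1

    picked = []
    ctrl_strata = strat_all[ctrl_idx]
    for lab, want in zip(labels, targets):
        avail = ctrl_idx[ctrl_strata == lab]
        if avail.size < want:
            decade, male = divmod(int(lab), 2)
            raise SimulationError(
                f"matching stratum age {decade * 10}s/"
                f"{'male' if male else 'female'}: {avail.size} controls "
                f"retained, {want} required; increase pool_size")
        if want > 0:
            picked.append(rng.choice(avail, size=want, replace=False))
    return np.sort(np.concatenate(picked)) if picked else np.array([], dtype=int)
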