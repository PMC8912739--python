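"""Desk-scale orchestration of the full gene-environment study.

:func:`run_study` reproduces the structure of the study's result tables
on any cohort + dosage + panel triple: descriptive statistics, main
adjusted odds ratios with stepwise-AIC covariate selection, per-PRS-
stratum odds ratios with a trend term, the joint PRS x exposure odds-
ratio grid, outcome-(site/stage-)specific odds ratios with genetic risk
equivalents, and stratified (subgroup) GREs with interaction tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gre import GREResult, gre_from_model
from .prs import PRS_CATEGORIES, RiskLociPanel, attach_prs
from .regression import (
    ConvergenceError,
    FittedLogisticModel,
    ModelSpec,
    RankDeficiencyError,
    descriptive_table,
    fit_logistic,
    interaction_test,
    joint_effects,
    stepwise_aic,
)
from .synthetic import COVARIATE_REGISTRY, EXPOSURE_LEVELS

__all__ = ["StudyConfig", "SubgroupSpec", "StudyReport", "run_study",
           "subgroup_gre"]

log = logging.getLogger("polygre")

#: stratifier name -> (cohort column or derived column, level labels,
#: adjustment terms to remove inside the strata)
_STRATIFIERS = {
    "age55": ("age_gt55", {0: "age<=55", 1: "age>55"}, ()),
    "sex": ("sex", {"female": "female", "male": "male"}, ("sex",)),
    "family_history": ("family_history", {0: "no family history",
                                          1: "family history"},
                       ("family_history",)),
    "colonoscopy": ("colonoscopy", {0: "no colonoscopy", 1: "colonoscopy"},
                    ("colonoscopy",)),
}


@dataclass(frozen=True)
class StudyConfig:
    """Analysis-side knobs of the pipeline."""

    prs_reference: str = "controls"  # percentile reference population
    prs_coding: str = "per10"        # continuous-PRS coding in models
    forced_terms: tuple = ("age", "sex")  # the matching factors
    candidate_terms: Optional[tuple] = None  # None -> covariates present
    ci_level: float = 0.95
    interaction_method: str = "lrt"
    gre_method: str = "delta"
    subgroups: tuple = ("age55", "sex", "family_history", "colonoscopy")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SubgroupSpec:
    stratifier: str

    def __post_init__(self) -> None:
        if self.stratifier not in _STRATIFIERS:
            raise ValueError(
                f"unknown stratifier '{self.stratifier}'; choose from "
                f"{sorted(_STRATIFIERS)}")


@dataclass
class StudyReport:
    """Assembled analysis output: one attribute per report section."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    figure2: pd.DataFrame
    selected_terms: tuple
    provenance: dict
    models: dict = field(default_factory=dict, repr=False)

    def sections(self) -> dict:
        return {"table1": self.table1, "table2": self.table2,
                "table3": self.table3, "table4": self.table4,
                "table5": self.table5, "figure2": self.figure2}

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.sections().items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True,
                       default=str) + "\n")
        (out / "summary.txt").write_text(self.to_text())

    def to_text(self) -> str:
        lines = ["Study report", "============", ""]
        lines.append(f"selected covariates: {', '.join(self.selected_terms) or '(none)'}")
        lines.append(f"interaction p (continuous PRS): "
                     f"{self.provenance['interaction_p_continuous']:.3g}")
        lines.append(f"interaction p (categorical PRS): "
                     f"{self.provenance['interaction_p_categorical']:.3g}")
        lines.append("")
        for name, frame in self.sections().items():
            lines += [name, "-" * len(name), frame.to_string(index=False), ""]
        lines.append("No multiple-testing adjustment is applied across "
                     "subgroup analyses.")
        return "\n".join(lines) + "\n"


def _fmt_or(row) -> str:
    return f"{row['OR']:.2f} ({row['ci_low']:.2f}, {row['ci_high']:.2f})"


def _or_rows(model: FittedLogisticModel, ci_level: float) -> dict:
    return {r.contrast: r for r in model.exposure_ors(ci_level)}


def run_study(
    cohort: pd.DataFrame,
    dosages: pd.DataFrame,
    panel: RiskLociPanel,
    config: StudyConfig = StudyConfig(),
) -> StudyReport:
    """Execute the whole analysis plan and assemble a :class:`StudyReport`.

    Stages (in order): exclusion of missing-exposure rows; PRS build and
    percentile assignment; stepwise-AIC covariate selection; the main,
    PRS-stratified, joint and outcome-specific association tables; the
    subgroup GRE panel. Any stage failure aborts with a stage-named
    diagnostic.
    """
    n_input = len(cohort)
    data = cohort.dropna(subset=["exposure"]).copy()
    n_excluded = n_input - len(data)
    log.info("excluded %d rows with missing exposure", n_excluded)

    data = attach_prs(data, dosages, panel, reference=config.prs_reference)
    data["exposure_trend"] = data["exposure"].cat.codes.astype(float)
    data["age_gt55"] = (data["age"] > 55).astype(np.int64)

    if config.candidate_terms is None:
        candidates = tuple(c for c in COVARIATE_REGISTRY if c in data.columns)
    else:
        candidates = tuple(config.candidate_terms)

    provenance: dict = {
        "config_digest": config.digest(),
        "n_input": n_input,
        "n_excluded_missing_exposure": n_excluded,
        "n_cases": int((data["case"] == 1).sum()),
        "n_controls": int((data["case"] == 0).sum()),
        "model_rows": {},
    }

    def _stage(name):
        log.info("stage: %s", name)
        return name

    # -- covariate selection ------------------------------------------------
    stage = _stage("stepwise covariate selection")
    try:
        base = ModelSpec(exposure="exposure", adjust=config.forced_terms,
                         prs=config.prs_coding)
        sw = stepwise_aic(data, config.forced_terms, candidates, base_spec=base)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    selected = tuple(t for t in sw.spec.adjust if t not in config.forced_terms)
    full_adjust = config.forced_terms + selected

    # -- descriptive table --------------------------------------------------
    stage = _stage("descriptive table")
    table1 = descriptive_table(data.drop(columns=["exposure_trend",
                                                  "age_gt55"]))

    # -- main association table ---------------------------------------------
    stage = _stage("main association models")
    try:
        spec_agesex = ModelSpec(exposure="exposure",
                                adjust=config.forced_terms)
        m_agesex = fit_logistic(data, spec_agesex)
        spec_full = ModelSpec(exposure="exposure", adjust=full_adjust,
                              prs=config.prs_coding)
        m_full = fit_logistic(data, spec_full)
        it_cont = interaction_test(data, spec_full, ("exposure", "prs"),
                                   config.interaction_method)
        spec_cat = ModelSpec(exposure="exposure", adjust=full_adjust,
                             prs="category")
        it_cat = interaction_test(data, spec_cat, ("exposure", "prs"),
                                  config.interaction_method)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    provenance["model_rows"]["table2_full"] = {
        "n_used": m_full.n_used, "n_dropped": m_full.n_dropped}
    provenance["interaction_p_continuous"] = it_cont.p_value
    provenance["interaction_p_categorical"] = it_cat.p_value

    rows = []
    ors1, ors2 = _or_rows(m_agesex, config.ci_level), _or_rows(m_full, config.ci_level)
    for level in EXPOSURE_LEVELS:
        if level == EXPOSURE_LEVELS[0]:
            rows.append({"exposure": level,
                         "n_cases": ors2_n(data, level, 1),
                         "n_controls": ors2_n(data, level, 0),
                         "OR_age_sex": "Ref.", "OR_full": "Ref."})
            continue
        r1, r2 = ors1[level], ors2[level]
        rows.append({
            "exposure": level, "n_cases": r2.n_cases,
            "n_controls": r2.n_controls,
            "OR_age_sex": f"{r1.odds_ratio:.2f} ({r1.ci_low:.2f}, {r1.ci_high:.2f})",
            "OR_full": f"{r2.odds_ratio:.2f} ({r2.ci_low:.2f}, {r2.ci_high:.2f})",
        })
    table2 = pd.DataFrame(rows)
    table2["interaction_p_continuous"] = [it_cont.p_value] + [np.nan] * 3

    # -- per-PRS-stratum table ----------------------------------------------
    stage = _stage("PRS-stratified models")
    rows = []
    for cat in PRS_CATEGORIES:
        sub = data[data["prs_category"] == cat]
        spec_s = ModelSpec(exposure="exposure", adjust=full_adjust)
        trend_spec = ModelSpec(exposure=None,
                               adjust=("exposure_trend",) + full_adjust)
        try:
            m_s = fit_logistic(sub, spec_s)
            m_t = fit_logistic(sub, trend_spec)
            ors = _or_rows(m_s, config.ci_level)
            t = m_t.or_table(config.ci_level).loc["exposure_trend"]
            trend = f"{t['OR']:.2f} ({t['ci_low']:.2f}, {t['ci_high']:.2f})"
            note = ""
        except (ConvergenceError, RankDeficiencyError, ValueError) as exc:
            ors, trend, note = {}, "", f"model failed: {exc}"
            warnings.warn(f"PRS stratum '{cat}': {exc}")
        for level in EXPOSURE_LEVELS:
            n_ca = int(((sub["exposure"] == level) & (sub["case"] == 1)).sum())
            n_co = int(((sub["exposure"] == level) & (sub["case"] == 0)).sum())
            if level == EXPOSURE_LEVELS[0]:
                disp = "Ref."
            elif level in ors:
                r = ors[level]
                disp = f"{r.odds_ratio:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})"
            else:
                disp = ""
            rows.append({"prs_category": cat, "exposure": level,
                         "n_cases": n_ca, "n_controls": n_co, "OR": disp,
                         "OR_per_category_increase":
                             trend if level == EXPOSURE_LEVELS[0] else "",
                         "note": note})
    table3 = pd.DataFrame(rows)
    table3["interaction_p_categorical"] = (
        [it_cat.p_value] + [np.nan] * (len(table3) - 1))

    # -- joint-effects grid ---------------------------------------------------
    stage = _stage("joint effects")
    try:
        table4 = joint_effects(data, adjust=full_adjust,
                               ci_level=config.ci_level)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # -- outcome-specific ORs and GREs ---------------------------------------
    stage = _stage("site/stage-specific models and GREs")
    site = data["site"]
    stage_col = data["stage"]
    outcomes = {
        "all": data["case"] == 1,
        "colon": site.isin(["proximal_colon", "distal_colon"]),
        "proximal_colon": site == "proximal_colon",
        "distal_colon": site == "distal_colon",
        "rectum": site == "rectum",
        "stages_I-III": stage_col == "I-III",
        "stage_IV": stage_col == "IV",
    }
    rows = []
    is_control = data["case"] == 0
    for name, case_mask in outcomes.items():
        sub = data[is_control | case_mask]
        try:
            m = fit_logistic(sub, ModelSpec(exposure="exposure",
                                            adjust=full_adjust,
                                            prs=config.prs_coding))
            ors = _or_rows(m, config.ci_level)
            gres = {g.contrast: g for g in gre_from_model(
                m, method=config.gre_method, level=config.ci_level)}
        except (ConvergenceError, RankDeficiencyError, ValueError) as exc:
            raise RuntimeError(
                f"stage '{stage}' failed for outcome '{name}': {exc}") from exc
        provenance["model_rows"][f"table5_{name}"] = {
            "n_used": m.n_used, "n_dropped": m.n_dropped}
        for level in EXPOSURE_LEVELS:
            n_ca = int(((sub["exposure"] == level) & (sub["case"] == 1)).sum())
            n_co = int(((sub["exposure"] == level) & (sub["case"] == 0)).sum())
            if level == EXPOSURE_LEVELS[0]:
                rows.append({"outcome": name, "exposure": level,
                             "n_cases": n_ca, "n_controls": n_co,
                             "OR": "Ref.", "GRE": "Ref.",
                             "gre_value": np.nan, "gre_ci_low": np.nan,
                             "gre_ci_high": np.nan})
                continue
            r, g = ors[level], gres[level]
            rows.append({
                "outcome": name, "exposure": level, "n_cases": n_ca,
                "n_controls": n_co,
                "OR": f"{r.odds_ratio:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})",
                "GRE": f"{g.gre:.1f} ({g.ci_low:.1f}, {g.ci_high:.1f})",
                "gre_value": g.gre, "gre_ci_low": g.ci_low,
                "gre_ci_high": g.ci_high})
    table5 = pd.DataFrame(rows)

    # -- subgroup GREs --------------------------------------------------------
    stage = _stage("subgroup GREs")
    fig_rows = []
    for strat in config.subgroups:
        res = subgroup_gre(data, config, SubgroupSpec(strat),
                           adjust=full_adjust)
        for stratum, gre_list in res["strata"].items():
            if isinstance(gre_list, str):
                fig_rows.append({"stratifier": strat, "stratum": stratum,
                                 "exposure": "", "gre": np.nan,
                                 "ci_low": np.nan, "ci_high": np.nan,
                                 "interaction_p": res["interaction_p"],
                                 "note": gre_list})
                continue
            for g in gre_list:
                fig_rows.append({"stratifier": strat, "stratum": stratum,
                                 "exposure": g.contrast, "gre": g.gre,
                                 "ci_low": g.ci_low, "ci_high": g.ci_high,
                                 "interaction_p": res["interaction_p"],
                                 "note": ""})
    figure2 = pd.DataFrame(fig_rows)

    return StudyReport(
        table1=table1, table2=table2, table3=table3, table4=table4,
        table5=table5, figure2=figure2, selected_terms=selected,
        provenance=provenance,
        models={"age_sex": m_agesex, "full": m_full, "stepwise": sw})


def ors2_n(data: pd.DataFrame, level: str, case: int) -> int:
    return int(((data["exposure"] == level) & (data["case"] == case)).sum())


def subgroup_gre(
    data: pd.DataFrame,
    config: StudyConfig,
    spec: SubgroupSpec,
    adjust: Optional[Sequence[str]] = None,
) -> dict:
    """Per-stratum GREs plus a pooled product-term interaction test.

    The stratum models use the study covariate set minus the stratifier
    itself and the PRS as a continuous (per-10-percentile) covariate; the
    interaction p comes from a pooled model with stratifier x exposure
    product terms. A stratum in which some exposure level is unobserved
    is flagged and its GREs are omitted.
    """
    col, labels, drop = _STRATIFIERS[spec.stratifier]
    if adjust is None:
        adjust = config.forced_terms
    if col == "age_gt55" and "age_gt55" not in data.columns:
        data = data.copy()
        data["age_gt55"] = (data["age"] > 55).astype(np.int64)

    strat_adjust = tuple(t for t in adjust if t not in drop)
    out: dict = {"stratifier": spec.stratifier, "strata": {}, "notes": []}

    observed = [v for v in labels if (data[col] == v).any()]
    if len(observed) < 2:
        warnings.warn(
            f"stratifier '{spec.stratifier}' has a single observed stratum; "
            "returning pooled results")
        observed_vals = observed or list(labels)
        m = fit_logistic(data, ModelSpec(exposure="exposure",
                                         adjust=strat_adjust,
                                         prs=config.prs_coding))
        out["strata"]["pooled"] = gre_from_model(m, method=config.gre_method,
                                                 level=config.ci_level)
        out["interaction_p"] = np.nan
        return out

    for value in observed:
        label = labels[value]
        sub = data[data[col] == value]
        present = set(sub["exposure"].dropna().unique())
        missing_levels = [l for l in EXPOSURE_LEVELS if l not in present]
        if missing_levels:
            out["strata"][label] = (
                f"exposure level(s) {missing_levels} unobserved; GRE omitted")
            continue
        try:
            m = fit_logistic(sub, ModelSpec(exposure="exposure",
                                            adjust=strat_adjust,
                                            prs=config.prs_coding))
            out["strata"][label] = gre_from_model(
                m, method=config.gre_method, level=config.ci_level)
        except (ConvergenceError, RankDeficiencyError, ValueError) as exc:
            out["strata"][label] = f"model failed: {exc}"

    pooled_adjust = strat_adjust + (col,) if col not in strat_adjust else strat_adjust
    pooled_spec = ModelSpec(exposure="exposure", adjust=pooled_adjust,
                            prs=config.prs_coding)
    it = interaction_test(data, pooled_spec, ("exposure", col),
                          config.interaction_method)
    out["interaction_p"] = it.p_value
    return out
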