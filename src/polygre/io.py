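"""Plain-text readers/writers for cohort, dosage, panel and config files.

All tabular files are tab-delimited with a header row; the dosage matrix
carries subject ids in its first column. Simulation configs round-trip
through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .prs import PRS_CATEGORIES, RiskLociPanel
from .synthetic import (
    COVARIATE_REGISTRY,
    EXPOSURE_LEVELS,
    SITE_LEVELS,
    STAGE_LEVELS,
    SimulationConfig,
)

__all__ = [
    "write_cohort", "read_cohort",
    "write_dosages", "read_dosages",
    "write_panel", "read_panel",
    "write_config", "read_config",
]

PathLike = Union[str, Path]

_CATEGORICALS: dict[str, tuple[list, bool]] = {
    "exposure": (EXPOSURE_LEVELS, True),
    "sex": (["female", "male"], False),
    "site": (SITE_LEVELS, False),
    "stage": (STAGE_LEVELS, False),
    "prs_category": (PRS_CATEGORIES, True),
}
for _name, _c in COVARIATE_REGISTRY.items():
    if len(_c.levels) > 2:
        _CATEGORICALS[_name] = ([str(l) for l in _c.levels], True)


def write_cohort(cohort: pd.DataFrame, path: PathLike) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    for col, (levels, ordered) in _CATEGORICALS.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=levels,
                                     ordered=ordered)
    if "subject_id" in df.columns:
        df.index = pd.Index(df["subject_id"], name="subject_id")
    return df


def write_dosages(dosages: pd.DataFrame, path: PathLike) -> None:
    dosages.to_csv(path, sep="\t", index=True, index_label="subject_id")


def read_dosages(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return df.set_index("subject_id")


def write_panel(panel: RiskLociPanel, path: PathLike) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_panel(path: PathLike) -> RiskLociPanel:
    return RiskLociPanel.from_frame(pd.read_csv(path, sep="\t"))


def _plain(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, (tuple, list, np.ndarray)):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    return value


def write_config(config: SimulationConfig, path: PathLike) -> None:
    data = {k: _plain(v) for k, v in dataclasses.asdict(config).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_config(path: PathLike) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("beta_exposure", "exposure_control_prevalences",
                "age_range", "risk_allele_freqs"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    if data.get("covariate_effects"):
        data["covariate_effects"] = {
            k: tuple(np.atleast_1d(v).tolist())
            for k, v in data["covariate_effects"].items()}
    return SimulationConfig(**data)
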