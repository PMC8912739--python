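"""Polygenic risk score construction and percentile stratification.

The score is the (optionally weighted) sum of risk-allele dosages over a
panel of independent risk loci. Scores are converted to percentiles with
respect to a reference population — by default the study controls, who
approximate the source population in a case-control design — and then to
the five conventional risk strata used for stratified reporting:

    very_low  : <= 10th percentile
    low       : 11th-25th
    medium    : 26th-75th
    high      : 76th-90th
    very_high : > 90th
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PRS_CATEGORIES",
    "CATEGORY_CUTS",
    "RiskLocus",
    "RiskLociPanel",
    "PanelMismatchError",
    "compute_prs",
    "percentile_of_scores",
    "categorize_percentiles",
    "assign_percentiles",
    "attach_prs",
]

PRS_CATEGORIES = ["very_low", "low", "medium", "high", "very_high"]

#: upper percentile bound of each category, in order
CATEGORY_CUTS = (10.0, 25.0, 75.0, 90.0, 100.0)


class PanelMismatchError(ValueError):
    """Dosage matrix and risk-loci panel do not describe the same loci."""


@dataclass(frozen=True)
class RiskLocus:
    locus_id: str
    risk_allele: str = "A"
    frequency: float = float("nan")
    weight: float = 1.0


@dataclass
class RiskLociPanel:
    """A panel of risk loci with risk-allele orientation and weights.

    Weights default to 1 (an unweighted allele count), the convention for
    a pure risk-allele-sum score.
    """

    loci: list[RiskLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus ids in panel: {dupes}")
        for l in self.loci:
            if l.weight < 0:
                raise ValueError(f"negative weight for locus {l.locus_id}")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def weights(self) -> np.ndarray:
        return np.array([l.weight for l in self.loci], dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([l.frequency for l in self.loci], dtype=float)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RiskLociPanel":
        loci = [
            RiskLocus(
                locus_id=str(row["locus_id"]),
                risk_allele=str(row.get("risk_allele", "A")),
                frequency=float(row.get("frequency", float("nan"))),
                weight=float(row.get("weight", 1.0)),
            )
            for _, row in frame.iterrows()
        ]
        return cls(loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "risk_allele": [l.risk_allele for l in self.loci],
                "frequency": self.frequencies,
                "weight": self.weights,
            }
        )


def compute_prs(dosages: pd.DataFrame, panel: RiskLociPanel) -> pd.Series:
    """Per-subject weighted sum of risk-allele dosages.

    ``dosages`` is a subjects x loci frame with locus ids as columns and
    entries in [0, 2]. Loci in the matrix that are absent from the panel
    are ignored; panel loci missing from the matrix raise
    :class:`PanelMismatchError` listing the offending ids.
    """
    missing = [i for i in panel.locus_ids if i not in dosages.columns]
    if missing:
        raise PanelMismatchError(
            f"{len(missing)} panel loci absent from dosage matrix: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    sub = dosages[panel.locus_ids].to_numpy(dtype=float)
    if sub.size and (np.nanmin(sub) < -1e-9 or np.nanmax(sub) > 2 + 1e-9):
        raise ValueError("dosages must lie in [0, 2]")
    score = sub @ panel.weights
    return pd.Series(score, index=dosages.index, name="prs_score")


def percentile_of_scores(
    scores: Union[pd.Series, np.ndarray, Sequence[float]],
    reference: Union[str, pd.Series, np.ndarray, Sequence[float]] = "self",
) -> np.ndarray:
    """Mean-rank percentile of each score within a reference distribution.

    For a score tied with ``ce`` reference values and exceeding ``cl`` of
    them, the percentile is ``100 * (cl + (ce + 1) / 2) / n_ref`` — the
    mean rank the score would take inside the reference, divided by the
    reference size. On the reference itself this reduces to the classical
    mean-rank percentile (a vector 1..100 scores percentiles 1..100).
    """
    s = np.asarray(scores, dtype=float)
    if isinstance(reference, str):
        if reference != "self":
            raise ValueError("reference must be 'self' or an array of scores")
        ref = s
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference population")
    ref_sorted = np.sort(ref)
    count_less = np.searchsorted(ref_sorted, s, side="left")
    count_le = np.searchsorted(ref_sorted, s, side="right")
    mean_rank = count_less + (count_le - count_less + 1) / 2.0
    # scores beyond the reference maximum would exceed rank n_ref; cap so
    # percentiles stay in (0, 100]
    return np.minimum(100.0 * mean_rank / ref.size, 100.0)


def categorize_percentiles(percentiles: np.ndarray) -> pd.Categorical:
    """Map percentiles to the five ordered risk strata."""
    p = np.asarray(percentiles, dtype=float)
    if p.size and (np.nanmin(p) <= 0 or np.nanmax(p) > 100 + 1e-9):
        raise ValueError("percentiles must lie in (0, 100]")
    idx = np.searchsorted(np.array(CATEGORY_CUTS[:-1]), p, side="left")
    codes = np.clip(idx, 0, 4)
    return pd.Categorical.from_codes(codes, categories=PRS_CATEGORIES, ordered=True)


def assign_percentiles(
    scores: Union[pd.Series, Sequence[float]],
    reference: Union[str, Sequence[float]] = "self",
) -> pd.DataFrame:
    """Score, percentile and risk category per subject.

    Returns a frame with columns ``prs_score``, ``prs_percentile`` and
    ``prs_category`` (ordered categorical).
    """
    index = scores.index if isinstance(scores, pd.Series) else None
    pct = percentile_of_scores(scores, reference)
    return pd.DataFrame(
        {
            "prs_score": np.asarray(scores, dtype=float),
            "prs_percentile": pct,
            "prs_category": categorize_percentiles(pct),
        },
        index=index,
    )


def attach_prs(
    cohort: pd.DataFrame,
    dosages: pd.DataFrame,
    panel: RiskLociPanel,
    reference: str = "controls",
    case_col: str = "case",
) -> pd.DataFrame:
    """Append PRS score/percentile/category columns to a cohort table.

    ``reference`` selects the percentile reference population: ``"controls"``
    ranks everyone against the controls, ``"all"`` against the pooled
    sample.
    """
    aligned = dosages.reindex(cohort.index)
    if aligned.isna().all(axis=1).any():
        missing = aligned.index[aligned.isna().all(axis=1)][:5].tolist()
        raise PanelMismatchError(f"no dosage rows for subjects {missing}")
    scores = compute_prs(aligned, panel)
    if reference == "controls":
        ref = scores[cohort[case_col] == 0].to_numpy()
        if ref.size == 0:
            raise ValueError("no controls available as percentile reference")
    elif reference == "all":
        ref = scores.to_numpy()
    else:
        raise ValueError("reference must be 'controls' or 'all'")
    out = cohort.copy()
    out[["prs_score", "prs_percentile", "prs_category"]] = assign_percentiles(
        scores, ref
    )
    return out
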