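"""The peri-operative prognosis predictive score (PPSP).

The score counts how many of 8 peri-operative parameters are abnormal:
four pre-treatment (age, CA125, CRP, d-dimer), three post-surgery (white
blood cell count, CRP, albumin) and the white-blood-cell difference
(post-surgery minus pre-treatment). Each abnormal parameter contributes 1,
so the score ranges 0-8; patients with score >= 6 form the high-risk class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roc as _roc
from .roc import HIGH, LOW

logger = logging.getLogger(__name__)

#: markers a score component may reference; ``wbc_diff`` is derived
#: from ``wbc_post`` and ``wbc_pre`` at scoring time.
KNOWN_MARKERS = frozenset({
    "age", "ca125_pre", "crp_pre", "ddimer_pre",
    "wbc_post", "crp_post", "albumin_post", "wbc_diff",
})


@dataclass(frozen=True)
class ScoreComponent:
    """One dichotomised parameter: abnormal means value >= cutoff
    (high-abnormal) or value < cutoff (low-abnormal)."""

    marker: str
    cutoff: float
    direction: str = HIGH

    def __post_init__(self) -> None:
        if self.marker not in KNOWN_MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if self.direction not in (HIGH, LOW):
            raise ValueError("direction must be high-abnormal or low-abnormal")

    def is_abnormal(self, value: float) -> bool | None:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if self.direction == HIGH:
            return bool(value >= self.cutoff)
        return bool(value < self.cutoff)


@dataclass(frozen=True)
class ScoreDefinition:
    components: tuple[ScoreComponent, ...]
    score_cutoff: int = 6

    def __post_init__(self) -> None:
        markers = [c.marker for c in self.components]
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate marker in score definition")
        if not (0 <= self.score_cutoff <= len(self.components)):
            raise ValueError("score cutoff outside the score range")

    @property
    def max_score(self) -> int:
        return len(self.components)

    def to_json(self) -> str:
        return json.dumps(
            {
                "components": [
                    {"marker": c.marker, "cutoff": c.cutoff, "direction": c.direction}
                    for c in self.components
                ],
                "score_cutoff": self.score_cutoff,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreDefinition":
        obj = json.loads(text)
        comps = tuple(
            ScoreComponent(c["marker"], float(c["cutoff"]), c.get("direction", HIGH))
            for c in obj["components"]
        )
        return cls(components=comps, score_cutoff=int(obj["score_cutoff"]))


def paper_score_definition() -> ScoreDefinition:
    """The published 8-component definition with score cutoff 6.

    Abnormal means: age >= 55 y; CA125 >= 124.5 U/mL; pre-treatment CRP
    >= 0.26 mg/dL; d-dimer >= 1.1 ug/mL; post-surgery WBC >= 57.00 x10^2/uL;
    post-surgery CRP >= 0.08 mg/dL; post-surgery albumin < 4.0 g/dL;
    WBC difference (post - pre) >= -29.00 x10^2/uL.
    """
    return ScoreDefinition(
        components=(
            ScoreComponent("age", 55.0, HIGH),
            ScoreComponent("ca125_pre", 124.5, HIGH),
            ScoreComponent("crp_pre", 0.26, HIGH),
            ScoreComponent("ddimer_pre", 1.1, HIGH),
            ScoreComponent("wbc_post", 57.00, HIGH),
            ScoreComponent("crp_post", 0.08, HIGH),
            ScoreComponent("albumin_post", 4.0, LOW),
            ScoreComponent("wbc_diff", -29.00, HIGH),
        ),
        score_cutoff=6,
    )


def wbc_difference(record) -> float:
    """Post-surgery minus pre-treatment white blood cell count (x10^2/uL).

    Returns NaN if either count is missing.
    """
    pre = record.get("wbc_pre") if hasattr(record, "get") else getattr(record, "wbc_pre")
    post = record.get("wbc_post") if hasattr(record, "get") else getattr(record, "wbc_post")
    if pre is None or post is None:
        return float("nan")
    pre, post = float(pre), float(post)
    if np.isnan(pre) or np.isnan(post):
        return float("nan")
    return post - pre


def _component_value(record, marker: str):
    if marker == "wbc_diff":
        return wbc_difference(record)
    if hasattr(record, "get"):
        v = record.get(marker)
    else:
        v = getattr(record, marker)
    return float("nan") if v is None else float(v)


def compute_ppsp(record, definition: ScoreDefinition | None = None,
                 partial: bool = False) -> float:
    """Score one patient record (mapping or object with marker attributes).

    By default a record missing any component is scored NaN (complete-case).
    With ``partial=True`` the score is computed over the available components
    and rescaled to the 0-max range (sensitivity analysis only).
    """
    definition = definition or paper_score_definition()
    flags = [c.is_abnormal(_component_value(record, c.marker)) for c in definition.components]
    n_missing = sum(f is None for f in flags)
    if n_missing:
        if not partial:
            return float("nan")
        available = [f for f in flags if f is not None]
        if not available:
            return float("nan")
        return sum(available) * definition.max_score / len(available)
    return float(sum(flags))


def classify_ppsp(score: float, definition: ScoreDefinition | None = None) -> str:
    """'high' iff score >= the definition's cutoff, else 'low'."""
    definition = definition or paper_score_definition()
    if isinstance(score, float) and np.isnan(score):
        raise ValueError("cannot classify a missing score")
    if not (0 <= score <= definition.max_score):
        raise ValueError(f"score {score} outside [0, {definition.max_score}]")
    return "high" if score >= definition.score_cutoff else "low"


def score_cohort(cohort: pd.DataFrame, definition: ScoreDefinition | None = None,
                 partial: bool = False) -> pd.DataFrame:
    """Append ``ppsp_score`` and ``ppsp_class`` columns to a cohort table.

    Rows with incomplete components get NaN score and empty class; the
    number of complete-case exclusions is logged.
    """
    definition = definition or paper_score_definition()
    scores = cohort.apply(lambda r: compute_ppsp(r, definition, partial=partial), axis=1)
    out = cohort.copy()
    out["ppsp_score"] = scores
    out["ppsp_class"] = [
        "" if np.isnan(s) else classify_ppsp(s, definition) for s in scores
    ]
    n_excluded = int(scores.isna().sum())
    if n_excluded:
        logger.info("PPSP complete-case scoring excluded %d of %d patients",
                    n_excluded, len(cohort))
    return out


def derive_score_cutoff(scores, outcomes) -> int:
    """Youden-optimal integer threshold for the score against a binary outcome.

    Applies the same ROC/Youden machinery used for the individual markers.
    Degenerate input (all scores equal) returns that score with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if np.unique(s).size == 1:
        warnings.warn("all scores identical; Youden index is 0 at every threshold")
        return int(s[0])
    curve = _roc.compute_roc(s, y, direction=HIGH)
    cutoff, _, _ = _roc.youden_cutoff(curve)
    return int(round(cutoff))
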