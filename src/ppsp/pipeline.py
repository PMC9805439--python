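"""End-to-end study pipeline on a patient-level cohort table.

Stages: per-marker Youden cutoffs on the recurrence outcome, composite
score construction, score-threshold selection, univariate odds ratios for
every dichotomised factor, multivariable logistic models for recurrence
and mortality, and Cox / Kaplan-Meier / log-rank analyses by score class
overall and within early (I/II) vs advanced (III/IV) FIGO strata.

All randomness lives in the cohort generator; given a cohort and a config
the pipeline is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import published, roc, scoring, stats
from .roc import HIGH, LOW
from .scoring import ScoreComponent, ScoreDefinition

logger = logging.getLogger(__name__)

#: abnormal side per score component (albumin is low-abnormal)
DIRECTIONS = {
    "age": HIGH, "ca125_pre": HIGH, "crp_pre": HIGH, "ddimer_pre": HIGH,
    "wbc_post": HIGH, "crp_post": HIGH, "albumin_post": LOW, "wbc_diff": HIGH,
}

DEFAULT_COVARIATES = ("figo_advanced", "wbc_diff", "ppsp_high")


class PipelineError(RuntimeError):
    """A stage's precondition failed; carries the stage name and detail."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {detail}")


@dataclass
class PipelineConfig:
    outcome: str = "recurrence"
    use_paper_cutoffs: bool = True
    fixed_score_cutoff: int | None = 6  # None -> derive by Youden on the score
    covariates: tuple = DEFAULT_COVARIATES
    markers: tuple = tuple(DIRECTIONS)

    def validate(self, cohort: pd.DataFrame) -> None:
        if self.outcome not in ("recurrence", "death"):
            raise ValueError("outcome must be 'recurrence' or 'death'")
        unknown = set(self.markers) - set(DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown markers {sorted(unknown)}")
        needed = {"recurrence", "death", "pfs_time", "os_time", "figo_stage"}
        missing = needed - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort lacks columns {sorted(missing)}")


@dataclass
class StudyReport:
    n_patients: int
    cutoffs: dict                    # marker -> CutoffReport
    definition: ScoreDefinition
    score_cutoff: int
    score_distribution: dict         # score value -> count
    univariate: dict                 # outcome -> {factor -> EffectEstimate}
    multivariate: dict               # outcome -> {factor -> EffectEstimate}
    cox: dict                        # endpoint -> {factor -> EffectEstimate}
    km: dict                         # stratum -> {class -> SurvivalCurve}
    log_rank: dict                   # stratum+endpoint -> TestResult
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, (stats.EffectEstimate, stats.TestResult)):
                return dataclasses.asdict(obj)
            if isinstance(obj, roc.CutoffReport):
                return obj.to_dict()
            if isinstance(obj, stats.SurvivalCurve):
                return {
                    "event_times": obj.event_times.tolist(),
                    "survival": obj.survival.tolist(),
                    "at_risk": obj.at_risk.tolist(),
                }
            if isinstance(obj, ScoreDefinition):
                return json.loads(obj.to_json())
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.bool_):
                return bool(obj)
            raise TypeError(f"cannot serialise {type(obj)}")

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


def marker_values(cohort: pd.DataFrame, marker: str) -> pd.Series:
    """Column for a component marker; ``wbc_diff`` is computed on the fly."""
    if marker == "wbc_diff":
        return cohort["wbc_post"] - cohort["wbc_pre"]
    return cohort[marker]


def _abnormal_indicator(cohort: pd.DataFrame, component: ScoreComponent) -> pd.Series:
    v = marker_values(cohort, component.marker)
    if component.direction == HIGH:
        ind = v >= component.cutoff
    else:
        ind = v < component.cutoff
    return ind.where(v.notna())  # NaN propagates


def derive_cutoffs(cohort: pd.DataFrame, outcome: str = "recurrence",
                   markers=tuple(DIRECTIONS)) -> dict:
    """Per-marker Youden-optimal cutoff reports against a binary outcome."""
    y_all = cohort[outcome].astype(int)
    out = {}
    for marker in markers:
        v = marker_values(cohort, marker)
        keep = v.notna()
        if keep.sum() == 0 or y_all[keep].nunique() < 2:
            raise PipelineError("derive_cutoffs", f"no usable data for column {marker!r}")
        out[marker] = roc.cutoff_report(
            marker, v[keep].to_numpy(), y_all[keep].to_numpy(), DIRECTIONS[marker]
        )
    return out


def _univariate_block(cohort: pd.DataFrame, definition: ScoreDefinition,
                      outcome: str, warn: list) -> dict:
    y = cohort[outcome].astype(int)
    factors: dict[str, pd.Series] = {
        c.marker: _abnormal_indicator(cohort, c) for c in definition.components
    }
    factors["figo_advanced"] = (cohort["figo_stage"] >= 3).astype(float)
    if "ppsp_score" in cohort:
        factors["ppsp_high"] = (
            (cohort["ppsp_score"] >= definition.score_cutoff)
            .where(cohort["ppsp_score"].notna())
        )
    block = {}
    for name, ind in factors.items():
        keep = ind.notna()
        a = int(((ind == 1) & (y == 1) & keep).sum())
        b = int(((ind == 1) & (y == 0) & keep).sum())
        c = int(((ind == 0) & (y == 1) & keep).sum())
        d = int(((ind == 0) & (y == 0) & keep).sum())
        try:
            block[name] = stats.odds_ratio_2x2(stats.ContingencyTable(a, b, c, d))
        except ValueError:
            warn.append(f"zero cell for factor {name!r} ({outcome}); Haldane correction applied")
            block[name] = stats.odds_ratio_2x2(
                stats.ContingencyTable(a, b, c, d), haldane=True
            )
    return block


def _design_matrix(cohort: pd.DataFrame, definition: ScoreDefinition, covariates):
    cols = {}
    for name in covariates:
        if name == "figo_advanced":
            cols[name] = (cohort["figo_stage"] >= 3).astype(float)
        elif name == "ppsp_high":
            cols[name] = (
                (cohort["ppsp_score"] >= definition.score_cutoff)
                .where(cohort["ppsp_score"].notna())
                .astype(float)
            )
        else:
            comp = next(c for c in definition.components if c.marker == name)
            cols[name] = _abnormal_indicator(cohort, comp).astype(float)
    X = pd.DataFrame(cols)
    keep = X.notna().all(axis=1)
    return X[keep].to_numpy(dtype=float), keep


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig | None = None) -> StudyReport:
    """Run the full study on a cohort table and assemble a report."""
    config = config or PipelineConfig()
    if len(cohort) == 0:
        raise PipelineError("derive_cutoffs", "empty cohort")
    config.validate(cohort)
    warn: list[str] = []

    # stage 1: per-marker cutoffs
    cutoffs = derive_cutoffs(cohort, config.outcome, config.markers)
    logger.info("stage 1: cutoffs derived for %d markers on n=%d", len(cutoffs), len(cohort))

    # stage 2: score definition and scoring
    if config.use_paper_cutoffs:
        definition = scoring.paper_score_definition()
    else:
        definition = ScoreDefinition(
            components=tuple(
                ScoreComponent(m, cutoffs[m].cutoff, DIRECTIONS[m]) for m in config.markers
            ),
            score_cutoff=config.fixed_score_cutoff or 6,
        )
    scored = scoring.score_cohort(cohort, definition)
    n_scored = int(scored["ppsp_score"].notna().sum())
    logger.info("stage 2: scored %d/%d patients (complete cases)", n_scored, len(cohort))

    # stage 3: score threshold
    if config.fixed_score_cutoff is not None:
        score_cutoff = int(config.fixed_score_cutoff)
    else:
        keep = scored["ppsp_score"].notna()
        score_cutoff = scoring.derive_score_cutoff(
            scored.loc[keep, "ppsp_score"], scored.loc[keep, config.outcome].astype(int)
        )
    definition = ScoreDefinition(components=definition.components, score_cutoff=score_cutoff)
    scored["ppsp_class"] = [
        "" if np.isnan(s) else scoring.classify_ppsp(s, definition)
        for s in scored["ppsp_score"]
    ]
    dist = (
        scored["ppsp_score"].dropna().astype(int).value_counts().sort_index().to_dict()
    )

    # stage 4: univariate odds ratios, both outcomes
    univariate = {
        oc: _univariate_block(scored, definition, oc, warn)
        for oc in ("recurrence", "death")
    }

    # stage 5: multivariable logistic models
    multivariate = {}
    for oc in ("recurrence", "death"):
        X, keep = _design_matrix(scored, definition, config.covariates)
        y = scored.loc[keep, oc].astype(int).to_numpy()
        try:
            fit = stats.fit_logistic(y, X, names=list(config.covariates))
            multivariate[oc] = fit.estimates
        except (stats.ConvergenceError, ValueError) as exc:
            warn.append(f"multivariable logistic ({oc}) failed: {exc}")
            multivariate[oc] = {}

    # stage 6: Cox, KM, log-rank by score class and FIGO stratum
    cox = {}
    for endpoint, (tcol, ecol) in (
        ("pfs", ("pfs_time", "recurrence")),
        ("os", ("os_time", "death")),
    ):
        X, keep = _design_matrix(scored, definition, config.covariates)
        try:
            fit = stats.fit_cox(
                scored.loc[keep, tcol].to_numpy(),
                scored.loc[keep, ecol].astype(int).to_numpy(),
                X, names=list(config.covariates),
            )
            cox[endpoint] = fit.estimates
        except (stats.ConvergenceError, ValueError) as exc:
            warn.append(f"Cox model ({endpoint}) failed: {exc}")
            cox[endpoint] = {}

    km: dict = {}
    lr: dict = {}
    strata = {
        "all": scored["ppsp_class"] != "",
        "figo_early": (scored["ppsp_class"] != "") & (scored["figo_stage"] <= 2),
        "figo_advanced": (scored["ppsp_class"] != "") & (scored["figo_stage"] >= 3),
    }
    for sname, mask in strata.items():
        sub = scored[mask]
        for endpoint, (tcol, ecol) in (
            ("pfs", ("pfs_time", "recurrence")),
            ("os", ("os_time", "death")),
        ):
            groups = []
            curves = {}
            for cls in ("low", "high"):
                g = sub[sub["ppsp_class"] == cls]
                if len(g) == 0:
                    continue
                t = g[tcol].to_numpy()
                e = g[ecol].astype(int).to_numpy()
                curves[cls] = stats.kaplan_meier(t, e)
                groups.append((t, e))
                if e.sum() < 5:
                    warn.append(
                        f"low event count ({int(e.sum())}) in {sname}/{endpoint}/{cls}; "
                        "interpret with caution"
                    )
            km[f"{sname}_{endpoint}"] = curves
            if len(groups) == 2 and sum(int(e.sum()) for _, e in groups) > 0:
                lr[f"{sname}_{endpoint}"] = stats.log_rank(groups)
            else:
                warn.append(f"log-rank skipped for {sname}/{endpoint}: need two classes with events")

    for w in warn:
        warnings.warn(w)
    return StudyReport(
        n_patients=len(cohort),
        cutoffs=cutoffs,
        definition=definition,
        score_cutoff=score_cutoff,
        score_distribution=dist,
        univariate=univariate,
        multivariate=multivariate,
        cox=cox,
        km=km,
        log_rank=lr,
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# reproduction of the printed study numbers
# ---------------------------------------------------------------------------

def reproduce_targets(tolerance: float = 0.01) -> pd.DataFrame:
    """Recompute every printed number that follows from in-study integer counts.

    Each row compares a quantity recomputed by this package from published
    counts/rates against the printed value, at the stated absolute tolerance
    on the printed scale (the recurrence percentage is printed to one
    decimal, so its tolerance is 0.05).
    """
    rows = []

    def add(name, computed, printed, tol=tolerance):
        rows.append({
            "quantity": name, "computed": computed, "printed": printed,
            "abs_diff": abs(computed - printed), "tolerance": tol,
            "ok": abs(computed - printed) <= tol,
        })

    figo = stats.odds_ratio_2x2(stats.ContingencyTable(*published.figo_recurrence_table()))
    printed_or = published.UNIVARIATE_RECURRENCE["figo_advanced"]
    add("figo_or", figo.point, printed_or[0])
    add("figo_or_ci_low", figo.ci_low, printed_or[1])
    add("figo_or_ci_high", figo.ci_high, printed_or[2])

    for marker, key in (("age", "age"), ("crp_pre", "crp_pre")):
        _, _, _, sens, spec, ppv, npv = published.CUTOFF_TABLE[marker]
        table = roc.reconstruct_2x2(
            sens, spec, published.N_RECURRENT, published.N_NON_RECURRENT
        )
        got_ppv, got_npv = roc.predictive_values(
            sens, spec, published.N_RECURRENT, published.N_NON_RECURRENT
        )
        add(f"{key}_ppv", got_ppv, ppv)
        add(f"{key}_npv", got_npv, npv)
        est = stats.odds_ratio_2x2(table)
        p_or = published.UNIVARIATE_RECURRENCE[key]
        add(f"{key}_or", est.point, p_or[0])
        add(f"{key}_or_ci_low", est.ci_low, p_or[1])
        add(f"{key}_or_ci_high", est.ci_high, p_or[2])

    add(
        "recurrence_pct",
        100.0 * published.N_RECURRENT / published.N_TOTAL,
        published.RECURRENCE_PCT,
        tol=0.05,
    )

    parity = stats.pearson_chi_square(np.array(published.PARITY_TABLE))
    add("parity_chi_square_p", parity.p_value, published.PARITY_P, tol=0.001)

    return pd.DataFrame(rows)
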