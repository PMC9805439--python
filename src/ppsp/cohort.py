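"""Seeded synthetic ovarian-cancer cohorts around primary debulking surgery.

The generator emulates the structure of a retrospective surgical cohort:
a recurrence fraction near 29%, group-wise marker distributions for the
seven laboratory parameters plus age (right-skewed markers log-normal,
the rest truncated normal), FIGO stage and parity frequencies per stratum,
and proportional-hazards event times with administrative censoring. It
exists so the downstream cutoff, scoring and survival machinery can be
exercised and validated without any patient data.

Units follow clinical convention: age in years, CA125 in U/mL, CRP in
mg/dL, d-dimer in ug/mL, white blood cell counts in x10^2/uL, albumin in
g/dL, follow-up times in months.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

LOGNORMAL = "log-normal"
NORMAL = "normal"

NONREC = "non_recurrent"
REC = "recurrent"

#: drawing order of the distributional columns (fixed for reproducibility)
MARKER_ORDER = (
    "age", "ca125_pre", "crp_pre", "ddimer_pre",
    "wbc_pre", "wbc_post", "crp_post", "albumin_post",
)

COLUMNS = (
    "patient_id", "age", "figo_stage", "parity", "recurrence", "death",
    "pfs_time", "os_time", "ca125_pre", "crp_pre", "ddimer_pre",
    "wbc_pre", "wbc_post", "crp_post", "albumin_post",
)


@dataclass(frozen=True)
class MarkerDistribution:
    """One stratum's marker distribution.

    For ``log-normal``, ``location`` is the median on the natural scale and
    ``scale`` the standard deviation of the log. For ``normal``, they are
    the mean and SD; draws are truncated at zero.
    """

    family: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in (LOGNORMAL, NORMAL):
            raise ValueError(f"invalid distribution family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.family == LOGNORMAL and self.location <= 0:
            raise ValueError("log-normal median must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == LOGNORMAL:
            return np.exp(rng.normal(math.log(self.location), self.scale, size))
        a = (0.0 - self.location) / self.scale
        return truncnorm.rvs(a, np.inf, loc=self.location, scale=self.scale,
                             size=size, random_state=rng)


def _lognormal_sigma(mean: float, median: float) -> float:
    """Log-scale SD implied by a printed mean/median pair (mean = median e^{s^2/2})."""
    return math.sqrt(2.0 * math.log(mean / median))


@dataclass
class CohortConfig:
    """Everything the cohort generator needs; JSON-serialisable."""

    n_patients: int
    recurrence_fraction: float
    marker_distributions: dict  # marker -> {stratum -> MarkerDistribution}
    figo_probs: dict            # stratum -> 4 probabilities for stages I-IV
    parity_nulliparous: dict    # stratum -> P(parity == 0)
    hazard_log_ratios: dict = field(default_factory=dict)
    baseline_hazard_scale: float = 36.0   # Weibull scale, months
    baseline_hazard_shape: float = 1.2    # Weibull shape
    censoring_horizon: float = 120.0      # months of administrative follow-up
    min_follow_up: float = 12.0           # months, shortest censored follow-up
    death_given_recurrence: float = 0.6
    post_progression_mean: float = 18.0   # months, exponential survival after recurrence
    missingness_rates: dict = field(default_factory=dict)  # marker -> MCAR probability
    seed: int | None = None

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for p, what in (
            (self.recurrence_fraction, "recurrence_fraction"),
            (self.death_given_recurrence, "death_given_recurrence"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{what} must be a probability")
        for v, what in (
            (self.baseline_hazard_scale, "baseline_hazard_scale"),
            (self.baseline_hazard_shape, "baseline_hazard_shape"),
            (self.censoring_horizon, "censoring_horizon"),
            (self.post_progression_mean, "post_progression_mean"),
        ):
            if v <= 0:
                raise ValueError(f"{what} must be positive")
        if not 0 < self.min_follow_up <= self.censoring_horizon:
            raise ValueError("min_follow_up must lie in (0, censoring_horizon]")
        for marker, strata in self.marker_distributions.items():
            if marker not in MARKER_ORDER:
                raise ValueError(f"unknown marker {marker!r}")
            for s in (NONREC, REC):
                if not isinstance(strata[s], MarkerDistribution):
                    raise ValueError(f"{marker}/{s} is not a MarkerDistribution")
        for s in (NONREC, REC):
            pr = np.asarray(self.figo_probs[s], dtype=float)
            if pr.size != 4 or (pr < 0).any() or not math.isclose(pr.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"figo_probs[{s}] must be 4 probabilities summing to 1")
            if not 0.0 <= self.parity_nulliparous[s] <= 1.0:
                raise ValueError("parity_nulliparous must be a probability")
        for marker, r in self.missingness_rates.items():
            if marker not in MARKER_ORDER:
                raise ValueError(f"unknown marker in missingness_rates: {marker!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must be probabilities")

    # -- JSON round trip -----------------------------------------------------
    def to_json(self) -> str:
        obj = dataclasses.asdict(self)
        obj["marker_distributions"] = {
            m: {s: dataclasses.asdict(d) for s, d in strata.items()}
            for m, strata in self.marker_distributions.items()
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        obj = json.loads(text)
        obj["marker_distributions"] = {
            m: {s: MarkerDistribution(**d) for s, d in strata.items()}
            for m, strata in obj["marker_distributions"].items()
        }
        return cls(**obj)


def default_config() -> CohortConfig:
    """Defaults calibrated to the published per-stratum summary statistics.

    Locations/scales are the printed group statistics: truncated-normal
    markers use the stratum mean +/- SD directly; log-normal markers use the
    stratum median as location with the log-SD implied by the mean/median
    ratio. Stage and parity frequencies are the stratum counts. The
    recurrence fraction is the published 28.9%. Follow-up quantities
    (Weibull baseline, 120-month horizon, post-progression survival) are
    this package's own invention — the source tables report no follow-up
    distribution — and are documented in the methods note.
    """
    md = {
        "age": {
            NONREC: MarkerDistribution(NORMAL, 55.91, 12.82),
            REC: MarkerDistribution(NORMAL, 60.26, 12.60),
        },
        "ca125_pre": {
            NONREC: MarkerDistribution(LOGNORMAL, 79.00, _lognormal_sigma(688.0, 79.00)),
            REC: MarkerDistribution(LOGNORMAL, 211.0, _lognormal_sigma(1384.0, 211.0)),
        },
        "crp_pre": {
            NONREC: MarkerDistribution(LOGNORMAL, 0.20, _lognormal_sigma(1.76, 0.20)),
            REC: MarkerDistribution(LOGNORMAL, 0.75, _lognormal_sigma(2.04, 0.75)),
        },
        "ddimer_pre": {
            NONREC: MarkerDistribution(LOGNORMAL, 1.20, _lognormal_sigma(4.11, 1.20)),
            REC: MarkerDistribution(LOGNORMAL, 2.20, _lognormal_sigma(4.81, 2.20)),
        },
        "wbc_pre": {
            NONREC: MarkerDistribution(NORMAL, 74.94, 32.27),
            REC: MarkerDistribution(NORMAL, 69.77, 22.48),
        },
        "wbc_post": {
            NONREC: MarkerDistribution(NORMAL, 54.31, 15.53),
            REC: MarkerDistribution(NORMAL, 62.02, 28.07),
        },
        "crp_post": {
            NONREC: MarkerDistribution(LOGNORMAL, 0.13, _lognormal_sigma(0.67, 0.13)),
            REC: MarkerDistribution(LOGNORMAL, 0.30, _lognormal_sigma(1.14, 0.30)),
        },
        "albumin_post": {
            NONREC: MarkerDistribution(NORMAL, 3.93, 0.49),
            REC: MarkerDistribution(NORMAL, 3.70, 0.54),
        },
    }
    return CohortConfig(
        n_patients=235,
        recurrence_fraction=0.289,
        marker_distributions=md,
        figo_probs={
            NONREC: [122 / 167, 18 / 167, 23 / 167, 4 / 167],
            REC: [13 / 68, 9 / 68, 28 / 68, 18 / 68],
        },
        parity_nulliparous={NONREC: 61 / 165, REC: 14 / 66},
        missingness_rates={
            m: 0.03 for m in MARKER_ORDER if m != "age"
        },
        seed=0,
    )


def _linear_predictor(config: CohortConfig, frame: pd.DataFrame) -> np.ndarray:
    """Sum of configured log hazard-ratios times covariates.

    Continuous markers are z-scored within the cohort; the binary covariates
    ``figo_advanced`` (stage III/IV) and ``parity_ge1`` enter as raw 0/1 so a
    configured log-HR is the direct group contrast.
    """
    lp = np.zeros(len(frame))
    for name, beta in config.hazard_log_ratios.items():
        if name == "figo_advanced":
            x = (frame["figo_stage"] >= 3).to_numpy(dtype=float)
        elif name == "parity_ge1":
            x = (frame["parity"] >= 1).to_numpy(dtype=float)
        elif name in MARKER_ORDER:
            raw = frame[name].to_numpy(dtype=float)
            sd = raw.std()
            x = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
        else:
            raise ValueError(f"unknown hazard covariate {name!r}")
        lp += float(beta) * x
    return lp


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort as a patient-level DataFrame.

    One root seed drives dedicated sub-streams (labels, one per marker and
    stratum, survival, missingness), so a fixed seed yields byte-identical
    cohorts. Patients assigned to the recurrent stratum receive a Weibull
    proportional-hazards event time; events beyond the administrative
    horizon are censored (recurrence flipped off). Overall survival adds an
    exponential post-progression time for patients who die after recurrence
    and equals the censored follow-up otherwise, so pfs_time <= os_time by
    construction. Marker missingness is applied last, after event times are
    drawn, so it never influences outcomes (missing completely at random).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_streams = 3 + 2 * len(MARKER_ORDER)
    children = root.spawn(n_streams)
    rng_labels = np.random.default_rng(children[0])
    rng_surv = np.random.default_rng(children[1])
    rng_miss = np.random.default_rng(children[2])
    marker_streams = {
        (marker, stratum): np.random.default_rng(children[3 + 2 * i + j])
        for i, marker in enumerate(MARKER_ORDER)
        for j, stratum in enumerate((NONREC, REC))
    }

    n = config.n_patients
    recurrent = rng_labels.random(n) < config.recurrence_fraction
    strata = np.where(recurrent, REC, NONREC)

    frame = pd.DataFrame(index=range(n))
    frame["patient_id"] = [f"P{i + 1:05d}" for i in range(n)]

    figo = np.zeros(n, dtype=int)
    parity = np.zeros(n, dtype=int)
    for s in (NONREC, REC):
        mask = strata == s
        k = int(mask.sum())
        if k == 0:
            continue
        figo[mask] = rng_labels.choice([1, 2, 3, 4], size=k, p=config.figo_probs[s])
        nulli = rng_labels.random(k) < config.parity_nulliparous[s]
        parity[mask] = np.where(nulli, 0, 1 + rng_labels.poisson(1.0, size=k))
    frame["figo_stage"] = figo
    frame["parity"] = parity

    for marker in MARKER_ORDER:
        col = np.zeros(n)
        for s in (NONREC, REC):
            mask = strata == s
            k = int(mask.sum())
            if k:
                col[mask] = config.marker_distributions[marker][s].sample(
                    marker_streams[(marker, s)], k
                )
        frame[marker] = col

    # --- event times -------------------------------------------------------
    lp = _linear_predictor(config, frame)
    shape, scale = config.baseline_hazard_shape, config.baseline_hazard_scale
    # Weibull PH: S(t) = exp(-(t/scale)^shape * e^lp)
    exp_draw = rng_surv.exponential(1.0, size=n)
    event_time = scale * (exp_draw / np.exp(lp)) ** (1.0 / shape)
    follow_up = rng_surv.uniform(config.min_follow_up, config.censoring_horizon, size=n)
    death_draw = rng_surv.random(n)
    post_prog = rng_surv.exponential(config.post_progression_mean, size=n)

    recurrence = recurrent & (event_time <= config.censoring_horizon)
    # assigned-recurrent events beyond the horizon are administratively censored
    pfs = np.where(
        recurrence, event_time,
        np.where(recurrent, config.censoring_horizon, follow_up),
    )
    death = recurrence & (death_draw < config.death_given_recurrence)
    # recurrent patients: death at pfs + post-progression time if within the
    # horizon, otherwise followed alive to the horizon; censored patients
    # have os_time == pfs_time (their last follow-up)
    os_time = np.where(recurrence, np.where(death, pfs + post_prog, config.censoring_horizon), pfs)
    over = death & (os_time > config.censoring_horizon)
    death = death & ~over
    os_time = np.where(recurrence, np.minimum(os_time, config.censoring_horizon), os_time)
    os_time = np.where(recurrence & ~death, config.censoring_horizon, os_time)

    frame["recurrence"] = recurrence
    frame["death"] = death
    frame["pfs_time"] = pfs
    frame["os_time"] = os_time

    for marker, rate in config.missingness_rates.items():
        if rate > 0:
            miss = rng_miss.random(n) < rate
            frame.loc[miss, marker] = np.nan

    return frame[list(COLUMNS)]


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV: booleans as true/false, missing values empty."""
    out = cohort.copy()
    for col in ("recurrence", "death"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    frame = pd.read_csv(path)
    for col in ("recurrence", "death"):
        frame[col] = frame[col].map(
            lambda v: bool(v) if isinstance(v, (bool, np.bool_))
            else str(v).strip().lower() == "true"
        ).astype(bool)
    frame["figo_stage"] = frame["figo_stage"].astype(int)
    frame["parity"] = frame["parity"].astype(int)
    return frame
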