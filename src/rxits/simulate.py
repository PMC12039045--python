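"""Synthetic patient-level prescribing data with a known generating model.

The generator emulates a national primary-care cohort: a registered
population growing linearly over the study window, patients carrying
demographic/clinical subgroup labels, and monthly prescription issues driven
by a two-state (currently prescribed / not prescribed) Bernoulli chain.

A patient who was *not* prescribed in month ``t-1`` initiates in month ``t``
with probability

    q_t = baseline_rate * monthly_trend**t
          * exp(seasonal + step/slope terms + outlier terms)  * modifier

(the same segmented log-linear form the analysis model assumes), while a
patient who *was* prescribed repeats with probability ``repeat_persistence``.
Persistence is what separates prevalent prescribing (anyone with an issue
this month) from new prescribing (an issue after a 24-month gap), giving
every downstream stage a ground truth.

``truth_expected_rate`` is the closed-form oracle: the exact expectation of
the chain, marginalised over subgroup rate modifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .calendar import StudyCalendar

__all__ = [
    "ConfigurationError",
    "SimulationTruth",
    "generate_population",
    "generate_prescriptions",
    "truth_expected_rate",
    "simulate_count_series",
    "DEFAULT_SUBGROUP_PREVALENCES",
    "DEFAULT_RATE_MODIFIERS",
    "DRUG_CLASSES",
]

OPEN_END = np.inf  # registration_end sentinel for still-registered patients

DRUG_CLASSES = ("ssri", "tricyclic", "maoi", "other")

# Registered-population composition of a large English primary-care cohort
# in late 2022 (fractions of the registered denominator). Labels with a
# "family:" prefix are mutually exclusive within the family; the remainder
# of a family (e.g. unknown IMD) carries no flag. Plain labels are
# independent, so learning disability and autism can co-occur.
DEFAULT_SUBGROUP_PREVALENCES: dict[str, float] = {
    "learning_disability": 0.0057,
    "autism": 0.0104,
    "care_home": 0.0069,
    "sex:F": 0.499,
    "sex:M": 0.501,
    "age_band:0-19": 0.219,
    "age_band:20-29": 0.123,
    "age_band:30-39": 0.144,
    "age_band:40-49": 0.128,
    "age_band:50-59": 0.136,
    "age_band:60-69": 0.111,
    "age_band:70-79": 0.088,
    "age_band:80+": 0.051,
    "imd:1": 0.197,
    "imd:2": 0.193,
    "imd:3": 0.205,
    "imd:4": 0.193,
    "imd:5": 0.177,
    "region:east": 0.229,
    "region:east_midlands": 0.174,
    "region:london": 0.071,
    "region:north_east": 0.047,
    "region:north_west": 0.087,
    "region:south_east": 0.065,
    "region:south_west": 0.139,
    "region:west_midlands": 0.041,
    "region:yorkshire": 0.145,
    "ethnicity:white": 0.662,
    "ethnicity:asian": 0.072,
    "ethnicity:black": 0.025,
    "ethnicity:mixed": 0.015,
    "ethnicity:other": 0.021,
    "diagnosis:anxiety": 0.129,
    "diagnosis:both": 0.085,
    "diagnosis:depression": 0.053,
    "diagnosis:neither": 0.733,
}

# Multiplicative modifiers on the initiation probability; ratios of the
# subgroup prescribing rates to the overall rate in the same cohort.
DEFAULT_RATE_MODIFIERS: dict[str, float] = {
    "learning_disability": 2.28,
    "autism": 1.47,
    "sex:F": 1.33,
    "sex:M": 0.67,
}

DEFAULT_CLASS_PROBS: dict[str, float] = {
    "ssri": 0.58,
    "tricyclic": 0.19,
    "maoi": 0.02,
    "other": 0.21,
}


class ConfigurationError(ValueError):
    """Raised when a SimulationTruth is not a valid generating model."""


@dataclass
class SimulationTruth:
    """Parameters of the generating process (all effects on the log scale).

    ``baseline_rate`` is the per-patient-month initiation probability at
    t = 0; ``monthly_trend`` multiplies it each month; one sine/cosine pair
    at period 12 gives annual seasonality; the four step/slope terms switch
    on at the calendar's two interruptions with the same coding as the
    analysis design matrix; ``outlier_effects`` maps months (ISO string or
    index) to extra log-scale effects; ``repeat_persistence`` is the
    probability that a currently prescribed patient is prescribed again next
    month. The registered population is ``population_start`` at t = 0 and
    grows by ``population_growth`` patients per month (linearly, including
    through the burn-in).
    """

    baseline_rate: float
    monthly_trend: float = 1.0
    seasonal_amplitude_sin: float = 0.0
    seasonal_amplitude_cos: float = 0.0
    step_restriction: float = 0.0
    slope_restriction: float = 0.0
    step_recovery: float = 0.0
    slope_recovery: float = 0.0
    outlier_effects: dict = field(default_factory=dict)
    repeat_persistence: float = 0.0
    population_start: int = 10_000
    population_growth: float = 0.0
    subgroup_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_PREVALENCES)
    )
    subgroup_rate_modifiers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_MODIFIERS)
    )
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    burn_in_months: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_rate < 1.0):
            raise ConfigurationError("baseline_rate must lie in (0, 1)")
        if not (0.0 <= self.repeat_persistence <= 1.0):
            raise ConfigurationError("repeat_persistence must lie in [0, 1]")
        if self.monthly_trend <= 0:
            raise ConfigurationError("monthly_trend must be positive")
        if self.burn_in_months < 0:
            raise ConfigurationError("burn_in_months must be non-negative")
        if self.population_start < 1:
            raise ConfigurationError("population_start must be >= 1")
        for label, p in self.subgroup_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"prevalence of {label!r} outside [0, 1]: {p}"
                )
        for family, probs in self._families().items():
            if sum(probs.values()) > 1.0 + 1e-9:
                raise ConfigurationError(
                    f"prevalences of family {family!r} sum to more than 1"
                )
        for m in self.subgroup_rate_modifiers.values():
            if m < 0:
                raise ConfigurationError("rate modifiers must be non-negative")
        bad = [c for c in self.class_probs if c not in DRUG_CLASSES]
        if bad or abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                "class_probs must cover only "
                f"{DRUG_CLASSES} and sum to 1 (got {self.class_probs})"
            )

    # -- label bookkeeping -------------------------------------------------

    def _families(self) -> dict[str, dict[str, float]]:
        """Mutually exclusive label families, keyed by prefix."""
        fams: dict[str, dict[str, float]] = {}
        for label, p in self.subgroup_prevalences.items():
            if ":" in label:
                fam = label.split(":", 1)[0]
                fams.setdefault(fam, {})[label] = p
        return fams

    def _plain_labels(self) -> dict[str, float]:
        return {
            label: p
            for label, p in self.subgroup_prevalences.items()
            if ":" not in label
        }

    def labels(self) -> list[str]:
        return sorted(self.subgroup_prevalences)

    # -- generating rate ---------------------------------------------------

    def outlier_indices(self, calendar: StudyCalendar) -> dict[int, float]:
        out: dict[int, float] = {}
        for key, effect in self.outlier_effects.items():
            t = key if isinstance(key, int) else calendar.t_index(key)
            out[t] = float(effect)
        return out

    def log_initiation_rate(
        self, calendar: StudyCalendar, t: np.ndarray | int
    ) -> np.ndarray:
        """log q_t for the reference patient (modifier 1) at month index t."""
        t = np.asarray(t, dtype=float)
        i1, i2 = calendar.interruption_1, calendar.interruption_2
        eta = (
            math.log(self.baseline_rate)
            + t * math.log(self.monthly_trend)
            + self.seasonal_amplitude_sin * np.sin(2 * np.pi * t / 12.0)
            + self.seasonal_amplitude_cos * np.cos(2 * np.pi * t / 12.0)
        )
        eta = eta + (t >= i1) * (
            self.step_restriction + self.slope_restriction * np.maximum(0, t - i1 + 1)
        )
        eta = eta + (t >= i2) * (
            self.step_recovery + self.slope_recovery * np.maximum(0, t - i2 + 1)
        )
        out = self.outlier_indices(calendar)
        for month, effect in out.items():
            eta = eta + np.where(t == month, effect, 0.0)
        return eta

    def initiation_rate(
        self, calendar: StudyCalendar, t: np.ndarray | int
    ) -> np.ndarray:
        return np.exp(self.log_initiation_rate(calendar, t))

    # -- presets -----------------------------------------------------------

    @classmethod
    def overall_prescribing(cls, scale: float = 1.0, seed: int = 0) -> "SimulationTruth":
        """Study conditions for the *prevalent* prescribing outcome.

        Initiation 0.0029 and persistence 0.962 put the stationary prevalence
        near 71 per 1000 at the window start, rising ~0.3%/month; the
        pandemic effects are the overall-prescribing interruption estimates
        (-3.4% step / +0.3%/month during restrictions; +2.3% / -0.5%/month in
        recovery) with mild March/April dips absorbed by outlier terms.
        ``scale`` shrinks the ~23.9M registered population for desk runs.
        """
        return cls(
            baseline_rate=0.0029,
            monthly_trend=1.0033,
            seasonal_amplitude_sin=0.02,
            seasonal_amplitude_cos=0.01,
            step_restriction=math.log(1 - 0.034),
            slope_restriction=math.log(1 + 0.003),
            step_recovery=math.log(1 + 0.023),
            slope_recovery=math.log(1 - 0.005),
            outlier_effects={"2020-03": -0.05, "2020-04": -0.03},
            repeat_persistence=0.962,
            population_start=max(2, round(23_864_380 * scale)),
            population_growth=(25_504_380 - 23_864_380) / 59 * scale,
            burn_in_months=30,
            seed=seed,
        )

    @classmethod
    def new_prescribing(cls, scale: float = 1.0, seed: int = 0) -> "SimulationTruth":
        """Study conditions for the *new* (incident) prescribing outcome:
        initiation ~3.3 per 1000 naive patients per month, flat pre-trend,
        and the new-prescribing interruption estimates (-24.8% step /
        +1.5%/month; +9.1% / -2.2%/month) with deep March/April outliers."""
        return cls(
            baseline_rate=0.0033,
            monthly_trend=1.001,
            seasonal_amplitude_sin=0.03,
            seasonal_amplitude_cos=0.02,
            step_restriction=math.log(1 - 0.248),
            slope_restriction=math.log(1 + 0.015),
            step_recovery=math.log(1 + 0.091),
            slope_recovery=math.log(1 - 0.022),
            outlier_effects={"2020-03": -0.10, "2020-04": -0.25},
            repeat_persistence=0.962,
            population_start=max(2, round(23_864_380 * scale)),
            population_growth=(25_504_380 - 23_864_380) / 59 * scale,
            burn_in_months=30,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "baseline_rate",
                "monthly_trend",
                "seasonal_amplitude_sin",
                "seasonal_amplitude_cos",
                "step_restriction",
                "slope_restriction",
                "step_recovery",
                "slope_recovery",
                "repeat_persistence",
                "population_start",
                "population_growth",
                "burn_in_months",
                "seed",
            )
        }
        d["outlier_effects"] = dict(self.outlier_effects)
        d["subgroup_prevalences"] = dict(self.subgroup_prevalences)
        d["subgroup_rate_modifiers"] = dict(self.subgroup_rate_modifiers)
        d["class_probs"] = dict(self.class_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(**d)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _population_path(truth: SimulationTruth, calendar: StudyCalendar) -> np.ndarray:
    """Target registered-patient count for each month -burn_in .. T-1."""
    months = np.arange(-truth.burn_in_months, calendar.n_months)
    path = truth.population_start + months * truth.population_growth
    path = np.floor(path + 0.5).astype(int)
    if (path < 1).any():
        raise ConfigurationError("population path reaches zero patients")
    return path


def generate_population(
    truth: SimulationTruth, calendar: StudyCalendar
) -> pd.DataFrame:
    """Generate registration records with subgroup flags.

    Returns a frame with ``patient_id``, ``reg_start``, ``reg_end`` (month
    indices; ``reg_end`` is exclusive and ``inf`` when open) and one 0/1
    column per subgroup label. The registered count at every in-window month
    t equals ``population_start + t * population_growth`` up to rounding to
    whole patients; the same linear path extends back through the burn-in.
    """
    rng = np.random.default_rng([truth.seed, 0x5E9])
    path = _population_path(truth, calendar)
    months = np.arange(-truth.burn_in_months, calendar.n_months)

    starts = [np.full(path[0], months[0])]
    total = path[0]
    closed: list[tuple[int, int]] = []  # (patient index, reg_end)
    open_ids = list(range(path[0]))
    for k in range(1, len(months)):
        d = int(path[k] - path[k - 1])
        if d > 0:
            starts.append(np.full(d, months[k]))
            open_ids.extend(range(total, total + d))
            total += d
        elif d < 0:
            drop = rng.choice(len(open_ids), size=-d, replace=False)
            for j in sorted(drop, reverse=True):
                closed.append((open_ids.pop(j), int(months[k])))

    reg_start = np.concatenate(starts)
    reg_end = np.full(total, OPEN_END)
    for pid, end in closed:
        reg_end[pid] = end

    df = pd.DataFrame(
        {
            "patient_id": np.arange(total),
            "reg_start": reg_start.astype(int),
            "reg_end": reg_end,
        }
    )

    # subgroup flags: families are multinomial, plain labels independent
    n = total
    for label in sorted(truth._plain_labels()):
        df[label] = (rng.random(n) < truth.subgroup_prevalences[label]).astype(np.int8)
    for family in sorted(truth._families()):
        levels = sorted(truth._families()[family])
        probs = np.array([truth.subgroup_prevalences[l] for l in levels])
        edges = np.concatenate([[0.0], np.cumsum(probs)])
        u = rng.random(n)
        which = np.searchsorted(edges, u, side="right") - 1
        for i, label in enumerate(levels):
            df[label] = (which == i).astype(np.int8)
    return df


# ---------------------------------------------------------------------------
# prescriptions
# ---------------------------------------------------------------------------

def _patient_modifiers(truth: SimulationTruth, patients: pd.DataFrame) -> np.ndarray:
    mod = np.ones(len(patients))
    for label in sorted(truth.subgroup_rate_modifiers):
        if label in patients.columns:
            m = truth.subgroup_rate_modifiers[label]
            mod *= np.where(patients[label].to_numpy(dtype=bool), m, 1.0)
    return mod


def _stationary_prevalence(q: np.ndarray | float, r: float) -> np.ndarray:
    """Fixed point of pi = r*pi + q*(1-pi), elementwise; 0 when degenerate."""
    q = np.asarray(q, dtype=float)
    denom = q + 1.0 - r
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(denom > 0, q / np.where(denom > 0, denom, 1.0), 1.0)
    return np.clip(np.where(q == 0, 0.0, pi), 0.0, 1.0)


def generate_prescriptions(
    patients: pd.DataFrame, truth: SimulationTruth, calendar: StudyCalendar
) -> pd.DataFrame:
    """Simulate prescription events from the initiation/persistence chain.

    Patients registered at the burn-in start carry prescribing history from
    before data capture: their initial prescribed/not state is drawn from
    the chain's stationary distribution at that month, so prevalence starts
    the window in (quasi-)steady state. Patients who register later start
    unprescribed. Returns a frame with ``patient_id``, ``month`` (index,
    burn-in months negative) and ``drug_class``. Deterministic given the
    truth's seed and independent of the draws used by
    :func:`generate_population`.
    """
    rng = np.random.default_rng([truth.seed, 0xE7])
    n = len(patients)
    reg_start = patients["reg_start"].to_numpy()
    reg_end = patients["reg_end"].to_numpy(dtype=float)
    pids = patients["patient_id"].to_numpy()
    mod = _patient_modifiers(truth, patients)
    max_mod = mod.max() if n else 1.0

    months = np.arange(-truth.burn_in_months, calendar.n_months)
    q = truth.initiation_rate(calendar, months)
    worst = q * max_mod
    if (worst >= 1.0).any():
        bad = months[int(np.argmax(worst >= 1.0))]
        raise ConfigurationError(
            f"implied initiation probability >= 1 at month {calendar.month_of(bad)}"
        )

    pi0 = _stationary_prevalence(q[0] * mod, truth.repeat_persistence)
    prev = rng.random(n) < pi0
    ev_pid: list[np.ndarray] = []
    ev_month: list[np.ndarray] = []
    for k, t in enumerate(months):
        active = (reg_start <= t) & (t < reg_end)
        p = np.where(prev, truth.repeat_persistence, q[k] * mod)
        hit = active & (rng.random(n) < p)
        idx = np.nonzero(hit)[0]
        ev_pid.append(pids[idx])
        ev_month.append(np.full(idx.size, t))
        prev = hit

    pid = np.concatenate(ev_pid) if ev_pid else np.empty(0, dtype=int)
    month = np.concatenate(ev_month) if ev_month else np.empty(0, dtype=int)
    classes = sorted(truth.class_probs)
    probs = np.array([truth.class_probs[c] for c in classes])
    drug = rng.choice(np.array(classes, dtype=object), size=pid.size, p=probs)
    return pd.DataFrame(
        {"patient_id": pid, "month": month.astype(int), "drug_class": drug}
    )


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------

def _modifier_mixture(truth: SimulationTruth) -> list[tuple[float, float]]:
    """(weight, modifier) pairs over the distinct modifier combinations."""
    components: list[list[tuple[float, float]]] = []
    plain = truth._plain_labels()
    fams = truth._families()
    for label, m in sorted(truth.subgroup_rate_modifiers.items()):
        if m == 1.0:
            continue
        if label in plain:
            p = plain[label]
            components.append([(1 - p, 1.0), (p, m)])
    for family, levels in sorted(fams.items()):
        if not any(
            truth.subgroup_rate_modifiers.get(l, 1.0) != 1.0 for l in levels
        ):
            continue
        comp = [
            (p, truth.subgroup_rate_modifiers.get(l, 1.0))
            for l, p in sorted(levels.items())
        ]
        rest = 1.0 - sum(p for p, _ in comp)
        if rest > 1e-12:
            comp.append((rest, 1.0))
        components.append(comp)
    if not components:
        return [(1.0, 1.0)]
    mix: list[tuple[float, float]] = []
    for combo in product(*components):
        w = math.prod(p for p, _ in combo)
        m = math.prod(mm for _, mm in combo)
        if w > 0:
            mix.append((w, m))
    return mix


def truth_expected_rate(
    truth: SimulationTruth, calendar: StudyCalendar, month: int | str
) -> float:
    """Expected prevalent-prescribing rate per 1000 registered patients.

    Runs the exact two-state recursion pi_t = r*pi_{t-1} + q_t*(1-pi_{t-1})
    forward from the burn-in start, beginning at the chain's stationary
    prevalence there (matching the generator's initial state), separately
    for each distinct subgroup rate-modifier combination, and returns the
    prevalence mixture at ``month`` scaled to a per-1000 rate. Exact for a
    constant registered population; patients who register after the burn-in
    start begin unprescribed, so under population growth the realised rate
    is slightly diluted relative to this value.
    """
    t_target = month if isinstance(month, int) else calendar.t_index(month)
    if not (-truth.burn_in_months <= t_target < calendar.n_months):
        raise ConfigurationError(
            f"month index {t_target} outside the generated range"
        )
    months = np.arange(-truth.burn_in_months, t_target + 1)
    q = truth.initiation_rate(calendar, months)
    r = truth.repeat_persistence
    rate = 0.0
    for w, m in _modifier_mixture(truth):
        qm = np.clip(q * m, 0.0, 1.0)
        pi = float(_stationary_prevalence(qm[0], r))
        for qt in qm:
            pi = r * pi + qt * (1.0 - pi)
        rate += w * pi
    return 1000.0 * rate


# ---------------------------------------------------------------------------
# series-level simulator (counts straight from the log-linear rate)
# ---------------------------------------------------------------------------

def simulate_count_series(
    truth: SimulationTruth,
    calendar: StudyCalendar,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Monthly counts drawn directly from the segmented log-linear model.

    The expected count in month t is ``N_t * q_t`` with ``q_t`` the truth's
    initiation rate and ``N_t`` the linear population path; counts are
    Poisson. This bypasses the patient-level chain, so the fitted model's
    coefficients are directly comparable with the truth's — the harness for
    parameter-recovery and calibration studies.

    Returns a frame with columns ``month`` (index), ``numerator``,
    ``denominator``, restricted to the analysis window.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    t = np.arange(calendar.n_months)
    pop = _population_path(truth, calendar)[truth.burn_in_months :]
    rate = truth.initiation_rate(calendar, t)
    if (rate >= 1.0).any():
        bad = int(t[np.argmax(rate >= 1.0)])
        raise ConfigurationError(
            f"implied rate >= 1 at month {calendar.month_of(bad)}"
        )
    y = rng.poisson(pop * rate)
    return pd.DataFrame({"month": t, "numerator": y, "denominator": pop})


def with_seed(truth: SimulationTruth, seed: int) -> SimulationTruth:
    """Copy of ``truth`` with a different seed (for replicate studies)."""
    return replace(truth, seed=seed)
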