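"""Synthetic multistate cohort generator.

Emulates a claims-linked cohort of middle-aged adults followed for roughly a
decade: each person enters disease-free (after baseline screening), carries
fixed categorical covariates, and acquires chronic-condition onsets from a
history-dependent multistate process.  Between onsets the process is a race of
competing exponential clocks: each not-yet-acquired condition ``c`` fires at

    rate(c | history, covariates)
        = baseline_rate[c]
          * exp(sum of covariate log-hazard-ratios for c)
          * prod over acquired a of progression_multiplier[a][c]

so hazards are piecewise-constant between events and the process is Markov in
(history, covariates).  A condition occurs at most once per person.  Onsets are
simulated on the window ``[-baseline_lookback_years, censor_time]``; negative
onset times represent pre-baseline disease history and are used by
:func:`screen_baseline_free` to emulate the exclusion of participants with any
condition at baseline.  Follow-up is dropout-free: observation ends only at the
administrative censoring time.

Each person has their own pseudo-random stream derived from
``(seed, person_id)`` via NumPy's SeedSequence, so cohorts are reproducible
under resizing and bit-identical across process invocations.

Default parameter values are illustrative: the real study's incidence inputs
are not public, so the defaults are chosen to give a cohort in which roughly
half of participants develop a first condition over nine years, with a
CMD-heavy rate profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, CONDITION_INDEX, Condition, as_condition

PERSON_COLUMNS = ["person_id", "gender", "age_band", "censor_time"]
EVENT_COLUMNS = ["person_id", "condition", "onset_time"]

#: Illustrative baseline onset rates, events per person-year.  Chosen so the
#: all-cause first-onset hazard is ~0.078/yr (about half the cohort develops a
#: primary condition over 9 years) with cardiometabolic conditions dominating.
ILLUSTRATIVE_RATES: dict[Condition, float] = {
    Condition.CANCER: 0.006,
    Condition.CVD: 0.008,
    Condition.HYPERTENSION: 0.016,
    Condition.DYSLIPIDEMIA: 0.016,
    Condition.DIABETES: 0.006,
    Condition.ASTHMA: 0.006,
    Condition.MENTAL: 0.008,
    Condition.NEURODEGEN: 0.001,
    Condition.HIP_REPLACEMENT: 0.002,
    Condition.OSTEOARTHRITIS: 0.009,
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level structure: size, follow-up, and covariate distributions.

    Parameters
    ----------
    n_persons
        Number of persons to simulate (positive).
    followup_years
        Administrative censoring time, years since entry (default 9.0,
        matching ~9 years of claims linkage).
    baseline_lookback_years
        Length of the pre-baseline window on which the same onset process runs
        to generate disease history for screening (default 2.0).
    p_female
        Bernoulli probability of gender "F" (default 0.565).
    p_age_55_64
        Bernoulli probability of age band "55-64" versus "45-54"
        (default 0.41).
    covariates
        Extra categorical covariates: name -> {level: probability}.
    seed
        Default random seed; ``simulate_cohort`` may override it.
    """

    n_persons: int
    followup_years: float = 9.0
    baseline_lookback_years: float = 2.0
    p_female: float = 0.565
    p_age_55_64: float = 0.41
    covariates: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if self.baseline_lookback_years < 0:
            raise ValueError("baseline_lookback_years must be nonnegative")
        for p, name in [(self.p_female, "p_female"), (self.p_age_55_64, "p_age_55_64")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, levels in self.covariates.items():
            total = float(sum(levels.values()))
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(
                    f"covariate {name!r} level probabilities sum to {total}, not 1"
                )
            if any(p < 0 for p in levels.values()):
                raise ValueError(f"covariate {name!r} has a negative probability")


@dataclass(frozen=True)
class HazardSpec:
    """Ground-truth onset hazards for the multistate process.

    ``baseline_rate`` maps each condition to its disease-free onset rate in
    events per person-year.  ``covariate_loghr`` maps ``(covariate_name,
    level)`` to per-condition log hazard ratios applied when a person has that
    level.  ``progression_multiplier[a][c]`` scales the hazard of ``c`` once
    ``a`` has been acquired; multipliers combine multiplicatively across
    acquired conditions, and the diagonal is ignored (a condition occurs at
    most once).
    """

    baseline_rate: Mapping[Condition, float]
    covariate_loghr: Mapping[tuple[str, str], Mapping[Condition, float]] = field(
        default_factory=dict
    )
    progression_multiplier: Mapping[Condition, Mapping[Condition, float]] = field(
        default_factory=dict
    )

    def validate(self, spec: CohortSpec | None = None) -> None:
        for c in CONDITIONS:
            rate = float(self.baseline_rate.get(c, 0.0))
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(f"baseline_rate[{c.value}] must be finite and >= 0")
        for a, row in self.progression_multiplier.items():
            as_condition(a)
            for c, m in row.items():
                as_condition(c)
                if not np.isfinite(m) or m < 0:
                    raise ValueError(
                        f"progression_multiplier[{a}][{c}] must be finite and >= 0"
                    )
        if spec is not None:
            known = {("gender", "F"), ("gender", "M"),
                     ("age_band", "45-54"), ("age_band", "55-64")}
            for name, levels in spec.covariates.items():
                known.update((name, lvl) for lvl in levels)
            for key in self.covariate_loghr:
                if key not in known:
                    raise ValueError(f"covariate_loghr references unknown level {key}")

    def rate_vector(self) -> np.ndarray:
        return np.array(
            [float(self.baseline_rate.get(c, 0.0)) for c in CONDITIONS], dtype=float
        )

    def multiplier_matrix(self) -> np.ndarray:
        """10x10 matrix M with M[a, c] = multiplier of c's hazard once a occurred."""
        m = np.ones((len(CONDITIONS), len(CONDITIONS)), dtype=float)
        for a, row in self.progression_multiplier.items():
            ia = CONDITION_INDEX[as_condition(a).value]
            for c, val in row.items():
                ic = CONDITION_INDEX[as_condition(c).value]
                if ia != ic:  # diagonal ignored by contract
                    m[ia, ic] = float(val)
        return m

    def loghr_vector(self, key: tuple[str, str]) -> np.ndarray:
        out = np.zeros(len(CONDITIONS), dtype=float)
        row = self.covariate_loghr.get(key)
        if row:
            for c, v in row.items():
                out[CONDITION_INDEX[as_condition(c).value]] = float(v)
        return out


def uniform_progression(multiplier: float) -> dict[Condition, dict[Condition, float]]:
    """All off-diagonal progression multipliers set to a single value."""
    return {
        a: {c: float(multiplier) for c in CONDITIONS if c is not a}
        for a in CONDITIONS
    }


def null_hazard_spec() -> HazardSpec:
    """Illustrative rates, no covariate effects, all progression multipliers 1.

    The 'global null' configuration: condition onsets are independent of
    history and covariates, so any estimated progression effect is spurious.
    """
    return HazardSpec(baseline_rate=dict(ILLUSTRATIVE_RATES))


def default_hazard_spec(progression: float = 2.0) -> HazardSpec:
    """Illustrative default hazards with history-dependent acceleration.

    A uniform cross-condition progression multiplier (default 2.0) encodes the
    qualitative structure the analysis is designed to detect: acquiring any
    condition doubles the hazard of every other condition, so the time to a
    subsequent condition shrinks as conditions accumulate.  Modest covariate
    effects are included: the older age band carries a log(1.5) hazard ratio
    on every condition, and men carry a log(1.25) hazard ratio on the
    cardiometabolic conditions.
    """
    male_cmd = {
        Condition.CVD: float(np.log(1.25)),
        Condition.HYPERTENSION: float(np.log(1.25)),
        Condition.DYSLIPIDEMIA: float(np.log(1.25)),
        Condition.DIABETES: float(np.log(1.25)),
    }
    older = {c: float(np.log(1.5)) for c in CONDITIONS}
    return HazardSpec(
        baseline_rate=dict(ILLUSTRATIVE_RATES),
        covariate_loghr={("gender", "M"): male_cmd, ("age_band", "55-64"): older},
        progression_multiplier=uniform_progression(progression),
    )


def _sample_level(rng: np.random.Generator, levels: list[str], cum: np.ndarray) -> str:
    r = rng.random()
    idx = int(np.searchsorted(cum, r, side="right"))
    return levels[min(idx, len(levels) - 1)]


def simulate_cohort(
    spec: CohortSpec,
    hazards: HazardSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of persons and their raw onset events.

    Returns ``(persons, events)``:

    * ``persons`` — one row per person: person_id, gender, age_band, one
      column per extra covariate, censor_time (years since entry).
    * ``events`` — one row per onset: person_id, condition, onset_time (years
      since entry; negative for pre-baseline onsets).  At most one event per
      (person, condition); events after censor_time are discarded.

    Identical ``(spec, hazards, seed)`` gives bit-identical output.  Each
    person's stream is ``np.random.default_rng([seed, person_id])``.
    """
    spec.validate()
    hazards.validate(spec)
    if seed is None:
        seed = spec.seed

    base = hazards.rate_vector()
    mult_matrix = hazards.multiplier_matrix()
    n_cond = len(CONDITIONS)
    cond_names = [c.value for c in CONDITIONS]
    extra_names = list(spec.covariates)
    extra_levels = {k: list(v) for k, v in spec.covariates.items()}
    extra_cum = {
        k: np.cumsum([float(v[lvl]) for lvl in extra_levels[k]])
        for k, v in spec.covariates.items()
    }

    # per covariate pattern, the covariate-adjusted rate vector
    pattern_rates: dict[tuple[str, ...], np.ndarray] = {}

    def rates_for(pattern: tuple[str, ...]) -> np.ndarray:
        cached = pattern_rates.get(pattern)
        if cached is None:
            loghr = np.zeros(n_cond)
            keys = [("gender", pattern[0]), ("age_band", pattern[1])]
            keys += list(zip(extra_names, pattern[2:]))
            for key in keys:
                loghr += hazards.loghr_vector(key)
            cached = base * np.exp(loghr)
            pattern_rates[pattern] = cached
        return cached

    censor = float(spec.followup_years)
    lookback = float(spec.baseline_lookback_years)

    person_rows: list[tuple] = []
    event_pids: list[int] = []
    event_conds: list[str] = []
    event_times: list[float] = []

    for pid in range(spec.n_persons):
        rng = np.random.default_rng([seed, pid])
        gender = "F" if rng.random() < spec.p_female else "M"
        age_band = "55-64" if rng.random() < spec.p_age_55_64 else "45-54"
        extras = tuple(
            _sample_level(rng, extra_levels[k], extra_cum[k]) for k in extra_names
        )
        person_rates = rates_for((gender, age_band) + extras)

        mult = np.ones(n_cond)
        acquired = np.zeros(n_cond, dtype=bool)
        t = -lookback
        while True:
            active = np.where(acquired, 0.0, person_rates * mult)
            total = float(active.sum())
            if total <= 0.0:
                break
            t += rng.exponential() / total
            if t > censor:
                break
            r = rng.random() * total
            j = int(np.searchsorted(np.cumsum(active), r, side="right"))
            j = min(j, n_cond - 1)
            acquired[j] = True
            mult *= mult_matrix[j]
            event_pids.append(pid)
            event_conds.append(cond_names[j])
            event_times.append(t)

        person_rows.append((pid, gender, age_band) + extras + (censor,))

    persons = pd.DataFrame(
        person_rows,
        columns=["person_id", "gender", "age_band", *extra_names, "censor_time"],
    )
    events = pd.DataFrame(
        {
            "person_id": np.asarray(event_pids, dtype=np.int64),
            "condition": event_conds,
            "onset_time": np.asarray(event_times, dtype=float),
        }
    )
    return persons, events


def screen_baseline_free(
    persons: pd.DataFrame, events: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every person with any onset at or before baseline (time 0).

    Emulates the study design of excluding participants with any of the ten
    conditions at baseline.  Returns the screened persons table and only the
    post-baseline events of the survivors.
    """
    pre = events.loc[events["onset_time"] <= 0.0, "person_id"].unique()
    keep_persons = persons.loc[~persons["person_id"].isin(pre)].reset_index(drop=True)
    keep_ids = set(keep_persons["person_id"].tolist())
    kept_events = events.loc[
        events["person_id"].isin(keep_ids) & (events["onset_time"] > 0.0)
    ].reset_index(drop=True)
    return keep_persons, kept_events


def simulate_screened_cohort(
    spec: CohortSpec, hazards: HazardSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and apply baseline screening in one step."""
    persons, events = simulate_cohort(spec, hazards, seed=seed)
    return screen_baseline_free(persons, events)
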