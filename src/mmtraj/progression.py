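"""Progression relative risks under the 5-year-window design.

The design asks: given that a person's first condition (or first two
conditions, in order) is a specific exposure, how much more likely are they to
develop a specific outcome as their *next* condition within a fixed window,
compared with the outcome's incidence as a *first* condition among people who
entered follow-up disease-free?

Concretely, for a window ``w`` (default 5 years):

* **Reference arm** — every person disease-free at baseline with at least
  ``w`` years of follow-up; response 1 iff the outcome occurred as the
  person's rank-1 (primary) condition within ``w`` years of entry.
* **Exposed arm** — persons whose rank-1 condition (and rank-2, for pair
  exposures, in the stated order) matches the exposure, with every exposure
  onset within ``w`` years of entry, and at least ``w`` years of follow-up
  remaining after the last exposure onset; response 1 iff the outcome occurs
  as the immediately next-ranked condition within ``w`` years of the last
  exposure onset.

Arms are disjoint: exposed persons are removed from the reference rows of
their own contrast.  The relative risk is estimated by a Poisson model with a
sandwich variance on the stacked rows (a risk-ratio estimator on binary
responses); :class:`ProgressionModel` evaluates the full grid of contrasts and
applies Benjamini-Hochberg FDR control across it.

Two documented switches alter the window anchoring and outcome semantics:
``anchor='entry'`` measures the outcome window from study entry instead of the
last exposure onset, and ``allow_intervening=True`` accepts the outcome at any
later rank (not just the next one) within the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, as_condition
from .stats import ConvergenceError, FitResult, benjamini_hochberg, poisson_rr


@dataclass(frozen=True)
class ProgressionContrast:
    """One exposure -> outcome contrast.

    ``primary`` (and optionally ``secondary``, for ordered-pair exposures)
    define the exposure; ``outcome`` must differ from both.
    """

    primary: str
    outcome: str
    secondary: str | None = None
    window_years: float = 5.0

    def __post_init__(self) -> None:
        as_condition(self.primary)
        as_condition(self.outcome)
        if self.secondary is not None:
            as_condition(self.secondary)
        exposure = {self.primary} | ({self.secondary} if self.secondary else set())
        if self.outcome in exposure:
            raise ValueError("outcome must differ from the exposure conditions")
        if self.secondary == self.primary:
            raise ValueError("primary and secondary exposure conditions must differ")
        if self.window_years <= 0:
            raise ValueError("window_years must be positive")

    @property
    def label(self) -> str:
        if self.secondary is None:
            return f"{self.primary} -> {self.outcome}"
        return f"({self.primary}, {self.secondary}) -> {self.outcome}"


@dataclass
class RREstimate:
    """Estimated relative risk for one progression contrast."""

    contrast: ProgressionContrast
    n_exposed: int
    n_reference: int
    cases_exposed: int
    cases_reference: int
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None = None
    suppressed: bool = False
    estimable: bool = True
    fit: FitResult | None = None


def person_sequences(
    trajectories: pd.DataFrame,
    persons: pd.DataFrame,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-person wide table of the first three onsets plus follow-up.

    Index person_id; columns c1, t1, c2, t2, c3, t3 (NaN where absent),
    censor_time, and any requested covariate columns.  Also carries, for the
    ``allow_intervening`` semantics, a per-condition onset-time column
    ``t_<CODE>`` for every condition.
    """
    seq = persons.set_index("person_id")[["censor_time", *covariates]].copy()
    for r in (1, 2, 3):
        sub = trajectories.loc[trajectories["rank"] == r].set_index("person_id")
        seq[f"c{r}"] = sub["condition"]
        seq[f"t{r}"] = sub["onset_time"]
    wide = trajectories.pivot(index="person_id", columns="condition",
                              values="onset_time")
    for cond in CONDITIONS:
        col = wide[cond.value] if cond.value in wide.columns else np.nan
        seq[f"t_{cond.value}"] = col
    return seq.sort_index()


# sequence-derived columns stripped from the regression rows
_SEQ_COLUMNS = (
    ["c1", "t1", "c2", "t2", "c3", "t3"]
    + [f"t_{c.value}" for c in CONDITIONS]
)


def build_reference(
    seq: pd.DataFrame,
    outcome: str,
    window: float = 5.0,
    exclude_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Reference-arm rows: outcome as primary condition within the window.

    One row per eligible person (at least ``window`` years of follow-up),
    columns person_id, y, exposed (= 0), plus any covariate columns carried by
    ``seq``.  ``exclude_ids`` removes persons (used to keep arms disjoint).
    """
    eligible = seq.loc[seq["censor_time"] >= window]
    if exclude_ids is not None and len(exclude_ids) > 0:
        eligible = eligible.loc[~eligible.index.isin(set(exclude_ids))]
    if eligible.empty:
        raise ValueError("no eligible reference persons")
    y = ((eligible["c1"] == outcome) & (eligible["t1"] <= window)).fillna(False)
    out = eligible.drop(columns=_SEQ_COLUMNS).copy()
    out["y"] = y.astype(int)
    out["exposed"] = 0
    return out.reset_index()


def build_exposed(
    seq: pd.DataFrame,
    contrast: ProgressionContrast,
    anchor: str = "onset",
    allow_intervening: bool = False,
) -> pd.DataFrame:
    """Exposed-arm rows for one contrast; see the module docstring.

    Raises :class:`ValueError` when no person meets the exposure definition,
    so an inestimable contrast is reported rather than silently dropped.
    """
    if anchor not in ("onset", "entry"):
        raise ValueError("anchor must be 'onset' or 'entry'")
    w = contrast.window_years
    if contrast.secondary is None:
        sel = (
            (seq["c1"] == contrast.primary)
            & (seq["t1"] <= w)
            & (seq["censor_time"] - seq["t1"] >= w)
        ).fillna(False)
        t_last = seq["t1"]
        next_c, next_t = seq["c2"], seq["t2"]
    else:
        sel = (
            (seq["c1"] == contrast.primary)
            & (seq["c2"] == contrast.secondary)
            & (seq["t2"] <= w)
            & (seq["censor_time"] - seq["t2"] >= w)
        ).fillna(False)
        t_last = seq["t2"]
        next_c, next_t = seq["c3"], seq["t3"]

    sub = seq.loc[sel]
    if sub.empty:
        raise ValueError(f"no exposed persons for contrast {contrast.label}")
    start = t_last.loc[sel] if anchor == "onset" else 0.0
    if allow_intervening:
        t_out = sub[f"t_{contrast.outcome}"]
        y = ((t_out > t_last.loc[sel]) & (t_out - start <= w)).fillna(False)
    else:
        y = (
            (next_c.loc[sel] == contrast.outcome)
            & (next_t.loc[sel] - start <= w)
        ).fillna(False)
    out = sub.drop(columns=_SEQ_COLUMNS).copy()
    out["y"] = y.astype(int)
    out["exposed"] = 1
    return out.reset_index()


def _design(rows: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "exposed": rows["exposed"].astype(float)})
    if covariates:
        dummies = pd.get_dummies(
            rows[list(covariates)], drop_first=True, dtype=float
        )
        X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)],
                      axis=1)
    return X


def estimate_rr(
    contrast: ProgressionContrast,
    seq: pd.DataFrame,
    covariates: Sequence[str] = (),
    min_cell: int = 5,
    anchor: str = "onset",
    allow_intervening: bool = False,
) -> RREstimate:
    """Estimate the relative risk for one contrast.

    Stacks the reference and exposed rows (arms disjoint), fits the Poisson
    relative-risk model on the exposure indicator plus dummy-coded covariates,
    and returns the RR with its robust Wald 95% CI.  Contrasts with an empty
    exposure stratum or a zero case count in either arm are returned with
    ``estimable=False``; strata with fewer than ``min_cell`` persons set the
    ``suppressed`` flag.
    """
    try:
        exposed = build_exposed(
            seq, contrast, anchor=anchor, allow_intervening=allow_intervening
        )
    except ValueError:
        return RREstimate(
            contrast, 0, 0, 0, 0, np.nan, np.nan, np.nan, np.nan,
            suppressed=True, estimable=False,
        )
    reference = build_reference(
        seq, contrast.outcome, window=contrast.window_years,
        exclude_ids=exposed["person_id"].tolist(),
    )
    n1, n0 = len(exposed), len(reference)
    x1, x0 = int(exposed["y"].sum()), int(reference["y"].sum())
    suppressed = n1 < min_cell or n0 < min_cell
    if x1 == 0 or x0 == 0:
        return RREstimate(
            contrast, n1, n0, x1, x0, np.nan, np.nan, np.nan, np.nan,
            suppressed=suppressed, estimable=False,
        )

    rows = pd.concat([reference, exposed], ignore_index=True)
    # aggregate identical rows into frequency weights: same fit, much faster
    group_cols = ["exposed", "y", *covariates]
    agg = rows.groupby(group_cols, sort=True, observed=True).size().reset_index(name="w")
    X = _design(agg, covariates)
    try:
        fit = poisson_rr(agg["y"], X, freq_weights=agg["w"])
    except ConvergenceError:
        return RREstimate(
            contrast, n1, n0, x1, x0, np.nan, np.nan, np.nan, np.nan,
            suppressed=suppressed, estimable=False,
        )
    coef = float(fit.params["exposed"])
    ci = fit.conf_int(robust=True, exp=True).loc["exposed"]
    p = float(fit.p_values(robust=True)["exposed"])
    return RREstimate(
        contrast, n1, n0, x1, x0,
        rr=float(np.exp(coef)), ci_low=float(ci["lower"]),
        ci_high=float(ci["upper"]), p_value=p,
        suppressed=suppressed, estimable=True, fit=fit,
    )


RESULT_COLUMNS = [
    "exposure_primary", "exposure_secondary", "outcome",
    "n_exposed", "n_reference", "cases_exposed", "cases_reference",
    "rr", "ci_low", "ci_high", "p", "q", "suppressed", "estimable",
]


class ProgressionModel:
    """The progression relative-risk grid as a fittable model.

    Built from a trajectory table and a persons table; ``fit`` evaluates every
    primary -> secondary contrast (10 x 9) and every observed ordered
    (primary, secondary) -> tertiary contrast with at least ``min_exposed``
    exposed persons, then applies Benjamini-Hochberg across the combined
    family of estimable contrasts.

    Parameters
    ----------
    trajectories, persons
        Tables in the documented schemas.
    window_years
        Risk window (default 5.0).
    covariates
        Person columns to adjust for (dummy-coded).
    min_cell
        Small-cell suppression threshold on stratum person counts (default 5).
    min_exposed
        Minimum exposed persons for a pair exposure to enter the grid.
    anchor, allow_intervening
        Window anchoring and outcome semantics switches (module docstring).
    """

    def __init__(
        self,
        trajectories: pd.DataFrame,
        persons: pd.DataFrame,
        window_years: float = 5.0,
        covariates: Sequence[str] = (),
        min_cell: int = 5,
        min_exposed: int = 5,
        anchor: str = "onset",
        allow_intervening: bool = False,
    ):
        self.window_years = float(window_years)
        self.covariates = tuple(covariates)
        self.min_cell = int(min_cell)
        self.min_exposed = int(min_exposed)
        self.anchor = anchor
        self.allow_intervening = allow_intervening
        self.seq = person_sequences(trajectories, persons, covariates=self.covariates)

    def contrasts(self, include_tertiary: bool = True) -> list[ProgressionContrast]:
        """The contrast grid the model will evaluate."""
        w = self.window_years
        out = [
            ProgressionContrast(p.value, o.value, window_years=w)
            for p in CONDITIONS
            for o in CONDITIONS
            if p is not o
        ]
        if include_tertiary:
            seq = self.seq
            ok = (
                (seq["t2"] <= w)
                & (seq["censor_time"] - seq["t2"] >= w)
            ).fillna(False)
            pair_counts = (
                seq.loc[ok].groupby(["c1", "c2"], observed=True).size()
            )
            for (c1, c2), n in pair_counts.items():
                if n < self.min_exposed:
                    continue
                for o in CONDITIONS:
                    if o.value not in (c1, c2):
                        out.append(
                            ProgressionContrast(c1, o.value, secondary=c2,
                                                window_years=w)
                        )
        return out

    def estimate(self, contrast: ProgressionContrast) -> RREstimate:
        """Estimate a single contrast under the model's configuration."""
        return estimate_rr(
            contrast, self.seq, covariates=self.covariates,
            min_cell=self.min_cell, anchor=self.anchor,
            allow_intervening=self.allow_intervening,
        )

    def fit(self, fdr_q: float = 0.05, include_tertiary: bool = True
            ) -> "ProgressionResults":
        estimates = [self.estimate(c) for c in self.contrasts(include_tertiary)]
        estimable = [e for e in estimates if e.estimable]
        if estimable:
            reject, qvals = benjamini_hochberg(
                [e.p_value for e in estimable], q=fdr_q
            )
            for e, q in zip(estimable, qvals):
                e.q_value = float(q)
        return ProgressionResults(self, estimates, fdr_q)


class ProgressionResults:
    """Results of a fitted progression grid."""

    def __init__(self, model: ProgressionModel, estimates: list[RREstimate],
                 fdr_q: float):
        self.model = model
        self.fdr_q = fdr_q
        self._estimates = estimates

    @property
    def estimates(self) -> pd.DataFrame:
        """The complete raw view, one row per contrast."""
        rows = []
        for e in self._estimates:
            rows.append(
                {
                    "exposure_primary": e.contrast.primary,
                    "exposure_secondary": e.contrast.secondary or "",
                    "outcome": e.contrast.outcome,
                    "n_exposed": e.n_exposed,
                    "n_reference": e.n_reference,
                    "cases_exposed": e.cases_exposed,
                    "cases_reference": e.cases_reference,
                    "rr": e.rr,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p_value,
                    "q": np.nan if e.q_value is None else e.q_value,
                    "suppressed": e.suppressed,
                    "estimable": e.estimable,
                }
            )
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    @property
    def reported(self) -> pd.DataFrame:
        """FDR-significant, unsuppressed contrasts (the publishable view)."""
        df = self.estimates
        keep = df["estimable"] & ~df["suppressed"] & (df["q"] <= self.fdr_q)
        return df.loc[keep].reset_index(drop=True)

    @property
    def n_contrasts(self) -> int:
        return len(self._estimates)

    @property
    def n_estimable(self) -> int:
        return sum(e.estimable for e in self._estimates)

    def summary(self, max_rows: int = 30) -> str:
        rep = self.reported
        head = (
            f"Progression grid: {self.n_contrasts} contrasts "
            f"({self.n_estimable} estimable), window "
            f"{self.model.window_years} y, FDR q = {self.fdr_q}; "
            f"{len(rep)} reported after BH."
        )
        if rep.empty:
            return head + "\n(no FDR-significant contrasts)"
        shown = rep.sort_values("q").head(max_rows)
        cols = ["exposure_primary", "exposure_secondary", "outcome",
                "rr", "ci_low", "ci_high", "p", "q"]
        return head + "\n" + shown[cols].to_string(
            index=False, float_format=lambda v: f"{v:.4g}"
        )
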