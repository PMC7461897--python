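"""Ordinal condition sequencing: trajectories, cumulative incidence, gap times.

A person's conditions are ranked by onset time — the first is the primary
condition, then secondary, tertiary, quaternary, and so on (ranks beyond 4 are
computed and kept, labelled "5+" in summaries).  The gap time at rank 1 is the
time from study entry to the primary onset; at rank k >= 2 it is the time from
the previous onset to the current one, so gap times telescope to the final
onset time.

Exact onset-time ties cannot occur in the continuous-time simulator but can in
loaded claims-like data (same-day records).  Two tie rules are provided:

* ``canonical`` (default): tied events are ordered by the canonical condition
  ordering and both kept, flagged ``tied`` (their gap is 0 by construction);
* ``collapse``: only the canonically-first event of each same-time run is
  kept, flagged ``tied``.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .conditions import CONDITION_INDEX

TRAJECTORY_COLUMNS = ["person_id", "rank", "condition", "onset_time", "gap_time", "tied"]


class GapSummary(NamedTuple):
    median: float
    q1: float
    q3: float
    n: int


def assign_ranks(events: pd.DataFrame, tie_rule: str = "canonical") -> pd.DataFrame:
    """Build the trajectory table from post-baseline onset events.

    Parameters
    ----------
    events
        Columns person_id, condition, onset_time; all onset times positive;
        at most one row per (person, condition) — duplicates raise.
    tie_rule
        ``canonical`` or ``collapse`` (see module docstring).

    Returns
    -------
    DataFrame with columns person_id, rank, condition, onset_time, gap_time,
    tied, sorted by (person_id, rank).
    """
    if tie_rule not in ("canonical", "collapse"):
        raise ValueError(f"unknown tie_rule: {tie_rule!r}")
    if events.empty:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS).astype(
            {"person_id": np.int64, "rank": np.int64, "onset_time": float,
             "gap_time": float, "tied": bool}
        )
    dup = events.duplicated(subset=["person_id", "condition"])
    if dup.any():
        bad = events.loc[dup, ["person_id", "condition"]].iloc[0]
        raise ValueError(
            f"duplicate event for person {bad['person_id']} condition {bad['condition']}"
        )

    df = events[["person_id", "condition", "onset_time"]].copy()
    df["_ci"] = df["condition"].map(CONDITION_INDEX)
    if df["_ci"].isna().any():
        bad = df.loc[df["_ci"].isna(), "condition"].iloc[0]
        raise ValueError(f"unknown condition code: {bad!r}")
    df = df.sort_values(
        ["person_id", "onset_time", "_ci"], kind="mergesort"
    ).reset_index(drop=True)

    same_person = df["person_id"].eq(df["person_id"].shift())
    tied_prev = same_person & df["onset_time"].eq(df["onset_time"].shift())
    tied_next = tied_prev.shift(-1, fill_value=False) & df["person_id"].eq(
        df["person_id"].shift(-1)
    )
    df["tied"] = tied_prev | tied_next

    if tie_rule == "collapse":
        df = df.loc[~tied_prev].reset_index(drop=True)

    df["rank"] = df.groupby("person_id").cumcount() + 1
    prev_time = df.groupby("person_id")["onset_time"].shift()
    df["gap_time"] = df["onset_time"] - prev_time.fillna(0.0)

    out = df[TRAJECTORY_COLUMNS].copy()
    out["rank"] = out["rank"].astype(np.int64)
    return out


def count_with_at_least(trajectories: pd.DataFrame, k: int) -> int:
    """Number of persons with at least ``k`` onsets."""
    if trajectories.empty:
        return 0
    return int((trajectories.groupby("person_id")["rank"].max() >= k).sum())


def cumulative_incidence(
    trajectories: pd.DataFrame,
    n_at_risk: int,
    k: int,
    strict: bool = True,
    empty_as_zero: bool = False,
) -> float:
    """Proportion of the at-risk cohort with at least ``k`` condition onsets.

    ``strict`` restricts ``k`` to 1..4 (the ordinal ranks the analysis
    reports); with ``strict=False`` any positive ``k`` is allowed.  An empty
    cohort (``n_at_risk == 0``) raises unless ``empty_as_zero`` is set.
    """
    if strict and not 1 <= k <= 4:
        raise ValueError("k must be in 1..4 (strict mode)")
    if not strict and k < 1:
        raise ValueError("k must be >= 1")
    if n_at_risk == 0:
        if empty_as_zero:
            return 0.0
        raise ValueError("empty cohort: n_at_risk is 0")
    n_traj = trajectories["person_id"].nunique() if not trajectories.empty else 0
    if n_at_risk < n_traj:
        raise ValueError("n_at_risk smaller than the number of persons with events")
    return count_with_at_least(trajectories, k) / n_at_risk


def incidence_table(trajectories: pd.DataFrame, n_at_risk: int) -> pd.DataFrame:
    """Cumulative incidence of the primary..quaternary condition (k = 1..4)."""
    rows = [
        {
            "k": k,
            "n_with_k_or_more": count_with_at_least(trajectories, k),
            "cumulative_incidence": cumulative_incidence(trajectories, n_at_risk, k),
        }
        for k in (1, 2, 3, 4)
    ]
    return pd.DataFrame(rows)


def gap_summary(
    trajectories: pd.DataFrame,
    rank: int,
    person_ids: Sequence[int] | None = None,
) -> GapSummary:
    """Median and quartiles of the gap time at a given rank.

    Quartiles use linear interpolation between closest ranks (the NumPy
    default), a fixed documented convention.  ``person_ids`` optionally
    restricts to a stratum; an empty stratum raises.
    """
    sub = trajectories.loc[trajectories["rank"] == rank]
    if person_ids is not None:
        sub = sub.loc[sub["person_id"].isin(set(person_ids))]
    gaps = sub["gap_time"].to_numpy(dtype=float)
    if gaps.size == 0:
        raise ValueError(f"no trajectories at rank {rank} in the requested stratum")
    q1, med, q3 = np.percentile(gaps, [25, 50, 75], method="linear")
    return GapSummary(float(med), float(q1), float(q3), int(gaps.size))


def gap_summary_table(
    trajectories: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    ranks: Sequence[int] = (1, 2, 3, 4),
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Gap-time summaries per rank, optionally stratified by person covariates.

    ``by`` names columns of ``persons`` (e.g. gender, age_band); the overall
    (unstratified) rows are always included with stratum label "all".
    """
    rows = []

    def add_rows(label: str, ids: Sequence[int] | None) -> None:
        for r in ranks:
            try:
                s = gap_summary(trajectories, r, person_ids=ids)
            except ValueError:
                continue
            rows.append(
                {"stratum": label, "rank": r, "median": s.median,
                 "q1": s.q1, "q3": s.q3, "n": s.n}
            )

    add_rows("all", None)
    if by and persons is not None:
        for key, grp in persons.groupby(list(by), sort=True):
            key_t = key if isinstance(key, tuple) else (key,)
            label = "|".join(f"{c}={v}" for c, v in zip(by, key_t))
            add_rows(label, grp["person_id"].tolist())
    return pd.DataFrame(rows, columns=["stratum", "rank", "median", "q1", "q3", "n"])
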