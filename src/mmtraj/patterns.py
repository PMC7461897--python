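"""Multimorbidity pattern mining over ordinal trajectories.

Patterns are the conditions at ranks 1..k of each person with at least k
onsets, viewed either ordered (permutations: who came first matters) or
unordered (combinations: an unordered key aggregates all its orderings), at
condition level (10 codes) or group level (6 groups).  Group-level keys are
multisets: a person whose first two conditions are hypertension then
dyslipidemia contributes the key (CMD, CMD) — two concurrent cardiometabolic
disorders remain visible as such rather than collapsing to a single group.

Percentages are taken over the subpopulation with >= k conditions.  Rows with
fewer than ``min_count`` persons (default 5) are flagged ``suppressed`` and
withheld from public serializations, mirroring small-cell confidentiality
practice in claims data.

The module also provides the contribution-by-rank table and the two
categorical tests used on it (Pearson chi-square, Cochran-Armitage trend).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import (
    CONDITION_INDEX,
    CONDITION_TO_GROUP_NAME,
    CONDITIONS,
    GROUP_INDEX,
)
from .stats import TestResult

KEY_SEP = "|"


@dataclass
class PatternTable:
    """Counts and percentages of the first-k condition (or group) patterns."""

    k: int
    level: str
    ordered: bool
    n_eligible: int  # persons with >= k onsets
    min_count: int
    table: pd.DataFrame  # columns: pattern, count, pct, suppressed

    def to_frame(self, public: bool = False) -> pd.DataFrame:
        """The table as a DataFrame; ``public=True`` drops suppressed rows."""
        if public:
            return self.table.loc[~self.table["suppressed"]].reset_index(drop=True)
        return self.table.copy()


def _first_k_matrix(trajectories: pd.DataFrame, k: int) -> np.ndarray:
    """(n_persons, k) array of condition codes at ranks 1..k, eligible persons only."""
    sub = trajectories.loc[trajectories["rank"] <= k, ["person_id", "rank", "condition"]]
    counts = sub.groupby("person_id")["rank"].max()
    eligible = counts.index[counts >= k]
    sub = sub.loc[sub["person_id"].isin(eligible)]
    wide = sub.pivot(index="person_id", columns="rank", values="condition")
    return wide.sort_index().to_numpy(dtype=object)


def pattern_table(
    trajectories: pd.DataFrame,
    k: int,
    level: str = "condition",
    ordered: bool = False,
    min_count: int = 5,
) -> PatternTable:
    """Count the first-k patterns; see the module docstring for semantics."""
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3, or 4")
    if level not in ("condition", "group"):
        raise ValueError("level must be 'condition' or 'group'")

    mat = _first_k_matrix(trajectories, k)
    n_eligible = mat.shape[0]
    index = CONDITION_INDEX
    if level == "group":
        mat = np.vectorize(CONDITION_TO_GROUP_NAME.__getitem__, otypes=[object])(mat) \
            if n_eligible else mat
        index = GROUP_INDEX

    keys: list[tuple[str, ...]] = []
    for row in mat:
        key = tuple(row)
        if not ordered:
            key = tuple(sorted(key, key=index.__getitem__))
        keys.append(key)

    counter: dict[tuple[str, ...], int] = {}
    for key in keys:
        counter[key] = counter.get(key, 0) + 1

    rows = sorted(
        counter.items(),
        key=lambda kv: (-kv[1], tuple(index[c] for c in kv[0])),
    )
    table = pd.DataFrame(
        {
            "pattern": [KEY_SEP.join(key) for key, _ in rows],
            "count": [n for _, n in rows],
        }
    )
    table["pct"] = 100.0 * table["count"] / n_eligible if n_eligible else 0.0
    table["suppressed"] = table["count"] < min_count
    return PatternTable(
        k=k, level=level, ordered=ordered,
        n_eligible=n_eligible, min_count=min_count, table=table,
    )


def combination_of(pattern: str, level: str = "condition") -> str:
    """Canonical unordered key of an ordered pattern key."""
    index = CONDITION_INDEX if level == "condition" else GROUP_INDEX
    return KEY_SEP.join(sorted(pattern.split(KEY_SEP), key=index.__getitem__))


def contribution_by_rank(
    trajectories: pd.DataFrame, max_rank: int = 4
) -> pd.DataFrame:
    """Share of each condition among onsets at each rank 1..max_rank.

    Returns one row per (condition, rank) with count and the percentage of all
    onsets at that rank; per-rank percentages sum to 100.  All ten conditions
    appear at every rank (zero counts included) for stable output shape.
    """
    rows = []
    for rank in range(1, max_rank + 1):
        at_rank = trajectories.loc[trajectories["rank"] == rank, "condition"]
        total = len(at_rank)
        counts = at_rank.value_counts()
        for cond in CONDITIONS:
            c = int(counts.get(cond.value, 0))
            rows.append(
                {
                    "condition": cond.value,
                    "rank": rank,
                    "count": c,
                    "pct": 100.0 * c / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def chi_square_2xk(table) -> TestResult:
    """Pearson chi-square test of homogeneity on an r x c count table.

    Statistic sum (O - E)^2 / E with E from the product of the marginals;
    upper-tail p on (r-1)(c-1) degrees of freedom.  Zero marginals (hence
    zero expected cells) raise.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ValueError("zero marginal: expected counts must all be positive")
    expected = row @ col / total
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, p, "pearson chi-square", df=float(df), n=int(total))


def cochran_armitage(
    successes: Sequence[float],
    totals: Sequence[float],
    scores: Sequence[float] | None = None,
) -> TestResult:
    """Cochran-Armitage test for trend in proportions across ordered levels.

    Z = sum s_i (x_i - n_i pbar) / sqrt(pbar (1-pbar) (sum n_i s_i^2 -
    (sum n_i s_i)^2 / N)) with equally spaced integer scores 1..k by default;
    positive Z means proportions increase with the level.  Two-sided normal
    p-value.  All-success or all-failure inputs raise (zero null variance).
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.size != n.size:
        raise ValueError("successes and totals must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 ordered levels are required")
    if np.any(x < 0) or np.any(n <= 0) or np.any(x > n):
        raise ValueError("need 0 <= successes <= totals and positive totals")
    s = (
        np.arange(1, x.size + 1, dtype=float)
        if scores is None
        else np.asarray(scores, dtype=float)
    )
    big_n = n.sum()
    pbar = x.sum() / big_n
    if pbar in (0.0, 1.0):
        raise ValueError("all-success or all-failure input: trend undefined")
    num = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / big_n)
    z = num / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(float(z), min(p, 1.0), "cochran-armitage trend", n=int(big_n), z=float(z))


def pattern_test_table(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-condition tests on the contribution-by-rank table.

    For each condition: a 2x2 chi-square comparing its share among primary
    versus secondary onsets, and a Cochran-Armitage trend in its share across
    ranks 1..4.  Conditions whose tables are degenerate (zero marginals) get
    NaN entries rather than failing the whole table.
    """
    contrib = contribution_by_rank(trajectories)
    rank_totals = contrib.groupby("rank")["count"].sum()
    rows = []
    for cond in CONDITIONS:
        sub = contrib.loc[contrib["condition"] == cond.value].set_index("rank")
        c1, c2 = int(sub.loc[1, "count"]), int(sub.loc[2, "count"])
        t1, t2 = int(rank_totals.get(1, 0)), int(rank_totals.get(2, 0))
        try:
            chi = chi_square_2xk([[c1, t1 - c1], [c2, t2 - c2]])
            chi_stat, chi_p = chi.statistic, chi.p_value
        except ValueError:
            chi_stat, chi_p = np.nan, np.nan
        succ = [int(sub.loc[r, "count"]) for r in (1, 2, 3, 4)]
        tot = [int(rank_totals.get(r, 0)) for r in (1, 2, 3, 4)]
        try:
            ca = cochran_armitage(succ, tot)
            ca_z, ca_p = ca.statistic, ca.p_value
        except ValueError:
            ca_z, ca_p = np.nan, np.nan
        rows.append(
            {
                "condition": cond.value,
                "chi2_primary_vs_secondary": chi_stat,
                "chi2_p": chi_p,
                "trend_z": ca_z,
                "trend_p": ca_p,
            }
        )
    return pd.DataFrame(rows)
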