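"""End-to-end pipeline: simulate -> screen -> sequence -> patterns -> progression.

Each stage writes its declared delimited-text outputs under the run directory;
a ``manifest.json`` records the config hash, seed, schema version and per-file
row counts so a rerun with the same config and seed is byte-identical.  Any
stage failure removes the partially written run directory.
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, SCHEMA_VERSION, config_hash, config_to_dict
from .patterns import pattern_table, contribution_by_rank, pattern_test_table
from .progression import ProgressionModel
from .sequencing import assign_ranks, gap_summary_table, incidence_table
from .simulate import screen_baseline_free, simulate_cohort
from .validate import validate_tables

FLOAT_FORMAT = "%.10g"  # >= 6 significant digits, deterministic


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return len(df)


def write_progression_views(results, out_dir: Path) -> dict[str, int]:
    """Serialize the raw and reported progression views.

    Suppressed rows keep their estimates in the raw view but have their person
    and case counts withheld; the reported view contains only estimable,
    unsuppressed, FDR-significant rows.
    """
    raw = results.estimates.copy()
    masked = raw["suppressed"]
    for col in ("n_exposed", "n_reference", "cases_exposed", "cases_reference"):
        raw.loc[masked, col] = pd.NA
    counts = {}
    counts["progression_raw.csv"] = _write(raw, out_dir / "progression_raw.csv")
    counts["progression_reported.csv"] = _write(
        results.reported, out_dir / "progression_reported.csv"
    )
    return counts


def run_all(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute the full pipeline deterministically; returns the run directory."""
    config.validate()
    if seed is None:
        seed = config.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    log: list[str] = [f"seed={seed} (single top-level seed, split per person)"]
    try:
        log.append("stage=simulate")
        persons_raw, events_raw = simulate_cohort(config.cohort, config.hazards,
                                                  seed=seed)
        log.append("stage=screen_baseline_free")
        persons, events = screen_baseline_free(persons_raw, events_raw)
        counts["persons.csv"] = _write(persons, out / "persons.csv")
        counts["events.csv"] = _write(events, out / "events.csv")

        report = validate_tables(out / "persons.csv", out / "events.csv")
        if not report.ok:
            raise RuntimeError(f"internal schema violation:\n{report}")

        log.append("stage=sequence")
        traj = assign_ranks(events, tie_rule=config.analysis.tie_rule)
        counts["trajectories.csv"] = _write(traj, out / "trajectories.csv")
        counts["incidence.csv"] = _write(
            incidence_table(traj, len(persons)), out / "incidence.csv"
        )
        counts["gaps_summary.csv"] = _write(
            gap_summary_table(traj, persons, by=("gender", "age_band")),
            out / "gaps_summary.csv",
        )

        log.append("stage=patterns")
        for k in (2, 3, 4):
            for level in ("condition", "group"):
                for ordered in (False, True):
                    tab = pattern_table(
                        traj, k, level=level, ordered=ordered,
                        min_count=config.analysis.min_cell,
                    )
                    name = (
                        f"patterns_k{k}_{'cond' if level == 'condition' else 'group'}_"
                        f"{'ordered' if ordered else 'unordered'}.csv"
                    )
                    counts[name] = _write(tab.to_frame(public=True), out / name)
        counts["contribution_by_rank.csv"] = _write(
            contribution_by_rank(traj), out / "contribution_by_rank.csv"
        )
        counts["pattern_tests.csv"] = _write(
            pattern_test_table(traj), out / "pattern_tests.csv"
        )

        log.append("stage=progression")
        model = ProgressionModel(
            traj, persons,
            window_years=config.analysis.window_years,
            covariates=config.analysis.covariates,
            min_cell=config.analysis.min_cell,
        )
        results = model.fit(fdr_q=config.analysis.fdr_q)
        counts.update(write_progression_views(results, out))

        manifest = {
            "schema_version": SCHEMA_VERSION,
            "package_version": __version__,
            "config_hash": config_hash(config),
            "config": config_to_dict(config),
            "seed": seed,
            "row_counts": counts,
            "log": log,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out
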