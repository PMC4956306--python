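"""Selection rules, group statistics, metaphase index and mitotic timing.

The unit of analysis is the cell: per-cell mean SAC/CREST ratios are
compared between conditions, since replicate counts in this kind of
experiment are cells, not kinetochores.  Two selection rules mirror common
practice: for checkpoint proteins that are visibly retained only on a
subset of kinetochores (Mad1/Mad2/Zw10) the k brightest kinetochores are
analysed (default k=20, ranked by background-corrected SAC intensity);
for proteins retained everywhere (BubR1) all kinetochores are taken.

Group comparisons report per-condition mean +/- SEM of cell means, fold
change over control, and either a two-sided Welch t-test (two groups) or
one-way ANOVA with Tukey's HSD (more than two).  Significance stars follow
the usual thresholds: p < 0.05 "*", < 0.01 "**", < 0.001 "***", else "ns".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SelectionRule",
    "CellSummary",
    "GroupComparison",
    "TimingRecord",
    "MetaphaseCounts",
    "select_kinetochores",
    "summarize_cells",
    "compare_groups",
    "metaphase_index",
    "timing_summary",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class SelectionRule:
    """Which kinetochores of a cell enter the per-cell mean."""

    mode: str = "brightest_k"  # "brightest_k" | "all"
    k: int = 20
    rank_channel: str = "SAC"

    def __post_init__(self) -> None:
        if self.mode not in ("brightest_k", "all"):
            raise ValueError("mode must be 'brightest_k' or 'all'")
        if self.mode == "brightest_k" and self.k < 1:
            raise ValueError("k must be >= 1 for brightest_k")
        if self.rank_channel not in ("SAC", "CREST"):
            raise ValueError("rank_channel must be 'SAC' or 'CREST'")


@dataclass
class CellSummary:
    cell_id: str
    condition: str
    n_kts_used: int
    mean_ratio: float
    mean_distance_um: float = float("nan")
    under_k: bool = False


@dataclass
class GroupComparison:
    condition: str
    control: str
    n_control: int
    n_test: int
    mean_control: float
    sem_control: float
    mean_test: float
    sem_test: float
    fold_change: float
    test_name: str
    statistic: float
    df: float
    p_value: float
    stars: str


def select_kinetochores(
    measurements: pd.DataFrame, rule: SelectionRule | None = None
) -> tuple[pd.DataFrame, bool]:
    """Apply a selection rule to one cell's measurement table.

    Rows without a valid ratio (``crest_nonpositive``) are excluded first.
    ``brightest_k`` keeps the top k by corrected intensity on the rank
    channel, ties broken by the other channel's corrected intensity and
    then kt_id; with fewer than k valid rows all are kept and the under-k
    flag is returned.  An empty valid set is an error.
    """
    rule = rule or SelectionRule()
    valid = measurements[measurements["ratio"].notna() & ~measurements["crest_nonpositive"]]
    if len(valid) == 0:
        raise ValueError("no kinetochores with a valid SAC/CREST ratio")
    if rule.mode == "all":
        return valid, False
    primary = "corrected_sac" if rule.rank_channel == "SAC" else "corrected_crest"
    secondary = "corrected_crest" if rule.rank_channel == "SAC" else "corrected_sac"
    ranked = valid.sort_values(
        [primary, secondary, "kt_id"], ascending=[False, False, True], kind="stable"
    )
    return ranked.head(rule.k), len(valid) < rule.k


def summarize_cells(
    measurements: pd.DataFrame,
    rule: SelectionRule | None = None,
    distances: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-cell mean SAC/CREST ratio over the selected kinetochore subset.

    ``measurements`` is the pooled table (one row per kinetochore, with
    cell_id and condition columns); ``distances`` optionally maps cell_id to
    that cell's mean inter-kinetochore distance.
    """
    rule = rule or SelectionRule()
    rows = []
    for cell_id, group in measurements.groupby("cell_id", sort=True):
        subset, under_k = select_kinetochores(group, rule)
        rows.append(
            CellSummary(
                cell_id=str(cell_id),
                condition=str(group["condition"].iloc[0]),
                n_kts_used=len(subset),
                mean_ratio=float(subset["ratio"].mean()),
                mean_distance_um=(distances or {}).get(str(cell_id), float("nan")),
                under_k=under_k,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _group_values(cell_summaries: pd.DataFrame, value_col: str) -> dict[str, np.ndarray]:
    return {
        str(cond): grp[value_col].to_numpy(dtype=float)
        for cond, grp in cell_summaries.groupby("condition", sort=True)
    }


def compare_groups(
    cell_summaries: pd.DataFrame,
    control: str,
    test: str = "welch_t",
    value_col: str = "mean_ratio",
) -> list[GroupComparison]:
    """Compare each condition against control on per-cell means.

    ``welch_t``: two-sided unequal-variance t-test per condition pair.
    ``anova_tukey``: one-way ANOVA over all conditions; per-comparison
    p-values are Tukey-HSD adjusted, the reported statistic is the ANOVA F
    and df the residual degrees of freedom.  Fold change is the ratio of
    group means (test over control).  Every condition needs >= 2 cells.
    """
    groups = _group_values(cell_summaries, value_col)
    if control not in groups:
        raise ValueError(f"control condition {control!r} not present")
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 cells")
    others = [c for c in sorted(groups) if c != control]
    ctrl = groups[control]

    def sem(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1) / math.sqrt(len(v)))

    results: list[GroupComparison] = []
    if test == "welch_t":
        for cond in others:
            t = sps.ttest_ind(groups[cond], ctrl, equal_var=False)
            results.append(
                _comparison(cond, control, ctrl, groups[cond], "welch_t",
                            float(t.statistic), float(t.df), float(t.pvalue), sem)
            )
    elif test == "anova_tukey":
        all_conds = [control] + others
        values = np.concatenate([groups[c] for c in all_conds])
        labels = np.concatenate([[c] * len(groups[c]) for c in all_conds])
        f_stat, _ = sps.f_oneway(*[groups[c] for c in all_conds])
        tukey = pairwise_tukeyhsd(values, labels)
        summary = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        df_resid = float(len(values) - len(all_conds))
        for cond in others:
            row = summary[
                ((summary["group1"] == control) & (summary["group2"] == cond))
                | ((summary["group1"] == cond) & (summary["group2"] == control))
            ].iloc[0]
            results.append(
                _comparison(cond, control, ctrl, groups[cond], "anova_tukey",
                            float(f_stat), df_resid, float(row["p-adj"]), sem)
            )
    else:
        raise ValueError("test must be 'welch_t' or 'anova_tukey'")
    return results


def _comparison(cond, control, ctrl_vals, test_vals, name, stat, df, p, sem) -> GroupComparison:
    mean_c = float(np.mean(ctrl_vals))
    mean_t = float(np.mean(test_vals))
    return GroupComparison(
        condition=cond,
        control=control,
        n_control=len(ctrl_vals),
        n_test=len(test_vals),
        mean_control=mean_c,
        sem_control=sem(ctrl_vals),
        mean_test=mean_t,
        sem_test=sem(test_vals),
        fold_change=mean_t / mean_c if mean_c > 0 else float("nan"),
        test_name=name,
        statistic=stat,
        df=df,
        p_value=p,
        stars=significance_stars(p),
    )


# ---------------------------------------------------------------------------
# Metaphase index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaphaseCounts:
    """One replicate's count of metaphase cells among total living cells."""

    replicate: str
    condition: str
    n_metaphase: int
    n_total_living: int

    def __post_init__(self) -> None:
        if self.n_total_living <= 0:
            raise ValueError("n_total_living must be > 0")
        if not 0 <= self.n_metaphase <= self.n_total_living:
            raise ValueError("need 0 <= n_metaphase <= n_total_living")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_metaphase / self.n_total_living


def metaphase_index(counts: Iterable[MetaphaseCounts]) -> pd.DataFrame:
    """Metaphase index (% of living cells in metaphase) per condition.

    Per-replicate percentages are averaged across replicates; the spread is
    the sample SD (NaN with ``sd_available=False`` for a single replicate).
    """
    counts = list(counts)
    if not counts:
        raise ValueError("no replicate counts given")
    rows = []
    frame = pd.DataFrame(
        {"condition": [c.condition for c in counts], "percent": [c.percent for c in counts]}
    )
    for cond, grp in frame.groupby("condition", sort=True):
        vals = grp["percent"].to_numpy()
        rows.append(
            {
                "condition": cond,
                "n_replicates": len(vals),
                "mean_percent": float(vals.mean()),
                "sd_percent": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                "sd_available": len(vals) > 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mitotic timing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingRecord:
    """Annotated mitotic event times (minutes) for one filmed cell.

    All times share the movie clock; NEB (nuclear envelope breakdown) is
    the reference event.  A cell has at most one terminal event, anaphase
    onset or death; otherwise the movie ended with the cell still arrested.
    """

    cell_id: str
    condition: str
    t_neb_min: float
    movie_end_min: float
    t_anaphase_min: float | None = None
    t_death_min: float | None = None

    def __post_init__(self) -> None:
        if self.t_anaphase_min is not None and self.t_death_min is not None:
            raise ValueError(f"{self.cell_id}: at most one of anaphase/death may be set")
        for name in ("t_anaphase_min", "t_death_min"):
            t = getattr(self, name)
            if t is not None and t <= self.t_neb_min:
                raise ValueError(f"{self.cell_id}: {name} must be after NEB")
        if self.movie_end_min < self.t_neb_min:
            raise ValueError(f"{self.cell_id}: movie ends before NEB")


def timing_summary(
    records: Iterable[TimingRecord],
    arrest_threshold_min: float = 80.0,
    death_window_min: float = 240.0,
) -> pd.DataFrame:
    """Per-condition mitotic timing summary.

    * mean NEB-to-anaphase duration among cells that reached anaphase;
    * fraction of cells arrested in metaphase for >= ``arrest_threshold_min``
      (no anaphase by the threshold — including cells that later divide or
      die); assessed only on cells observable to the threshold, censored
      cells are excluded from the denominator and counted;
    * among arrested cells, the fraction dying later than
      ``death_window_min`` after NEB.
    """
    rows = []
    frame_rows: dict[str, list[TimingRecord]] = {}
    for rec in records:
        frame_rows.setdefault(rec.condition, []).append(rec)
    if not frame_rows:
        raise ValueError("no timing records given")
    for cond in sorted(frame_rows):
        recs = frame_rows[cond]
        durations = [
            r.t_anaphase_min - r.t_neb_min for r in recs if r.t_anaphase_min is not None
        ]
        arrested = 0
        assessable = 0
        censored = 0
        died_after_window = 0
        for r in recs:
            anaphase_delay = None if r.t_anaphase_min is None else r.t_anaphase_min - r.t_neb_min
            death_delay = None if r.t_death_min is None else r.t_death_min - r.t_neb_min
            observed = r.movie_end_min - r.t_neb_min
            if anaphase_delay is not None:
                assessable += 1
                if anaphase_delay >= arrest_threshold_min:
                    arrested += 1
            elif death_delay is not None and death_delay < arrest_threshold_min:
                assessable += 1  # left metaphase (died) before the threshold
            elif observed >= arrest_threshold_min:
                assessable += 1
                arrested += 1
                if death_delay is not None and death_delay > death_window_min:
                    died_after_window += 1
            else:
                censored += 1
        rows.append(
            {
                "condition": cond,
                "n_cells": len(recs),
                "n_anaphase": len(durations),
                "mean_neb_to_anaphase_min": float(np.mean(durations)) if durations else float("nan"),
                "n_assessable": assessable,
                "n_censored": censored,
                "fraction_arrested": arrested / assessable if assessable else float("nan"),
                "n_arrested": arrested,
                "fraction_death_after_arrest": died_after_window / arrested if arrested else float("nan"),
            }
        )
    return pd.DataFrame(rows)
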