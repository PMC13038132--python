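"""Descriptive analyses: serial-position curves, pre/post-item time, lags.

The central device for the gap experiments is the *signed lag*: the distance
of an item's serial position from the gap, negative for items presented
before it and positive for items after it (there is no lag 0).  With gap
positions 1..6 in a 7-item list the lags -5..-1 and +1..+5 are each
observable at several gap positions, so accuracy by lag x gap duration
separates proactive from retroactive effects of the extra free time.

The grouping-vs-time decomposition contrasts the three gap conditions of the
13-condition experiment cell-wise by lag: short_gap - no_gap isolates the
temporal-grouping effect, long_gap - short_gap the effect of extra free time
over and above grouping.

Error bars throughout are 95% within-subject confidence intervals
(Cousineau-Morey: subject-centered cell means, SEM corrected by
sqrt(C/(C-1)) for C cells).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from wmtime.data import KEY_COLUMNS
from wmtime.design import ISI_COLUMNS, N_ISIS, N_ITEMS, ExperimentDesign

__all__ = [
    "within_subject_ci",
    "serial_position_means",
    "pre_post_time_means",
    "lag_recode",
    "lag_table",
    "effect_decomposition",
]

GAP_DURATION = {"short_gap": "short", "long_gap": "long", "no_gap": "none"}
MAX_ABS_LAG = 5

_MEASURE_COLUMN = {"accuracy": "correct", "irt": "irt_ms"}


def within_subject_ci(
    cell_means: pd.DataFrame,
    subject: str = "subject_id",
    value: str = "value",
    level: float = 0.95,
) -> pd.DataFrame:
    """Within-subject CI halfwidths per cell from a subject x cell table.

    ``cell_means`` is long: one row per subject x cell, with the cell defined
    by every column other than ``subject`` and ``value``.  Subject means are
    removed (grand mean restored) before computing the per-cell SEM, which is
    then inflated by the Morey factor sqrt(C/(C-1)) for C cells and scaled by
    the two-sided t quantile.  A single subject yields zero halfwidths (with
    a warning): no between-replicate spread is estimable.
    """
    cell_cols = [c for c in cell_means.columns if c not in (subject, value)]
    if not cell_cols:
        raise ValueError("cell_means must contain at least one cell column")
    wide = cell_means.pivot_table(
        index=subject, columns=cell_cols, values=value, observed=True
    )
    n_subj, n_cells = wide.shape
    cells = wide.columns.to_frame(index=False)
    cells.columns = cell_cols
    if n_subj < 2:
        warnings.warn(
            "within-subject CI with a single subject: halfwidths set to 0",
            stacklevel=2,
        )
        cells["ci_halfwidth"] = 0.0
        return cells
    centered = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    morey = np.sqrt(n_cells / (n_cells - 1)) if n_cells > 1 else 1.0
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n_subj) * morey
    tq = stats.t.ppf(0.5 + level / 2.0, df=n_subj - 1)
    cells["ci_halfwidth"] = (tq * sem).to_numpy()
    return cells


def _subject_cell_means(
    data: pd.DataFrame, cell_cols: list[str], value: str
) -> pd.DataFrame:
    return (
        data.groupby(["subject_id", *cell_cols], as_index=False, observed=True)[value]
        .mean()
        .rename(columns={value: "value"})
    )


def _aggregate_with_ci(
    data: pd.DataFrame, cell_cols: list[str], value: str, level: float
) -> pd.DataFrame:
    """Mean over subject means plus within-subject CI, by cell."""
    per_subject = _subject_cell_means(data, cell_cols, value)
    means = (
        per_subject.groupby(cell_cols, as_index=False, observed=True)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )
    n = (
        data.groupby(cell_cols, as_index=False, observed=True)[value]
        .count()
        .rename(columns={value: "n"})
    )
    ci = within_subject_ci(per_subject, subject="subject_id", value="value", level=level)
    out = means.merge(n, on=cell_cols).merge(ci, on=cell_cols)
    return out.sort_values(cell_cols, ignore_index=True)


def serial_position_means(data: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Mean accuracy by condition x serial position with within-subject CIs."""
    if len(data) == 0:
        raise ValueError("empty recall dataset")
    out = _aggregate_with_ci(
        data, ["condition", "serial_position"], "correct", level
    )
    return out.rename(columns={"mean": "mean_accuracy"})


def pre_post_time_means(
    data: pd.DataFrame,
    design: ExperimentDesign | pd.DataFrame,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy by pre-item and by post-item time in the long-variable trials.

    The pre-item time of item i is the ISI before it plus the presentation
    duration (onset-asynchrony-style), and the post-item time is the ISI
    after it plus the presentation duration; with 50..1950 ms ISIs and 250 ms
    presentations both span 0.3 to 2.2 s in six levels.  Serial positions 1
    (no pre-item time) and 7 (no post-item time) are dropped before
    aggregation.  Returns ``(pre_table, post_table)``.
    """
    if not (data["condition"] == "long_variable").all():
        bad = sorted(set(data["condition"]) - {"long_variable"})
        raise ValueError(f"expected only long_variable trials, also got {bad}")
    trials = design.trials if isinstance(design, ExperimentDesign) else design
    merged = data.merge(
        trials[KEY_COLUMNS + ISI_COLUMNS + ["presentation_ms"]],
        on=KEY_COLUMNS,
        validate="many_to_one",
    )
    merged = merged[~merged["serial_position"].isin([1, N_ITEMS])].copy()
    isis = merged[ISI_COLUMNS].to_numpy()
    pos = merged["serial_position"].to_numpy()
    pres = merged["presentation_ms"].to_numpy()
    rows = np.arange(len(merged))
    merged["pre_time_s"] = (isis[rows, pos - 2] + pres) / 1000.0
    merged["post_time_s"] = (isis[rows, pos - 1] + pres) / 1000.0
    pre = _aggregate_with_ci(merged, ["pre_time_s"], "correct", level).rename(
        columns={"mean": "mean_accuracy"}
    )
    post = _aggregate_with_ci(merged, ["post_time_s"], "correct", level).rename(
        columns={"mean": "mean_accuracy"}
    )
    return pre, post


def lag_recode(data: pd.DataFrame) -> pd.DataFrame:
    """Add a signed-lag column to gap-experiment data.

    lag = position - gap_position - 1 for items at or before the gap,
    position - gap_position after it; the item just before the gap is lag -1
    and the item just after it lag +1.  No-gap rows get a missing lag.
    """
    out = data.copy()
    is_gap = out["condition"].isin(["short_gap", "long_gap"])
    if out.loc[is_gap, "gap_position"].isna().any():
        raise ValueError("gap trials with missing gap_position")
    gap = out["gap_position"].to_numpy(dtype=float, na_value=np.nan)
    pos = out["serial_position"].to_numpy(dtype=float)
    lag = np.where(pos <= gap, pos - gap - 1, pos - gap)
    lag[~is_gap.to_numpy()] = np.nan
    out["lag"] = pd.array(lag, dtype="Int64")
    return out


def _pseudo_gap_expand(no_gap: pd.DataFrame) -> pd.DataFrame:
    """Replicate no-gap trials across all six pseudo-gap positions.

    The no-gap baseline has no gap to anchor a lag, so each trial is aligned
    to every possible gap position in turn and the copies are averaged by the
    downstream aggregation; this mirrors how gap trials sample each lag from
    several gap positions.
    """
    copies = []
    for g in range(1, N_ISIS + 1):
        c = no_gap.copy()
        c["gap_position"] = g
        copies.append(c)
    out = pd.concat(copies, ignore_index=True)
    gap = out["gap_position"].to_numpy(dtype=float)
    pos = out["serial_position"].to_numpy(dtype=float)
    lag = np.where(pos <= gap, pos - gap - 1, pos - gap)
    out["lag"] = pd.array(lag, dtype="Int64")
    return out


def _lag_frame(data: pd.DataFrame, value: str) -> pd.DataFrame:
    """Recoded long table with gap_duration and lag, clipped to +/-5."""
    gap_rows = data[data["condition"].isin(["short_gap", "long_gap"])]
    parts = [lag_recode(gap_rows)] if len(gap_rows) else []
    no_gap = data[data["condition"] == "no_gap"]
    if len(no_gap):
        parts.append(_pseudo_gap_expand(no_gap))
    out = pd.concat(parts, ignore_index=True)
    out["gap_duration"] = out["condition"].map(GAP_DURATION)
    out = out[out["lag"].abs() <= MAX_ABS_LAG]
    return out.dropna(subset=[value])


def lag_table(
    data: pd.DataFrame, measure: str = "accuracy", level: float = 0.95
) -> pd.DataFrame:
    """Mean accuracy (or IRT) by gap duration x signed lag, with CIs.

    Lags beyond +/-5 (reachable only from gap positions 1 and 6) are
    excluded, leaving the ten lags -5..-1, +1..+5 per gap duration.
    """
    value = _MEASURE_COLUMN[measure]
    frame = _lag_frame(data, value)
    out = _aggregate_with_ci(frame, ["gap_duration", "lag"], value, level)
    return out.rename(columns={"mean": f"mean_{measure}"})


def effect_decomposition(
    data: pd.DataFrame, measure: str = "accuracy", level: float = 0.95
) -> pd.DataFrame:
    """Grouping and time effects by lag: short-no_gap and long-short.

    Requires all three gap conditions.  Effects are formed within subject
    (difference of the subject's cell means), then averaged, with
    within-subject CIs on each difference.
    """
    value = _MEASURE_COLUMN[measure]
    present = set(data["condition"].unique())
    missing = {"short_gap", "long_gap", "no_gap"} - present
    if missing:
        raise ValueError(f"missing conditions for decomposition: {sorted(missing)}")
    frame = _lag_frame(data, value)
    per_subject = _subject_cell_means(frame, ["gap_duration", "lag"], value)
    wide = per_subject.pivot_table(
        index=["subject_id", "lag"], columns="gap_duration", values="value"
    ).reset_index()
    wide["grouping_effect"] = wide["short"] - wide["none"]
    wide["time_effect"] = wide["long"] - wide["short"]
    out = (
        wide.groupby("lag", as_index=False)[["grouping_effect", "time_effect"]]
        .mean()
        .sort_values("lag", ignore_index=True)
    )
    for effect in ("grouping_effect", "time_effect"):
        ci = within_subject_ci(
            wide[["subject_id", "lag", effect]].rename(columns={effect: "value"}),
            level=level,
        )
        out = out.merge(
            ci.rename(columns={"ci_halfwidth": f"{effect}_ci"}), on="lag"
        )
    return out
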