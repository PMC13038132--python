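"""Trial tables and millisecond timelines for the three serial-recall experiments.

Three experiments manipulate the free time between the seven consonants of an
immediate-serial-recall list:

* **Experiment 1** varies whole-list pacing: all six interstimulus intervals
  (ISIs) short (50 ms, ``short_fixed``), all long (870 ms, ``long_fixed``),
  or a within-list permutation of six durations from 50 to 1950 ms
  (``long_variable``) whose sum (5200 ms) approximately matches the
  long-fixed sum (5220 ms).
* **Experiments 2a/2b** insert a single deviant ISI (a temporal *gap*) of
  500 ms (``short_gap``) or 2500 ms (``long_gap``) after one of the first six
  items, against a background of 50-ms ISIs; 2b adds a ``no_gap`` baseline.

Designs are tidy pandas tables, bitwise-reproducible from
``(experiment, n_subjects, seed)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONSONANT_POOL",
    "VARIABLE_ISIS_MS",
    "N_ITEMS",
    "N_ISIS",
    "TrialSpec",
    "PresentationSchedule",
    "ExperimentDesign",
    "sample_list_letters",
    "assign_variable_orders",
    "build_exp1_design",
    "build_exp2_design",
    "schedule_for_trial",
    "write_design_csv",
    "read_design_csv",
]

#: The 21 consonants of the German alphabet, the letter pool for all lists.
CONSONANT_POOL: tuple[str, ...] = tuple("BCDFGHJKLMNPQRSTVWXYZ")

#: The six ISI durations of the long-variable condition (ms).
VARIABLE_ISIS_MS: tuple[int, ...] = (50, 250, 550, 950, 1450, 1950)

#: All 720 orderings of the six variable ISIs, in lexicographic order.
ISI_PERMUTATIONS: tuple[tuple[int, ...], ...] = tuple(
    itertools.permutations(VARIABLE_ISIS_MS)
)

N_ITEMS = 7
N_ISIS = 6

STANDARD_ISI_MS = 50
LONG_FIXED_ISI_MS = 870
SHORT_GAP_MS = 500
LONG_GAP_MS = 2500
FIXATION_MS = 500

EXP1_CONDITIONS = ("short_fixed", "long_fixed", "long_variable")
GAP_CONDITIONS = ("short_gap", "long_gap")

_EXP_TIMING = {
    # experiment -> (presentation_ms, retention_ms)
    "exp1": (250, 1250),
    "exp2a": (300, 1000),
    "exp2b": (300, 1000),
}

ISI_COLUMNS = [f"isi{i}" for i in range(1, N_ISIS + 1)]

DESIGN_COLUMNS = [
    "experiment_id",
    "subject_id",
    "block",
    "trial",
    "condition",
    "gap_position",
    *ISI_COLUMNS,
    "presentation_ms",
    "retention_ms",
    "letters",
]


@dataclass(frozen=True)
class TrialSpec:
    """One trial's condition labels and millisecond timing parameters."""

    experiment_id: str
    subject_id: int
    block: int
    trial: int
    condition: str
    isis_ms: tuple[int, ...]
    presentation_ms: int
    retention_ms: int
    gap_position: int | None = None
    list_letters: str | None = None

    def __post_init__(self) -> None:
        if len(self.isis_ms) != N_ISIS:
            raise ValueError(
                f"expected {N_ISIS} ISIs for a {N_ITEMS}-item list, "
                f"got {len(self.isis_ms)}"
            )
        if any(isi < 0 for isi in self.isis_ms):
            raise ValueError(f"ISIs must be nonnegative, got {self.isis_ms}")
        has_gap = self.condition in GAP_CONDITIONS
        if has_gap and self.gap_position is None:
            raise ValueError(f"{self.condition} trial requires a gap_position")
        if not has_gap and self.gap_position is not None:
            raise ValueError(
                f"gap_position given for non-gap condition {self.condition!r}"
            )

    @classmethod
    def from_row(cls, row) -> "TrialSpec":
        """Build a TrialSpec from one row of a tidy design table."""
        gap = row["gap_position"]
        gap = None if pd.isna(gap) else int(gap)
        letters = row.get("letters") if hasattr(row, "get") else row["letters"]
        return cls(
            experiment_id=str(row["experiment_id"]),
            subject_id=int(row["subject_id"]),
            block=int(row["block"]),
            trial=int(row["trial"]),
            condition=str(row["condition"]),
            isis_ms=tuple(int(row[c]) for c in ISI_COLUMNS),
            presentation_ms=int(row["presentation_ms"]),
            retention_ms=int(row["retention_ms"]),
            gap_position=gap,
            list_letters=None if letters is None or pd.isna(letters) else str(letters),
        )


@dataclass(frozen=True)
class PresentationSchedule:
    """Event timeline of one trial's encoding phase, in seconds.

    Onsets are measured from the onset of the first list item; the 500-ms
    fixation that precedes it is recorded in ``fixation_s`` but takes no part
    in any model computation.
    """

    onsets_s: np.ndarray
    offsets_s: np.ndarray
    isis_s: np.ndarray
    retention_s: float
    fixation_s: float = FIXATION_MS / 1000.0

    @property
    def presentation_s(self) -> float:
        return float(self.offsets_s[0] - self.onsets_s[0])

    @property
    def encoding_duration_s(self) -> float:
        """Total span of the encoding phase: 7 presentations + 6 ISIs."""
        return float(N_ITEMS * self.presentation_s + self.isis_s.sum())


@dataclass
class ExperimentDesign:
    """Full trial table for one experiment, all subjects."""

    experiment_id: str
    n_subjects: int
    seed: int
    trials: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.trials)

    def trials_for_subject(self, subject_id: int) -> pd.DataFrame:
        return self.trials[self.trials["subject_id"] == subject_id]


def sample_list_letters(seed: int | np.random.Generator) -> str:
    """Draw 7 distinct consonants without replacement from the 21-letter pool."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(rng.choice(CONSONANT_POOL, size=N_ITEMS, replace=False))


def assign_variable_orders(
    n_subjects: int, trials_per_subject: int, seed: int
) -> np.ndarray:
    """Assign ISI orderings to (subject, trial) slots with maximally even use.

    Deals permutation indices from repeatedly reshuffled full cycles of all
    720 orderings, so across all ``n_subjects * trials_per_subject`` slots the
    usage counts of the 720 orderings differ by at most one.  With 20 subjects
    and 36 variable-ISI trials each, every ordering is used exactly once.

    Returns an ``(n_subjects, trials_per_subject)`` integer array of indices
    into :data:`ISI_PERMUTATIONS`.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be positive, got {n_subjects}")
    if trials_per_subject < 1:
        raise ValueError(
            f"trials_per_subject must be positive, got {trials_per_subject}"
        )
    rng = np.random.default_rng(seed)
    total = n_subjects * trials_per_subject
    n_perms = len(ISI_PERMUTATIONS)
    cycles = []
    while sum(len(c) for c in cycles) < total:
        cycles.append(rng.permutation(n_perms))
    flat = np.concatenate(cycles)[:total]
    return flat.reshape(n_subjects, trials_per_subject)


def _isis_for_condition(
    condition: str, gap_position: int | None, perm_index: int | None
) -> tuple[int, ...]:
    if condition in ("short_fixed", "no_gap"):
        return (STANDARD_ISI_MS,) * N_ISIS
    if condition == "long_fixed":
        return (LONG_FIXED_ISI_MS,) * N_ISIS
    if condition == "long_variable":
        return ISI_PERMUTATIONS[perm_index]
    if condition in GAP_CONDITIONS:
        gap_ms = SHORT_GAP_MS if condition == "short_gap" else LONG_GAP_MS
        isis = [STANDARD_ISI_MS] * N_ISIS
        isis[gap_position - 1] = gap_ms
        return tuple(isis)
    raise ValueError(f"unknown condition {condition!r}")


def _finish_design(
    experiment_id: str, rows: list[dict], n_subjects: int, seed: int
) -> ExperimentDesign:
    trials = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    trials["gap_position"] = trials["gap_position"].astype("Int64")
    return ExperimentDesign(
        experiment_id=experiment_id,
        n_subjects=n_subjects,
        seed=seed,
        trials=trials,
    )


def build_exp1_design(n_subjects: int, seed: int) -> ExperimentDesign:
    """Experiment 1: 6 blocks x 18 trials, 3 pacing conditions, 36 trials each.

    Each block holds 6 trials per condition in random order.  The
    long-variable ISI orderings are dealt by :func:`assign_variable_orders`
    so that across 20 subjects each of the 720 orderings occurs exactly once.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be positive, got {n_subjects}")
    presentation_ms, retention_ms = _EXP_TIMING["exp1"]
    n_blocks, per_block = 6, 6  # 6 blocks x (6 trials x 3 conditions)
    orders = assign_variable_orders(n_subjects, n_blocks * per_block, seed)
    rows: list[dict] = []
    for s in range(1, n_subjects + 1):
        rng = np.random.default_rng([seed, s])
        order_iter = iter(orders[s - 1])
        for block in range(1, n_blocks + 1):
            conditions = rng.permutation(np.repeat(EXP1_CONDITIONS, per_block))
            for t, condition in enumerate(conditions, start=1):
                perm_index = (
                    int(next(order_iter)) if condition == "long_variable" else None
                )
                isis = _isis_for_condition(condition, None, perm_index)
                rows.append(
                    {
                        "experiment_id": "exp1",
                        "subject_id": s,
                        "block": block,
                        "trial": t,
                        "condition": condition,
                        "gap_position": pd.NA,
                        **dict(zip(ISI_COLUMNS, isis)),
                        "presentation_ms": presentation_ms,
                        "retention_ms": retention_ms,
                        "letters": sample_list_letters(rng),
                    }
                )
    return _finish_design("exp1", rows, n_subjects, seed)


def build_exp2_design(variant: str, n_subjects: int, seed: int) -> ExperimentDesign:
    """Experiments 2a/2b: a single gap at one of six positions, short or long.

    Variant ``a``: 8 blocks x 36 trials, 12 conditions (6 gap positions x
    2 gap durations), 3 trials each per block.  Variant ``b`` adds a no-gap
    baseline (13 conditions, 8 blocks x 39 trials).
    """
    if variant not in ("a", "b"):
        raise ValueError(f"variant must be 'a' or 'b', got {variant!r}")
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be positive, got {n_subjects}")
    experiment_id = f"exp2{variant}"
    presentation_ms, retention_ms = _EXP_TIMING[experiment_id]
    cells: list[tuple[str, int | None]] = [
        (cond, gap) for cond in GAP_CONDITIONS for gap in range(1, N_ISIS + 1)
    ]
    if variant == "b":
        cells.append(("no_gap", None))
    n_blocks, per_cell = 8, 3
    rows: list[dict] = []
    for s in range(1, n_subjects + 1):
        rng = np.random.default_rng([seed, 2 if variant == "a" else 3, s])
        for block in range(1, n_blocks + 1):
            block_cells = list(cells) * per_cell
            order = rng.permutation(len(block_cells))
            for t, idx in enumerate(order, start=1):
                condition, gap = block_cells[idx]
                isis = _isis_for_condition(condition, gap, None)
                rows.append(
                    {
                        "experiment_id": experiment_id,
                        "subject_id": s,
                        "block": block,
                        "trial": t,
                        "condition": condition,
                        "gap_position": pd.NA if gap is None else gap,
                        **dict(zip(ISI_COLUMNS, isis)),
                        "presentation_ms": presentation_ms,
                        "retention_ms": retention_ms,
                        "letters": sample_list_letters(rng),
                    }
                )
    return _finish_design(experiment_id, rows, n_subjects, seed)


def schedule_for_trial(trial: TrialSpec) -> PresentationSchedule:
    """Convert a trial's condition timing into an event timeline in seconds."""
    isis_s = np.asarray(trial.isis_ms, dtype=float) / 1000.0
    if isis_s.shape != (N_ISIS,) or np.any(isis_s < 0):
        raise ValueError(f"malformed ISI vector: {trial.isis_ms}")
    pres_s = trial.presentation_ms / 1000.0
    onsets = np.empty(N_ITEMS)
    onsets[0] = 0.0
    # onset_{i+1} = offset_i + isi_i
    onsets[1:] = np.cumsum(pres_s + isis_s)
    offsets = onsets + pres_s
    return PresentationSchedule(
        onsets_s=onsets,
        offsets_s=offsets,
        isis_s=isis_s,
        retention_s=trial.retention_ms / 1000.0,
    )


def write_design_csv(design: ExperimentDesign, path) -> None:
    design.trials.to_csv(path, index=False)


def read_design_csv(path) -> ExperimentDesign:
    trials = pd.read_csv(path)
    trials["gap_position"] = trials["gap_position"].astype("Int64")
    experiment_id = str(trials["experiment_id"].iloc[0])
    n_subjects = int(trials["subject_id"].nunique())
    # the seed is not recoverable from a CSV; callers track it via manifests
    return ExperimentDesign(
        experiment_id=experiment_id, n_subjects=n_subjects, seed=-1, trials=trials
    )
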