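"""Trial-level synthetic recall data with the structure the analyses assume.

`simulate_accuracy` draws binary serial-recall outcomes from the
encoding-resource model's per-position probabilities, optionally with
between-subject heterogeneity (a normal offset on each subject's logistic
threshold tau).  `simulate_irt` builds a descriptive interresponse-time (IRT)
fixture embodying the temporal-grouping signature — a sharp IRT increase at
the output position just after the gap, equal in expectation for short and
long gaps — which the model itself does not produce (it predicts no RTs).

An item is scored correct only when recalled in its own output position
(strict positional scoring, `score_serial_recall`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from wmtime.design import N_ITEMS, ExperimentDesign
from wmtime.model import ModelParams, resource_matrix, free_time_matrix
from scipy.special import expit

__all__ = [
    "simulate_accuracy",
    "simulate_irt",
    "score_serial_recall",
    "write_recall_csv",
    "read_recall_csv",
    "validate_recall_dataset",
]

KEY_COLUMNS = ["experiment_id", "subject_id", "block", "trial"]
DATA_COLUMNS = KEY_COLUMNS + ["condition", "gap_position", "serial_position", "correct"]


def _long_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Expand a trial table to one row per trial x serial position."""
    n = len(trials)
    rep = trials.loc[
        trials.index.repeat(N_ITEMS),
        KEY_COLUMNS + ["condition", "gap_position"],
    ].reset_index(drop=True)
    rep["serial_position"] = np.tile(np.arange(1, N_ITEMS + 1), n)
    return rep


def simulate_accuracy(
    design: ExperimentDesign,
    params: ModelParams,
    subject_sd: float = 0.0,
    seed: int = 0,
    time_definition: str = "isi",
) -> pd.DataFrame:
    """Draw Bernoulli recall outcomes from the model for every design trial.

    ``subject_sd`` > 0 offsets each subject's tau by a normal deviate with
    that standard deviation, a minimal between-subject heterogeneity knob
    (default 0: all subjects share the generating parameters).
    """
    if subject_sd < 0:
        raise ValueError(f"subject_sd must be >= 0, got {subject_sd}")
    rng = np.random.default_rng(seed)
    trials = design.trials
    # strengths depend only on (p, r); the subject offset shifts tau alone
    strengths = params.p * resource_matrix(
        free_time_matrix(trials, time_definition), params
    )
    subjects = np.sort(trials["subject_id"].unique())
    offsets = dict(
        zip(subjects.tolist(), rng.normal(0.0, subject_sd, size=len(subjects)))
    )
    tau_per_trial = params.tau + trials["subject_id"].map(offsets).to_numpy()
    probs = expit(params.gain * (strengths - tau_per_trial[:, None]))
    correct = rng.random(probs.shape) < probs
    out = _long_frame(trials)
    out["correct"] = correct.ravel().astype(np.int64)
    return out


def simulate_irt(
    design: ExperimentDesign,
    base_irt_ms: float = 400.0,
    group_boundary_bump_ms: float = 300.0,
    noise_sd_ms: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Descriptive IRT fixture with an equal post-gap spike for both gaps.

    irt = base + bump * [output position == gap_position + 1] + noise.
    The bump is applied identically on short-gap and long-gap trials and
    never on no-gap trials, mirroring the conjecture that both gap durations
    induce temporal grouping to the same degree.  ``correct`` is left missing:
    this is an RT fixture, not a model output.
    """
    if base_irt_ms <= 0:
        raise ValueError(f"base_irt_ms must be positive, got {base_irt_ms}")
    if group_boundary_bump_ms < 0 or noise_sd_ms < 0:
        raise ValueError("bump and noise durations must be nonnegative")
    rng = np.random.default_rng(seed)
    out = _long_frame(design.trials)
    gap = out["gap_position"].to_numpy(dtype=float, na_value=np.nan)
    is_boundary = out["serial_position"].to_numpy() == gap + 1
    irt = base_irt_ms + group_boundary_bump_ms * is_boundary
    irt = irt + rng.normal(0.0, noise_sd_ms, size=len(out))
    out["correct"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["irt_ms"] = irt
    return out


def score_serial_recall(responses, targets) -> np.ndarray:
    """Strict positional scoring: 1 where response matches target in place."""
    responses = list(responses)
    targets = list(targets)
    if len(responses) != N_ITEMS or len(targets) != N_ITEMS:
        raise ValueError(
            f"responses and targets must each have {N_ITEMS} letters, "
            f"got {len(responses)} and {len(targets)}"
        )
    return np.array(
        [int(r == t) for r, t in zip(responses, targets)], dtype=np.int64
    )


def validate_recall_dataset(data: pd.DataFrame) -> None:
    """Check the tidy recall-data contract: 7 rows per trial, binary scoring."""
    missing = [c for c in DATA_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"recall dataset is missing columns: {missing}")
    counts = data.groupby(KEY_COLUMNS, dropna=False).size()
    if not (counts == N_ITEMS).all():
        bad = counts[counts != N_ITEMS]
        raise ValueError(
            f"every trial must have exactly {N_ITEMS} rows; offending trials:\n{bad}"
        )
    observed = data["correct"].dropna()
    if not observed.isin([0, 1]).all():
        raise ValueError("correct must be binary (0/1) where present")


def write_recall_csv(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_recall_csv(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    data["gap_position"] = data["gap_position"].astype("Int64")
    data["correct"] = data["correct"].astype("Int64")
    return data
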