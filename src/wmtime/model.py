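"""Gradually recovering encoding-resource model of serial recall.

Each trial starts with the resource at its ceiling ``R_max``.  Encoding item
``i`` instantaneously consumes a fixed proportion ``p`` of the currently
available resource ``R_i``; the consumed amount ``p * R_i`` is the item's
memory strength.  During the free interitem time ``t_i`` that follows item
``i`` the resource recovers linearly at rate ``r`` per second, capped at the
ceiling:

    R_1     = R_max
    R_{i+1} = min(R_max, (1 - p) * R_i + r * t_i)

Memory strength is converted to recall probability by a logistic function
with slope ``gain`` and threshold ``tau``:

    P(recall_i) = 1 / (1 + exp(-gain * (p * R_i - tau)))

Recovery acts only forward in time, so extra free time helps every later
item (a *global, proactive* benefit) and no earlier one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from wmtime.design import (
    ISI_COLUMNS,
    N_ISIS,
    N_ITEMS,
    ExperimentDesign,
    PresentationSchedule,
)

__all__ = [
    "ModelParams",
    "DEFAULT_PARAMS",
    "ResourceTrajectory",
    "resource_trajectory",
    "recall_probability",
    "predict_trial",
    "predict_design",
    "predict_condition_means",
    "free_time_matrix",
]

TIME_DEFINITIONS = ("isi", "isi_plus_presentation")


@dataclass(frozen=True)
class ModelParams:
    """The four free parameters plus the fixed resource ceiling.

    Parameters
    ----------
    p : proportion of the available resource consumed per encoded item,
        in (0, 1).
    r : resource recovery rate per second of free time, >= 0.
    gain : slope of the logistic strength-to-probability mapping, > 0.
    tau : threshold of the logistic mapping (strength at which recall
        probability is 0.5).
    r_max : resource ceiling; fixed at 1 by convention since its scale is
        absorbed by ``p`` and ``tau``.
    """

    p: float = 0.23
    r: float = 0.11
    gain: float = 13.0
    tau: float = 0.11
    r_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if self.r < 0.0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        if self.gain <= 0.0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.r_max <= 0.0:
            raise ValueError(f"r_max must be > 0, got {self.r_max}")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        """Read parameters from a flat JSON or YAML key-value file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")


#: Simulation parameter values: p=.23, r=.11, gain=13, tau=.11, r_max=1.
DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class ResourceTrajectory:
    """Resource available at each encoding event and resulting strengths."""

    available: np.ndarray  # R_i, one per serial position
    strengths: np.ndarray  # p * R_i


def resource_matrix(free_time_s: np.ndarray, params: ModelParams) -> np.ndarray:
    """Available resource per position for a batch of trials.

    ``free_time_s`` has shape ``(n_trials, 6)``; returns ``(n_trials, 7)``.
    """
    t = np.atleast_2d(np.asarray(free_time_s, dtype=float))
    if t.shape[1] != N_ISIS:
        raise ValueError(f"expected {N_ISIS} free-time intervals, got {t.shape[1]}")
    if np.any(t < 0):
        raise ValueError("free-time intervals must be nonnegative")
    R = np.empty((t.shape[0], N_ITEMS))
    R[:, 0] = params.r_max
    for i in range(N_ISIS):
        R[:, i + 1] = np.minimum(
            params.r_max, (1.0 - params.p) * R[:, i] + params.r * t[:, i]
        )
    return R


def resource_trajectory(isis_s, params: ModelParams) -> ResourceTrajectory:
    """Resource trajectory over one trial given its free-time intervals (s)."""
    R = resource_matrix(np.asarray(isis_s, dtype=float)[None, :], params)[0]
    return ResourceTrajectory(available=R, strengths=params.p * R)


def recall_probability(strength, params: ModelParams):
    """Logistic mapping from memory strength to recall probability."""
    return expit(params.gain * (np.asarray(strength, dtype=float) - params.tau))


def _trial_free_time(
    schedule: PresentationSchedule, time_definition: str
) -> np.ndarray:
    if time_definition == "isi":
        return schedule.isis_s
    if time_definition == "isi_plus_presentation":
        return schedule.isis_s + schedule.presentation_s
    raise ValueError(
        f"time_definition must be one of {TIME_DEFINITIONS}, got {time_definition!r}"
    )


def predict_trial(
    schedule: PresentationSchedule,
    params: ModelParams,
    time_definition: str = "isi",
) -> np.ndarray:
    """Recall probability at each of the 7 serial positions of one trial.

    By default the recovery time ``t_i`` is the blank ISI alone (offset of
    item ``i`` to onset of item ``i+1``); ``time_definition =
    'isi_plus_presentation'`` instead lets the resource also recover during
    the next item's presentation.
    """
    traj = resource_trajectory(_trial_free_time(schedule, time_definition), params)
    return recall_probability(traj.strengths, params)


def free_time_matrix(
    design: ExperimentDesign | pd.DataFrame, time_definition: str = "isi"
) -> np.ndarray:
    """Per-trial free-time intervals in seconds, shape ``(n_trials, 6)``."""
    trials = design.trials if isinstance(design, ExperimentDesign) else design
    t = trials[ISI_COLUMNS].to_numpy(dtype=float) / 1000.0
    if time_definition == "isi_plus_presentation":
        t = t + trials["presentation_ms"].to_numpy(dtype=float)[:, None] / 1000.0
    elif time_definition != "isi":
        raise ValueError(
            f"time_definition must be one of {TIME_DEFINITIONS}, got {time_definition!r}"
        )
    return t


def predict_design(
    design: ExperimentDesign | pd.DataFrame,
    params: ModelParams,
    time_definition: str = "isi",
) -> np.ndarray:
    """Recall probabilities for every design trial, shape ``(n_trials, 7)``."""
    t = free_time_matrix(design, time_definition)
    R = resource_matrix(t, params)
    return recall_probability(params.p * R, params)


def predict_condition_means(
    design: ExperimentDesign,
    params: ModelParams,
    time_definition: str = "isi",
) -> pd.DataFrame:
    """Expected accuracy by condition x serial position (tidy table)."""
    trials = design.trials
    if len(trials) == 0:
        raise ValueError("design has no trials: every condition cell is empty")
    probs = predict_design(design, params, time_definition)
    tidy = pd.DataFrame(
        {
            "condition": np.repeat(trials["condition"].to_numpy(), N_ITEMS),
            "serial_position": np.tile(np.arange(1, N_ITEMS + 1), len(trials)),
            "p_recall": probs.ravel(),
        }
    )
    out = (
        tidy.groupby(["condition", "serial_position"], as_index=False)["p_recall"]
        .mean()
        .sort_values(["condition", "serial_position"], ignore_index=True)
    )
    return out
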