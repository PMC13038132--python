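"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by the dumbest defensible route
(per-row summation, millisecond Euler stepping) and share no code with the
package's vectorized paths.
"""

import math

import numpy as np

from wmtime.model import ModelParams


def euler_recall_probabilities(
    isis_ms, params: ModelParams, dt_ms: float = 1.0
) -> np.ndarray:
    """Recall probabilities via explicit time-stepping of the recovery dynamic.

    Encoding consumes p*R instantaneously at each item onset; during the
    following interitem interval the resource grows by r*dt per step, capped
    at r_max every step.  ISIs are whole milliseconds, so 1-ms steps traverse
    each interval exactly.
    """
    R = params.r_max
    probs = []
    for i in range(7):
        strength = params.p * R
        probs.append(1.0 / (1.0 + math.exp(-params.gain * (strength - params.tau))))
        R = R - strength
        if i < 6:
            n_steps = int(round(isis_ms[i] / dt_ms))
            for _ in range(n_steps):
                R = min(params.r_max, R + params.r * dt_ms / 1000.0)
    return np.array(probs)


def per_row_nll(data, design, params: ModelParams) -> float:
    """Negative log likelihood by naive per-row recomputation."""
    from wmtime.design import TrialSpec, schedule_for_trial
    from wmtime.model import predict_trial

    keyed = design.trials.set_index(["subject_id", "block", "trial"])
    total = 0.0
    for _, row in data.iterrows():
        trial_row = keyed.loc[(row["subject_id"], row["block"], row["trial"])]
        trial_row = dict(trial_row)
        trial_row.update(
            subject_id=row["subject_id"], block=row["block"], trial=row["trial"]
        )
        sched = schedule_for_trial(TrialSpec.from_row(trial_row))
        pi = predict_trial(sched, params)[int(row["serial_position"]) - 1]
        pi = min(max(pi, 1e-9), 1 - 1e-9)
        y = float(row["correct"])
        total -= y * math.log(pi) + (1 - y) * math.log(1 - pi)
    return total
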