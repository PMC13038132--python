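"""Millisecond time-stepping oracle for the recovery dynamic (script-local)."""

import math

import numpy as np


def euler_recall_probabilities(isis_ms, params, dt_ms: float = 1.0) -> np.ndarray:
    """Recall probabilities by explicit 1-ms stepping of resource recovery."""
    R = params.r_max
    probs = []
    for i in range(7):
        strength = params.p * R
        probs.append(1.0 / (1.0 + math.exp(-params.gain * (strength - params.tau))))
        R = R - strength
        if i < 6:
            for _ in range(int(round(isis_ms[i] / dt_ms))):
                R = min(params.r_max, R + params.r * dt_ms / 1000.0)
    return np.array(probs)
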