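"""Pipeline configuration and the design -> simulate -> analyze -> fit runner.

A single master seed drives every stage: stage seeds are split off the
master with ``numpy.random.SeedSequence(master).generate_state(4)`` (mod
2^31), in the fixed order design, simulate, irt-fixture, fit, so any stage
can be rerun in isolation from its recorded seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from wmtime import analysis
from wmtime.data import simulate_accuracy, simulate_irt, write_recall_csv
from wmtime.design import build_exp1_design, build_exp2_design, write_design_csv
from wmtime.fitting import fit
from wmtime.model import ModelParams, TIME_DEFINITIONS

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

logger = logging.getLogger("wmtime")

EXPERIMENTS = ("exp1", "exp2a", "exp2b")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML/JSON."""

    experiment: str = "exp2b"
    n_subjects: int = 25
    seed: int = 1
    params: ModelParams = field(default_factory=ModelParams)
    subject_sd: float = 0.0
    out_dir: str = "wmtime_run"
    irt_fixture: bool = False
    time_definition: str = "isi"
    fit_model: bool = False
    n_starts: int = 10

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if self.subject_sd < 0:
            raise ValueError(f"subject_sd must be >= 0, got {self.subject_sd}")
        if self.time_definition not in TIME_DEFINITIONS:
            raise ValueError(f"unknown time_definition {self.time_definition!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d and not isinstance(d["params"], ModelParams):
            d["params"] = ModelParams.from_dict(d["params"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
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


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds split off the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(4) % (2**31)
    return {
        "design": int(state[0]),
        "simulate": int(state[1]),
        "irt": int(state[2]),
        "fit": int(state[3]),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run design -> simulate -> analyze (-> fit) and write a manifest.

    Outputs are tidy CSVs plus ``manifest.json`` recording the config, the
    stage seeds and a sha256 per artifact.  Identical configs produce
    byte-identical CSVs.
    """
    config.validate()
    seeds = stage_seeds(config.seed)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def _write(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        files[name] = path
        logger.info("wrote %s", path)

    try:
        stage = "design"
        if config.experiment == "exp1":
            design = build_exp1_design(config.n_subjects, seeds["design"])
        else:
            design = build_exp2_design(
                config.experiment[-1], config.n_subjects, seeds["design"]
            )
        _write("design.csv", lambda p: write_design_csv(design, p))

        stage = "simulate"
        data = simulate_accuracy(
            design,
            config.params,
            subject_sd=config.subject_sd,
            seed=seeds["simulate"],
            time_definition=config.time_definition,
        )
        _write("data.csv", lambda p: write_recall_csv(data, p))

        stage = "analyze"
        sp = analysis.serial_position_means(data)
        _write("serial_position_means.csv", lambda p: sp.to_csv(p, index=False))
        if config.experiment == "exp1":
            lv_data = data[data["condition"] == "long_variable"]
            pre, post = analysis.pre_post_time_means(lv_data, design)
            _write("pre_item_time_means.csv", lambda p: pre.to_csv(p, index=False))
            _write("post_item_time_means.csv", lambda p: post.to_csv(p, index=False))
        else:
            lt = analysis.lag_table(data)
            _write("lag_table.csv", lambda p: lt.to_csv(p, index=False))
            if config.experiment == "exp2b":
                eff = analysis.effect_decomposition(data)
                _write("effect_table.csv", lambda p: eff.to_csv(p, index=False))
                if config.irt_fixture:
                    irt = simulate_irt(design, seed=seeds["irt"])
                    _write("irt_data.csv", lambda p: write_recall_csv(irt, p))
                    irt_eff = analysis.effect_decomposition(irt, measure="irt")
                    _write(
                        "irt_effect_table.csv",
                        lambda p: irt_eff.to_csv(p, index=False),
                    )

        if config.fit_model:
            stage = "fit"
            result = fit(
                data,
                design,
                n_starts=config.n_starts,
                seed=seeds["fit"],
                time_definition=config.time_definition,
            )
            payload = {
                "estimates": result.estimates.to_dict(),
                "neg_log_lik": result.neg_log_lik,
                "n_obs": result.n_obs,
                "converged": result.converged,
                "n_starts": result.n_starts,
            }
            _write(
                "fit.json",
                lambda p: p.write_text(json.dumps(payload, indent=2) + "\n"),
            )
    except Exception:
        logger.error("pipeline stage %r failed", stage)
        raise

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "artifacts": {name: _sha256(path) for name, path in files.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
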