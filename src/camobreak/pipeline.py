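"""End-to-end orchestration: design -> simulate -> estimate -> infer -> report.

A run is fully described by a :class:`RunConfig` (palette, observer profile,
subject count, master seed, alpha).  Every artefact is written to the run
directory together with a provenance manifest (config hash, seeds, library
versions), because the pipeline's conclusions are ordering statements that
must be traceable to a seed.  A stage-completion state file makes partially
failed runs resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .censored import estimate_cells
from .inference import analyse_experiment, count_errors
from .observer import ObserverModel, preset_effect_profiles, simulate_experiment

__all__ = ["RunConfig", "run_experiment", "make_fixtures"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "estimate", "errors", "analyse", "report")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    profile: str = "chromatic_like"
    n_subjects: int = 25
    master_seed: int = 0
    n_blocks: int = 4
    alpha: float = 0.05
    palette: str = "grey"
    out_dir: str = "run"
    observer: ObserverModel | None = None

    def to_json_dict(self) -> dict:
        d = asdict(self)
        if self.observer is not None:
            d["observer"] = {
                "mu": {f"{t}:{s}": v for (t, s), v in self.observer.mu.items()},
                "sigma": self.observer.sigma,
                "tau_rt": self.observer.tau_rt,
                "beta_err": {f"{t}:{s}": v for (t, s), v in self.observer.beta_err.items()},
                "tau_err": self.observer.tau_err,
                "censor_time": self.observer.censor_time,
                "rt_resolution": self.observer.rt_resolution,
            }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        obs = d.pop("observer", None)
        cfg = cls(**d)
        if obs is not None:
            parse = lambda m: {tuple(k.split(":")): v for k, v in m.items()}
            cfg.observer = ObserverModel(
                mu=parse(obs["mu"]),
                sigma=obs["sigma"],
                tau_rt=obs["tau_rt"],
                beta_err=parse(obs["beta_err"]),
                tau_err=obs["tau_err"],
                censor_time=obs.get("censor_time", 15.0),
                rt_resolution=obs.get("rt_resolution", 0.01),
            )
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "camobreak": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(obj.columns), "rows": obj.to_dict(orient="records")}
    if hasattr(obj, "groups") and hasattr(obj, "text"):  # OrderingSummary
        return {
            "groups": [list(g) for g in obj.groups],
            "text": obj.text,
            "overlapping": obj.overlapping,
            "alpha": obj.alpha,
        }
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_experiment(config: RunConfig, resume: bool = True) -> Path:
    """Execute the full pipeline and return the run directory.

    Exact stages (simulation, estimation) are bit-identical on rerun with
    the same config; the Tukey Monte-Carlo integration uses its own fixed
    seed, so the inferential report is reproducible as well.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state_path = out / "state.json"
    state = {"completed": []}
    if resume and state_path.exists():
        state = json.loads(state_path.read_text())

    def done(stage: str) -> bool:
        return stage in state["completed"]

    def mark(stage: str) -> None:
        state["completed"].append(stage)
        state_path.write_text(json.dumps(state))

    (out / "config.json").write_text(json.dumps(config.to_json_dict(), indent=2))
    obs = config.observer or preset_effect_profiles(config.profile)

    trials_path = out / "trials.csv"
    if not (done("simulate") and trials_path.exists()):
        logger.info("simulating %d subjects (seed %d)", config.n_subjects, config.master_seed)
        trials = simulate_experiment(
            obs, config.n_subjects, config.master_seed, n_blocks=config.n_blocks
        )
        trials.to_csv(trials_path, index=False)
        mark("simulate")
    trials = pd.read_csv(trials_path)
    trials["error"] = trials["error"].astype("boolean")

    cells_path = out / "cells.csv"
    if not (done("estimate") and cells_path.exists()):
        logger.info("estimating censored cell means")
        estimate_cells(trials).to_csv(cells_path, index=False)
        mark("estimate")
    cells = pd.read_csv(cells_path)

    errors_path = out / "error_counts.csv"
    if not (done("errors") and errors_path.exists()):
        count_errors(trials).to_csv(errors_path, index=False)
        mark("errors")
    errors = pd.read_csv(errors_path)

    logger.info("fitting mixed models")
    report = analyse_experiment(cells, errors, alpha=config.alpha)

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))

    lines = []
    for kind in ("rt", "errors"):
        sub = report[kind]
        if "ordering" in sub:
            lines.append(f"{kind}: {sub['ordering'].text}")
        elif "per_size" in sub:
            for size, s in sub["per_size"].items():
                lines.append(f"{kind} ({size}): {s['ordering'].text}")
    (out / "ordering.txt").write_text("\n".join(lines) + "\n")

    manifest = {
        "config_hash": config.content_hash(),
        "master_seed": config.master_seed,
        "versions": _versions(),
        "artefacts": sorted(p.name for p in out.iterdir() if p.name != "state.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    mark("report")
    return out


def make_fixtures(seed: int = 0) -> pd.DataFrame:
    """Deterministic miniature dataset: 3 subjects x 1 block (150 trials).

    Exercises every treatment x size cell; used by the test suite and the
    documentation examples.
    """
    obs = preset_effect_profiles("chromatic_like")
    return simulate_experiment(obs, n_subjects=3, master_seed=seed, n_blocks=1, include_practice=False)
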