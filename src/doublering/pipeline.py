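"""End-to-end pipeline: synth -> tune -> order params -> fit -> analyze.

Each stage reads and writes the package's standard file formats inside a
report directory and records provenance (configuration, seeds, package
version). Stages can be toggled; a failure halts with the stage name
while earlier outputs persist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .inference import InferenceConfig, ObservedOrderParams, infer_couplings
from .population import build_epoch_matrices, subspace_report
from .simulate import order_params_from_rates
from .synth import ScenarioSpec, default_density, generate_session
from .tuning import extract_epochs, fit_cosine, \
    participation_from_amplitudes, smooth_and_average

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("synth", "tune", "orderparams", "fit", "analyze")


@dataclass
class PipelineConfig:
    """Nested configuration of all pipeline stages."""

    out_dir: str = "report"
    stages: tuple = DEFAULT_STAGES
    seed: int = 0
    scenario: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)
    schema_version: int = 1

    def to_dict(self):
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the report directory."""
    from . import io as dio

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages_completed": [],
    }

    state = {}
    try:
        if "synth" in config.stages:
            stage = "synth"
            spec = ScenarioSpec(seed=config.seed, **config.scenario)
            density = default_density(seed=config.seed)
            trials, truth = generate_session(spec, density)
            trials.to_csv(out / "events.csv",
                          out / "spikes.csv" if trials.spikes is not None
                          else None)
            np.savetxt(out / "ground_truth_coords.csv", truth.coords_table,
                       delimiter=",",
                       header="theta_A,theta_B,eta_A,eta_B", comments="")
            dio.save_yaml(out / "ground_truth.yaml", {
                "couplings": truth.couplings.to_dict(),
                "seed": truth.seed,
                "visible_units": truth.visible_units.tolist(),
            })
            state.update(trials=trials, truth=truth, density=density,
                         spec=spec)
            provenance["stages_completed"].append(stage)

        if "tune" in config.stages:
            stage = "tune"
            trials = state["trials"]
            tensor, events = smooth_and_average(trials)
            epochs = extract_epochs(tensor, events)
            angles = trials.condition_angles
            rows = []
            for name, mean in (("prep", epochs.prep_mean),
                               ("move", epochs.move_mean)):
                fit = fit_cosine(mean, angles)
                fit.eta = participation_from_amplitudes(fit.b)
                rows.append(fit.to_frame(epoch=name))
            import pandas as pd

            pd.concat(rows).to_csv(out / "tuning.csv", index=False)
            state.update(tensor=tensor, events=events, epochs=epochs,
                         tuning=rows)
            provenance["stages_completed"].append(stage)

        if "orderparams" in config.stages:
            stage = "orderparams"
            tensor = state["tensor"]
            truth = state.get("truth")
            coords = None
            if truth is not None:
                from .model import NeuronCoords

                coords = NeuronCoords.from_table(truth.coords_table)
            ops = order_params_from_rates(tensor.rates, coords,
                                          tensor.condition_angles,
                                          t=tensor.t)
            mean = ops.condition_mean()
            dt = float(np.diff(tensor.t).mean())
            obs = ObservedOrderParams(dt, mean["r0"], mean["rA"],
                                      mean["rB"], mean["r0A"],
                                      mean["r0B"],
                                      events=state.get("events"))
            dio.save_observed_order_params(out / "orderparams.h5", obs)
            state["obs"] = obs
            provenance["stages_completed"].append(stage)

        if "fit" in config.stages:
            stage = "fit"
            obs = state["obs"]
            density = state.get("density") or default_density(
                seed=config.seed)
            cfg = InferenceConfig(seed=config.seed, **config.fit)
            result = infer_couplings(obs, density, cfg)
            dio.save_inference_result(out / "fit_result.h5", result)
            state["fit_result"] = result
            provenance["stages_completed"].append(stage)

        if "analyze" in config.stages:
            stage = "analyze"
            tensor = state["tensor"]
            epochs = state["epochs"]
            em = build_epoch_matrices(tensor, epochs)
            rep = subspace_report(em, seed=config.seed,
                                  **config.analyze)
            with open(out / "subspace_report.json", "w") as fh:
                json.dump(rep.to_dict(), fh, indent=2)
            provenance["stages_completed"].append(stage)
    except Exception as exc:
        provenance["failed_stage"] = stage
        provenance["error"] = str(exc)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
        raise StageError(stage, exc) from exc

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return out
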