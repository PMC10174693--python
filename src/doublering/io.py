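"""File I/O: HDF5 for arrays, CSV for tables, YAML for configurations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .inference import InferenceResult, ObservedOrderParams
from .model import CouplingParams, ExternalInputSeries, NeuronCoords
from .simulate import RateTensor

__all__ = [
    "save_rate_tensor",
    "load_rate_tensor",
    "save_observed_order_params",
    "load_observed_order_params",
    "save_inference_result",
    "load_inference_result",
    "save_input_series_csv",
    "load_input_series_csv",
    "load_yaml",
    "save_yaml",
]

_OBS_SERIES = ("r0", "rA", "rB", "r0A", "r0B")


def save_rate_tensor(path, tensor: RateTensor):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("rates", data=tensor.rates, compression="gzip")
        fh.create_dataset("time", data=tensor.t)
        fh.create_dataset("condition_angles", data=tensor.condition_angles)
        if tensor.coords is not None:
            fh.create_dataset("coords", data=tensor.coords.as_table())


def load_rate_tensor(path) -> RateTensor:
    import h5py

    with h5py.File(path, "r") as fh:
        coords = None
        if "coords" in fh:
            coords = NeuronCoords.from_table(fh["coords"][...])
        return RateTensor(fh["rates"][...], fh["time"][...],
                          fh["condition_angles"][...], coords=coords)


def save_observed_order_params(path, obs: ObservedOrderParams):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["dt"] = obs.dt
        fh.attrs["t0"] = obs.t0
        for name in _OBS_SERIES:
            fh.create_dataset(name, data=getattr(obs, name))
        if obs.sem:
            grp = fh.create_group("sem")
            for k, v in obs.sem.items():
                grp.create_dataset(k, data=np.asarray(v))
        if obs.events:
            for k, v in obs.events.items():
                fh.attrs[f"event_{k}"] = v


def load_observed_order_params(path) -> ObservedOrderParams:
    import h5py

    with h5py.File(path, "r") as fh:
        series = {name: fh[name][...] for name in _OBS_SERIES}
        sem = None
        if "sem" in fh:
            sem = {k: fh["sem"][k][...] for k in fh["sem"]}
        events = {k[len("event_"):]: float(v)
                  for k, v in fh.attrs.items() if k.startswith("event_")}
        return ObservedOrderParams(float(fh.attrs["dt"]), **series,
                                   sem=sem, events=events or None,
                                   t0=float(fh.attrs.get("t0", 0.0)))


def save_inference_result(path, result: InferenceResult):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["e_rec"] = result.e_rec
        fh.attrs["e_ext"] = result.e_ext
        fh.attrs["e_tot"] = result.e_tot
        fh.attrs["alpha"] = result.alpha
        fh.create_dataset("couplings", data=result.couplings.as_array())
        grp = fh.create_group("inputs")
        grp.attrs["dt"] = result.inputs.dt
        grp.attrs["t0"] = result.inputs.t0
        grp.attrs["phi_ext"] = result.inputs.phi_ext
        for name in ("C0", "CA", "CB", "eps_A", "eps_B"):
            grp.create_dataset(name, data=getattr(result.inputs, name))
        fh.create_dataset("residuals", data=result.residuals)
        fh.create_dataset("trajectory", data=result.trajectory)
        if result.candidates:
            cand = np.array([[*x, et, er, ee]
                             for x, et, er, ee in result.candidates])
            fh.create_dataset("candidates", data=cand)


def load_inference_result(path) -> InferenceResult:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh["inputs"]
        inputs = ExternalInputSeries(
            float(grp.attrs["dt"]), grp["C0"][...], grp["CA"][...],
            grp["CB"][...], grp["eps_A"][...], grp["eps_B"][...],
            phi_ext=float(grp.attrs["phi_ext"]),
            t0=float(grp.attrs["t0"]))
        candidates = []
        if "candidates" in fh:
            for row in fh["candidates"][...]:
                candidates.append((row[:4], row[4], row[5], row[6]))
        return InferenceResult(
            CouplingParams.from_array(fh["couplings"][...]), inputs,
            float(fh.attrs["e_rec"]), float(fh.attrs["e_ext"]),
            float(fh.attrs["e_tot"]), float(fh.attrs["alpha"]),
            fh["residuals"][...], fh["trajectory"][...], candidates)


def save_input_series_csv(path, inputs: ExternalInputSeries):
    inputs.to_frame().to_csv(path, index=False)


def load_input_series_csv(path, phi_ext=0.0) -> ExternalInputSeries:
    return ExternalInputSeries.from_frame(pd.read_csv(path),
                                          phi_ext=phi_ext)


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(path, payload):
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
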