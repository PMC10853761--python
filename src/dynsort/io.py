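"""HDF5 and CSV containers for geometries, EIs, recordings and models."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    ElectricalImage,
    ElectrodeArray,
    InputTemplate,
    Recording,
    StateSpaceModel,
)
from .synthetic import GroundTruth


# -- geometry ---------------------------------------------------------------

def save_geometry(path: str | Path, array: ElectrodeArray) -> None:
    pd.DataFrame(
        {
            "electrode_id": array.ids,
            "x_um": array.positions[:, 0],
            "y_um": array.positions[:, 1],
        }
    ).to_csv(path, index=False)


def load_geometry(path: str | Path) -> ElectrodeArray:
    df = pd.read_csv(path)
    pos = df[["x_um", "y_um"]].to_numpy(dtype=float)
    # pitch = nearest-neighbor distance
    if len(df) > 1:
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        pitch = float(np.sqrt(d2.min()))
    else:
        pitch = 1.0
    return ElectrodeArray(ids=df["electrode_id"].to_numpy(np.int64), positions=pos, pitch=pitch)


# -- EIs --------------------------------------------------------------------

def save_eis(path: str | Path, eis: list[ElectricalImage]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eis", data=np.stack([e.voltages for e in eis]))
        f.create_dataset("neuron_ids", data=np.array([e.neuron_id for e in eis]))
        f.attrs["sampling_rate_hz"] = eis[0].sampling_rate


def load_eis(path: str | Path) -> list[ElectricalImage]:
    with h5py.File(path, "r") as f:
        data = f["eis"][...]
        ids = f["neuron_ids"][...]
        fs = float(f.attrs["sampling_rate_hz"])
    return [
        ElectricalImage(neuron_id=int(n), voltages=v, sampling_rate=fs)
        for n, v in zip(ids, data)
    ]


# -- recordings -------------------------------------------------------------

def save_recording(path: str | Path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("amplitudes_uA", data=rec.amplitudes)
        f.attrs["stim_electrode"] = int(rec.stim_electrode)
        f.attrs["sampling_rate_hz"] = rec.sampling_rate


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][...],
            amplitudes=f["amplitudes_uA"][...],
            stim_electrode=int(f.attrs["stim_electrode"]),
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
        )


# -- models -----------------------------------------------------------------

def _save_model(group: h5py.Group, model: StateSpaceModel) -> None:
    group.create_dataset("A", data=model.A)
    group.create_dataset("B", data=model.B)
    group.create_dataset("electrode_subset", data=model.electrode_subset)
    group.create_dataset("template/pulses", data=model.template.pulses)
    group.create_dataset("template/pulse_times", data=model.template.pulse_times)
    group.attrs["role"] = model.role
    if model.neuron_id is not None:
        group.attrs["neuron_id"] = int(model.neuron_id)
    if model.stim_electrode is not None:
        group.attrs["stim_electrode"] = int(model.stim_electrode)


def _load_model(group: h5py.Group) -> StateSpaceModel:
    role = group.attrs["role"]
    template = InputTemplate(
        pulses=group["template/pulses"][...],
        pulse_times=group["template/pulse_times"][...],
        role=role,
    )
    return StateSpaceModel(
        A=group["A"][...],
        B=group["B"][...],
        electrode_subset=group["electrode_subset"][...],
        template=template,
        role=role,
        neuron_id=int(group.attrs["neuron_id"]) if "neuron_id" in group.attrs else None,
        stim_electrode=(
            int(group.attrs["stim_electrode"]) if "stim_electrode" in group.attrs else None
        ),
        stability_tol=np.inf,  # stored models were already vetted at fit time
    )


def save_models(path: str | Path, models: list[StateSpaceModel]) -> None:
    with h5py.File(path, "w") as f:
        for i, model in enumerate(models):
            name = (
                f"ei_{model.neuron_id}" if model.role == "ei" else f"artifact_{model.stim_electrode}"
            )
            _save_model(f.create_group(name or f"model_{i}"), model)


def load_models(path: str | Path) -> list[StateSpaceModel]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            out.append(_load_model(f[name]))
    return out


# -- ground truth / calls / thresholds (CSV) --------------------------------

def save_ground_truth(spikes_path: str | Path, activation_path: str | Path, truth: GroundTruth) -> None:
    rows = [
        {"trial": t, "neuron_id": n, "latency_samples": lat}
        for t, lst in sorted(truth.spikes.items())
        for n, lat in lst
    ]
    pd.DataFrame(rows, columns=["trial", "neuron_id", "latency_samples"]).to_csv(
        spikes_path, index=False
    )
    act = [
        {"neuron_id": n, "q50_uA": q50, "slope": s}
        for n, (q50, s) in sorted(truth.activation.items())
    ]
    pd.DataFrame(act, columns=["neuron_id", "q50_uA", "slope"]).to_csv(
        activation_path, index=False
    )


def save_calls(path: str | Path, calls: list) -> None:
    pd.DataFrame(
        [
            {
                "trial": c.trial,
                "neuron_id": c.neuron_id,
                "amplitude_uA": c.amplitude,
                "detected": int(c.detected),
                "latency_samples": -1 if c.latency is None else c.latency,
                "score": c.score,
            }
            for c in calls
        ]
    ).to_csv(path, index=False)


def load_calls(path: str | Path) -> list:
    from .detect import SpikeCall

    df = pd.read_csv(path)
    return [
        SpikeCall(
            neuron_id=int(r.neuron_id),
            trial=int(r.trial),
            amplitude=float(r.amplitude_uA),
            detected=bool(r.detected),
            latency=None if r.latency_samples < 0 else int(r.latency_samples),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def save_thresholds(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(
        rows, columns=["neuron_id", "stim_electrode", "q50_uA", "slope", "converged"]
    ).to_csv(path, index=False)


def load_thresholds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
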