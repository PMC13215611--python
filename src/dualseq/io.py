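"""Persistence: HDF5 epoch containers, JSON models, npz network weights."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .eventdecomp import EventModel
from .seqmodel import ModelConfig, SequenceModel
from .synthdata import EpochSet


def save_epochs(path, epochs: EpochSet) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("stim_sample", data=epochs.stim_sample)
        f.create_dataset("rt_sample", data=epochs.rt_sample)
        f.create_dataset("valid_samples", data=epochs.valid_samples)
        f.attrs["fs"] = epochs.fs
        f.attrs["pre_pad_ms"] = epochs.pre_pad_ms
        f.attrs["post_pad_ms"] = epochs.post_pad_ms
    epochs.metadata.to_csv(path.with_suffix(".metadata.csv"), index=False)


def load_epochs(path) -> EpochSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        epochs = EpochSet(
            data=f["data"][()], fs=float(f.attrs["fs"]),
            stim_sample=f["stim_sample"][()],
            rt_sample=f["rt_sample"][()],
            valid_samples=f["valid_samples"][()],
            metadata=pd.read_csv(path.with_suffix(".metadata.csv")),
            pre_pad_ms=float(f.attrs["pre_pad_ms"]),
            post_pad_ms=float(f.attrs["post_pad_ms"]))
    return epochs


def save_event_model(path, model: EventModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_event_model(path) -> EventModel:
    return EventModel.from_dict(json.loads(Path(path).read_text()))


def save_sequence_model(path, model: SequenceModel) -> None:
    cfg = dataclasses.asdict(model.config)
    np.savez(path, __config__=json.dumps(cfg), **model.params)


def load_sequence_model(path) -> SequenceModel:
    with np.load(path, allow_pickle=False) as f:
        cfg = json.loads(str(f["__config__"]))
        cfg["temporal_kernel_ms"] = tuple(cfg["temporal_kernel_ms"])
        model = SequenceModel(ModelConfig(**cfg))
        for k in model.params:
            model.params[k] = f[k]
    return model
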