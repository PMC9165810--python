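"""Dataset and checkpoint serialization.

Datasets are written as a directory holding ``epochs.npz`` (stacked data,
labels, subject/session ids) plus a human-readable ``sidecar.json`` with
the montage, provenance and — for synthetic data — the full ground-truth
spec, so every artifact directory is self-describing and re-runnable.
Checkpoints are a single ``.npz`` bundling all parameter arrays with the
embedded model configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from residual_eegnet import __version__, nn
from residual_eegnet.architecture import ModelConfig, build_model
from residual_eegnet.data_model import PHYSIONET_CHANNELS, EEGEpoch, TaskLabel
from residual_eegnet.synthetic import SyntheticDataset, SyntheticSpec

SIDECAR = "sidecar.json"
ARRAYS = "epochs.npz"


def save_dataset(directory, epochs: list[EEGEpoch], extra: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.stack([ep.data for ep in epochs])
    labels = np.array([int(ep.label) for ep in epochs], dtype=np.int64)
    subjects = np.array([ep.subject_id for ep in epochs], dtype=np.int64)
    sessions = np.array([ep.session_id for ep in epochs], dtype=np.int64)
    np.savez_compressed(directory / ARRAYS, data=data, labels=labels,
                        subjects=subjects, sessions=sessions)
    sidecar = {
        "format": "residual-eegnet dataset v1",
        "software_version": __version__,
        "n_epochs": len(epochs),
        "sampling_rate_hz": epochs[0].sampling_rate if epochs else None,
        "montage": list(PHYSIONET_CHANNELS),
        "label_encoding": {lab.name: int(lab) for lab in TaskLabel},
    }
    if extra:
        sidecar.update(extra)
    (directory / SIDECAR).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return directory


def save_synthetic_dataset(directory, dataset: SyntheticDataset) -> Path:
    return save_dataset(directory, dataset.epochs,
                        extra={"synthetic_spec": dataset.ground_truth.to_jsonable()})


def load_dataset(directory) -> tuple[list[EEGEpoch], dict]:
    directory = Path(directory)
    sidecar = json.loads((directory / SIDECAR).read_text())
    with np.load(directory / ARRAYS) as z:
        data, labels = z["data"], z["labels"]
        subjects, sessions = z["subjects"], z["sessions"]
    fs = sidecar.get("sampling_rate_hz") or 160.0
    epochs = [
        EEGEpoch(data=data[i], subject_id=int(subjects[i]),
                 session_id=int(sessions[i]), label=TaskLabel(int(labels[i])),
                 sampling_rate=fs)
        for i in range(data.shape[0])
    ]
    return epochs, sidecar


def load_synthetic_spec(sidecar: dict) -> SyntheticSpec:
    return SyntheticSpec.from_jsonable(sidecar["synthetic_spec"])


def save_checkpoint(path, model: nn.Model, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    header = {
        "format": "residual-eegnet checkpoint v1",
        "software_version": __version__,
        "model_config": model.config.to_jsonable(),
        "input_samples": int(model.input_samples),
        "dtype": str(model.parameters()[0].value.dtype),
        "meta": meta or {},
    }
    np.savez_compressed(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **state)
    return path


def load_checkpoint(path) -> tuple[nn.Model, dict]:
    with np.load(Path(path)) as z:
        header = json.loads(bytes(z["__header__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__header__"}
    cfg = ModelConfig.from_jsonable(header["model_config"])
    model = build_model(cfg, seed=0, dtype=np.dtype(header["dtype"]).type,
                        input_samples=header["input_samples"])
    model.load_state_dict(state)
    return model, header
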