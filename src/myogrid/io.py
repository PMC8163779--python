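"""Persistence: streams in HDF5, models as npz with a layer manifest."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import nn
from .model import GridConvNetClassifier
from .synthetic import EmgStream, Segment


def save_stream(path, stream: EmgStream) -> None:
    """One chunked dataset per trial: raw samples plus annotation sidecar."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("emg", data=stream.samples, chunks=True)
        d.attrs["sample_rate"] = stream.sample_rate
        d.attrs["segments"] = json.dumps(
            [[s.label, s.start_ms, s.end_ms, s.active] for s in stream.segments]
        )


def load_stream(path) -> EmgStream:
    with h5py.File(path, "r") as f:
        d = f["emg"]
        segments = tuple(
            Segment(int(l), float(a), float(b), bool(act))
            for l, a, b, act in json.loads(d.attrs["segments"])
        )
        return EmgStream(d[...], float(d.attrs["sample_rate"]), segments)


def export_stream_text(path, stream: EmgStream) -> None:
    """Delimited text with a one-line header (sample_rate, per-sample label)."""
    labels = np.full(stream.n_samples, 0, dtype=int)
    for seg in stream.segments:
        i0, i1 = int(seg.start_ms), int(seg.end_ms)
        labels[i0:i1] = seg.label
    header = f"sample_rate={stream.sample_rate} columns=label,ch0..ch31"
    data = np.column_stack([labels, stream.samples])
    np.savetxt(path, data, fmt=["%d"] + ["%.6e"] * stream.samples.shape[1], header=header)


def save_model(path, clf: GridConvNetClassifier) -> None:
    """Checkpoint with an explicit feature/head layer-partition manifest."""
    meta = {
        "init_params": clf.get_params(),
        "layer_partition": clf.layer_partition(),
        "training_log": clf.training_log_,
    }
    np.savez(
        path,
        classes=clf.classes_,
        scale=np.float64(clf.scale_),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **clf.params_,
    )


def load_model(path) -> GridConvNetClassifier:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        init = meta["init_params"]
        if isinstance(init.get("amp_jitter"), list):  # JSON has no tuples
            init["amp_jitter"] = tuple(init["amp_jitter"])
        clf = GridConvNetClassifier(**init)
        clf.classes_ = z["classes"]
        clf.scale_ = float(z["scale"])
        clf.training_log_ = meta["training_log"]
        clf.params_ = {k: z[k] for k in nn.ALL_PARAMS}
        clf.n_features_in_ = 32
    return clf


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
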