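"""Persistence: HDF5 containers for movies/trains/state, CSV exports."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .stimulus import EventTrain, StimulusMovie

__all__ = ["save_movie", "load_movie", "save_train", "load_train",
           "save_state_snapshot", "load_state_snapshot"]


def _write_meta(group, meta: dict):
    group.attrs["meta_json"] = json.dumps(meta, default=float)


def _read_meta(group) -> dict:
    raw = group.attrs.get("meta_json", "{}")
    return json.loads(raw)


def save_movie(path: str, movie: StimulusMovie):
    with h5py.File(path, "w") as f:
        g = f.create_group("movie")
        g.create_dataset("frames", data=movie.frames, compression="gzip")
        g.attrs["pixel_scale"] = movie.pixel_scale
        g.attrs["frame_interval"] = movie.frame_interval
        g.attrs["extent"] = movie.extent
        _write_meta(g, movie.meta)


def load_movie(path: str) -> StimulusMovie:
    with h5py.File(path, "r") as f:
        g = f["movie"]
        return StimulusMovie(frames=g["frames"][...],
                             pixel_scale=float(g.attrs["pixel_scale"]),
                             frame_interval=float(g.attrs["frame_interval"]),
                             extent=float(g.attrs["extent"]),
                             meta=_read_meta(g))


def save_train(path: str, train: EventTrain):
    with h5py.File(path, "w") as f:
        g = f.create_group("train")
        g.create_dataset("data", data=train.data, compression="gzip")
        times = np.arange(train.n_bins) * train.bin_ms
        g.create_dataset("times", data=times)
        g.attrs["bin_ms"] = train.bin_ms
        _write_meta(g, train.meta)


def load_train(path: str) -> EventTrain:
    with h5py.File(path, "r") as f:
        g = f["train"]
        return EventTrain(data=g["data"][...], bin_ms=float(g.attrs["bin_ms"]),
                          meta=_read_meta(g))


def export_train_csv(path: str, train: EventTrain):
    """Two-column CSV of event onsets (synapse_id, event_onset_ms)."""
    train.onsets_frame().to_csv(path, index=False)


def save_state_snapshot(path: str, arrays: dict, params: dict):
    with h5py.File(path, "w") as f:
        g = f.create_group("state")
        for name, arr in arrays.items():
            g.create_dataset(name, data=np.asarray(arr))
        _write_meta(g, params)


def load_state_snapshot(path: str):
    with h5py.File(path, "r") as f:
        g = f["state"]
        arrays = {k: g[k][...] for k in g.keys()}
        return arrays, _read_meta(g)
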