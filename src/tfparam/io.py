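"""Hierarchical array container for cohorts and derived surfaces (HDF5).

Layout: one group per subject (``subject_000``, ...) holding one subgroup per
condition with ``data`` (trials × channels × samples), ``times`` and labels;
cohort-level datasets hold behavior and channel positions. Derived surfaces
are written beside the inputs so every pipeline stage can resume from the
container.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .synthgen import EpochSet
from .tfr import PowerSurface

__all__ = ["save_cohort", "load_cohort", "save_surfaces", "load_surfaces"]


def save_cohort(path, subjects, behavior=None, channel_positions=None,
                ground_truth=None) -> None:
    """Write a cohort (list of condition → EpochSet dicts) to ``path``."""
    with h5py.File(path, "w") as h5:
        for s, conds in enumerate(subjects):
            g = h5.create_group(f"subject_{s:03d}")
            for cond, ep in conds.items():
                cg = g.create_group(cond)
                cg.create_dataset("data", data=ep.data, compression="gzip")
                cg.create_dataset("times", data=ep.times)
                cg.create_dataset("labels", data=np.asarray(ep.condition_labels, dtype="S"))
                cg.attrs["sampling_rate"] = ep.sampling_rate
                cg.attrs["subject_id"] = ep.subject_id
        if behavior is not None:
            h5.create_dataset("behavior", data=np.asarray(behavior, dtype=float))
        if channel_positions is not None:
            h5.create_dataset("channel_positions", data=np.asarray(channel_positions, dtype=float))
        if ground_truth is not None:
            h5.attrs["ground_truth_json"] = json.dumps(
                _jsonable(getattr(ground_truth, "records", ground_truth)))


def load_cohort(path):
    """Read a cohort container; returns (subjects, behavior, channel_positions)."""
    subjects = []
    behavior = None
    positions = None
    with h5py.File(path, "r") as h5:
        names = sorted(k for k in h5 if k.startswith("subject_"))
        for name in names:
            g = h5[name]
            conds = {}
            for cond in g:
                cg = g[cond]
                conds[cond] = EpochSet(
                    data=cg["data"][()], sampling_rate=float(cg.attrs["sampling_rate"]),
                    times=cg["times"][()],
                    condition_labels=cg["labels"][()].astype(str),
                    subject_id=str(cg.attrs["subject_id"]))
            subjects.append(conds)
        if "behavior" in h5:
            behavior = h5["behavior"][()]
        if "channel_positions" in h5:
            positions = h5["channel_positions"][()]
    return subjects, behavior, positions


def save_surfaces(path, surfaces: dict[str, PowerSurface], mode: str = "a") -> None:
    """Write named power surfaces under ``/surfaces/<name>``."""
    with h5py.File(path, mode) as h5:
        root = h5.require_group("surfaces")
        for name, surf in surfaces.items():
            if name in root:
                del root[name]
            g = root.create_group(name)
            g.create_dataset("values", data=surf.values, compression="gzip")
            g.create_dataset("frequencies", data=surf.frequencies)
            g.create_dataset("frame_times", data=surf.frame_times)
            g.attrs["units"] = surf.units
            g.attrs["condition"] = surf.condition
            g.attrs["subject_id"] = surf.subject_id


def load_surfaces(path) -> dict[str, PowerSurface]:
    out = {}
    with h5py.File(path, "r") as h5:
        if "surfaces" not in h5:
            return out
        root = h5["surfaces"]

        def collect(name, obj):
            if isinstance(obj, h5py.Group) and "values" in obj:
                out[name] = PowerSurface(
                    values=obj["values"][()], frequencies=obj["frequencies"][()],
                    frame_times=obj["frame_times"][()], units=str(obj.attrs["units"]),
                    condition=str(obj.attrs["condition"]),
                    subject_id=str(obj.attrs["subject_id"]))

        root.visititems(collect)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj
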