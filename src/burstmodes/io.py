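"""Serialization: TSV for arrays, JSON for scalar summaries, run manifests.

TSV files are tab-separated with a header row, '.' decimal separator and no
thousands separators; floats are written with ``repr`` precision so every
file round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .burst_model import BurstyGeneModel
from .cme import ExtremaSet, MomentSummary, StationaryPMF
from .reaction_core import Trajectory

__all__ = [
    "write_pmf_tsv",
    "read_pmf_tsv",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_json",
    "write_manifest",
    "load_model_config",
    "save_model_config",
    "extrema_to_dict",
    "moments_to_dict",
]


def _to_tsv(df: pd.DataFrame, path) -> None:
    # repr gives the shortest digit string that round-trips exactly
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def write_pmf_tsv(pmf: StationaryPMF, path) -> None:
    df = pd.DataFrame({"n": np.arange(pmf.support), "p": pmf.probs})
    _to_tsv(df, path)


def read_pmf_tsv(path) -> StationaryPMF:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return StationaryPMF(
        probs=df["p"].to_numpy(), truncation_tail=np.nan, model_fingerprint=""
    )


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    cols = {"t": traj.times}
    labels = traj.species_labels or tuple(
        f"n{i}" for i in range(traj.states.shape[0])
    )
    for i, lab in enumerate(labels):
        cols[str(lab)] = traj.states[i]
    _to_tsv(pd.DataFrame(cols), path)


def read_trajectory_tsv(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = tuple(c for c in df.columns if c != "t")
    return Trajectory(
        times=df["t"].to_numpy(),
        states=np.vstack([df[c].to_numpy() for c in labels]),
        species_labels=labels,
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_manifest(path, command: str, params: dict, seed=None, tolerances=None) -> None:
    """Run manifest: everything needed to reproduce an artifact."""
    from . import __version__

    write_json(
        {
            "command": command,
            "parameters": params,
            "seed": seed,
            "tolerances": tolerances or {},
            "package_version": __version__,
            "numpy_version": np.__version__,
        },
        path,
    )


def load_model_config(path) -> BurstyGeneModel:
    """Read a model from a YAML/JSON config file
    (``{feedback: {...}, mu_star, delta, volume}``)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    try:
        return BurstyGeneModel.from_dict(cfg)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed model config {path}: {exc}") from exc


def save_model_config(model: BurstyGeneModel, path) -> None:
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))
    else:
        write_json(model.to_dict(), p)


def extrema_to_dict(ext: ExtremaSet) -> dict:
    return {
        "maxima": [list(p) for p in ext.maxima],
        "minima": [list(p) for p in ext.minima],
        "boundary_extremum_at_zero": ext.boundary_extremum_at_zero,
    }


def moments_to_dict(mom: MomentSummary) -> dict:
    d = asdict(mom)
    d["central_moments"] = list(map(float, mom.central_moments))
    return d
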