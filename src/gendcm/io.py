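"""HDF5 serialization of datasets, inversion results, and group tables.

Every container carries a ``schema_version`` attribute; loading a file written
by a future schema raises.  Round-trips are exact for integers and labels and
bit-exact for float arrays (no recoding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .group import GroupResult
from .spectral import CSDDataset

__all__ = ["SCHEMA_VERSION", "InversionRecord", "save_result", "load_result"]

SCHEMA_VERSION = 1


@dataclass
class InversionRecord:
    """On-disk form of a fitted model: posterior, trajectory, predictions."""

    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    F_trace: np.ndarray
    lam: float
    converged: bool
    block_names: list[str]
    block_sizes: list[int]
    predicted: CSDDataset | None = None


def _write_csd(grp: h5py.Group, csd: CSDDataset) -> None:
    grp.create_dataset("freq", data=csd.freq)
    grp.attrs["channels"] = json.dumps(list(csd.channels))
    cond_grp = grp.create_group("conditions")
    for cond, G in csd.G.items():
        cond_grp.create_dataset(cond, data=G)


def _read_csd(grp: h5py.Group) -> CSDDataset:
    freq = np.asarray(grp["freq"])
    channels = tuple(json.loads(grp.attrs["channels"]))
    G = {cond: np.asarray(ds) for cond, ds in grp["conditions"].items()}
    return CSDDataset(freq=freq, G=G, channels=channels)


def save_result(path, obj) -> None:
    """Write a :class:`CSDDataset`, fitted results, or :class:`GroupResult`."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(obj, CSDDataset):
            f.attrs["kind"] = "CSDDataset"
            _write_csd(f, obj)
            return
        if isinstance(obj, GroupResult):
            f.attrs["kind"] = "GroupResult"
            f.attrs["n_hemispheres"] = obj.n_hemispheres
            f.attrs["q"] = obj.q
            f.attrs["m_total"] = obj.m_total
            f.attrs["labels"] = json.dumps(list(obj.table.index))
            for col in obj.table.columns:
                f.create_dataset(f"table/{col}", data=obj.table[col].to_numpy())
            return
        # Fitted-model results (SpectralDCMResults or InversionResult-like).
        params = getattr(obj, "params", None)
        if params is not None:
            mean = params.theta
            blocks = params.layout.blocks
        else:
            mean = obj.posterior_mean
            blocks = getattr(obj, "blocks", ())
        f.attrs["kind"] = "InversionResult"
        f.attrs["lam"] = float(obj.lam)
        f.attrs["converged"] = bool(obj.converged)
        f.attrs["block_names"] = json.dumps([b for b, _ in blocks])
        f.attrs["block_sizes"] = json.dumps([n for _, n in blocks])
        post = f.create_group("posterior")
        post.create_dataset("mean", data=np.asarray(mean))
        cov = getattr(obj, "cov_params", None)
        if cov is None:
            cov = obj.posterior_cov
        post.create_dataset("cov", data=np.asarray(cov))
        f.create_dataset("F_trace", data=np.asarray(obj.F_trace))
        predicted = getattr(obj, "predicted_dataset", None)
        if callable(predicted):
            _write_csd(f.create_group("predicted"), predicted())


def load_result(path):
    """Load whatever :func:`save_result` wrote; raises on future schemas."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version > SCHEMA_VERSION:
            raise ValueError(
                f"{path} was written by schema version {version}; "
                f"this build reads up to {SCHEMA_VERSION}"
            )
        kind = f.attrs.get("kind")
        if kind == "CSDDataset":
            return _read_csd(f)
        if kind == "GroupResult":
            labels = json.loads(f.attrs["labels"])
            table = pd.DataFrame(
                {col: np.asarray(ds) for col, ds in f["table"].items()}, index=labels
            )
            table = table[["mean_B", "t", "df", "p", "fdr_reject", "sign"]]
            table["fdr_reject"] = table["fdr_reject"].astype(bool)
            return GroupResult(
                table=table,
                n_hemispheres=int(f.attrs["n_hemispheres"]),
                q=float(f.attrs["q"]),
                m_total=int(f.attrs["m_total"]),
            )
        if kind == "InversionResult":
            predicted = _read_csd(f["predicted"]) if "predicted" in f else None
            return InversionRecord(
                posterior_mean=np.asarray(f["posterior/mean"]),
                posterior_cov=np.asarray(f["posterior/cov"]),
                F_trace=np.asarray(f["F_trace"]),
                lam=float(f.attrs["lam"]),
                converged=bool(f.attrs["converged"]),
                block_names=json.loads(f.attrs["block_names"]),
                block_sizes=json.loads(f.attrs["block_sizes"]),
                predicted=predicted,
            )
        raise ValueError(f"{path}: unrecognised container kind {kind!r}")
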