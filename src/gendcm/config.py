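"""Run configuration: a declarative YAML schema mirroring the usual DCM options.

A config names the data feature (``analysis: CSD``), one model block per
source (``source`` kind, optional ``B`` condition-effect indices, optional
``J``/``K`` observed-state indices), the frequency window ``Fdcm``, the
condition labels, and inversion settings.  Unknown keys are rejected with
field-level messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .models import get_model, registered_models
from .network import NetworkSpec, default_network

__all__ = ["ConfigError", "ModelOptions", "InversionOptions", "RunConfig", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass
class ModelOptions:
    """Per-source options: model kind, condition effects, observed states."""

    source: str
    B: list[int] | None = None  # intrinsic connections free to vary; None = all
    J: list[int] | None = None  # populations contributing to the signal (fixed weight 1)
    K: list[int] | None = None  # populations whose contribution is estimated


@dataclass
class InversionOptions:
    restarts: int = 1
    maxiter: int = 64
    tol: float = 1e-2


@dataclass
class RunConfig:
    analysis: str = "CSD"
    models: list[ModelOptions] = dc_field(default_factory=lambda: [
        ModelOptions(source="MMC"), ModelOptions(source="BGT"),
    ])
    Fdcm: tuple[float, float] = (5.0, 45.0)
    n_freq: int = 41
    conditions: tuple[str, ...] = ("OFF", "ON")
    inversion: InversionOptions = dc_field(default_factory=InversionOptions)
    seed: int = 0
    out: str | None = None

    def frequency_grid(self) -> np.ndarray:
        return np.linspace(self.Fdcm[0], self.Fdcm[1], self.n_freq)

    def network(self) -> NetworkSpec:
        kinds = [m.source for m in self.models]
        if kinds == ["MMC", "BGT"]:
            return default_network()
        raise ConfigError(
            f"no shipped network for source set {kinds}; build a NetworkSpec "
            "programmatically for custom compositions"
        )

    def b_indices(self) -> dict[str, tuple[int, ...]]:
        net = self.network()
        out: dict[str, tuple[int, ...]] = {}
        for (name, kind), opts in zip(net.sources, self.models):
            n_conn = get_model(kind).spec.n_connections
            if opts.B is None:
                out[name] = tuple(range(1, n_conn + 1))
            else:
                bad = [i for i in opts.B if not 1 <= i <= n_conn]
                if bad:
                    raise ConfigError(
                        f"model {name}: B indices {bad} outside 1..{n_conn}"
                    )
                out[name] = tuple(opts.B)
        out["ext"] = tuple(range(1, len(net.b_ext_groups) + 1))
        return out


_MODEL_KEYS = {"source", "B", "J", "K"}
_INV_KEYS = {"restarts", "maxiter", "tol"}
_TOP_KEYS = {"analysis", "models", "Fdcm", "n_freq", "conditions", "inversion", "seed", "out"}


def _check_keys(d: dict, allowed: set, ctx: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{ctx}: unknown keys {sorted(unknown)}; allowed {sorted(allowed)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    cfg = RunConfig()
    analysis = raw.get("analysis", "CSD")
    if analysis != "CSD":
        raise ConfigError(f"analysis: only 'CSD' is supported, got {analysis!r}")
    cfg.analysis = analysis

    if "models" in raw:
        if not isinstance(raw["models"], list) or not raw["models"]:
            raise ConfigError("models: must be a non-empty list of model blocks")
        models = []
        for i, blk in enumerate(raw["models"]):
            if not isinstance(blk, dict):
                raise ConfigError(f"models[{i}]: must be a mapping")
            _check_keys(blk, _MODEL_KEYS, f"models[{i}]")
            if "source" not in blk:
                raise ConfigError(f"models[{i}]: missing required key 'source'")
            kind = blk["source"]
            if kind not in registered_models():
                raise ConfigError(
                    f"models[{i}].source: unknown model kind {kind!r}; "
                    f"registered kinds: {list(registered_models())}"
                )
            for key in ("B", "J", "K"):
                if key in blk and blk[key] is not None:
                    val = blk[key]
                    if not isinstance(val, list) or not all(
                        isinstance(x, int) and x >= 1 for x in val
                    ):
                        raise ConfigError(
                            f"models[{i}].{key}: must be a list of 1-based integer indices"
                        )
            models.append(
                ModelOptions(source=kind, B=blk.get("B"), J=blk.get("J"), K=blk.get("K"))
            )
        cfg.models = models

    if "Fdcm" in raw:
        f = raw["Fdcm"]
        if (not isinstance(f, list) or len(f) != 2
                or not all(isinstance(x, (int, float)) for x in f) or not f[0] < f[1]):
            raise ConfigError("Fdcm: must be [f_min, f_max] with f_min < f_max")
        if f[0] <= 0:
            raise ConfigError("Fdcm: frequencies must be positive")
        cfg.Fdcm = (float(f[0]), float(f[1]))
    if "n_freq" in raw:
        n = raw["n_freq"]
        if not isinstance(n, int) or n < 2:
            raise ConfigError("n_freq: must be an integer >= 2")
        cfg.n_freq = n
    if "conditions" in raw:
        c = raw["conditions"]
        if not isinstance(c, list) or not 1 <= len(c) <= 2 or not all(
            isinstance(x, str) for x in c
        ):
            raise ConfigError("conditions: must be a list of 1 or 2 labels")
        cfg.conditions = tuple(c)
    if "inversion" in raw:
        inv = raw["inversion"]
        if not isinstance(inv, dict):
            raise ConfigError("inversion: must be a mapping")
        _check_keys(inv, _INV_KEYS, "inversion")
        opts = InversionOptions()
        if "restarts" in inv:
            if not isinstance(inv["restarts"], int) or inv["restarts"] < 1:
                raise ConfigError("inversion.restarts: must be an integer >= 1")
            opts.restarts = inv["restarts"]
        if "maxiter" in inv:
            if not isinstance(inv["maxiter"], int) or inv["maxiter"] < 1:
                raise ConfigError("inversion.maxiter: must be an integer >= 1")
            opts.maxiter = inv["maxiter"]
        if "tol" in inv:
            if not isinstance(inv["tol"], (int, float)) or inv["tol"] <= 0:
                raise ConfigError("inversion.tol: must be a positive number")
            opts.tol = float(inv["tol"])
        cfg.inversion = opts
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ConfigError("seed: must be an integer")
        cfg.seed = raw["seed"]
    if "out" in raw and raw["out"] is not None:
        if not isinstance(raw["out"], str):
            raise ConfigError("out: must be a path string")
        cfg.out = raw["out"]
    cfg.network()  # validates the source composition
    return cfg
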