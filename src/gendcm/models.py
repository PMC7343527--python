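"""Neural mass model definitions and registry.

Each source in a network is a convolution-based neural mass model: a set of
neural populations whose mean membrane potential ``v`` responds to presynaptic
firing rate through a synaptic kernel ``h(t) = (t/T) exp(-t/T)``.  Written as a
second-order ODE, population ``j`` of a source obeys::

    dv_j/dt    = vdot_j
    dvdot_j/dt = (sum_l gamma_l * S(v_l) + afferent_j + drive_j
                  - 2 * vdot_j - v_j / T_j) / T_j

where ``S`` is the baseline-subtracted sigmoid converting membrane potential to
a deviation in firing rate, ``gamma_l`` are signed intrinsic coupling strengths
(excitatory positive, inhibitory negative), ``afferent_j`` collects extrinsic
(between-source) input and ``drive_j`` endogenous input.  Time constants are in
seconds internally; priors are quoted in ms and converted at the boundary.

Two models ship: the motor cortex microcircuit (MMC, 4 populations, 14
intrinsic connections) and the basal ganglia-thalamus model (BGT, 5
populations, 9 connections).  New models can be registered at run time with
:func:`register_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Connection",
    "ModelSpec",
    "ModelDefinition",
    "sigmoid_rate",
    "sigmoid_slope",
    "model_flow",
    "default_priors",
    "register_model",
    "get_model",
    "registered_models",
    "MMC",
    "BGT",
]


@dataclass(frozen=True)
class Connection:
    """A signed intrinsic connection between two populations of one source."""

    source: str
    target: str
    sign: int
    index: int  # 1-based index used in tables of priors and condition effects

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"connection sign must be +/-1, got {self.sign}")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of one neural mass model.

    Parameters
    ----------
    kind
        Model identifier (``"MMC"``, ``"BGT"``, or a user-registered name).
    populations
        Ordered population labels; the state vector is ``[v..., vdot...]`` in
        this order.
    connections
        Intrinsic connections with signs and 1-based indices; indices must be
        ``1..n_connections`` with no repeats.
    input_population
        Population receiving endogenous innovations.
    output_mixture
        Per-population weights of the observed signal (the lead-field gain is
        applied on top of these).
    intrinsic_delay_ms
        Expected within-source axonal delay (prior mean, ms).
    """

    kind: str
    populations: tuple[str, ...]
    connections: tuple[Connection, ...]
    input_population: str
    output_mixture: Mapping[str, float]
    intrinsic_delay_ms: float = 1.0

    def __post_init__(self) -> None:
        labels = set(self.populations)
        indices = sorted(c.index for c in self.connections)
        if indices != list(range(1, len(self.connections) + 1)):
            raise ValueError("connection indices must be 1..n with no repeats")
        for c in self.connections:
            if c.source not in labels or c.target not in labels:
                raise ValueError(f"connection {c} references unknown population")
        if self.input_population not in labels:
            raise ValueError(f"unknown input population {self.input_population}")
        for p in self.output_mixture:
            if p not in labels:
                raise ValueError(f"unknown output population {p}")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_states(self) -> int:
        return 2 * len(self.populations)

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    def coupling_matrix(self, gamma: np.ndarray) -> np.ndarray:
        """Signed population-to-population coupling matrix ``W[target, source]``."""
        gamma = np.asarray(gamma, dtype=float)
        if gamma.shape != (self.n_connections,):
            raise ValueError(
                f"expected {self.n_connections} coupling strengths, got {gamma.shape}"
            )
        idx = {p: i for i, p in enumerate(self.populations)}
        W = np.zeros((self.n_populations, self.n_populations))
        for c in self.connections:
            W[idx[c.target], idx[c.source]] += c.sign * gamma[c.index - 1]
        return W

    def output_weights(self) -> np.ndarray:
        w = np.zeros(self.n_populations)
        for p, val in self.output_mixture.items():
            w[self.populations.index(p)] = val
        return w


@dataclass(frozen=True)
class ModelDefinition:
    """Registry entry: architecture, priors, and (optionally) a custom flow."""

    spec: ModelSpec
    priors: Mapping[str, tuple[np.ndarray, np.ndarray]]
    flow: Callable | None = None  # custom flow(state, params, afferent, drive)


def sigmoid_rate(v: np.ndarray | float, R: float) -> np.ndarray | float:
    """Firing-rate deviation from baseline for membrane potential ``v``.

    ``S(v) - S(0)`` with ``S(v) = 1 / (1 + exp(-R v))``; odd in ``v`` and
    bounded in (-1/2, 1/2).  ``R`` parameterises the slope (population
    response-variability).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    if np.any(np.asarray(R) <= 0):
        raise ValueError("sigmoid slope R must be positive")
    out = 1.0 / (1.0 + np.exp(-R * v)) - 0.5
    return out if out.ndim else float(out)


def sigmoid_slope(v: np.ndarray | float, R: float) -> np.ndarray | float:
    """Derivative of :func:`sigmoid_rate` with respect to ``v`` (R/4 at v=0)."""
    s = 1.0 / (1.0 + np.exp(-np.multiply(R, v)))
    return R * s * (1.0 - s)


# ---------------------------------------------------------------------------
# Shipped architectures.
#
# The correspondence between connection indices and anatomical arrows is a
# frozen convention (see docs/methods.md); signs follow the transmitter of the
# presynaptic population (GABAergic negative, glutamatergic positive), with
# inhibitory self-connections on excitatory populations for gain control.
# ---------------------------------------------------------------------------

_MMC_CONNECTIONS = (
    Connection("MP", "MP", -1, 1),
    Connection("MP", "SP", +1, 2),
    Connection("II", "MP", -1, 3),
    Connection("II", "II", -1, 4),
    Connection("MP", "II", +1, 5),
    Connection("DP", "II", +1, 6),
    Connection("SP", "SP", -1, 7),
    Connection("SP", "II", +1, 8),
    Connection("II", "DP", -1, 9),
    Connection("DP", "DP", -1, 10),
    Connection("SP", "DP", +1, 11),
    Connection("II", "SP", -1, 12),
    Connection("SP", "MP", +1, 13),
    Connection("MP", "DP", +1, 14),
)

MMC = ModelSpec(
    kind="MMC",
    populations=("MP", "SP", "II", "DP"),
    connections=_MMC_CONNECTIONS,
    input_population="MP",
    output_mixture={"SP": 0.2, "MP": 0.2, "DP": 0.6},
    intrinsic_delay_ms=1.0,
)

_BGT_CONNECTIONS = (
    Connection("Str", "Str", -1, 1),
    Connection("Str", "GPe", -1, 2),
    Connection("GPe", "GPe", -1, 3),
    Connection("GPe", "STN", -1, 4),
    Connection("STN", "GPe", +1, 5),
    Connection("Str", "GPi", -1, 6),
    Connection("STN", "GPi", +1, 7),
    Connection("GPi", "GPi", -1, 8),
    Connection("GPi", "Tha", -1, 9),
)

BGT = ModelSpec(
    kind="BGT",
    populations=("Str", "GPe", "STN", "GPi", "Tha"),
    connections=_BGT_CONNECTIONS,
    input_population="Str",
    output_mixture={"STN": 1.0},
    intrinsic_delay_ms=4.0,
)

# Prior expectations (natural scale) and lognormal dispersions per block.
# Time constants are stored in ms, matching how they are usually quoted;
# conversion to seconds happens when natural-scale parameters are assembled.
_MMC_PRIORS = {
    "gamma": (
        np.array(
            [357, 872, 387, 340, 311, 405, 377, 429, 331, 403, 753, 376, 382, 414],
            dtype=float,
        ),
        np.full(14, 1.0 / 4),
    ),
    "T_ms": (np.array([3.7, 3.2, 14.1, 10.6]), np.full(4, 1.0 / 8)),
    "R": (np.array([2.0 / 3]), np.array([1.0 / 32])),
}

_BGT_PRIORS = {
    "gamma": (
        np.array([962, 828, 1403, 719, 526, 568, 345, 780, 301], dtype=float),
        np.full(9, 1.0 / 2),
    ),
    "T_ms": (np.array([9.3, 12.2, 3.5, 12.1, 10.1]), np.full(5, 1.0 / 4)),
    "R": (np.array([2.0 / 3]), np.array([1.0 / 16])),
}

_REGISTRY: dict[str, ModelDefinition] = {}


def register_model(
    kind: str,
    spec: ModelSpec,
    priors: Mapping[str, tuple[np.ndarray, np.ndarray]],
    flow: Callable | None = None,
) -> None:
    """Register a neural mass model so networks can address it by name.

    ``priors`` must provide ``(mean, log_variance)`` pairs for blocks
    ``"gamma"`` (length = number of connections), ``"T_ms"`` (length = number
    of populations) and ``"R"`` (length 1).  A custom ``flow`` callable with
    signature ``flow(state, gamma, T_s, R, afferent, drive)`` may replace the
    generic convolution dynamics.
    """
    if kind in _REGISTRY:
        raise ValueError(f"model kind {kind!r} is already registered")
    if spec.kind != kind:
        raise ValueError("spec.kind must match the registered name")
    for block, length in (
        ("gamma", spec.n_connections),
        ("T_ms", spec.n_populations),
        ("R", 1),
    ):
        if block not in priors:
            raise ValueError(f"priors missing required block {block!r}")
        mean, var = priors[block]
        if np.shape(mean) != (length,) or np.shape(var) != (length,):
            raise ValueError(
                f"prior block {block!r} must have length {length} (mean and variance)"
            )
    _REGISTRY[kind] = ModelDefinition(spec=spec, priors=dict(priors), flow=flow)


def get_model(kind: str) -> ModelDefinition:
    try:
        return _REGISTRY[kind]
    except KeyError:
        raise KeyError(
            f"unknown model kind {kind!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def registered_models() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


register_model("MMC", MMC, _MMC_PRIORS)
register_model("BGT", BGT, _BGT_PRIORS)


def default_priors(kind: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Prior ``(mean, log-variance)`` blocks for a registered model."""
    return {k: (m.copy(), v.copy()) for k, (m, v) in get_model(kind).priors.items()}


def model_flow(
    kind: str,
    state: np.ndarray,
    gamma: np.ndarray,
    T_s: np.ndarray,
    R: float,
    afferent: np.ndarray | float = 0.0,
    drive: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Intrinsic flow of one source: time derivative of ``[v..., vdot...]``.

    ``gamma`` are signed-by-convention *magnitudes* (signs come from the model
    spec), ``T_s`` time constants in seconds, ``afferent`` extrinsic drive and
    ``drive`` endogenous input per population (both enter the acceleration
    equation divided by the target time constant, i.e. linearly).
    """
    mdl = get_model(kind)
    spec = mdl.spec
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.n_states,):
        raise ValueError(
            f"state length {state.shape} does not match {kind} ({spec.n_states})"
        )
    T_s = np.asarray(T_s, dtype=float)
    if np.any(T_s <= 0):
        raise ValueError("time constants must be positive")
    if mdl.flow is not None:
        return np.asarray(mdl.flow(state, gamma, T_s, R, afferent, drive), dtype=float)
    P = spec.n_populations
    v, vdot = state[:P], state[P:]
    W = spec.coupling_matrix(gamma)
    syn = W @ np.asarray(sigmoid_rate(v, R))
    acc = (syn + afferent + drive - 2.0 * vdot - v / T_s) / T_s
    return np.concatenate([vdot, acc])
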