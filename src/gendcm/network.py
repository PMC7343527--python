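"""Composition of heterogeneous neural mass sources into one dynamical system.

A :class:`NetworkSpec` names an ordered set of sources (each an instance of a
registered model kind), the excitatory extrinsic connections between them, and
which extrinsic connections carry condition-specific effects.  The assembled
global flow evaluates each source's intrinsic dynamics and adds extrinsic
afferents: the presynaptic population's membrane potential is passed through
its *own* source's sigmoid (firing-rate semantics stay source-local) and the
resulting rate, scaled by the connection strength ``A``, enters the
postsynaptic acceleration equation exactly like intrinsic drive.

Axonal delays are not part of the flow itself; they are book-kept as a
state-pair delay matrix (:func:`build_delay_matrix`) and applied to the
Jacobian by first-order Taylor embedding in :mod:`gendcm.spectral`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cache

import numpy as np

from .models import ModelDefinition, get_model, model_flow, sigmoid_rate

__all__ = [
    "ExtrinsicConnection",
    "NetworkSpec",
    "DelayStructure",
    "default_network",
    "network_flow",
    "assemble_flow",
    "build_delay_matrix",
]


@dataclass(frozen=True)
class ExtrinsicConnection:
    """Excitatory between-source connection, indexed into the A block (1-based)."""

    from_source: str
    from_population: str
    to_source: str
    to_population: str
    index: int


@dataclass(frozen=True)
class NetworkSpec:
    """Sources, extrinsic wiring, and condition-effect bookkeeping.

    ``sources`` is an ordered tuple of ``(name, kind)`` pairs; ``channels``
    maps one observation channel to each source (lead-field gain times the
    source's output mixture).  ``b_ext_groups`` lists, per extrinsic
    condition-effect parameter, the A indices it modulates jointly.
    """

    sources: tuple[tuple[str, str], ...]
    extrinsic: tuple[ExtrinsicConnection, ...] = ()
    channels: tuple[str, ...] = ()
    b_ext_groups: tuple[tuple[int, ...], ...] = ()
    a_prior_mean: tuple[float, ...] = ()
    a_prior_var: tuple[float, ...] = ()
    delay_prior_mean_ms: tuple[float, ...] = ()
    delay_prior_var: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names")
        for _, kind in self.sources:
            get_model(kind)  # raises for unregistered kinds
        indices = sorted(c.index for c in self.extrinsic)
        if indices != list(range(1, len(self.extrinsic) + 1)):
            raise ValueError("extrinsic A indices must be 1..n with no repeats")
        by_name = dict(self.sources)
        for c in self.extrinsic:
            for src, pop in (
                (c.from_source, c.from_population),
                (c.to_source, c.to_population),
            ):
                if src not in by_name:
                    raise ValueError(f"extrinsic connection references unknown source {src!r}")
                if pop not in get_model(by_name[src]).spec.populations:
                    raise ValueError(
                        f"extrinsic connection references unknown population {pop!r} of {src!r}"
                    )
        covered = [i for grp in self.b_ext_groups for i in grp]
        if len(set(covered)) != len(covered):
            raise ValueError("an A index appears in more than one b_ext group")

    # -- structural helpers -------------------------------------------------
    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.sources)

    def definition(self, name: str) -> ModelDefinition:
        return get_model(dict(self.sources)[name])

    @cache
    def state_offsets(self) -> dict[str, int]:
        off, out = 0, {}
        for name, kind in self.sources:
            out[name] = off
            off += get_model(kind).spec.n_states
        return out

    @property
    def n_states(self) -> int:
        return sum(get_model(k).spec.n_states for _, k in self.sources)

    @cache
    def state_source_index(self) -> np.ndarray:
        """Source index of every global state."""
        return np.concatenate(
            [
                np.full(get_model(k).spec.n_states, i, dtype=int)
                for i, (_, k) in enumerate(self.sources)
            ]
        )

    @cache
    def state_population_id(self) -> np.ndarray:
        """Globally unique population id of every state (v and vdot share it)."""
        ids, base = [], 0
        for _, kind in self.sources:
            P = get_model(kind).spec.n_populations
            ids.append(np.tile(np.arange(base, base + P), 2))
            base += P
        return np.concatenate(ids)

    @cache
    def v_index(self, source: str, population: str) -> int:
        spec = self.definition(source).spec
        return self.state_offsets()[source] + spec.populations.index(population)

    @cache
    def vdot_index(self, source: str, population: str) -> int:
        spec = self.definition(source).spec
        return (
            self.state_offsets()[source]
            + spec.n_populations
            + spec.populations.index(population)
        )


@dataclass(frozen=True)
class DelayStructure:
    """Four-class axonal delays expanded to a state-pair matrix (seconds).

    ``D[i, j]`` is the delay with which state ``j`` influences state ``i``:
    zero within one population (leak and structural v/vdot terms are
    undelayed), the within-source delay between populations of one source, and
    the source-pair delay otherwise.
    """

    d: np.ndarray  # source-pair delays, order [to, from] flattened Fortran-style
    D: np.ndarray  # n_states x n_states

    def __post_init__(self) -> None:
        if np.any(self.D < 0):
            raise ValueError("delays must be nonnegative")


def build_delay_matrix(network: NetworkSpec, d_s: np.ndarray) -> DelayStructure:
    """Expand per-source-pair delays to a state-pair matrix.

    ``d_s`` (seconds) is ordered ``[within-source-1, source-1 -> source-2, ...,
    within-source-n]``: entry ``from * n_sources + to`` is the delay from
    ``from`` to ``to``.  For the shipped two-source network this is the
    conventional ``[within MMC, MMC -> BGT, BGT -> MMC, within BGT]`` order.
    """
    ns = network.n_sources
    d_s = np.asarray(d_s, dtype=float)
    if d_s.shape != (ns * ns,):
        raise ValueError(f"expected {ns * ns} delays, got {d_s.shape}")
    if np.any(d_s < 0):
        raise ValueError("delays must be nonnegative")
    pair = d_s.reshape(ns, ns).T  # pair[to, from]
    src = network.state_source_index()
    pop = network.state_population_id()
    D = pair[np.ix_(src, src)].copy()
    D[pop[:, None] == pop[None, :]] = 0.0
    return DelayStructure(d=d_s.copy(), D=D)


def default_network() -> NetworkSpec:
    """The shipped motor-cortex + basal-ganglia-thalamus network.

    Four extrinsic connections (all glutamatergic): two thalamocortical
    projections onto middle and deep pyramidal cells, the corticostriatal
    projection, and the hyperdirect pathway from deep pyramidal cells to STN.
    Condition effects on extrinsic strengths come in three groups: both
    thalamocortical arrows share one, corticostriatal and hyperdirect each get
    their own.
    """
    return NetworkSpec(
        sources=(("mmc", "MMC"), ("bgt", "BGT")),
        extrinsic=(
            ExtrinsicConnection("bgt", "Tha", "mmc", "MP", 1),
            ExtrinsicConnection("bgt", "Tha", "mmc", "DP", 2),
            ExtrinsicConnection("mmc", "DP", "bgt", "Str", 3),
            ExtrinsicConnection("mmc", "DP", "bgt", "STN", 4),
        ),
        channels=("M1", "STN"),
        b_ext_groups=((1, 2), (3,), (4,)),
        a_prior_mean=(110.0, 588.0, 672.0, 127.0),
        a_prior_var=(0.25, 0.25, 0.25, 0.25),
        delay_prior_mean_ms=(1.0, 8.0, 8.0, 4.0),
        delay_prior_var=(1.0 / 32,) * 4,
    )


def network_flow(
    network: NetworkSpec,
    state: np.ndarray,
    params: dict,
    drive: np.ndarray | None = None,
) -> np.ndarray:
    """Global flow over the stacked state vector.

    ``params`` holds natural-scale values: ``gamma`` and ``T_s`` and ``R``
    per-source dicts, plus the extrinsic strengths ``A``.  ``drive`` is a
    per-population endogenous input on the *input populations* only, given as
    a full global-population vector (zeros elsewhere) or ``None``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_states,):
        raise ValueError(f"state length {state.shape} != {network.n_states}")
    offsets = network.state_offsets()
    A = np.asarray(params.get("A", np.zeros(len(network.extrinsic))), dtype=float)
    if A.shape != (len(network.extrinsic),):
        raise ValueError("A length does not match extrinsic connections")

    # Extrinsic afferents: presynaptic rate through the presynaptic source's
    # own sigmoid slope parameter.
    afferents = {name: np.zeros(network.definition(name).spec.n_populations)
                 for name in network.source_names}
    for c in network.extrinsic:
        v_pre = state[network.v_index(c.from_source, c.from_population)]
        rate = sigmoid_rate(v_pre, params["R"][c.from_source])
        spec_to = network.definition(c.to_source).spec
        afferents[c.to_source][spec_to.populations.index(c.to_population)] += (
            A[c.index - 1] * rate
        )

    out = np.empty(network.n_states)
    for name, kind in network.sources:
        spec = network.definition(name).spec
        o = offsets[name]
        dr = 0.0
        if drive is not None:
            base = sum(
                network.definition(n).spec.n_populations
                for n in network.source_names[: network.source_names.index(name)]
            )
            dr = np.asarray(drive, dtype=float)[base : base + spec.n_populations]
        out[o : o + spec.n_states] = model_flow(
            kind,
            state[o : o + spec.n_states],
            params["gamma"][name],
            params["T_s"][name],
            params["R"][name],
            afferent=afferents[name],
            drive=dr,
        )
    return out


def assemble_flow(network: NetworkSpec, params: dict):
    """Bind a network and parameters into ``flow(state, drive=None)``."""

    def flow(state: np.ndarray, drive: np.ndarray | None = None) -> np.ndarray:
        return network_flow(network, state, params, drive)

    return flow
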