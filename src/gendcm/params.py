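"""Parameter vectors, lognormal priors, and condition effects.

All nonnegative parameters (coupling strengths, time constants, delays, noise
amplitudes, gains) are estimated as exponential scale factors of their prior
expectations: ``theta_i ~ N(0, sigma_i^2)`` on the log scale, with natural
value ``vartheta_i = pi_i * exp(theta_i)``.  Condition-specific effects ``B``
are additive on the log scale (multiplicative on the natural scale): the
baseline condition uses ``pi * exp(theta)`` and the modulated condition
``pi * exp(theta + B)`` on the affected connections.

The flat parameter vector is laid out in named blocks derived from the
network: per-source coupling strengths and time constants, extrinsic
strengths, per-source and extrinsic condition effects, sigmoid slopes, delays,
noise spectral parameters, and lead-field gains.  For the shipped two-source
network this is 76 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkSpec

__all__ = [
    "ParameterLayout",
    "PriorSet",
    "ParameterSet",
    "build_priors",
    "scale_parameters",
    "default_b_indices",
    "condition_parameters",
]

_NOISE_BLOCKS = ("alpha_u", "beta_u", "alpha_c", "beta_c", "alpha_s", "beta_s")


@dataclass(frozen=True)
class ParameterLayout:
    """Ordered named blocks of the flat parameter vector."""

    blocks: tuple[tuple[str, int], ...]

    @property
    def n_params(self) -> int:
        return sum(n for _, n in self.blocks)

    def slices(self) -> dict[str, slice]:
        out, off = {}, 0
        for name, n in self.blocks:
            out[name] = slice(off, off + n)
            off += n
        return out

    @classmethod
    def for_network(
        cls,
        network: NetworkSpec,
        k_states: dict[str, tuple[int, ...]] | None = None,
    ) -> "ParameterLayout":
        blocks: list[tuple[str, int]] = []
        for name, _ in network.sources:
            spec = network.definition(name).spec
            blocks.append((f"gamma_{name}", spec.n_connections))
            blocks.append((f"T_{name}", spec.n_populations))
        blocks.append(("A", len(network.extrinsic)))
        for name, _ in network.sources:
            spec = network.definition(name).spec
            blocks.append((f"B_{name}", spec.n_connections))
        blocks.append(("B_ext", len(network.b_ext_groups)))
        blocks.append(("R", network.n_sources))
        blocks.append(("d", network.n_sources**2))
        blocks.extend((b, 1) for b in _NOISE_BLOCKS)
        blocks.append(("L", len(network.channels)))
        if k_states:
            for name, idx in k_states.items():
                if idx:
                    blocks.append((f"K_{name}", len(idx)))
        return cls(blocks=tuple(blocks))


class ParameterSet:
    """A flat log-scale parameter vector with named block access."""

    def __init__(self, layout: ParameterLayout, theta: np.ndarray | None = None):
        self.layout = layout
        self._slices = layout.slices()
        if theta is None:
            theta = np.zeros(layout.n_params)
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (layout.n_params,):
            raise ValueError(
                f"theta length {theta.shape} != layout size {layout.n_params}"
            )
        self.theta = theta

    def __getitem__(self, block: str) -> np.ndarray:
        return self.theta[self._slices[block]]

    def __setitem__(self, block: str, value) -> None:
        self.theta[self._slices[block]] = value

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.layout, self.theta.copy())

    def block_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.layout.blocks)

    def to_dict(self) -> dict[str, np.ndarray]:
        return {name: np.array(self[name]) for name, _ in self.layout.blocks}


@dataclass
class PriorSet:
    """Prior expectations (natural scale) and log-variances per parameter.

    ``pi`` stores prior means on the scale in which they are quoted (ms for
    time constants and delays); B blocks have ``pi = 0`` because they are
    additive log-scale offsets, not scale factors.  ``hE_mean``/``hE_var``
    parameterise the Gaussian prior on the data log-precision.
    """

    layout: ParameterLayout
    pi: np.ndarray
    sigma2: np.ndarray
    hE_mean: float = 16.0
    hE_var: float = 4.0
    # Observed-state options: j_states fixes unit-weight output states per
    # source (replacing the default mixture); k_states adds states whose
    # contribution is estimated (scale-factor prior 1, variance 1/32).
    j_states: dict | None = None
    k_states: dict | None = None
    _slices: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._slices = self.layout.slices()
        n = self.layout.n_params
        if self.pi.shape != (n,) or self.sigma2.shape != (n,):
            raise ValueError("prior mean/variance length mismatch with layout")
        if np.any(self.sigma2 <= 0):
            raise ValueError("prior variances must be positive")

    def block(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        s = self._slices[name]
        return self.pi[s], self.sigma2[s]

    def precision(self) -> np.ndarray:
        return np.diag(1.0 / self.sigma2)


def build_priors(
    network: NetworkSpec,
    hE_mean: float = 16.0,
    hE_var: float = 4.0,
    j_states: dict[str, tuple[int, ...]] | None = None,
    k_states: dict[str, tuple[int, ...]] | None = None,
) -> PriorSet:
    """Assemble the full prior specification for a network.

    Per-source blocks come from the registered model definitions; condition
    effects inherit the dispersion of the couplings they modulate; extrinsic,
    delay, noise, and lead-field priors are network-level conventions.
    ``j_states``/``k_states`` optionally override which populations (1-based
    indices) feed the observed signal: J states contribute with fixed unit
    weight, K states with an estimated weight (prior 1, log-variance 1/32).
    """
    for opt in (j_states, k_states):
        if opt:
            for name, idx in opt.items():
                P = network.definition(name).spec.n_populations
                bad = [i for i in idx if not 1 <= i <= P]
                if bad:
                    raise ValueError(f"observed-state indices {bad} outside 1..{P} for {name!r}")
    layout = ParameterLayout.for_network(network, k_states)
    pi = np.zeros(layout.n_params)
    s2 = np.zeros(layout.n_params)
    sl = layout.slices()
    for name, _ in network.sources:
        pri = network.definition(name).priors
        pi[sl[f"gamma_{name}"]], s2[sl[f"gamma_{name}"]] = pri["gamma"]
        pi[sl[f"T_{name}"]], s2[sl[f"T_{name}"]] = pri["T_ms"]
        pi[sl[f"B_{name}"]] = 0.0
        s2[sl[f"B_{name}"]] = pri["gamma"][1]
    pi[sl["A"]] = network.a_prior_mean
    s2[sl["A"]] = network.a_prior_var
    pi[sl["B_ext"]] = 0.0
    s2[sl["B_ext"]] = 0.25
    for i, (name, _) in enumerate(network.sources):
        pri = network.definition(name).priors
        pi[sl["R"]][i : i + 1], s2[sl["R"]][i : i + 1] = pri["R"]
    pi[sl["d"]] = network.delay_prior_mean_ms
    s2[sl["d"]] = network.delay_prior_var
    for b in _NOISE_BLOCKS:
        pi[sl[b]], s2[sl[b]] = 1.0, 0.25
    pi[sl["L"]], s2[sl["L"]] = 1.0, 4.0
    if k_states:
        for name, idx in k_states.items():
            if idx:
                pi[sl[f"K_{name}"]], s2[sl[f"K_{name}"]] = 1.0, 1.0 / 32
    return PriorSet(
        layout=layout, pi=pi, sigma2=s2, hE_mean=hE_mean, hE_var=hE_var,
        j_states=dict(j_states) if j_states else None,
        k_states=dict(k_states) if k_states else None,
    )


def scale_parameters(theta: np.ndarray | ParameterSet, priors: PriorSet) -> np.ndarray:
    """Natural-scale parameters ``pi * exp(theta)`` (elementwise)."""
    th = theta.theta if isinstance(theta, ParameterSet) else np.asarray(theta, dtype=float)
    if th.shape != priors.pi.shape:
        raise ValueError("theta and priors are not conformable")
    return priors.pi * np.exp(th)


def default_b_indices(network: NetworkSpec) -> dict[str, tuple[int, ...]]:
    """All intrinsic connections and all extrinsic groups free to vary."""
    out = {
        name: tuple(range(1, network.definition(name).spec.n_connections + 1))
        for name, _ in network.sources
    }
    out["ext"] = tuple(range(1, len(network.b_ext_groups) + 1))
    return out


def condition_parameters(
    theta: ParameterSet,
    priors: PriorSet,
    network: NetworkSpec,
    condition: str = "baseline",
    b_indices: dict[str, tuple[int, ...]] | None = None,
) -> dict:
    """Natural-scale parameter dictionary for one experimental condition.

    ``condition`` is ``"baseline"`` (B ignored) or ``"modulated"`` (B added to
    the log-scale factors of the connections declared in ``b_indices`` before
    exponentiation).  A nonzero B on an undeclared connection is a contract
    violation and raises.
    """
    if condition not in ("baseline", "modulated"):
        raise ValueError(f"unknown condition {condition!r}")
    if b_indices is None:
        b_indices = default_b_indices(network)

    def _scaled(block: str, b_block: str | None, declared: tuple[int, ...]) -> np.ndarray:
        pi, _ = priors.block(block)
        th = np.array(theta[block], dtype=float)
        if b_block is not None:
            B = np.asarray(theta[b_block], dtype=float)
            mask = np.zeros(B.size, dtype=bool)
            if declared:
                mask[np.asarray(declared, dtype=int) - 1] = True
            if np.any(np.abs(B[~mask]) > 1e-12):
                raise ValueError(
                    f"nonzero condition effect outside declared b_indices in {b_block}"
                )
            if condition == "modulated":
                th = th + np.where(mask, B, 0.0)
        return pi * np.exp(th)

    gamma, T_s, R = {}, {}, {}
    for i, (name, _) in enumerate(network.sources):
        gamma[name] = _scaled(f"gamma_{name}", f"B_{name}", tuple(b_indices.get(name, ())))
        pi_T, _ = priors.block(f"T_{name}")
        T_s[name] = pi_T * np.exp(theta[f"T_{name}"]) * 1e-3  # ms -> s
        pi_R, _ = priors.block("R")
        R[name] = float(pi_R[i] * np.exp(theta["R"][i]))

    # Extrinsic strengths: each B_ext entry modulates its declared A group.
    pi_A, _ = priors.block("A")
    th_A = np.array(theta["A"], dtype=float)
    B_ext = np.asarray(theta["B_ext"], dtype=float)
    declared_ext = tuple(b_indices.get("ext", ()))
    ext_mask = np.zeros(B_ext.size, dtype=bool)
    if declared_ext:
        ext_mask[np.asarray(declared_ext, dtype=int) - 1] = True
    if np.any(np.abs(B_ext[~ext_mask]) > 1e-12):
        raise ValueError("nonzero condition effect outside declared b_indices in B_ext")
    if condition == "modulated":
        for g in declared_ext:
            for a_idx in network.b_ext_groups[g - 1]:
                th_A[a_idx - 1] += B_ext[g - 1]
    A = pi_A * np.exp(th_A)

    pi_d, _ = priors.block("d")
    d_s = pi_d * np.exp(theta["d"]) * 1e-3  # ms -> s
    noise = {b: float(priors.block(b)[0][0] * np.exp(theta[b][0])) for b in _NOISE_BLOCKS}
    pi_L, _ = priors.block("L")
    L = pi_L * np.exp(theta["L"])
    out = {
        "gamma": gamma,
        "T_s": T_s,
        "R": R,
        "A": A,
        "d_s": d_s,
        "noise": noise,
        "L": L,
    }
    if priors.j_states or priors.k_states:
        mixture = {}
        for name, _ in network.sources:
            spec = network.definition(name).spec
            if priors.j_states and name in priors.j_states:
                w = np.zeros(spec.n_populations)
                w[np.asarray(priors.j_states[name], dtype=int) - 1] = 1.0
            else:
                w = spec.output_weights()
            if priors.k_states and priors.k_states.get(name):
                pi_K, _ = priors.block(f"K_{name}")
                wk = pi_K * np.exp(theta[f"K_{name}"])
                for i, p in enumerate(priors.k_states[name]):
                    w[p - 1] += wk[i]
            mixture[name] = w
        out["mixture"] = mixture
    return out
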