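"""Spectral forward model: from parameters to cross-spectral densities.

The network's stochastic dynamics are linearized around the origin fixed
point.  With Jacobian ``J``, input matrix ``U`` (how innovations enter the
flow), and observation rows ``L`` (lead-field gains times output mixtures),
axonal delays are absorbed into a delay-embedded Jacobian by first-order
Taylor expansion ``x(t - d) ~ x(t) - d xdot(t)``::

    Jd = (I + D o J)^-1 J        (o = elementwise product)

and the transfer function from innovation site ``u`` to channel ``c`` is
``H(w) = L (i w I - Jd)^-1 U``.  The predicted cross-spectral density adds
power-law innovations and observation noise::

    G(f) = H diag(g_u) H* + alpha_c f^-beta_c 11' + diag(alpha_s f^-beta_s)
    g_u(f) = input_gain * alpha_u * f^-beta_u

with frequencies in Hz normalised by 1 Hz inside the power laws.  ``G`` is
Hermitian with real nonnegative diagonal at every frequency whenever ``Jd``
is stable; an unstable ``Jd`` raises :class:`UnstableModelError`, which the
inversion uses for step rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import get_model, sigmoid_slope
from .network import DelayStructure, NetworkSpec, build_delay_matrix, network_flow

__all__ = [
    "CSDDataset",
    "SpectralModel",
    "UnstableModelError",
    "linearize",
    "jacobian",
    "input_matrix",
    "lead_rows",
    "delay_embed",
    "transfer_function",
    "predict_csd",
    "coherence",
    "population_spectra",
]

DEFAULT_INPUT_GAIN = 512.0


class UnstableModelError(RuntimeError):
    """Raised when the (delay-embedded) Jacobian has an unstable mode."""


@dataclass
class CSDDataset:
    """Per-condition complex cross-spectral matrices on a frequency grid.

    ``G[condition]`` has shape ``(n_freq, n_channels, n_channels)``.
    """

    freq: np.ndarray
    G: dict[str, np.ndarray]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 1 or np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequency grid must be 1-D and strictly increasing")
        nc = len(self.channels)
        for cond, g in self.G.items():
            g = np.asarray(g, dtype=complex)
            if g.shape != (self.freq.size, nc, nc):
                raise ValueError(f"G[{cond!r}] has shape {g.shape}")
            self.G[cond] = g

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.G)

    def auto_spectra(self, condition: str) -> np.ndarray:
        """Real channel auto-spectra, shape (n_freq, n_channels)."""
        return np.real(np.einsum("fcc->fc", self.G[condition]))


@dataclass
class SpectralModel:
    """Linearized system: Jacobian, delay embedding, inputs, observation rows."""

    J: np.ndarray
    U: np.ndarray
    Lrows: np.ndarray
    Jd: np.ndarray | None = None
    freq: np.ndarray | None = None


def jacobian(network: NetworkSpec, params: dict) -> np.ndarray:
    """Closed-form Jacobian of the assembled flow at the origin.

    Valid because the baseline-subtracted sigmoid makes the origin a fixed
    point; the sigmoid slope at zero is ``R/4``.
    """
    n = network.n_states
    J = np.zeros((n, n))
    offsets = network.state_offsets()
    for name, kind in network.sources:
        spec = get_model(kind).spec
        o, P = offsets[name], spec.n_populations
        T = np.asarray(params["T_s"][name], dtype=float)
        W = spec.coupling_matrix(np.asarray(params["gamma"][name], dtype=float))
        slope = sigmoid_slope(0.0, params["R"][name])
        J[o : o + P, o + P : o + 2 * P] = np.eye(P)
        J[o + P : o + 2 * P, o : o + P] = (W * slope - np.eye(P) / T[:, None]) / T[:, None]
        J[o + P : o + 2 * P, o + P : o + 2 * P] = -2.0 * np.eye(P) / T[:, None]
    A = np.asarray(params.get("A", np.zeros(len(network.extrinsic))), dtype=float)
    for c in network.extrinsic:
        i = network.vdot_index(c.to_source, c.to_population)
        j = network.v_index(c.from_source, c.from_population)
        T_to = params["T_s"][c.to_source][
            network.definition(c.to_source).spec.populations.index(c.to_population)
        ]
        J[i, j] += A[c.index - 1] * sigmoid_slope(0.0, params["R"][c.from_source]) / T_to
    return J


def input_matrix(network: NetworkSpec, params: dict) -> np.ndarray:
    """``dflow/dinnovations``: one column per innovation site (input population)."""
    n = network.n_states
    cols = []
    for name, kind in network.sources:
        spec = get_model(kind).spec
        p = spec.populations.index(spec.input_population)
        col = np.zeros(n)
        col[network.vdot_index(name, spec.input_population)] = 1.0 / params["T_s"][name][p]
        cols.append(col)
    return np.column_stack(cols)


def lead_rows(network: NetworkSpec, params: dict) -> np.ndarray:
    """Observation rows: lead-field gain times output mixture over v-states.

    ``params["mixture"]`` (per-source weight vectors) overrides the models'
    default output mixtures when the observed states are user-specified.
    """
    L = np.asarray(params["L"], dtype=float)
    mixture = params.get("mixture")
    rows = np.zeros((len(network.channels), network.n_states))
    for i, (name, kind) in enumerate(network.sources):
        spec = get_model(kind).spec
        o = network.state_offsets()[name]
        w = mixture[name] if mixture is not None else spec.output_weights()
        rows[i, o : o + spec.n_populations] = L[i] * w
    return rows


def linearize(
    network: NetworkSpec,
    params: dict,
    operating_point: np.ndarray | None = None,
    h: float = 1e-6,
) -> SpectralModel:
    """Numerical linearization of the assembled flow by central differences.

    ``operating_point`` defaults to the origin and must be a fixed point
    (``max |flow| < 1e-9``).  The relative step is ``h`` (absolute where the
    state is zero).  :func:`jacobian` is the closed-form equivalent used on
    the hot path; the two agree to finite-difference accuracy.
    """
    n = network.n_states
    x0 = np.zeros(n) if operating_point is None else np.asarray(operating_point, dtype=float)
    f0 = network_flow(network, x0, params)
    if np.max(np.abs(f0)) >= 1e-9:
        raise ValueError(
            f"operating point is not a fixed point (max |flow| = {np.max(np.abs(f0)):.3g})"
        )
    J = np.empty((n, n))
    for j in range(n):
        step = h * max(1.0, abs(x0[j]))
        e = np.zeros(n)
        e[j] = step
        J[:, j] = (
            network_flow(network, x0 + e, params) - network_flow(network, x0 - e, params)
        ) / (2 * step)
    # Innovation columns by the same central-difference rule.
    n_in = network.n_sources
    pop_base = 0
    U = np.empty((n, n_in))
    for i, (name, kind) in enumerate(network.sources):
        spec = get_model(kind).spec
        drive = np.zeros(sum(network.definition(s).spec.n_populations for s, _ in network.sources))
        k = pop_base + spec.populations.index(spec.input_population)
        drive[k] = h
        fp = network_flow(network, x0, params, drive=drive)
        drive[k] = -h
        fm = network_flow(network, x0, params, drive=drive)
        U[:, i] = (fp - fm) / (2 * h)
        pop_base += spec.n_populations
    if not (np.all(np.isfinite(J)) and np.all(np.isfinite(U))):
        raise FloatingPointError("non-finite derivative in linearization")
    return SpectralModel(J=J, U=U, Lrows=lead_rows(network, params))


def delay_embed(J: np.ndarray, D: DelayStructure | np.ndarray) -> np.ndarray:
    """First-order Taylor delay embedding ``Jd = (I + D o J)^-1 J``."""
    Dm = D.D if isinstance(D, DelayStructure) else np.asarray(D, dtype=float)
    M = np.eye(J.shape[0]) + Dm * J
    try:
        Jd = np.linalg.solve(M, J)
    except np.linalg.LinAlgError:
        Jd = np.full_like(J, np.nan)
    if not np.all(np.isfinite(Jd)):
        raise np.linalg.LinAlgError(
            "delay operator (I + D*J) is singular or ill-conditioned "
            f"(cond={np.linalg.cond(M):.3g})"
        )
    return Jd


def _embedded_jacobian(network: NetworkSpec, params: dict) -> np.ndarray:
    J = jacobian(network, params)
    D = build_delay_matrix(network, np.asarray(params["d_s"], dtype=float))
    return delay_embed(J, D)


def transfer_function(
    network: NetworkSpec, params: dict, freq: np.ndarray
) -> np.ndarray:
    """Channel-by-input transfer functions ``H(f)``, shape (n_freq, nc, n_in)."""
    Jd = _embedded_jacobian(network, params)
    max_re = np.max(np.linalg.eigvals(Jd).real)
    if max_re >= 0:
        raise UnstableModelError(
            f"delay-embedded Jacobian unstable (max Re eigenvalue {max_re:.3g}/s)"
        )
    U = input_matrix(network, params)
    Lr = lead_rows(network, params)
    n = Jd.shape[0]
    freq = np.asarray(freq, dtype=float)
    # Batched resolvent solve over the frequency grid.
    iw = 2j * np.pi * freq
    A = iw[:, None, None] * np.eye(n) - Jd[None, :, :]
    sol = np.linalg.solve(A, np.broadcast_to(U.astype(complex), (freq.size, n, U.shape[1])))
    return Lr @ sol


def predict_csd(
    network: NetworkSpec,
    params: dict,
    freq: np.ndarray,
    noise: dict | None = None,
    input_gain: float = DEFAULT_INPUT_GAIN,
    condition: str = "prediction",
    channel_noise: bool = True,
) -> CSDDataset:
    """Predicted cross-spectral density for one condition.

    ``params`` is a natural-scale parameter dictionary (as produced by
    :func:`gendcm.params.condition_parameters`); ``noise`` defaults to
    ``params["noise"]``.  Innovations at the two input sites are independent
    with identical power laws.
    """
    noise = dict(params["noise"] if noise is None else noise)
    freq = np.asarray(freq, dtype=float)
    H = transfer_function(network, params, freq)
    g_u = input_gain * noise["alpha_u"] * freq ** (-noise["beta_u"])
    G = np.einsum("fci,f,fdi->fcd", H, g_u, H.conj())
    if channel_noise:
        nc = H.shape[1]
        common = noise["alpha_c"] * freq ** (-noise["beta_c"])
        specific = noise["alpha_s"] * freq ** (-noise["beta_s"])
        G = G + common[:, None, None] * np.ones((nc, nc)) + specific[:, None, None] * np.eye(nc)
    G = 0.5 * (G + np.conj(np.swapaxes(G, 1, 2)))  # kill rounding asymmetry
    return CSDDataset(freq=freq, G={condition: G}, channels=tuple(network.channels))


def coherence(csd: CSDDataset) -> dict[str, np.ndarray]:
    """Magnitude-squared coherence ``|G_ij|^2 / (G_ii G_jj)`` per condition."""
    out = {}
    for cond, G in csd.G.items():
        auto = np.real(np.einsum("fcc->fc", G))
        if np.any(auto <= 0):
            raise ValueError("coherence undefined: nonpositive auto-spectrum")
        out[cond] = np.abs(G) ** 2 / (auto[:, :, None] * auto[:, None, :])
    return out


def population_spectra(
    network: NetworkSpec,
    params: dict,
    freq: np.ndarray,
    source: str,
    population: str,
    input_gain: float = DEFAULT_INPUT_GAIN,
) -> np.ndarray:
    """Auto-spectrum of a single population (virtual electrode, no channel noise)."""
    spec = network.definition(source).spec
    if population not in spec.populations:
        raise KeyError(f"unknown population {population!r} of source {source!r}")
    Jd = _embedded_jacobian(network, params)
    max_re = np.max(np.linalg.eigvals(Jd).real)
    if max_re >= 0:
        raise UnstableModelError(
            f"delay-embedded Jacobian unstable (max Re eigenvalue {max_re:.3g}/s)"
        )
    U = input_matrix(network, params)
    row = np.zeros(network.n_states)
    row[network.v_index(source, population)] = 1.0
    freq = np.asarray(freq, dtype=float)
    noise = params["noise"]
    g_u = input_gain * noise["alpha_u"] * freq ** (-noise["beta_u"])
    n = Jd.shape[0]
    iw = 2j * np.pi * freq
    A = iw[:, None, None] * np.eye(n) - Jd[None, :, :]
    sol = np.linalg.solve(A, np.broadcast_to(U.astype(complex), (freq.size, n, U.shape[1])))
    h = row @ sol  # (n_freq, n_inputs)
    return np.real(np.sum(g_u[:, None] * np.abs(h) ** 2, axis=1))
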