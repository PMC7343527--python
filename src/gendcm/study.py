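"""Synthetic studies with known ground truth.

This module stands in for an experimental cohort: it generates paired
baseline/modulated ("OFF"/"ON" medication) cross-spectral datasets from known
parameters, either analytically (spectral prediction plus complex-Wishart
sampling noise, the fast default) or by stochastic simulation of the
time-domain dynamics followed by multivariate autoregressive (MVAR) spectral
estimation (the slow validation path).

Ground-truth conventions (see docs/methods.md): hemisphere parameters are
drawn around the priors with a dispersion of 0.25 prior-sd on couplings, time
constants and extrinsic strengths; the lead-field gains are raised and the
observation noise lowered so the baseline STN spectrum shows a visible beta
peak; the default condition effect reduces the pallido-subthalamic (GPe->STN),
hyperdirect, and corticostriatal couplings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import get_model
from .network import NetworkSpec, default_network
from .params import (
    ParameterSet,
    PriorSet,
    build_priors,
    condition_parameters,
)
from .spectral import (
    DEFAULT_INPUT_GAIN,
    CSDDataset,
    UnstableModelError,
    lead_rows,
    predict_csd,
)

__all__ = [
    "StudyGroundTruth",
    "DEFAULT_B_TRUE",
    "colored_noise",
    "simulate_time_series",
    "estimate_csd_mvar",
    "generate_study",
]

logger = logging.getLogger(__name__)

# Default condition effect: dopaminergic-medication-like reduction of the
# pallido-subthalamic, hyperdirect and corticostriatal couplings.
DEFAULT_B_TRUE: dict[str, dict[int, float]] = {
    "bgt": {4: -0.5},       # GPe -> STN
    "ext": {2: -0.5, 3: -0.5},  # corticostriatal, hyperdirect
}


@dataclass
class StudyGroundTruth:
    """Per-hemisphere true parameters and the study design that produced them."""

    theta_true: list[np.ndarray]
    B_true: dict[str, dict[int, float]]
    seed: int
    noise_scale: float
    dof: int
    jitter_sd: float
    b_jitter_sd: float
    redraws: int = 0
    conditions: tuple[str, str] = ("OFF", "ON")


def colored_noise(
    alpha: float,
    beta: float,
    n_samples: int,
    dt: float,
    seed: int | np.random.Generator | None = None,
    f0: float = 1.0,
) -> np.ndarray:
    """Stationary power-law noise with one-sided PSD ``alpha (f/f0)^-beta``.

    Built by spectral factorisation: white Gaussian noise is shaped in the
    frequency domain by the square root of the target density.  ``beta = 0``
    gives white noise of density ``alpha``; ``beta`` up to 2 is supported.
    The DC component is removed.
    """
    if not (0 <= beta <= 2):
        raise ValueError(f"power-law exponent beta must be in [0, 2], got {beta}")
    if n_samples < 256:
        raise ValueError("n_samples must be >= 256")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, dt)
    amp = np.zeros(freqs.size)
    amp[1:] = np.sqrt(alpha * (freqs[1:] / f0) ** (-beta))
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    # Scale so that the periodogram density matches the target PSD.
    spec = amp * z * np.sqrt(n_samples / (4.0 * dt))
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = spec[-1].real * np.sqrt(2.0)
    return np.fft.irfft(spec, n=n_samples)


def _simulation_tables(network: NetworkSpec, params: dict, dt: float):
    """Per-lag population coupling matrices and bookkeeping for integration."""
    n_pop = sum(network.definition(s).spec.n_populations for s, _ in network.sources)
    pop_base, bases = {}, 0
    for name, _ in network.sources:
        pop_base[name] = bases
        bases += network.definition(name).spec.n_populations
    d_pair = np.asarray(params["d_s"], dtype=float).reshape(
        network.n_sources, network.n_sources
    ).T  # [to, from]
    lag_steps = np.rint(d_pair / dt).astype(int)
    mats: dict[int, np.ndarray] = {}
    src_index = {name: i for i, (name, _) in enumerate(network.sources)}
    for name, kind in network.sources:
        spec = get_model(kind).spec
        W = spec.coupling_matrix(params["gamma"][name])
        lag = lag_steps[src_index[name], src_index[name]]
        M = mats.setdefault(lag, np.zeros((n_pop, n_pop)))
        b = pop_base[name]
        P = spec.n_populations
        # self (same-population) couplings are undelayed synaptic terms too:
        # keep the within-source lag for cross-population arrows only.
        M0 = mats.setdefault(0, np.zeros((n_pop, n_pop)))
        M[b : b + P, b : b + P] += W - np.diag(np.diag(W))
        M0[b : b + P, b : b + P] += np.diag(np.diag(W))
    A = np.asarray(params["A"], dtype=float)
    for c in network.extrinsic:
        lag = lag_steps[src_index[c.to_source], src_index[c.from_source]]
        M = mats.setdefault(lag, np.zeros((n_pop, n_pop)))
        i = pop_base[c.to_source] + network.definition(c.to_source).spec.populations.index(
            c.to_population
        )
        j = pop_base[c.from_source] + network.definition(
            c.from_source
        ).spec.populations.index(c.from_population)
        M[i, j] += A[c.index - 1]
    R_pop = np.concatenate(
        [
            np.full(network.definition(name).spec.n_populations, params["R"][name])
            for name, _ in network.sources
        ]
    )
    T_pop = np.concatenate([params["T_s"][name] for name, _ in network.sources])
    input_idx = [
        pop_base[name]
        + network.definition(name).spec.populations.index(
            network.definition(name).spec.input_population
        )
        for name, _ in network.sources
    ]
    return mats, R_pop, T_pop, input_idx, n_pop


def simulate_time_series(
    network: NetworkSpec,
    params: dict,
    duration_s: float,
    dt_ms: float = 0.05,
    seed: int | None = None,
    burn_in_s: float = 2.0,
    input_gain: float = DEFAULT_INPUT_GAIN,
    observation_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic (Euler-Maruyama) integration of the delayed network dynamics.

    Endogenous power-law innovations drive the input populations; axonal
    delays are realised exactly with per-source-pair lag buffers (the spectral
    prediction approximates the same delays to first order).  Returns
    ``(t, Y)`` with one column per observation channel after discarding the
    burn-in.

    Raises ``RuntimeError`` if the state diverges (|v| > 1e6), which flags an
    unstable parameter draw.
    """
    if dt_ms > 0.1:
        raise ValueError("dt_ms must be <= 0.1 ms for a faithful integration")
    dt = dt_ms * 1e-3
    rng = np.random.default_rng(seed)
    n_keep = int(round(duration_s / dt))
    n_burn = int(round(burn_in_s / dt))
    n_total = n_keep + n_burn

    mats, R_pop, T_pop, input_idx, n_pop = _simulation_tables(network, params, dt)
    lags = sorted(mats)
    max_lag = max(lags)
    noise = params["noise"]
    u = np.column_stack(
        [
            colored_noise(
                input_gain * noise["alpha_u"], noise["beta_u"], n_total, dt, rng
            )
            for _ in input_idx
        ]
    )

    v = np.zeros(n_pop)
    vdot = np.zeros(n_pop)
    nbuf = max_lag + 1
    vbuf = np.zeros((nbuf, n_pop))
    v_hist = np.empty((n_total, n_pop))
    lag_mats = [(lag, mats[lag]) for lag in lags]
    inv_T = 1.0 / T_pop
    exp, matmul = np.exp, np.matmul  # keep the hot loop lean
    with np.errstate(over="ignore"):  # exp saturates harmlessly under extreme drive
        for t in range(n_total):
            acc = None
            for lag, M in lag_mats:
                v_lag = v if lag == 0 else vbuf[(t - lag) % nbuf]
                rate = 1.0 / (1.0 + exp(-R_pop * v_lag)) - 0.5
                term = matmul(M, rate)
                acc = term if acc is None else acc + term
            acc[input_idx] += u[t]
            acc = (acc - 2.0 * vdot - v * inv_T) * inv_T
            v = v + dt * vdot
            vdot = vdot + dt * acc
            vbuf[t % nbuf] = v
            v_hist[t] = v
            if t % 4096 == 0 and not np.all(np.abs(v) < 1e6):
                raise RuntimeError(
                    f"simulation diverged at t={t * dt:.3f}s (unstable parameters)"
                )
    if not np.all(np.abs(v_hist) < 1e6) or not np.all(np.isfinite(v_hist)):
        raise RuntimeError("simulation diverged (unstable parameters)")
    v_hist = v_hist[n_burn:]

    # Observation: per-source mixtures and lead-field gains on v-states.
    Lr = lead_rows(network, params)
    v_cols = np.concatenate(
        [
            np.arange(
                network.state_offsets()[name],
                network.state_offsets()[name]
                + network.definition(name).spec.n_populations,
            )
            for name, _ in network.sources
        ]
    )
    Y = v_hist @ Lr[:, v_cols].T
    if observation_noise:
        common = colored_noise(noise["alpha_c"], noise["beta_c"], n_keep, dt, rng)
        Y = Y + common[:, None]
        for c in range(Y.shape[1]):
            Y[:, c] += colored_noise(noise["alpha_s"], noise["beta_s"], n_keep, dt, rng)
    t_axis = np.arange(n_keep) * dt
    return t_axis, Y


def estimate_csd_mvar(
    series: np.ndarray,
    order: int = 12,
    freq: np.ndarray | None = None,
    dt: float = 1e-3,
    ridge: float = 1e-6,
) -> CSDDataset:
    """Cross-spectral density via a regularised least-squares MVAR fit.

    The spectral matrix is ``G(f) = 2 dt A(f)^-1 Sigma A(f)^-H`` with
    ``A(f) = I - sum_k A_k exp(-i 2 pi f k dt)`` (one-sided density
    convention).  ``ridge`` adds a small multiple of the mean regressor
    variance to the normal equations for conditioning.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] < series.shape[1]:
        series = series.T
    n, nc = series.shape
    if order < 1:
        raise ValueError("MVAR order must be >= 1")
    if n <= order * nc * 10:
        raise ValueError("series too short for the requested MVAR order")
    if freq is None:
        freq = np.linspace(5.0, 45.0, 41)
    freq = np.asarray(freq, dtype=float)

    Y = series[order:]
    X = np.concatenate([series[order - k : n - k] for k in range(1, order + 1)], axis=1)
    XtX = X.T @ X
    lam = ridge * np.trace(XtX) / XtX.shape[0]
    try:
        B = np.linalg.solve(XtX + lam * np.eye(XtX.shape[0]), X.T @ Y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"ill-conditioned MVAR regression: {err}") from err
    resid = Y - X @ B
    Sigma = resid.T @ resid / resid.shape[0]

    A_k = B.reshape(order, nc, nc).transpose(0, 2, 1)  # A_k[target, source]
    G = np.empty((freq.size, nc, nc), dtype=complex)
    k_idx = np.arange(1, order + 1)
    for i, f in enumerate(freq):
        phase = np.exp(-2j * np.pi * f * k_idx * dt)
        A_f = np.eye(nc) - np.tensordot(phase, A_k, axes=(0, 0))
        Ainv = np.linalg.inv(A_f)
        G[i] = 2.0 * dt * (Ainv @ Sigma @ Ainv.conj().T)
    G = 0.5 * (G + np.conj(np.swapaxes(G, 1, 2)))
    channels = tuple(f"ch{c}" for c in range(nc))
    return CSDDataset(freq=freq, G={"estimate": G}, channels=channels)


def _complex_wishart_sample(
    G: np.ndarray, dof: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample-CSD noise: average of ``dof`` rank-one outer products of
    complex Gaussian vectors with covariance ``G`` (per frequency)."""
    nf, nc, _ = G.shape
    out = np.empty_like(G)
    for i in range(nf):
        w, V = np.linalg.eigh(G[i])
        w = np.clip(w, 0.0, None)
        Lchol = V * np.sqrt(w)
        Z = (
            rng.standard_normal((nc, dof)) + 1j * rng.standard_normal((nc, dof))
        ) / np.sqrt(2.0)
        Y = Lchol @ Z
        out[i] = Y @ Y.conj().T / dof
    return out


def _study_base_theta(priors: PriorSet, noise_scale: float) -> np.ndarray:
    ps = ParameterSet(priors.layout)
    ps["L"] = 4.0
    ps["alpha_c"] = np.log(noise_scale) - 2.0
    ps["alpha_s"] = np.log(noise_scale) - 2.0
    return ps.theta


def generate_study(
    n_hemispheres: int = 20,
    B_true: dict[str, dict[int, float]] | None = None,
    noise_scale: float = 1.0,
    seed: int = 0,
    network: NetworkSpec | None = None,
    priors: PriorSet | None = None,
    freq: np.ndarray | None = None,
    dof: int = 46,
    jitter_sd_frac: float = 0.25,
    b_jitter_sd: float = 0.05,
    method: str = "analytic",
    duration_s: float = 60.0,
    input_gain: float = DEFAULT_INPUT_GAIN,
) -> tuple[list[CSDDataset], StudyGroundTruth]:
    """Paired OFF/ON synthetic CSD datasets with known ground truth.

    Per hemisphere, log-scale parameters are drawn around the study base
    (couplings, time constants and extrinsic strengths jittered by
    ``jitter_sd_frac`` prior-sd), the condition effect ``B_true`` (plus
    hemisphere jitter) is applied for the ON condition, and sample CSDs are
    produced analytically with complex-Wishart noise of ``dof`` segments
    (``method="analytic"``) or by stochastic simulation and MVAR estimation
    (``method="mvar"``).  Unstable draws are rejected and redrawn (at most 10
    attempts each, logged).
    """
    if n_hemispheres < 2:
        raise ValueError("n_hemispheres must be >= 2")
    if method not in ("analytic", "mvar"):
        raise ValueError(f"unknown method {method!r}")
    network = default_network() if network is None else network
    priors = build_priors(network) if priors is None else priors
    freq = np.linspace(5.0, 45.0, 41) if freq is None else np.asarray(freq, dtype=float)
    B_true = DEFAULT_B_TRUE if B_true is None else B_true
    rng = np.random.default_rng(seed)
    layout = priors.layout
    sl = layout.slices()

    jitter_sd = np.zeros(layout.n_params)
    for name, _ in network.sources:
        for block in (f"gamma_{name}", f"T_{name}"):
            jitter_sd[sl[block]] = jitter_sd_frac * np.sqrt(priors.block(block)[1])
    jitter_sd[sl["A"]] = jitter_sd_frac * np.sqrt(priors.block("A")[1])

    base = _study_base_theta(priors, noise_scale)
    datasets: list[CSDDataset] = []
    theta_true: list[np.ndarray] = []
    redraws = 0
    for _ in range(n_hemispheres):
        for attempt in range(10):
            theta = base + rng.normal(0.0, 1.0, layout.n_params) * jitter_sd
            ps = ParameterSet(layout, theta)
            for key, entries in B_true.items():
                block = "B_ext" if key == "ext" else f"B_{key}"
                for idx, val in entries.items():
                    ps[block][idx - 1] = val + rng.normal(0.0, b_jitter_sd)
            try:
                nat_off = condition_parameters(ps, priors, network, "baseline")
                nat_on = condition_parameters(ps, priors, network, "modulated")
                if method == "analytic":
                    g_off = predict_csd(network, nat_off, freq, input_gain=input_gain).G[
                        "prediction"
                    ]
                    g_on = predict_csd(network, nat_on, freq, input_gain=input_gain).G[
                        "prediction"
                    ]
                    G_off = _complex_wishart_sample(g_off, dof, rng)
                    G_on = _complex_wishart_sample(g_on, dof, rng)
                else:
                    sub_seed = int(rng.integers(2**31 - 1))
                    dt_ms = 0.05
                    csds = []
                    for k, nat in enumerate((nat_off, nat_on)):
                        _, Y = simulate_time_series(
                            network, nat, duration_s, dt_ms=dt_ms,
                            seed=sub_seed + k, input_gain=input_gain,
                        )
                        step = max(1, int(round(1e-3 / (dt_ms * 1e-3))))
                        est = estimate_csd_mvar(
                            Y[::step], order=12, freq=freq, dt=step * dt_ms * 1e-3
                        )
                        csds.append(est.G["estimate"])
                    G_off, G_on = csds
            except (UnstableModelError, RuntimeError) as err:
                redraws += 1
                logger.info("unstable draw rejected (attempt %d): %s", attempt + 1, err)
                continue
            datasets.append(
                CSDDataset(
                    freq=freq,
                    G={"OFF": G_off, "ON": G_on},
                    channels=tuple(network.channels),
                )
            )
            theta_true.append(ps.theta.copy())
            break
        else:
            raise RuntimeError("could not draw a stable hemisphere in 10 attempts")

    truth = StudyGroundTruth(
        theta_true=theta_true,
        B_true={k: dict(v) for k, v in B_true.items()},
        seed=seed,
        noise_scale=noise_scale,
        dof=dof,
        jitter_sd=jitter_sd_frac,
        b_jitter_sd=b_jitter_sd,
        redraws=redraws,
    )
    return datasets, truth
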