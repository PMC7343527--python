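"""Model/Results façade for fitting the spectral DCM to CSD data.

:class:`SpectralDCM` binds a :class:`~gendcm.spectral.CSDDataset` (one or two
conditions; the first is the baseline) to a network and prior specification.
``fit`` runs variational Laplace (optionally with chained multistart
re-initialisation) and returns a :class:`SpectralDCMResults` carrying the
posterior mean and covariance, the free-energy trajectory, per-condition
predicted spectra, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inversion import (
    InversionResult,
    feature_vector,
    features_to_csd,
    make_csd_batch_predictor,
    make_csd_predictor,
    multistart_invert,
)
from .network import NetworkSpec, default_network
from .params import (
    ParameterSet,
    PriorSet,
    build_priors,
    condition_parameters,
    default_b_indices,
)
from .spectral import CSDDataset, population_spectra, predict_csd

__all__ = ["SpectralDCM", "SpectralDCMResults"]


class SpectralDCM:
    """Spectral dynamic causal model for two-channel cross-spectral densities.

    Parameters
    ----------
    data
        Observed CSD features; conditions are fitted jointly with shared
        log-scale parameters and free condition effects B on the declared
        connections (first condition = baseline).
    network
        Defaults to the shipped motor-cortex + basal-ganglia-thalamus network.
    priors
        Defaults to the registered model priors and network-level conventions.
    b_indices
        Which connections may differ between conditions; defaults to all
        intrinsic connections and all extrinsic groups.
    """

    def __init__(
        self,
        data: CSDDataset,
        network: NetworkSpec | None = None,
        priors: PriorSet | None = None,
        b_indices: dict | None = None,
        input_gain: float = 512.0,
    ):
        self.data = data
        self.network = default_network() if network is None else network
        self.priors = build_priors(self.network) if priors is None else priors
        self.b_indices = (
            default_b_indices(self.network) if b_indices is None else b_indices
        )
        if tuple(data.channels) != tuple(self.network.channels):
            raise ValueError(
                f"data channels {data.channels} do not match network channels "
                f"{self.network.channels}"
            )
        if len(data.conditions) not in (1, 2):
            raise ValueError("expected one baseline and at most one modulated condition")
        self.input_gain = input_gain
        self._predict = make_csd_predictor(
            self.network,
            self.priors,
            data.freq,
            data.conditions,
            self.b_indices,
            input_gain=input_gain,
        )
        self._predict_batch = make_csd_batch_predictor(
            self.network,
            self.priors,
            data.freq,
            data.conditions,
            self.b_indices,
            input_gain=input_gain,
        )
        self.endog = feature_vector(data)

    @property
    def n_features(self) -> int:
        return self.endog.size

    @classmethod
    def from_config(cls, config, data: CSDDataset) -> "SpectralDCM":
        """Build a model from a validated :class:`~gendcm.config.RunConfig`."""
        network = config.network()
        j_states, k_states = {}, {}
        for (name, _), opts in zip(network.sources, config.models):
            if opts.J:
                j_states[name] = tuple(opts.J)
            if opts.K:
                k_states[name] = tuple(opts.K)
        priors = build_priors(
            network,
            j_states=j_states or None,
            k_states=k_states or None,
        )
        return cls(data, network=network, priors=priors, b_indices=config.b_indices())

    def predict(
        self, theta: np.ndarray | ParameterSet | None = None, condition: str = "baseline"
    ) -> CSDDataset:
        """Forward prediction for one condition at ``theta`` (default: priors)."""
        ps = (
            theta
            if isinstance(theta, ParameterSet)
            else ParameterSet(self.priors.layout, theta)
        )
        nat = condition_parameters(
            ps, self.priors, self.network, condition, self.b_indices
        )
        return predict_csd(
            self.network,
            nat,
            self.data.freq,
            input_gain=self.input_gain,
            condition=condition,
        )

    def fit(
        self,
        restarts: int = 1,
        maxiter: int = 64,
        tol: float = 1e-2,
        start: np.ndarray | None = None,
        seed: int | None = None,
    ) -> "SpectralDCMResults":
        """Invert the model by variational Laplace with chained restarts."""
        res = multistart_invert(
            self._predict,
            self.endog,
            prior_mean=np.zeros(self.priors.layout.n_params),
            prior_prec=self.priors.precision(),
            n_restarts=restarts,
            seed=seed,
            hE_mean=self.priors.hE_mean,
            hE_var=self.priors.hE_var,
            maxiter=maxiter,
            tol=tol,
            x0=start,
            predict_batch=self._predict_batch,
        )
        return SpectralDCMResults(self, res)


def _parameter_labels(priors: PriorSet, network: NetworkSpec) -> list[str]:
    labels = []
    arrows = {}
    for name, _ in network.sources:
        spec = network.definition(name).spec
        arrows[name] = {
            c.index: f"{c.source}->{c.target}" for c in spec.connections
        }
    ext = {c.index: f"{c.from_source}.{c.from_population}->{c.to_source}.{c.to_population}"
           for c in network.extrinsic}
    for block, n in priors.layout.blocks:
        for i in range(1, n + 1):
            if block.startswith(("gamma_", "B_")) and not block == "B_ext":
                src = block.split("_", 1)[1]
                if src in arrows:
                    labels.append(f"{block}[{i}] {arrows[src][i]}")
                    continue
            if block == "A":
                labels.append(f"A[{i}] {ext[i]}")
                continue
            if block == "B_ext":
                grp = "+".join(str(a) for a in network.b_ext_groups[i - 1])
                labels.append(f"B_ext[{i}] A{{{grp}}}")
                continue
            labels.append(f"{block}[{i}]" if n > 1 else block)
    return labels


class SpectralDCMResults:
    """Posterior summary of a fitted spectral DCM."""

    def __init__(self, model: SpectralDCM, result: InversionResult):
        self.model = model
        self._result = result
        self.params = ParameterSet(model.priors.layout, result.posterior_mean)
        self.cov_params = result.posterior_cov
        self.F_trace = result.F_trace
        self.lam = result.lam
        self.converged = result.converged
        self.n_iter = result.n_iter
        self.restart_F = result.restart_F

    @property
    def F(self) -> float:
        """Final free energy (approximate log model evidence)."""
        return float(self.F_trace[-1])

    @property
    def bse(self) -> np.ndarray:
        """Posterior standard deviations of the log-scale parameters."""
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        mean = self._result.posterior_mean
        return np.column_stack([mean - z * self.bse, mean + z * self.bse])

    @property
    def predicted(self) -> dict[str, CSDDataset]:
        """Per-condition predicted CSD at the posterior mean."""
        return {
            cond: self.model.predict(self.params, "baseline" if i == 0 else "modulated")
            for i, cond in enumerate(self.model.data.conditions)
        }

    def predicted_dataset(self) -> CSDDataset:
        """Predicted features reshaped into one multi-condition dataset."""
        return features_to_csd(
            self._result.predicted_features,
            self.model.data.freq,
            self.model.data.channels,
            self.model.data.conditions,
        )

    def population_spectrum(self, source: str, population: str,
                            condition: str = "baseline") -> np.ndarray:
        """MAP auto-spectrum of one population (virtual electrode, no channel noise)."""
        nat = condition_parameters(
            self.params, self.model.priors, self.model.network, condition,
            self.model.b_indices,
        )
        return population_spectra(
            self.model.network, nat, self.model.data.freq, source, population,
            input_gain=self.model.input_gain,
        )

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        labels = _parameter_labels(self.model.priors, self.model.network)
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "theta": self._result.posterior_mean,
                "sd": self.bse,
                f"ci{int((1-alpha)*100)}_low": ci[:, 0],
                f"ci{int((1-alpha)*100)}_high": ci[:, 1],
                "natural": self.model.priors.pi * np.exp(self._result.posterior_mean),
            },
            index=labels,
        )

    def summary(self, alpha: float = 0.05) -> str:
        head = (
            f"Spectral DCM ({' + '.join(k for _, k in self.model.network.sources)})\n"
            f"conditions: {', '.join(self.model.data.conditions)}   "
            f"n features: {self.model.n_features}\n"
            f"free energy: {self.F:.2f}   iterations: {self.n_iter}   "
            f"converged: {self.converged}   log-precision: {self.lam:.2f}\n"
        )
        with pd.option_context("display.max_rows", None, "display.width", 120):
            body = self.summary_frame(alpha).to_string(float_format=lambda x: f"{x:10.4f}")
        return head + body

    def save(self, path) -> None:
        from .io import save_result

        save_result(path, self)
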