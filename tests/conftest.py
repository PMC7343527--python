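import numpy as np
import pytest

from gendcm.models import ModelSpec, get_model, register_model
from gendcm.network import NetworkSpec, default_network
from gendcm.params import ParameterSet, build_priors, condition_parameters


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def priors(network):
    return build_priors(network)


@pytest.fixture()
def theta0(priors):
    return ParameterSet(priors.layout)


@pytest.fixture()
def nat_params(network, priors, theta0):
    """Natural-scale parameters at the prior means (baseline condition)."""
    return condition_parameters(theta0, priors, network, "baseline")


def _ensure_single_pop_model():
    """A one-population model with no intrinsic connections, for closed forms."""
    if "SINGLE" not in __import__("gendcm.models", fromlist=["registered_models"]).registered_models():
        spec = ModelSpec(
            kind="SINGLE",
            populations=("P",),
            connections=(),
            input_population="P",
            output_mixture={"P": 1.0},
            intrinsic_delay_ms=0.0,
        )
        pri = {
            "gamma": (np.zeros(0), np.zeros(0) + 1.0),
            "T_ms": (np.array([10.0]), np.array([0.25])),
            "R": (np.array([2.0 / 3]), np.array([1.0 / 32])),
        }
        register_model("SINGLE", spec, pri)


@pytest.fixture(scope="session")
def single_pop_network():
    """One isolated population observed directly; no extrinsic connections."""
    _ensure_single_pop_model()
    return NetworkSpec(
        sources=(("pop", "SINGLE"),),
        extrinsic=(),
        channels=("ch",),
        b_ext_groups=(),
        a_prior_mean=(),
        a_prior_var=(),
        delay_prior_mean_ms=(0.001,),
        delay_prior_var=(1.0 / 32,),
    )


def single_pop_params(T_s=0.01, noise=None, L=1.0, d_s=0.0):
    """Natural-scale parameter dict for the single-population network."""
    base_noise = {
        "alpha_u": 1.0,
        "beta_u": 1.0,
        "alpha_c": 0.0,
        "beta_c": 1.0,
        "alpha_s": 0.0,
        "beta_s": 1.0,
    }
    if noise:
        base_noise.update(noise)
    return {
        "gamma": {"pop": np.zeros(0)},
        "T_s": {"pop": np.array([T_s])},
        "R": {"pop": 2.0 / 3},
        "A": np.zeros(0),
        "d_s": np.array([d_s]),
        "noise": base_noise,
        "L": np.array([L]),
    }
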