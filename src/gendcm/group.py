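"""Group-level inference on condition effects.

Each hemisphere's inversion yields posterior-mean condition effects ``B`` (one
per intrinsic connection and extrinsic group, 26 in the shipped network).  At
the group level every connection is tested with a one-sample t-test of the B
estimates against zero (two-tailed), and Benjamini-Hochberg false-discovery
control is applied across the whole family of condition-effect parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import NetworkSpec, default_network
from .params import ParameterSet

__all__ = [
    "GroupResult",
    "one_sample_ttest",
    "bh_fdr",
    "extract_b_matrix",
    "b_parameter_labels",
    "summarize_group",
    "null_rejection_rates",
]


def one_sample_ttest(values: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed one-sample t-test against zero: returns ``(t, df, p)``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if np.isclose(np.var(values, ddof=1), 0.0):
        raise ValueError("zero sample variance")
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), int(values.size - 1), float(res.pvalue)


def bh_fdr(pvals: np.ndarray, m_total: int | None = None, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level ``q``.

    ``m_total`` sets the size of the test family; tests not listed in
    ``pvals`` are treated as nonsignificant (p = 1), so the step-up
    thresholds are ``k q / m_total``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("invalid FDR level q")
    m_total = pvals.size if m_total is None else int(m_total)
    if m_total < pvals.size:
        raise ValueError("m_total must be >= number of listed p-values")
    padded = np.concatenate([pvals, np.ones(m_total - pvals.size)])
    reject, *_ = multipletests(padded, alpha=q, method="fdr_bh")
    return reject[: pvals.size]


def b_parameter_labels(network: NetworkSpec) -> list[str]:
    """Human-readable labels of all condition-effect parameters, in block order."""
    labels = []
    for name, _ in network.sources:
        spec = network.definition(name).spec
        by_index = {c.index: c for c in spec.connections}
        for i in range(1, spec.n_connections + 1):
            c = by_index[i]
            labels.append(f"B_{name}[{i}] {c.source}->{c.target}")
    for g, group in enumerate(network.b_ext_groups, start=1):
        arrows = [
            f"{c.from_source}.{c.from_population}->{c.to_source}.{c.to_population}"
            for c in network.extrinsic
            if c.index in group
        ]
        labels.append(f"B_ext[{g}] " + "|".join(arrows))
    return labels


def extract_b_matrix(results, network: NetworkSpec | None = None) -> np.ndarray:
    """Stack per-hemisphere posterior-mean B vectors into an (n, m) matrix.

    ``results`` may be fitted results objects (anything with ``.params``
    holding a :class:`~gendcm.params.ParameterSet`), ParameterSets, flat
    vectors interpreted against the network layout, or an already-stacked
    matrix (returned as-is).
    """
    network = default_network() if network is None else network
    arr = np.asarray(results, dtype=object)
    if isinstance(results, np.ndarray) and results.ndim == 2:
        return np.asarray(results, dtype=float)
    rows = []
    for r in results:
        ps = getattr(r, "params", r)
        if isinstance(ps, np.ndarray):
            from .params import ParameterLayout

            ps = ParameterSet(ParameterLayout.for_network(network), ps)
        if not isinstance(ps, ParameterSet):
            raise TypeError(f"cannot extract B estimates from {type(r)}")
        blocks = [ps[f"B_{name}"] for name, _ in network.sources] + [ps["B_ext"]]
        rows.append(np.concatenate(blocks))
    return np.asarray(rows, dtype=float)


@dataclass
class GroupResult:
    """Per-connection group statistics and FDR decisions."""

    table: pd.DataFrame
    n_hemispheres: int
    q: float
    m_total: int

    @property
    def significant_uncorrected(self) -> list[str]:
        return list(self.table.index[self.table["p"] < self.q])

    @property
    def significant_fdr(self) -> list[str]:
        return list(self.table.index[self.table["fdr_reject"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="connection")


def summarize_group(
    results,
    network: NetworkSpec | None = None,
    q: float = 0.05,
    m_total: int | None = None,
) -> GroupResult:
    """Group table over all condition-effect parameters.

    One-sample t-tests per connection, BH-FDR over the full condition-effect
    family (``m_total`` defaults to the number of B parameters, 26 in the
    shipped network), and the signed direction of each effect.
    """
    network = default_network() if network is None else network
    B = extract_b_matrix(results, network)
    labels = b_parameter_labels(network)
    if B.shape[1] != len(labels):
        raise ValueError(
            f"B matrix has {B.shape[1]} columns, expected {len(labels)}"
        )
    n = B.shape[0]
    if n < 2:
        raise ValueError("need at least 2 hemispheres")
    t_vals, p_vals = [], []
    for j in range(B.shape[1]):
        if np.isclose(np.var(B[:, j], ddof=1), 0.0):
            # clamped or undeclared connections carry no evidence either way
            t_vals.append(0.0)
            p_vals.append(1.0)
            continue
        t, _, p = one_sample_ttest(B[:, j])
        t_vals.append(t)
        p_vals.append(p)
    m_total = len(labels) if m_total is None else m_total
    reject = bh_fdr(np.asarray(p_vals), m_total=m_total, q=q)
    table = pd.DataFrame(
        {
            "mean_B": B.mean(axis=0),
            "t": t_vals,
            "df": n - 1,
            "p": p_vals,
            "fdr_reject": reject,
            "sign": np.sign(B.mean(axis=0)).astype(int),
        },
        index=labels,
    )
    return GroupResult(table=table, n_hemispheres=n, q=q, m_total=m_total)


def null_rejection_rates(
    n_replicates: int = 200,
    n_hemispheres: int = 20,
    jitter_sd: float = 0.05,
    alpha: float = 0.05,
    network: NetworkSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-connection uncorrected rejection rate under a null study.

    Emulates the study generator with no true condition effect: hemisphere B
    estimates are pure between-hemisphere jitter.  Returns the fraction of
    replicates in which each connection's uncorrected p fell below ``alpha``
    (a calibration check of the group pipeline; should be close to ``alpha``).
    """
    network = default_network() if network is None else network
    m = len(b_parameter_labels(network))
    rng = np.random.default_rng(seed)
    hits = np.zeros(m)
    for _ in range(n_replicates):
        B = rng.normal(0.0, jitter_sd, size=(n_hemispheres, m))
        res = summarize_group(B, network, q=alpha)
        hits += (res.table["p"].to_numpy() < alpha)
    return hits / n_replicates
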