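"""Synthetic QSAR datasets with controlled signal structure.

Real descriptor tables in this problem mix three kinds of columns: a few
descriptors genuinely related to activity, near-duplicates of those
(inter-descriptor correlation above the 0.8 filtering threshold), and columns
carrying no signal at all.  The generator reproduces exactly that statistical
structure so that descriptor selection, model fitting, and validation can all
be exercised against a known ground truth.  It makes no attempt to mimic the
marginal distributions of real computed descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mixqsar.datasets import DescriptorTable
from mixqsar.errors import ConfigurationError

RESPONSE_KINDS = ("linear", "kernel_nonlinear")


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic dataset.

    ``n_informative`` descriptors are i.i.d. standard normal and drive the
    response.  Each of the ``n_redundant`` columns is a noisy copy of one
    informative column with target Pearson correlation
    ``redundancy_correlation`` (> 0.8 so it would fail the correlation
    filter).  ``n_noise`` columns are independent of the response.  The
    response is either a linear combination of the informative columns or,
    for ``kernel_nonlinear``, a sum of cosines of scaled squared distances to
    random anchor points -- a target realizable by the trigonometric kernel.
    Gaussian response noise has standard deviation ``noise_sd`` (lg units).
    """

    n_compounds: int = 100
    n_informative: int = 3
    n_redundant: int = 2
    n_noise: int = 5
    redundancy_correlation: float = 0.95
    noise_sd: float = 0.1
    response_kind: str = "linear"
    coefficients: np.ndarray | None = None
    n_anchors: int = 5
    distance_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ConfigurationError("n_informative must be >= 1")
        if min(self.n_redundant, self.n_noise, self.n_compounds) < 0:
            raise ConfigurationError("counts must be nonnegative")
        if not 0.8 < self.redundancy_correlation <= 1.0:
            raise ConfigurationError("redundancy_correlation must lie in (0.8, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.response_kind not in RESPONSE_KINDS:
            raise ConfigurationError(f"response_kind must be one of {RESPONSE_KINDS}")
        if self.coefficients is not None:
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if len(self.coefficients) != self.n_informative:
                raise ConfigurationError(
                    f"coefficients length {len(self.coefficients)} != "
                    f"n_informative {self.n_informative}"
                )


@dataclass
class GroundTruth:
    """What the generator actually did, for tests to check recovery against."""

    response_kind: str
    informative_names: list[str]
    redundant_names: list[str]
    noise_names: list[str]
    redundant_parent: dict[str, str]
    coefficients: np.ndarray | None = None
    anchors: np.ndarray | None = None
    anchor_weights: np.ndarray | None = None
    distance_scale: float | None = None
    noise_free_response: np.ndarray = field(default=None)  # type: ignore[assignment]


def make_synthetic_dataset(config: SyntheticConfig) -> tuple[DescriptorTable, GroundTruth]:
    """Generate a descriptor table plus its generating ground truth.

    Identical configs (including seed) produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_compounds, config.n_informative

    informative = rng.standard_normal((n, k))
    inf_names = [f"inf{j + 1}" for j in range(k)]

    red_names, parents, red_cols = [], {}, []
    rho = config.redundancy_correlation
    for j in range(config.n_redundant):
        parent = j % k
        noise = rng.standard_normal(n)
        col = rho * informative[:, parent] + np.sqrt(1.0 - rho**2) * noise
        name = f"red{j + 1}"
        red_names.append(name)
        parents[name] = inf_names[parent]
        red_cols.append(col)

    noise_names = [f"noise{j + 1}" for j in range(config.n_noise)]
    noise_cols = rng.standard_normal((n, config.n_noise))

    truth = GroundTruth(
        response_kind=config.response_kind,
        informative_names=inf_names,
        redundant_names=red_names,
        noise_names=noise_names,
        redundant_parent=parents,
    )

    if config.response_kind == "linear":
        coef = config.coefficients
        if coef is None:
            coef = rng.uniform(0.5, 2.0, size=k) * rng.choice([-1.0, 1.0], size=k)
        signal = informative @ coef
        truth.coefficients = np.asarray(coef, dtype=float)
    else:
        anchors = rng.standard_normal((config.n_anchors, k))
        weights = rng.uniform(0.5, 1.5, size=config.n_anchors) * rng.choice(
            [-1.0, 1.0], size=config.n_anchors
        )
        sq = ((informative[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        signal = np.cos(config.distance_scale * sq) @ weights
        truth.anchors = anchors
        truth.anchor_weights = weights
        truth.distance_scale = config.distance_scale

    truth.noise_free_response = signal.copy()
    response = signal + config.noise_sd * rng.standard_normal(n)

    columns = {}
    for name, col in zip(inf_names, informative.T):
        columns[name] = col
    for name, col in zip(red_names, red_cols):
        columns[name] = col
    for name, col in zip(noise_names, noise_cols.T):
        columns[name] = col
    descriptors = pd.DataFrame(columns)
    ids = [f"cmp{i + 1}" for i in range(n)]
    table = DescriptorTable(ids, descriptors, response)
    return table, truth
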