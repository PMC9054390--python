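"""Synthetic descriptor tables with known ground truth.

The generator emulates the shape of a tabular 0-2D molecular-descriptor
dataset with an acute-toxicity-like endpoint: a few hundred compounds, tens
of descriptors with correlated blocks, constant and null (all-missing)
columns, and an endpoint produced by a smooth nonlinear function (a mixture
of saturating and quadratic terms) of a small informative subset, scaled
into a -log LC50-like range and degraded with Gaussian noise.

The nonlinearity family is fixed so that an RBF network can represent the
signal while a linear model cannot — the quadratic terms are symmetric in
centred descriptors and carry no linear correlation with the endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatable import DescriptorTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "default_scenario"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic scenario.

    Defaults define the package's reference scenario: 400 compounds,
    40 informative-or-noise descriptors of which 5 drive the endpoint, two
    correlated blocks of 4 at intra-block correlation 0.7, endpoint scaled
    into [0, 9], noise standard deviation set to one quarter of the
    noiseless signal's standard deviation (signal-to-noise ratio about 4),
    plus 2 constant and 1 null column appended.
    """

    n_compounds: int = 400
    n_descriptors: int = 40
    n_informative: int = 5
    correlated_block_sizes: list = field(default_factory=lambda: [4, 4])
    block_correlation: float = 0.7
    noise_sd: float | None = None  # None -> signal_sd / 4
    n_constant: int = 2
    n_null: int = 1
    endpoint_range: tuple = (0.0, 9.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative cannot exceed n_descriptors")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.n_informative + sum(self.correlated_block_sizes) > self.n_descriptors:
            raise ValueError("informative + correlated-block columns exceed n_descriptors")


@dataclass
class GroundTruth:
    """What the generator knows: which descriptors matter and the
    noiseless endpoint."""

    informative_indices: list
    noiseless_y: np.ndarray
    noise_sd: float
    signal_sd: float

    def noiseless_function(self, Z: np.ndarray) -> np.ndarray:
        """Evaluate the noiseless endpoint on rows of informative-descriptor
        values (columns in the order of ``informative_indices``)."""
        return _signal(Z) * self._scale + self._offset

    _scale: float = 1.0
    _offset: float = 0.0


def _signal(Z: np.ndarray) -> np.ndarray:
    """Smooth nonlinear mixture of saturating and quadratic terms.

    Term kinds alternate; coefficients are fixed constants so that the
    function is identical across seeds.
    """
    k = Z.shape[1]
    out = np.zeros(Z.shape[0])
    for j in range(k):
        z = Z[:, j]
        if j % 2 == 0:
            out += 2.0 * np.tanh(1.3 * z)
        else:
            out += 1.0 * z**2
    return out


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Draw one synthetic table; bit-reproducible for equal seeds."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors

    X = np.empty((n, p))
    # informative descriptors: independent standard normal, first columns
    X[:, : spec.n_informative] = rng.standard_normal((n, spec.n_informative))
    col = spec.n_informative
    # correlated blocks via a one-factor model: pairwise corr = rho
    rho = spec.block_correlation
    for size in spec.correlated_block_sizes:
        common = rng.standard_normal((n, 1))
        idio = rng.standard_normal((n, size))
        X[:, col : col + size] = np.sqrt(rho) * common + np.sqrt(1 - rho) * idio
        col += size
    # remaining independent noise descriptors
    if col < p:
        X[:, col:] = rng.standard_normal((n, p - col))

    informative = list(range(spec.n_informative))
    g = _signal(X[:, informative])
    lo, hi = spec.endpoint_range
    gmin, gmax = g.min(), g.max()
    scale = (hi - lo) / (gmax - gmin) if gmax > gmin else 1.0
    offset = lo - gmin * scale
    noiseless = g * scale + offset
    signal_sd = float(noiseless.std())
    noise_sd = spec.noise_sd if spec.noise_sd is not None else signal_sd / 4.0
    y = noiseless + rng.normal(0.0, noise_sd, size=n)

    names = [f"D{j + 1:03d}" for j in range(p)]
    # appended degenerate columns
    extra = []
    for j in range(spec.n_constant):
        extra.append((f"CONST{j + 1}", np.full(n, 1.0)))
    for j in range(spec.n_null):
        extra.append((f"NULL{j + 1}", np.full(n, np.nan)))
    if extra:
        X = np.column_stack([X] + [c for _, c in extra])
        names = names + [nm for nm, _ in extra]

    table = DescriptorTable([f"C{i + 1:04d}" for i in range(n)], X, names, y)
    truth = GroundTruth(informative, noiseless, noise_sd, signal_sd)
    truth._scale = scale
    truth._offset = offset
    return table, truth


def default_scenario(seed: int = 0) -> tuple[DescriptorTable, GroundTruth]:
    """The reference scenario with only the seed varying."""
    return generate(SyntheticSpec(seed=seed))
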