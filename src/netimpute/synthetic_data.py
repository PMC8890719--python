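"""Synthetic networks, bulk training data and dropout-laden single cells.

The generator reproduces the statistical structure the imputation model
assumes, so every pipeline stage can be exercised end-to-end with known
ground truth:

* a sparse random regulatory network with bounded spectral radius, so the
  linear system Y = A Y + eps has a stable solution;
* bulk deviations simulated exactly from that system,
  Y = (I - A)^{-1} eps with i.i.d. Gaussian noise, so regressing a target
  on its true predictors recovers the generating coefficients;
* single cells built as per-gene mean expression (spanning several log2
  units) plus network-driven deviations, thinned by an
  expression-dependent Bernoulli dropout whose probability follows a
  logistic curve in the gene's mean — lowly expressed genes drop out more.
  The logistic form is deliberately different from the cubic-spline
  dropout model fitted by :mod:`netimpute.masking`, so that model is
  tested against an independent truth.

A ``constant_fraction`` of genes can be made flat (zero deviation): their
expression carries no cell-to-cell signal, which is the regime where
mean-based Baseline imputation is optimal and network predictions only add
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CenteredMatrix, ExpressionMatrix
from .network_inference import GeneModel, RegulatoryNetwork


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator; defaults give a stable, learnable regime.

    ``edge_density`` is the per-(target, candidate) edge probability;
    ``coefficient_range`` bounds absolute edge weights (sign random);
    ``spectral_radius_cap`` rescales the adjacency so the linear system is
    stable; ``noise_sd`` is the i.i.d. model-error sd of regulated genes,
    while parentless (source) genes vary with ``source_sd`` — their
    variation is driven from outside the modeled system, so it is larger;
    ``mean_expression_range`` is in log2 units; dropout probability for a
    gene with mean m is ``logistic(-dropout_slope * (m - dropout_midpoint))``.
    """

    n_genes: int = 100
    n_samples: int = 300
    n_cells: int = 200
    edge_density: float = 0.05
    coefficient_range: tuple[float, float] = (0.5, 1.5)
    spectral_radius_cap: float = 0.8
    noise_sd: float = 0.3
    source_sd: float = 1.0
    mean_expression_range: tuple[float, float] = (1.0, 8.0)
    dropout_midpoint: float = 3.0
    dropout_slope: float = 1.0
    constant_fraction: float = 0.0
    structure: str = "tf_target"
    regulator_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.spectral_radius_cap < 1.0:
            raise ValueError("spectral_radius_cap must be in (0, 1)")
        if not 0.0 <= self.edge_density < 1.0:
            raise ValueError("edge_density must be in [0, 1)")
        if not 0.0 <= self.constant_fraction <= 1.0:
            raise ValueError("constant_fraction must be in [0, 1]")
        if self.structure not in ("tf_target", "random"):
            raise ValueError("structure must be 'tf_target' or 'random'")
        if not 0.0 < self.regulator_fraction < 1.0:
            raise ValueError("regulator_fraction must be in (0, 1)")
        lo, hi = self.coefficient_range
        if lo < 0 or hi < lo:
            raise ValueError("coefficient_range must be 0 <= low <= high")

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def n_regulators(self) -> int:
        return max(1, int(np.ceil(self.regulator_fraction * self.n_genes)))

    def regulator_ids(self) -> list[str]:
        """In tf_target mode, the first genes act as upstream regulators."""
        return self.gene_ids()[: self.n_regulators()]

    def constant_gene_ids(self) -> list[str]:
        """The flat genes: the last floor(constant_fraction * n_genes) ids."""
        k = int(np.floor(self.constant_fraction * self.n_genes))
        return self.gene_ids()[self.n_genes - k :]


def _spectral_radius(a: np.ndarray) -> float:
    if not a.any():
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def generate_network(config: SimulationConfig) -> RegulatoryNetwork:
    """Random sparse regulatory network; no self-loops, deterministic per seed.

    ``tf_target`` (default) — a layered topology: only the regulator genes
    (the first ``regulator_fraction`` of the ids) carry outgoing edges, and
    only non-regulators receive them.  The per-target edge probability is
    inflated so the expected in-degree matches ``edge_density * (n_genes-1)``.
    The adjacency is nilpotent (spectral radius 0), so coefficients keep
    their drawn magnitudes and downstream regression on the true parents is
    well-posed: a target's optimal predictor set is exactly its parents.

    ``random`` — every off-diagonal entry is an edge with probability
    ``edge_density``.  Feedback loops are allowed; if the spectral radius
    exceeds the cap, all coefficients are rescaled uniformly (which may
    shrink them below ``coefficient_range``).
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    genes = config.gene_ids()
    if config.structure == "tf_target":
        n_reg = config.n_regulators()
        p_edge = min(1.0, config.edge_density * (g - 1) / n_reg)
        mask = np.zeros((g, g), dtype=bool)
        mask[n_reg:, :n_reg] = rng.random((g - n_reg, n_reg)) < p_edge
    else:
        mask = rng.random((g, g)) < config.edge_density
        np.fill_diagonal(mask, False)
    lo, hi = config.coefficient_range
    mags = rng.uniform(lo, hi, size=(g, g))
    signs = rng.choice([-1.0, 1.0], size=(g, g))
    a = np.where(mask, mags * signs, 0.0)
    radius = _spectral_radius(a)
    if radius > config.spectral_radius_cap:
        a *= config.spectral_radius_cap / radius
    models = {}
    for i, target in enumerate(genes):
        preds = np.flatnonzero(a[i])
        models[target] = GeneModel(
            target, {genes[j]: float(a[i, j]) for j in preds}
        )
    return RegulatoryNetwork(models, genes)


def _adjacency_or_error(network: RegulatoryNetwork) -> tuple[np.ndarray, list[str]]:
    genes = list(network.gene_universe)
    a = network.adjacency(genes)
    radius = _spectral_radius(a)
    if radius >= 1.0:
        raise ValueError(
            f"network is unstable (spectral radius {radius:.3f} >= 1); "
            "cannot simulate from it"
        )
    return a, genes


def _noise_scale(a: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Per-gene innovation sd: noise_sd for regulated genes, source_sd for roots."""
    has_parents = (a != 0).any(axis=1)
    return np.where(has_parents, config.noise_sd, config.source_sd)


def simulate_bulk(network: RegulatoryNetwork, config: SimulationConfig) -> CenteredMatrix:
    """Bulk deviations drawn exactly from the network: Y = (I - A)^{-1} eps.

    Columns (samples) are i.i.d.  Regulated genes get i.i.d. model error
    with sd ``noise_sd``; parentless genes vary with sd ``source_sd``.
    Centers are zero — the simulator works directly on the deviation scale.
    """
    a, genes = _adjacency_or_error(network)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scale = _noise_scale(a, config)
    eps = rng.normal(0.0, 1.0, size=(len(genes), config.n_samples)) * scale[:, None]
    dev = np.linalg.solve(np.eye(len(genes)) - a, eps)
    samples = [f"s{i:04d}" for i in range(config.n_samples)]
    return CenteredMatrix(dev, np.zeros(len(genes)), genes, samples)


def _logistic(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


def simulate_cells(
    network: RegulatoryNetwork, config: SimulationConfig
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Single cells on the log2 scale, before and after dropout.

    truth = per-gene mean + network-driven deviation, clamped at 0;
    observed = truth with entries zeroed by gene-wise Bernoulli dropout at
    probability ``logistic(-slope * (mean - midpoint))``.  Genes listed by
    ``config.constant_gene_ids()`` get zero deviation (their incoming edges
    are ignored during simulation, though not removed from the network —
    network imputation of such genes is deliberately mis-specified).
    """
    a, genes = _adjacency_or_error(network)
    g = len(genes)
    ss = np.random.SeedSequence([config.seed, 2])
    rng = np.random.default_rng(ss)
    lo, hi = config.mean_expression_range
    means = rng.uniform(lo, hi, size=g)

    constant = set(config.constant_gene_ids()) & set(genes)
    const_idx = np.array([i for i, gn in enumerate(genes) if gn in constant], dtype=int)
    a_sim = a.copy()
    scale = _noise_scale(a, config)
    eps = rng.normal(0.0, 1.0, size=(g, config.n_cells)) * scale[:, None]
    if const_idx.size:
        a_sim[const_idx, :] = 0.0
        eps[const_idx, :] = 0.0
    dev = np.linalg.solve(np.eye(g) - a_sim, eps)

    truth_vals = np.clip(means[:, None] + dev, 0.0, None)
    p_drop = _logistic(-config.dropout_slope * (means - config.dropout_midpoint))
    keep = rng.random((g, config.n_cells)) >= p_drop[:, None]
    observed_vals = np.where(keep, truth_vals, 0.0)

    cells = [f"c{i:04d}" for i in range(config.n_cells)]
    truth = ExpressionMatrix(truth_vals, genes, cells, "log2")
    observed = ExpressionMatrix(observed_vals, genes, cells, "log2")
    return truth, observed
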