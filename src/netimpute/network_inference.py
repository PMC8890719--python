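"""Sparse transcriptional regulatory network training.

Each gene is modelled independently: its expression deviation (log fold
change from the gene's mean across training samples) is regressed on the
deviations of all other genes, optionally plus the gene's own copy-number
state,

    y_i = alpha_i * c_i + sum_{j != i} alpha_ij * y_j + eps_i .

Predictor selection uses LASSO combined with stability selection
(complementary-pairs subsampling): the LASSO path is run on many random
half-samples, each gene's selection frequency is recorded, and genes
selected in at least a ``cutoff`` fraction of subsamples form the stable
support.  Coefficients are then re-estimated by ordinary least squares on
the full training data restricted to that support, so the stored
coefficients act directly on (unstandardized) deviations.

The per-subsample selection budget ``q`` bounds the per-family error rate
(expected number of falsely selected predictors) via
``PFER <= q^2 / ((2*cutoff - 1) * p)``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path

from .data_model import CenteredMatrix, CopyNumberMatrix

logger = logging.getLogger(__name__)

CNV_TOKEN = "__CNV__"


@dataclass
class StabilityParams:
    """Stability-selection settings.

    Parameters
    ----------
    cutoff
        Selection-frequency threshold in (0.5, 1]; default 0.6.
    pfer
        Target per-family error rate (> 0); default 0.05.
    n_subsamples
        Number of half-samples (pairs of complementary halves); default 100,
        i.e. 50 complementary pairs.
    q
        Per-subsample selection budget: at most the first ``q`` variables to
        enter the LASSO path are counted as selected.  When ``None`` it is
        derived from the error-rate bound,
        ``q = ceil(sqrt(pfer * (2*cutoff - 1) * p))``, but never below
        ``ceil(sqrt(p))`` so that multi-predictor targets remain
        recoverable at small candidate-pool sizes.
    weakness
        Randomized-LASSO weakness in (0, 1]: per subsample, each predictor's
        penalty is inflated by an independent uniform factor in
        ``[weakness, 1]``; 1.0 (default) disables the randomization.
    prune_alpha
        Two-sided significance level for backward elimination during the OLS
        refit on the stable support.  Because the selection budget q can
        exceed a target's true in-degree, redundant proxies (variables
        correlated with the target only through shared predictors) can pass
        the frequency cutoff; their *partial* coefficients given the true
        predictors are near zero, so they are removed by dropping the least
        significant variable until all survivors satisfy p < prune_alpha.
        ``None`` disables pruning.
    """

    cutoff: float = 0.6
    pfer: float = 0.05
    n_subsamples: int = 100
    q: int | None = None
    weakness: float = 1.0
    prune_alpha: float | None = 1e-3

    def __post_init__(self) -> None:
        if not 0.5 < self.cutoff <= 1.0:
            raise ValueError("cutoff must be in (0.5, 1]")
        if self.pfer <= 0:
            raise ValueError("pfer must be > 0")
        if self.n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")
        if self.q is not None and self.q < 1:
            raise ValueError("q must be a positive integer")
        if not 0.0 < self.weakness <= 1.0:
            raise ValueError("weakness must be in (0, 1]")

    def resolve_q(self, n_candidates: int) -> int:
        if self.q is not None:
            return min(self.q, n_candidates)
        bound = math.ceil(math.sqrt(self.pfer * (2.0 * self.cutoff - 1.0) * n_candidates))
        floor_q = math.ceil(math.sqrt(n_candidates))
        return max(1, min(max(bound, floor_q), n_candidates))

    def pfer_bound(self, n_candidates: int) -> float:
        """Expected falsely-selected predictors implied by the resolved q."""
        q = self.resolve_q(n_candidates)
        return q * q / ((2.0 * self.cutoff - 1.0) * n_candidates)


@dataclass
class GeneModel:
    """Sparse linear model for one target gene."""

    target: str
    coefficients: dict[str, float] = field(default_factory=dict)
    cnv_coefficient: float | None = None
    n_selected: int = 0

    def __post_init__(self) -> None:
        if self.target in self.coefficients:
            raise ValueError(f"self-edge on gene {self.target!r}")
        for pred, coef in self.coefficients.items():
            if not np.isfinite(coef):
                raise ValueError(f"non-finite coefficient for {self.target!r} <- {pred!r}")
        self.n_selected = len(self.coefficients) + (self.cnv_coefficient is not None)

    @property
    def is_empty(self) -> bool:
        return not self.coefficients and self.cnv_coefficient is None


@dataclass
class TrainingFit:
    """Residual diagnostics from the OLS refit of one gene model."""

    target: str
    residuals: np.ndarray
    residual_variance: float


@dataclass
class RegulatoryNetwork:
    """Collection of per-target gene models over a common gene universe."""

    models: dict[str, GeneModel]
    gene_universe: list[str]

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        for target, model in self.models.items():
            if model.target != target:
                raise ValueError(f"model key {target!r} != model.target {model.target!r}")
            for pred in model.coefficients:
                if pred == target:
                    raise ValueError(f"self-edge on gene {target!r}")
                if pred not in universe:
                    raise ValueError(
                        f"predictor {pred!r} of {target!r} missing from gene universe"
                    )

    @property
    def n_edges(self) -> int:
        return sum(len(m.coefficients) for m in self.models.values())

    def nonempty_targets(self) -> list[str]:
        return [t for t, m in self.models.items() if m.coefficients]

    def adjacency(self, gene_order: list[str]) -> np.ndarray:
        """Dense adjacency A (targets in rows) over ``gene_order``."""
        idx = {g: i for i, g in enumerate(gene_order)}
        a = np.zeros((len(gene_order), len(gene_order)))
        for target, model in self.models.items():
            if target not in idx:
                continue
            ti = idx[target]
            for pred, coef in model.coefficients.items():
                if pred in idx:
                    a[ti, idx[pred]] = coef
        return a


def _half_samples(n_samples: int, n_subsamples: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Complementary-pairs half-samples: each draw yields two disjoint halves."""
    half = n_samples // 2
    out: list[np.ndarray] = []
    while len(out) < n_subsamples:
        perm = rng.permutation(n_samples)
        out.append(np.sort(perm[:half]))
        if len(out) < n_subsamples:
            out.append(np.sort(perm[half : 2 * half]))
    return out


def _first_entering(x: np.ndarray, y: np.ndarray, q: int) -> np.ndarray:
    """Indices of the first q variables to enter the LASSO (LARS) path."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, _, coefs = lars_path(x, y, method="lasso", max_iter=q + 8)
    entered: list[int] = []
    seen: set[int] = set()
    for k in range(coefs.shape[1]):
        for j in np.flatnonzero(coefs[:, k]):
            if j not in seen:
                seen.add(int(j))
                entered.append(int(j))
        if len(entered) >= q:
            break
    return np.array(entered[:q], dtype=int)


def _prune_support(
    x: np.ndarray, y: np.ndarray, support: np.ndarray, alpha: float
) -> np.ndarray:
    """Backward elimination on the OLS refit at two-sided level ``alpha``."""
    from scipy import stats

    support = support.copy()
    while support.size:
        xs = x[:, support]
        beta, *_ = np.linalg.lstsq(xs, y, rcond=None)
        resid = y - xs @ beta
        dof = xs.shape[0] - xs.shape[1]
        if dof <= 0:
            break
        sigma2 = float(resid @ resid) / dof
        if sigma2 == 0:
            break
        try:
            cov = sigma2 * np.linalg.inv(xs.T @ xs)
        except np.linalg.LinAlgError:
            break
        se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
        tvals = np.abs(beta) / se
        pvals = 2.0 * stats.t.sf(tvals, dof)
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            break
        support = np.delete(support, worst)
    return support


def fit_gene_model(
    target: str,
    deviations: CenteredMatrix,
    cnv: CopyNumberMatrix | None = None,
    params: StabilityParams | None = None,
    seed: int = 0,
) -> tuple[GeneModel, TrainingFit]:
    """Fit one target gene's sparse predictor model by stability selection.

    All genes other than the target are candidates; if ``cnv`` provides the
    target's copy-number profile it joins the candidate pool like any other
    predictor.  Selection frequencies are computed over random half-samples;
    predictors with frequency >= cutoff are refit jointly by OLS on the full
    (unstandardized) deviations.
    """
    params = params or StabilityParams()
    gidx = deviations.gene_index()
    if target not in gidx:
        raise KeyError(f"target gene {target!r} not in matrix")
    n = deviations.n_cells
    if n < 20:
        raise ValueError(f"need >= 20 training samples, got {n}")

    ti = gidx[target]
    y = deviations.deviations[ti]
    if np.allclose(y, y[0]):
        # nothing to explain: zero-variance target yields an empty model
        model = GeneModel(target=target)
        return model, TrainingFit(target, y - y.mean(), 0.0)

    cand_names = [g for g in deviations.gene_ids if g != target]
    x = np.delete(deviations.deviations, ti, axis=0).T  # samples x candidates
    if cnv is not None:
        cg = cnv.gene_index()
        if target in cg:
            sidx = {s: i for i, s in enumerate(cnv.sample_ids)}
            try:
                cols = [sidx[c] for c in deviations.cell_ids]
            except KeyError as exc:
                raise ValueError(f"copy-number data missing sample {exc.args[0]!r}") from exc
            c_row = cnv.values[cg[target], cols]
            x = np.column_stack([x, c_row])
            cand_names = cand_names + [CNV_TOKEN]

    p = x.shape[1]
    q = params.resolve_q(p)
    rng = np.random.default_rng(seed)
    halves = _half_samples(n, params.n_subsamples, rng)

    counts = np.zeros(p)
    for rows in halves:
        xs = x[rows]
        ys = y[rows]
        sd = xs.std(axis=0)
        keep = np.flatnonzero(sd > 0)
        if keep.size == 0 or ys.std() == 0:
            continue
        xs = (xs[:, keep] - xs[:, keep].mean(axis=0)) / sd[keep]
        ys = ys - ys.mean()
        if params.weakness < 1.0:
            # randomized LASSO: scaling a standardized column by w is
            # equivalent to inflating its penalty by 1/w
            xs = xs * rng.uniform(params.weakness, 1.0, size=xs.shape[1])
        chosen = _first_entering(xs, ys, q)
        counts[keep[chosen]] += 1.0

    freq = counts / len(halves)
    support = np.flatnonzero(freq >= params.cutoff)
    if support.size and params.prune_alpha is not None:
        support = _prune_support(x, y, support, params.prune_alpha)

    coefficients: dict[str, float] = {}
    cnv_coef: float | None = None
    if support.size:
        beta, *_ = np.linalg.lstsq(x[:, support], y, rcond=None)
        for j, b in zip(support, beta):
            name = cand_names[j]
            if name == CNV_TOKEN:
                cnv_coef = float(b)
            else:
                coefficients[name] = float(b)
        residuals = y - x[:, support] @ beta
    else:
        residuals = y.copy()

    dof = max(n - support.size, 1)
    fit = TrainingFit(target, residuals, float(residuals @ residuals / dof))
    return GeneModel(target, coefficients, cnv_coef), fit


def train_network(
    deviations: CenteredMatrix,
    cnv: CopyNumberMatrix | None = None,
    params: StabilityParams | None = None,
    seed: int = 0,
    progress_every: int = 200,
) -> RegulatoryNetwork:
    """Train one independent sub-network per gene in the matrix.

    Per-gene failures are downgraded to warnings (the failed target gets an
    empty model) so one pathological gene cannot abort a long training run.
    """
    if deviations.n_genes == 0 or deviations.n_cells == 0:
        raise ValueError("cannot train a network on an empty matrix")
    params = params or StabilityParams()
    seeds = np.random.SeedSequence(seed).spawn(deviations.n_genes)
    models: dict[str, GeneModel] = {}
    for i, target in enumerate(deviations.gene_ids):
        target_seed = seeds[i]
        try:
            model, _ = fit_gene_model(target, deviations, cnv, params, seed=target_seed)
        except Exception as exc:  # noqa: BLE001 - per-target isolation is the contract
            logger.warning("model fit failed for %s: %s", target, exc)
            model = GeneModel(target=target)
        models[target] = model
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("trained %d/%d gene models", i + 1, deviations.n_genes)
    return RegulatoryNetwork(models, list(deviations.gene_ids))


def randomize_network(
    network: RegulatoryNetwork,
    mode: str = "full",
    fraction: float = 0.5,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Degrade the network by re-drawing predictor identities at random.

    ``full`` re-draws every edge's predictor uniformly from the gene
    universe; ``partial`` re-draws a given fraction of edges (default 50%).
    Coefficients and per-target edge counts are preserved, and re-drawn
    predictors avoid self-loops and duplicates within a target.
    """
    if mode not in ("full", "partial"):
        raise ValueError("mode must be 'full' or 'partial'")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = np.array(network.gene_universe)
    models: dict[str, GeneModel] = {}
    for target in network.gene_universe:
        model = network.models.get(target)
        if model is None or not model.coefficients:
            models[target] = GeneModel(
                target, {}, model.cnv_coefficient if model else None
            )
            continue
        preds = list(model.coefficients)
        coefs = [model.coefficients[p] for p in preds]
        n_edges = len(preds)
        if mode == "full":
            redraw = np.arange(n_edges)
        else:
            k = int(round(fraction * n_edges))
            redraw = rng.choice(n_edges, size=k, replace=False) if k else np.array([], int)
        new_preds = list(preds)
        taken = set(preds)
        for j in redraw:
            taken.discard(new_preds[j])
            while True:
                cand = str(universe[rng.integers(len(universe))])
                if cand != target and cand not in taken:
                    break
            new_preds[j] = cand
            taken.add(cand)
        models[target] = GeneModel(
            target, dict(zip(new_preds, coefs)), model.cnv_coefficient
        )
    return RegulatoryNetwork(models, list(network.gene_universe))
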