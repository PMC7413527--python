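"""Economic and agronomic optimal N-P-K doses over Monte-Carlo dose grids,
response curves, and GP posterior-sampled dose distributions with
conditional-expectation percentile recommendations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conversions import elemental_to_oxide
from .mitscherlich import MitscherlichParams, predict_surface
from .ml import draw_samples

__all__ = [
    "PriceModel",
    "DoseGrid",
    "DoseRecommendation",
    "net_return",
    "economic_optimum",
    "agronomic_optimum",
    "response_curve",
    "sample_optimal_doses",
    "conditional_expectation_dose",
    "surface_response",
    "model_response",
    "dose_feature_matrix",
]

NUTRIENTS = ("N", "P", "K")
DOSE_COLS = ("dose_N", "dose_P", "dose_K")

#: Histogram bins per nutrient when locating the modal optimal dose.
MODAL_BINS = 25


@dataclass(frozen=True)
class PriceModel:
    """Unit fertilizer costs ($/kg elemental) and tuber price ($/Mg)."""

    cost_N: float = 1.20
    cost_P: float = 1.10
    cost_K: float = 0.90
    tuber_price: float = 250.0

    def __post_init__(self) -> None:
        if min(self.cost_N, self.cost_P, self.cost_K, self.tuber_price) < 0:
            raise ValueError("prices must be non-negative")

    @property
    def costs(self) -> np.ndarray:
        return np.array([self.cost_N, self.cost_P, self.cost_K])


@dataclass(frozen=True)
class DoseGrid:
    """Random uniform dose triplets within per-nutrient bounds."""

    points: np.ndarray  # (n, 3) in N, P, K order
    bounds: tuple[float, float, float]
    seed: int | None = None

    @classmethod
    def uniform(cls, n_points: int = 1000,
                bounds: tuple[float, float, float] = (250.0, 110.0, 208.0),
                seed: int = 0) -> "DoseGrid":
        if n_points < 1:
            raise ValueError("n_points must be >= 1")
        if min(bounds) <= 0:
            raise ValueError("bounds must be positive")
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0.0, 1.0, size=(n_points, 3)) * np.asarray(bounds)
        return cls(points=pts, bounds=tuple(float(b) for b in bounds), seed=seed)

    @classmethod
    def lattice(cls, n_per_axis: int = 50,
                bounds: tuple[float, float, float] = (250.0, 110.0, 208.0)) -> "DoseGrid":
        """Dense regular lattice, used as an exhaustive-search oracle."""
        axes = [np.linspace(0.0, b, n_per_axis) for b in bounds]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        return cls(points=pts, bounds=tuple(float(b) for b in bounds))

    @property
    def spacing(self) -> np.ndarray:
        """Largest axis step for lattice grids (bound / (n^(1/3) - 1))."""
        n_axis = round(len(self.points) ** (1 / 3))
        return np.asarray(self.bounds) / max(n_axis - 1, 1)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=list(DOSE_COLS))


@dataclass
class DoseRecommendation:
    mode: str                      # "economic" | "agronomic"
    optimum: tuple[float, float, float]
    predicted: float
    net_return: float              # nan in agronomic mode
    oxide_doses: tuple[float, float]  # (P2O5, K2O) at the optimum
    per_sample_optima: np.ndarray | None = None  # (n_samples, 3)
    percentiles: dict[str, dict[int, float]] = field(default_factory=dict)
    modal_dose: dict[str, float] = field(default_factory=dict)
    mean_curve_optimum: tuple[float, float, float] | None = None


def net_return(predicted_yield, doses, prices: PriceModel) -> np.ndarray:
    """Marginal benefit: tuber revenue minus fertilizer cost, $/ha.

    ``yield * tuber_price - (cost_N*N + cost_P*P + cost_K*K)``.
    """
    y = np.asarray(predicted_yield, dtype=float)
    d = np.atleast_2d(np.asarray(doses, dtype=float))
    if np.any(y < 0):
        raise ValueError("yield cannot be negative")
    out = y * prices.tuber_price - d @ prices.costs
    return float(out[0]) if np.isscalar(predicted_yield) else out


def _argmax_tiebreak(values: np.ndarray, doses: np.ndarray,
                     tol: float = 1e-9) -> int:
    """Index of the maximum; ties resolved by lowest total dose, then lowest N."""
    best = values.max()
    cand = np.flatnonzero(values >= best - tol)
    totals = doses[cand].sum(axis=1)
    order = np.lexsort((doses[cand, 0], totals))
    return int(cand[order[0]])


def surface_response(params: MitscherlichParams,
                     covariate_row: pd.Series | None = None):
    """Dose-response callable backed by a Mitscherlich surface."""

    def predict(doses: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(doses, dtype=float))
        frame = pd.DataFrame(d, columns=list(DOSE_COLS))
        if covariate_row is not None:
            for k, v in covariate_row.items():
                if k not in frame.columns:
                    frame[k] = v
        return predict_surface(params, frame)

    return predict


def dose_feature_matrix(fixed_row: pd.Series, doses: np.ndarray,
                        standardizer=None) -> pd.DataFrame:
    """Replicate a raw feature row per dose triplet, overwrite the dose
    columns, and (optionally) re-standardize with training statistics."""
    d = np.atleast_2d(np.asarray(doses, dtype=float))
    frame = pd.DataFrame([fixed_row.to_dict()] * len(d))
    frame[list(DOSE_COLS)] = d
    if standardizer is not None:
        frame = standardizer.transform(frame)
    return frame


def model_response(model, fixed_row: pd.Series, standardizer=None):
    """Dose-response callable from a fitted model with all covariates held
    constant at ``fixed_row`` (raw scale)."""

    def predict(doses: np.ndarray) -> np.ndarray:
        X = dose_feature_matrix(fixed_row, doses, standardizer)
        return np.asarray(model.predict(X.to_numpy(dtype=float)))

    return predict


def _recommend(mode: str, doses: np.ndarray, predictions: np.ndarray,
               prices: PriceModel | None) -> DoseRecommendation:
    if mode == "economic":
        objective = net_return(predictions, doses, prices)
    else:
        objective = predictions
    i = _argmax_tiebreak(np.asarray(objective, dtype=float), doses)
    opt = tuple(float(v) for v in doses[i])
    ret = float(objective[i]) if mode == "economic" else float("nan")
    return DoseRecommendation(
        mode=mode, optimum=opt, predicted=float(predictions[i]), net_return=ret,
        oxide_doses=elemental_to_oxide(opt[1], opt[2]),
    )


def economic_optimum(predict_fn, grid: DoseGrid,
                     prices: PriceModel | None = None) -> DoseRecommendation:
    """Dose triplet maximizing net return over the grid.

    ``predict_fn`` must map (n, 3) dose arrays to predicted marketable yield
    in Mg/ha (raw scale; revenue and cost share units).
    """
    prices = prices or PriceModel()
    doses = grid.points
    preds = np.asarray(predict_fn(doses), dtype=float)
    return _recommend("economic", doses, preds, prices)


def agronomic_optimum(predict_fn, grid: DoseGrid) -> DoseRecommendation:
    """Dose triplet maximizing the predicted target itself."""
    doses = grid.points
    preds = np.asarray(predict_fn(doses), dtype=float)
    return _recommend("agronomic", doses, preds, None)


def response_curve(predict_fn, fixed_doses, nutrient: str,
                   dose_range: tuple[float, float] = (0.0, 250.0),
                   n_points: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Vary one nutrient's dose with the other two held at ``fixed_doses``."""
    if nutrient not in NUTRIENTS:
        raise ValueError("nutrient must be one of N, P, K")
    j = NUTRIENTS.index(nutrient)
    doses = np.tile(np.asarray(fixed_doses, dtype=float), (n_points, 1))
    grid = np.linspace(dose_range[0], dose_range[1], n_points)
    doses[:, j] = grid
    return grid, np.asarray(predict_fn(doses), dtype=float)


def sample_optimal_doses(gp_model, fixed_row: pd.Series, grid: DoseGrid,
                         n_samples: int = 1000, mode: str = "economic",
                         prices: PriceModel | None = None, seed: int = 0,
                         standardizer=None) -> DoseRecommendation:
    """Distribution of optimal doses over joint GP posterior samples.

    Draws ``n_samples`` response functions over the grid rows, locates the
    economic (or agronomic) optimum of each, and summarizes the per-sample
    optima with percentile tables and the modal histogram dose per nutrient.
    The mean-curve optimum (optimum of the posterior mean) is reported
    alongside and need not coincide with the distribution mode.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if mode not in ("economic", "agronomic"):
        raise ValueError("mode must be economic or agronomic")
    prices = prices or PriceModel()
    doses = grid.points
    X = dose_feature_matrix(fixed_row, doses, standardizer).to_numpy(dtype=float)

    samples = draw_samples(gp_model, X, n_samples=n_samples, seed=seed)
    if mode == "economic":
        objective = samples * prices.tuber_price - doses @ prices.costs
    else:
        objective = samples
    optima = np.empty((n_samples, 3))
    for s in range(n_samples):
        i = _argmax_tiebreak(objective[s], doses)
        optima[s] = doses[i]

    from .ml import gp_posterior  # mean of the same posterior

    mean, _ = gp_posterior(gp_model, X)
    rec = _recommend(mode, doses, mean, prices)
    rec.per_sample_optima = optima
    rec.mean_curve_optimum = rec.optimum

    for j, nut in enumerate(NUTRIENTS):
        vals = optima[:, j]
        rec.percentiles[nut] = {
            int(p): conditional_expectation_dose(vals, p)
            for p in (5, 25, 50, 75, 80, 95)
        }
        counts, edges = np.histogram(vals, bins=MODAL_BINS,
                                     range=(0.0, grid.bounds[j]))
        k = int(np.argmax(counts))
        rec.modal_dose[nut] = float(0.5 * (edges[k] + edges[k + 1]))
    return rec


def conditional_expectation_dose(per_sample_optima, x: float) -> float:
    """x-th percentile of the per-sample optimal doses for one nutrient.

    The dose that is sufficient (produces the sampled optimum) x% of the
    time; linear interpolation between order statistics.
    """
    arr = np.asarray(per_sample_optima, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample of optima")
    if not (0.0 < x <= 100.0):
        raise ValueError("percentile x must lie in (0, 100]")
    return float(np.percentile(arr, x, method="linear"))
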