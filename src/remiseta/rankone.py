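"""Best rank-one approximation of a setation grid.

The working hypothesis is multiplicative separability: the expected
count in group *j* on limb *i* is c·x_i·y_j, with no limb-by-group
interaction. The least-squares optimal (c, x, y) under the squared
Frobenius norm ‖A‖ = Σ a² is the leading singular triple of the grid;
x (the limb setation vector) and y (the group setation vector) are
normalized to Σx² = Σy² = 1 and the scale lands in c, which tracks the
overall setation level of a specimen and hence serves as an age proxy.

Three solvers are provided: a dense SVD, a deterministic power
iteration (cross-check), and alternating least squares that honours an
entry mask for grids with excluded (missing-segment) cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import SetationMatrix, to_grid

__all__ = [
    "RankOneModel",
    "DegenerateMatrixError",
    "ConvergenceError",
    "UndefinedCorrelationError",
    "rank_one_decompose",
    "decompose_matrix",
    "predict",
    "fit_correlation",
    "group_vector_correlation",
    "model_report",
]

POWER_TOL = 1e-12
POWER_MAX_ITER = 10_000
ALS_TOL = 1e-10
ALS_MAX_SWEEPS = 1_000


class DegenerateMatrixError(ValueError):
    """All-zero (or all-masked) grid: the scale coefficient c is undefined."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, last_residual: float):
        super().__init__(message)
        self.last_residual = last_residual


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance on one side)."""


@dataclass
class RankOneModel:
    c: float
    x: np.ndarray  # limb setation vector, Σx² = 1
    y: np.ndarray  # group setation vector, Σy² = 1
    residual: float  # Σ over fitted cells of (a - c·x·y)²
    fit_correlation: float
    method: str
    limb_indices: list[int] | None = None
    specimen_id: str = ""
    missing_policy: str = "zero"
    mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_limbs(self) -> int:
        return len(self.x)


def _orient(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # joint sign flip so Σx > 0; nonnegative grids then get nonnegative vectors
    if x.sum() < 0:
        return -x, -y
    return x, y


def _svd_triple(grid: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(grid, full_matrices=False)
    x, y = _orient(u[:, 0], vt[0])
    return float(s[0]), x, y


def _power_triple(grid: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    # deterministic start: column-sum direction (nonnegative for count data)
    y = grid.sum(axis=0)
    ny = np.linalg.norm(y)
    if ny == 0:  # fall back to a fixed direction
        y = np.ones(grid.shape[1])
        ny = np.linalg.norm(y)
    y = y / ny
    g = grid.T @ grid
    s_prev = 0.0
    for _ in range(POWER_MAX_ITER):
        z = g @ y
        s = np.linalg.norm(z)
        if s == 0:
            raise DegenerateMatrixError("power iteration collapsed to zero vector")
        y = z / s
        if abs(s - s_prev) <= POWER_TOL * max(1.0, s):
            break
        s_prev = s
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {POWER_MAX_ITER} iterations",
            float(s),
        )
    xz = grid @ y
    c = float(np.linalg.norm(xz))
    x, y = _orient(xz / c, y)
    return c, x, y


def _als_triple(
    grid: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    m = mask.astype(float)
    a = grid * m
    # dense leading triple of the zero-filled grid as a warm start
    _, x, y = _svd_triple(a)
    prev = np.inf
    for _ in range(ALS_MAX_SWEEPS):
        denom = m @ (y**2)
        if np.any(denom == 0):
            raise DegenerateMatrixError("a row has no unmasked entries")
        x = (a @ y) / denom
        denom = m.T @ (x**2)
        if np.any(denom == 0):
            raise DegenerateMatrixError("a column has no unmasked entries")
        y = (a.T @ x) / denom
        resid = float(np.sum(m * (grid - np.outer(x, y)) ** 2))
        if prev - resid <= ALS_TOL * max(1.0, resid):
            prev = resid
            break
        prev = resid
    else:
        raise ConvergenceError(
            f"ALS did not converge in {ALS_MAX_SWEEPS} sweeps", prev
        )
    scale = np.linalg.norm(x) * np.linalg.norm(y)
    if scale == 0:
        raise DegenerateMatrixError("ALS collapsed to the zero factor")
    x_n = x / np.linalg.norm(x)
    y_n = y / np.linalg.norm(y)
    x_n, y_n = _orient(x_n, y_n)
    return float(scale), x_n, y_n


def rank_one_decompose(
    grid: np.ndarray,
    mask: np.ndarray | None = None,
    method: str = "svd",
    limb_indices: list[int] | None = None,
) -> RankOneModel:
    """Least-squares rank-one factorization c·xᵀ·y of a count grid.

    ``svd`` and ``power`` compute the global Frobenius optimum (leading
    singular triple) and require a dense (all-true) mask; ``als_masked``
    minimizes the squared error over unmasked entries only.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("grid must be a nonempty 2-D array")
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape must match grid shape")
    if not np.any(grid[mask] != 0):
        raise DegenerateMatrixError("all fitted entries are zero; c is undefined")

    if method in ("svd", "power"):
        if not mask.all():
            raise ValueError(f"method {method!r} requires an all-true mask; use 'als_masked'")
        c, x, y = (_svd_triple if method == "svd" else _power_triple)(grid)
    elif method == "als_masked":
        c, x, y = _als_triple(grid, mask)
    else:
        raise ValueError(f"unknown method {method!r}")

    approx = c * np.outer(x, y)
    residual = float(np.sum((grid[mask] - approx[mask]) ** 2))
    model = RankOneModel(
        c=c,
        x=x,
        y=y,
        residual=residual,
        fit_correlation=np.nan,
        method=method,
        limb_indices=limb_indices,
        mask=mask,
    )
    try:
        model.fit_correlation = fit_correlation(grid, model, mask)
    except (UndefinedCorrelationError, ValueError):
        model.fit_correlation = float("nan")  # constant or tiny grid
    return model


def decompose_matrix(
    matrix: SetationMatrix, missing_policy: str = "zero", method: str = "svd"
) -> RankOneModel:
    """Decompose a :class:`SetationMatrix` under a missing-data policy."""
    grid, mask = to_grid(matrix, missing_policy)
    if missing_policy == "mask" and method in ("svd", "power") and not mask.all():
        method = "als_masked"
    model = rank_one_decompose(
        grid, mask, method=method, limb_indices=matrix.limb_indices
    )
    model.specimen_id = matrix.specimen_id
    model.missing_policy = missing_policy
    return model


def predict(model: RankOneModel) -> np.ndarray:
    """Approximation grid Â with entries c·x_i·y_j."""
    return model.c * np.outer(model.x, model.y)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3:
        raise ValueError("need at least 3 entries for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def fit_correlation(
    grid: np.ndarray, model: RankOneModel, mask: np.ndarray | None = None
) -> float:
    """Pearson r between observed and approximated counts, one point per cell."""
    grid = np.asarray(grid, dtype=float)
    if mask is None:
        mask = model.mask if model.mask is not None else np.ones(grid.shape, bool)
    approx = predict(model)
    return _pearson(grid[mask], approx[mask])


def group_vector_correlation(model_a: RankOneModel, model_b: RankOneModel) -> float:
    """Pearson r between two specimens' group setation vectors y."""
    if model_a.y.shape != model_b.y.shape:
        raise ValueError("group vectors must have equal length")
    return _pearson(model_a.y, model_b.y)


def model_report(model: RankOneModel) -> dict:
    """JSON-ready summary of a fitted model."""
    return {
        "specimen": model.specimen_id,
        "n_limbs": model.n_limbs,
        "c": round(float(model.c), 6),
        "x": [round(float(v), 6) for v in model.x],
        "y": [round(float(v), 6) for v in model.y],
        "residual": round(float(model.residual), 6),
        "fit_correlation": round(float(model.fit_correlation), 6),
        "method": model.method,
        "missing_policy": model.missing_policy,
        "limb_indices": model.limb_indices,
    }


def report_json(model: RankOneModel) -> str:
    return json.dumps(model_report(model), indent=2)
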