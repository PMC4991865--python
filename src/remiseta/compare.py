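"""Cross-specimen comparison of limb setation vectors on a common axis.

Specimens at different developmental stages have different numbers of
trunk limbs, so their limb setation vectors x live on different axes.
Stretching the younger specimen's limb coordinates affinely so that its
first and last limbs coincide with the older specimen's puts both
profiles on one scale, where they can be pooled and fitted with a
single quadratic trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SetationMatrix
from .rankone import RankOneModel, decompose_matrix, group_vector_correlation
from .trend import PolyFit, fit_polynomial, select_degree

__all__ = [
    "ScaledComparison",
    "stretch_indices",
    "pooled_trend",
    "limb_vector_trend",
    "compare_specimens",
    "pooled_points_frame",
]


def _indices(obj) -> np.ndarray:
    if isinstance(obj, SetationMatrix):
        return np.asarray(obj.limb_indices, float)
    return np.asarray(obj, float)


def stretch_indices(query, reference) -> np.ndarray:
    """Affinely map the query's limb numbers onto the reference's range.

    The query's first limb lands on the reference's first and its last
    on the reference's last: i' = r0 + (i - q0)·(r1 - r0)/(q1 - q0).
    """
    q = _indices(query)
    r = _indices(reference)
    if len(q) < 2 or len(r) < 2:
        raise ValueError("both specimens need at least 2 limbs to define a stretch")
    q0, q1 = q[0], q[-1]
    r0, r1 = r[0], r[-1]
    return r0 + (q - q0) * (r1 - r0) / (q1 - q0)


def limb_vector_trend(
    model: RankOneModel,
    limb_indices=None,
    max_degree: int = 5,
    alpha: float = 0.05,
) -> PolyFit:
    """Degree-selected polynomial trend of the limb setation vector x."""
    xs = _indices(limb_indices if limb_indices is not None else model.limb_indices)
    if xs is None or len(xs) != model.n_limbs:
        raise ValueError("limb indices must match the model's limb count")
    if model.n_limbs < max_degree + 2:
        raise ValueError("too few limbs for degree selection")
    return select_degree(
        xs, model.x, max_degree=max_degree, alpha=alpha,
        label=f"vector {model.specimen_id}".strip(),
    )


def pooled_trend(
    model_ref: RankOneModel,
    model_query: RankOneModel,
    mapped_indices,
    ref_indices=None,
) -> PolyFit:
    """Quadratic OLS fit to the pooled (index, x-component) points.

    Reference points enter at their own limb numbers, query points at
    their stretched positions; values are not resampled.
    """
    r = _indices(ref_indices if ref_indices is not None else model_ref.limb_indices)
    m = np.asarray(mapped_indices, float)
    xs = np.concatenate([r, m])
    ys = np.concatenate([model_ref.x, model_query.x])
    # pooled axes may collide where stretched positions hit integer limbs;
    # jitter-free tie handling: lstsq tolerates repeats, so bypass the
    # duplicate check of fit_polynomial
    coef, *_ = np.linalg.lstsq(np.vander(xs, 3, increasing=True), ys, rcond=None)
    pred = np.polynomial.polynomial.polyval(xs, coef)
    return PolyFit(
        label="pooled",
        degree=2,
        coefficients=np.asarray(coef, float),
        rss=float(np.sum((ys - pred) ** 2)),
        n=len(xs),
    )


@dataclass
class ScaledComparison:
    reference_id: str
    query_id: str
    mapped_indices: np.ndarray
    pooled_fit: PolyFit
    vector_fits: dict[str, PolyFit]
    group_correlation: float
    profile_correlation: float  # query x interpolated onto reference axis


def compare_specimens(
    reference: SetationMatrix,
    query: SetationMatrix,
    missing_policy: str = "zero",
    method: str = "svd",
    max_degree: int = 5,
    alpha: float = 0.05,
) -> ScaledComparison:
    """Full cross-specimen comparison of two setation matrices."""
    model_ref = decompose_matrix(reference, missing_policy, method)
    model_query = decompose_matrix(query, missing_policy, method)
    mapped = stretch_indices(query, reference)
    pooled = pooled_trend(model_ref, model_query, mapped)
    fits = {
        reference.specimen_id: limb_vector_trend(model_ref, max_degree=max_degree, alpha=alpha),
        query.specimen_id: limb_vector_trend(model_query, max_degree=max_degree, alpha=alpha),
    }
    ref_axis = np.asarray(reference.limb_indices, float)
    interp_q = np.interp(ref_axis, mapped, model_query.x)
    profile_corr = float(np.corrcoef(model_ref.x, interp_q)[0, 1])
    return ScaledComparison(
        reference_id=reference.specimen_id,
        query_id=query.specimen_id,
        mapped_indices=mapped,
        pooled_fit=pooled,
        vector_fits=fits,
        group_correlation=group_vector_correlation(model_ref, model_query),
        profile_correlation=profile_corr,
    )


def pooled_points_frame(
    model_ref: RankOneModel, model_query: RankOneModel, mapped_indices
) -> pd.DataFrame:
    """The pooled scatter behind the common trend, one row per point."""
    r = _indices(model_ref.limb_indices)
    recs = [
        {"specimen": model_ref.specimen_id, "position": float(i), "x": float(v)}
        for i, v in zip(r, model_ref.x)
    ] + [
        {"specimen": model_query.specimen_id, "position": float(i), "x": float(v)}
        for i, v in zip(np.asarray(mapped_indices, float), model_query.x)
    ]
    return pd.DataFrame(recs)
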