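"""Polynomial trends of setal counts along the body axis.

Per-segment setal sums rise from the anteriormost trunk limb to a
maximum in the anterior third of the trunk and decline toward the
posterior, developmentally youngest limbs. The trend of each segment
(and of the grand total) is summarized by an ordinary least-squares
polynomial in the limb number j, with the degree chosen by forward
nested F-tests: starting from a line, each added degree is kept only
while the incremental test is significant at ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

from .data import SetationMatrix, segment_sums
from .scheme import DEFAULT_SCHEME, SetalGroupScheme

__all__ = ["PolyFit", "fit_polynomial", "select_degree", "segment_trends", "fits_to_frame"]

# residual below this (relative to signal energy) counts as an exact fit
_SATURATION_RTOL = 1e-10


@dataclass
class PolyFit:
    """One fitted polynomial trend.

    ``coefficients`` are in ascending powers of the limb number;
    ``selection_pvalues`` holds the nested F-test p-value of each degree
    increment that was examined (degree 1→2 first). ``saturated`` marks
    a fit whose residual is numerically zero, beyond which F-tests are
    undefined.
    """

    label: str
    degree: int
    coefficients: np.ndarray
    rss: float
    n: int
    selection_pvalues: list[float] = field(default_factory=list)
    saturated: bool = False

    def predict(self, xs: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(xs, float), self.coefficients)


def _design(xs: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(np.asarray(xs, float), degree + 1, increasing=True)


def fit_polynomial(xs, ys, degree: int, label: str = "") -> PolyFit:
    """OLS polynomial fit of ``ys`` on ``xs`` at a fixed degree."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise ValueError("xs and ys must be 1-D arrays of equal length")
    uniq, counts = np.unique(xs, return_counts=True)
    if np.any(counts > 1):
        dups = uniq[counts > 1]
        raise ValueError(f"duplicated x values {dups.tolist()}: design is rank-deficient")
    if len(xs) <= degree:
        raise ValueError(f"need more than {degree} points for a degree-{degree} fit")
    res = sm.OLS(ys, _design(xs, degree)).fit()
    rss = float(res.ssr)
    scale = float(np.sum(ys**2)) + 1.0
    return PolyFit(
        label=label,
        degree=degree,
        coefficients=np.asarray(res.params, float),
        rss=rss,
        n=len(xs),
        saturated=rss <= _SATURATION_RTOL * scale,
    )


def select_degree(
    xs, ys, max_degree: int = 5, alpha: float = 0.05, label: str = ""
) -> PolyFit:
    """Forward nested-F degree selection.

    Fits degrees 1..``max_degree``; the degree grows while the F-test of
    each increment is significant (p < alpha) and stops at the first
    non-significant step, so ties favour the smaller model. A degree
    whose residual is numerically zero is returned immediately with the
    ``saturated`` flag: further F-statistics are undefined.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if len(xs) <= max_degree + 1:
        raise ValueError(f"need more than {max_degree + 1} points")
    models = {1: sm.OLS(ys, _design(xs, 1)).fit()}
    scale = float(np.sum(ys**2)) + 1.0
    pvalues: list[float] = []
    chosen = 1
    for k in range(2, max_degree + 1):
        if models[chosen].ssr <= _SATURATION_RTOL * scale:
            break  # exact fit already; stop growing
        models[k] = sm.OLS(ys, _design(xs, k)).fit()
        if models[k].ssr <= _SATURATION_RTOL * scale:
            # the bigger model interpolates: its improvement is trivially
            # "significant" but the F denominator vanishes
            pvalues.append(0.0)
            chosen = k
            break
        table = anova_lm(models[chosen], models[k])
        p = float(table["Pr(>F)"].iloc[1])
        pvalues.append(p)
        if p < alpha:
            chosen = k
        else:
            break
    best = models[chosen]
    rss = float(best.ssr)
    return PolyFit(
        label=label,
        degree=chosen,
        coefficients=np.asarray(best.params, float),
        rss=rss,
        n=len(xs),
        selection_pvalues=pvalues,
        saturated=rss <= _SATURATION_RTOL * scale,
    )


def segment_trends(
    matrix: SetationMatrix,
    scheme: SetalGroupScheme = DEFAULT_SCHEME,
    max_degree: int = 5,
    alpha: float = 0.05,
    include_missing_rows: bool = True,
) -> dict[str, PolyFit]:
    """Degree-selected trend of every ramal segment plus the grand total.

    Per-limb sums are formed with missing cells as zero. With
    ``include_missing_rows=False``, limbs lacking any segment are
    dropped before fitting (sensitivity mode for the posterior
    developmental tail).
    """
    sums = segment_sums(matrix, scheme)
    if not include_missing_rows:
        complete = [
            row.limb_index
            for row in matrix.rows
            if not any(c.is_missing for c in row.cells)
        ]
        sums = sums.loc[complete]
    xs = sums.index.to_numpy(float)
    out: dict[str, PolyFit] = {}
    for label in sums.columns:
        ys = sums[label].to_numpy(float)
        if np.all(ys == ys[0]):
            # constant (e.g. all-zero) series: a flat line, flagged saturated
            out[label] = PolyFit(
                label=label,
                degree=1,
                coefficients=np.array([ys[0], 0.0]),
                rss=0.0,
                n=len(xs),
                saturated=True,
            )
            continue
        out[label] = select_degree(xs, ys, max_degree=max_degree, alpha=alpha, label=label)
    return out


def fits_to_frame(fits: dict[str, PolyFit]) -> pd.DataFrame:
    """One row per fit: label, degree, coefficients, rss, n."""
    recs = []
    for label, fit in fits.items():
        recs.append(
            {
                "label": label,
                "degree": fit.degree,
                "coefficients": " ".join(f"{c:.6g}" for c in fit.coefficients),
                "rss": float(f"{fit.rss:.6g}"),
                "n": fit.n,
                "saturated": fit.saturated,
            }
        )
    return pd.DataFrame(recs)
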