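"""Ordinary and geographically weighted least squares on basin tables.

The regression couples basin mean habitat quality (response) to one
urbanization indicator at a time (NTL, POP or LUR; a joint fit is also
supported).  GWR solves a weighted least-squares problem at every basin i,

    Y = beta_0(u_i, v_i) + sum_k beta_k(u_i, v_i) X_k + eps,

with kernel weights on the distances from basin i's centroid, yielding local
coefficient surfaces.  Model comparison between OLS and GWR uses the
small-sample corrected AICc based on the hat-matrix trace,

    AICc = 2 n ln(sigma_ml) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S),

with sigma_ml^2 = RSS / n, and the residual standard error
sigma = sqrt(RSS / (n - tr S)) (tr S = p for OLS).  Both OLS and GWR are
solved from scratch via the normal equations; the Gaussian kernel at
infinite bandwidth has unit weights everywhere, so GWR then reproduces OLS
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "RegressionDesign",
    "OLSResult",
    "GWRFit",
    "ModelComparison",
    "design_from_table",
    "ols_fit",
    "gwr_fit",
    "select_bandwidth",
    "compare_models",
    "coefficient_sign_map",
]

KERNELS = ("gaussian", "bisquare", "adaptive_bisquare")


@dataclass
class RegressionDesign:
    """Response, predictors and projected coordinates for one regression."""

    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, k) predictors, intercept excluded
    coords: np.ndarray  # (n, 2) metres
    predictor_names: tuple[str, ...] = ()
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            self.X = self.X.T
        self.coords = np.asarray(self.coords, dtype=float).reshape(self.y.size, 2)
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise ValueError("design contains missing or non-finite values")
        n, k = self.X.shape
        if n < k + 2:
            raise ValueError(f"need at least k + 2 = {k + 2} observations, got {n}")
        if not self.predictor_names:
            self.predictor_names = tuple(f"x{i}" for i in range(k))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def design_matrix(self) -> np.ndarray:
        """(n, k+1) matrix with a leading intercept column."""
        return np.column_stack([np.ones(self.n), self.X])


def design_from_table(
    table: pd.DataFrame,
    predictors: Sequence[str] = ("ntl_mean",),
    response: str = "q_mean",
    coord_cols: tuple[str, str] = ("centroid_x", "centroid_y"),
) -> RegressionDesign:
    """Build a design from a basin indicator table."""
    return RegressionDesign(
        y=table[response].to_numpy(),
        X=table[list(predictors)].to_numpy(),
        coords=table[list(coord_cols)].to_numpy(),
        predictor_names=tuple(predictors),
        ids=table.index.to_numpy(),
    )


def _aicc(n: int, rss: float, trace_s: float) -> float:
    sigma_ml = np.sqrt(rss / n)
    denom = n - 2.0 - trace_s
    if denom <= 0 or sigma_ml <= 0:
        return np.inf
    return float(2 * n * np.log(sigma_ml) + n * np.log(2 * np.pi) + n * (n + trace_s) / denom)


@dataclass
class OLSResult:
    coef: np.ndarray  # (k+1,) with intercept first
    r2: float
    aicc: float
    sigma: float  # residual standard error sqrt(RSS / (n - p))
    rss: float
    n: int
    p: int
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)


def ols_fit(design: RegressionDesign) -> OLSResult:
    """Global least-squares fit via the normal equations."""
    Xd = design.design_matrix
    n, p = Xd.shape
    if np.linalg.matrix_rank(Xd) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ design.y)
    fitted = Xd @ beta
    resid = design.y - fitted
    rss = float(resid @ resid)
    tss = float(((design.y - design.y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    sigma = float(np.sqrt(rss / (n - p)))
    return OLSResult(
        coef=beta, r2=r2, aicc=_aicc(n, rss, float(p)), sigma=sigma,
        rss=rss, n=n, p=p, fitted=fitted, residuals=resid,
    )


@dataclass
class GWRFit:
    local_coef: np.ndarray  # (n, k+1), intercept first
    local_r2: np.ndarray  # (n,)
    aicc: float
    sigma: float
    hat_trace: float
    rss: float
    bandwidth: float
    kernel: str
    predictor_names: tuple[str, ...] = ()
    ids: np.ndarray | None = None
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)


def _kernel_weights(dists: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        if np.isinf(bandwidth):
            return np.ones_like(dists)
        return np.exp(-0.5 * (dists / bandwidth) ** 2)
    if kernel == "bisquare":
        u = dists / bandwidth
        w = (1 - u**2) ** 2
        return np.where(u < 1, w, 0.0)
    if kernel == "adaptive_bisquare":
        # bandwidth = number of nearest neighbours included
        k = max(int(round(bandwidth)), 2)
        h = np.sort(dists)[min(k, dists.size - 1)]
        if h <= 0:
            h = np.max(dists) or 1.0
        u = dists / h
        return np.where(u < 1, (1 - u**2) ** 2, 0.0)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


def gwr_fit(design: RegressionDesign, bandwidth: float, kernel: str = "gaussian") -> GWRFit:
    """Local weighted least squares at every basin.

    ``bandwidth`` is in metres for the distance kernels and a neighbour count
    for ``adaptive_bisquare``.  Raises if any local system is rank deficient
    (bandwidth too small), naming the basin.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    Xd = design.design_matrix
    n, p = Xd.shape
    D = cdist(design.coords, design.coords)
    coefs = np.empty((n, p))
    s_ii = np.empty(n)
    fitted = np.empty(n)
    local_r2 = np.empty(n)
    y = design.y
    for i in range(n):
        w = _kernel_weights(D[i], bandwidth, kernel)
        Xw = Xd * w[:, None]
        XtWX = Xd.T @ Xw
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            ident = design.ids[i] if design.ids is not None else i
            raise np.linalg.LinAlgError(
                f"local fit at basin {ident} is rank deficient; "
                f"bandwidth {bandwidth} is too small"
            ) from None
        beta_i = XtWX_inv @ (Xw.T @ y)
        coefs[i] = beta_i
        fitted[i] = Xd[i] @ beta_i
        # hat-matrix diagonal: x_i^T (X^T W X)^-1 X^T W e_i
        s_ii[i] = Xd[i] @ XtWX_inv @ (Xd[i] * w[i])
        wsum = w.sum()
        ybar_w = (w * y).sum() / wsum
        rss_w = float(w @ (y - Xd @ beta_i) ** 2)
        tss_w = float(w @ (y - ybar_w) ** 2)
        local_r2[i] = 1.0 - rss_w / tss_w if tss_w > 0 else 1.0
    resid = y - fitted
    rss = float(resid @ resid)
    trace = float(s_ii.sum())
    dof = n - trace
    sigma = float(np.sqrt(rss / dof)) if dof > 0 else np.inf
    return GWRFit(
        local_coef=coefs,
        local_r2=np.clip(local_r2, 0.0, 1.0),
        aicc=_aicc(n, rss, trace),
        sigma=sigma,
        hat_trace=trace,
        rss=rss,
        bandwidth=float(bandwidth),
        kernel=kernel,
        predictor_names=design.predictor_names,
        ids=design.ids,
        fitted=fitted,
        residuals=resid,
    )


def select_bandwidth(
    design: RegressionDesign,
    kernel: str = "gaussian",
    bounds: tuple[float, float] | None = None,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Golden-section search for the AICc-minimizing bandwidth.

    Deterministic for fixed data.  ``bounds`` defaults to a span from a tenth
    of the median pairwise distance to twice the maximum distance (for
    adaptive kernels: from p + 2 neighbours to n).
    """
    if design.n < 10:
        raise ValueError("bandwidth selection needs at least 10 basins")
    D = cdist(design.coords, design.coords)
    if bounds is None:
        if kernel == "adaptive_bisquare":
            bounds = (design.X.shape[1] + 3.0, float(design.n))
        else:
            pos = D[D > 0]
            bounds = (float(np.median(pos)) / 10.0, 2.0 * float(D.max()))
    lo, hi = bounds

    def crit(bw: float) -> float:
        try:
            return gwr_fit(design, bw, kernel).aicc
        except np.linalg.LinAlgError:
            return np.inf

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = crit(c), crit(d)
    for _ in range(max_iter):
        if (b - a) <= tol * max(abs(a), abs(b), 1.0):
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = crit(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = crit(d)
    candidates = [(crit(lo), lo), (fc, c), (fd, d), (crit(hi), hi)]
    finite = [(f, x) for f, x in candidates if np.isfinite(f)]
    if not finite:
        raise ValueError("AICc is non-finite over the whole bandwidth range")
    return float(min(finite)[1])


@dataclass
class ModelComparison:
    delta_aicc: float  # GWR - OLS
    delta_sigma: float  # GWR - OLS
    preferred: str | None  # 'GWR', 'OLS' or None when ambiguous
    ambiguous: bool


def compare_models(ols_result: OLSResult, gwr_result: GWRFit) -> ModelComparison:
    """Prefer GWR iff both its sigma and AICc are lower; otherwise flag.

    GWR is preferred only when it dominates on both criteria; OLS when it
    does; a split (or exact tie) is reported as ambiguous.
    """
    da = gwr_result.aicc - ols_result.aicc
    ds = gwr_result.sigma - ols_result.sigma
    if da < 0 and ds < 0:
        return ModelComparison(da, ds, "GWR", False)
    if da > 0 and ds > 0:
        return ModelComparison(da, ds, "OLS", False)
    return ModelComparison(da, ds, None, True)


def coefficient_sign_map(
    gwr_result: GWRFit, predictor: int | str = 0
) -> tuple[pd.Series, dict[str, float]]:
    """Sign of one predictor's local coefficient per basin, plus shares (%).

    ``predictor`` is an index into the non-intercept columns or a predictor
    name.  Returns (signs, shares) with shares summing to 100.
    """
    if isinstance(predictor, str):
        predictor = gwr_result.predictor_names.index(predictor)
    coefs = gwr_result.local_coef[:, predictor + 1]
    signs = np.sign(coefs).astype(int)
    index = (
        pd.Index(gwr_result.ids, name="basin_id")
        if gwr_result.ids is not None
        else pd.RangeIndex(len(coefs))
    )
    series = pd.Series(signs, index=index, name="sign")
    n = len(signs)
    shares = {
        "negative": 100.0 * (signs < 0).sum() / n,
        "positive": 100.0 * (signs > 0).sum() / n,
        "zero": 100.0 * (signs == 0).sum() / n,
    }
    return series, shares
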