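"""Second-order response-surface fitting and inference.

The model is the full quadratic polynomial

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j + e,

fitted by ordinary least squares.  The regression is solved on the CODED
model matrix for numerical conditioning (natural-unit CCD matrices can be
badly scaled when factor magnitudes differ by orders of magnitude) and then
mapped to natural units by the exact polynomial change of variables
x_coded = (x - center)/step; predictions from the two coefficient vectors
are identical to machine precision.

Inference follows the usual OLS machinery: coefficient covariance
MSE * (X'X)^{-1}, two-sided Student-t p-values with the residual degrees of
freedom, and a corrected-total ANOVA decomposition with an upper-tail F
test for the whole regression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rsmga.doe import (
    Design,
    Factor,
    InvalidParameterError,
    model_matrix,
    quadratic_regressors,
    quadratic_term_names,
)

__all__ = [
    "QuadraticSurface",
    "QuadraticFit",
    "AnovaTable",
    "StationaryPoint",
    "RankDeficiencyError",
    "SingularHessianError",
    "fit_quadratic",
    "predict",
    "residuals",
    "anova",
    "coefficient_stats",
    "stationary_point",
    "response_grid",
    "ResponseGrid",
]


class RankDeficiencyError(ValueError):
    """The model matrix is rank deficient; message names the collinear columns."""


class SingularHessianError(ValueError):
    """The fitted quadratic has a (numerically) singular Hessian: a ridge or
    otherwise degenerate surface with no isolated stationary point."""


@dataclass(frozen=True)
class QuadraticSurface:
    """A bare quadratic polynomial in natural units.

    ``coef`` follows the canonical term order (intercept, linear, pure
    quadratic, interactions i<j) for ``k`` factors.
    """

    coef: np.ndarray
    k: int
    term_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        object.__setattr__(self, "coef", coef)
        p = 1 + 2 * self.k + self.k * (self.k - 1) // 2
        if coef.shape != (p,):
            raise InvalidParameterError(
                f"quadratic in {self.k} factors needs {p} coefficients, got {coef.shape}"
            )
        if not self.term_names:
            names = [f"x{i + 1}" for i in range(self.k)]
            object.__setattr__(self, "term_names", tuple(quadratic_term_names(names)))

    def predict(self, points) -> np.ndarray | float:
        """Evaluate the polynomial at one (k,) point or an (n, k) batch."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        Z = quadratic_regressors(np.atleast_2d(pts))
        out = Z @ self.coef
        return float(out[0]) if single else out

    def gradient(self, point) -> np.ndarray:
        x = np.asarray(point, dtype=float)
        return self._linear() + self.hessian() @ x

    def hessian(self) -> np.ndarray:
        k = self.k
        H = np.diag(2.0 * self.coef[1 + k : 1 + 2 * k])
        for idx, (i, j) in enumerate(itertools.combinations(range(k), 2)):
            H[i, j] = H[j, i] = self.coef[1 + 2 * k + idx]
        return H

    def _linear(self) -> np.ndarray:
        return self.coef[1 : 1 + self.k]


@dataclass
class QuadraticFit:
    """An OLS fit of the full quadratic surface to a designed experiment."""

    factors: list[Factor]
    term_names: list[str]
    coef_coded: np.ndarray
    coef_natural: np.ndarray
    covariance_coded: np.ndarray
    covariance_natural: np.ndarray
    mse: float
    df_residual: int
    n_runs: int
    fitted: np.ndarray
    residual: np.ndarray

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def surface(self) -> QuadraticSurface:
        return QuadraticSurface(self.coef_natural, self.k, tuple(self.term_names))

    def predict(self, points):
        return self.surface.predict(points)

    def in_hull(self, point) -> bool:
        """Whether a natural-unit point lies inside the coded design hull
        (the box spanned by the design's extreme coded levels)."""
        x = np.asarray(point, dtype=float)
        coded = np.array([f.to_coded(v) for f, v in zip(self.factors, x)])
        return bool(np.all(np.abs(coded) <= self._coded_extent + 1e-12))

    _coded_extent: np.ndarray = field(default=None, repr=False)  # set by fit_quadratic


def _coded_to_natural_transform(factors: Sequence[Factor]) -> np.ndarray:
    """Matrix T with z_coded(x) = T u_natural(x) on the quadratic basis.

    Rows index coded-basis terms, columns natural-basis terms, both in
    canonical order.  Then beta_natural = T' beta_coded and
    Cov_natural = T' Cov_coded T.
    """
    k = len(factors)
    p = 1 + 2 * k + k * (k - 1) // 2
    c = np.array([f.center for f in factors])
    s = np.array([f.step for f in factors])
    pairs = list(itertools.combinations(range(k), 2))

    T = np.zeros((p, p))
    T[0, 0] = 1.0
    for i in range(k):
        # (x_i - c_i)/s_i
        r = 1 + i
        T[r, 0] = -c[i] / s[i]
        T[r, 1 + i] = 1.0 / s[i]
        # (x_i - c_i)^2 / s_i^2
        r = 1 + k + i
        T[r, 0] = c[i] ** 2 / s[i] ** 2
        T[r, 1 + i] = -2.0 * c[i] / s[i] ** 2
        T[r, 1 + k + i] = 1.0 / s[i] ** 2
    for idx, (i, j) in enumerate(pairs):
        # (x_i - c_i)(x_j - c_j)/(s_i s_j)
        r = 1 + 2 * k + idx
        d = s[i] * s[j]
        T[r, 0] = c[i] * c[j] / d
        T[r, 1 + i] = -c[j] / d
        T[r, 1 + j] = -c[i] / d
        T[r, 1 + 2 * k + idx] = 1.0 / d
    return T


def _name_collinear_columns(Z: np.ndarray, names: Sequence[str]) -> list[str]:
    from scipy.linalg import qr

    _, R, piv = qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Z.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    return [names[j] for j in sorted(piv[rank:])]


def fit_quadratic(design: Design, responses) -> QuadraticFit:
    """Fit the full second-order polynomial to a design's responses by OLS.

    Parameters
    ----------
    design : Design
    responses : array-like, length = number of runs

    Returns
    -------
    QuadraticFit
        Coefficients in both unit systems, natural-unit covariance
        (MSE * inverse Gram matrix mapped through the change of variables),
        residual mean square, fitted values and residuals.

    Raises
    ------
    InvalidParameterError
        If the response length does not match the design.
    RankDeficiencyError
        If the quadratic model matrix is rank deficient; the message names
        the collinear columns.
    """
    y = np.asarray(responses, dtype=float).ravel()
    if y.shape[0] != design.n_runs:
        raise InvalidParameterError(
            f"got {y.shape[0]} responses for a design with {design.n_runs} runs"
        )
    Z, names = model_matrix(design, units="coded")
    n, p = Z.shape
    if np.linalg.matrix_rank(Z) < p:
        bad = _name_collinear_columns(Z, names)
        raise RankDeficiencyError(
            "quadratic model matrix is rank deficient; collinear columns: " + ", ".join(bad)
        )

    beta_c, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ beta_c
    resid = y - fitted
    df_resid = n - p
    ss_res = float(resid @ resid)
    mse = ss_res / df_resid if df_resid > 0 else np.nan
    gram_inv = np.linalg.inv(Z.T @ Z)
    cov_c = mse * gram_inv

    T = _coded_to_natural_transform(design.factors)
    beta_n = T.T @ beta_c
    cov_n = T.T @ cov_c @ T

    fit = QuadraticFit(
        factors=list(design.factors),
        term_names=list(names),
        coef_coded=beta_c,
        coef_natural=beta_n,
        covariance_coded=cov_c,
        covariance_natural=cov_n,
        mse=mse,
        df_residual=df_resid,
        n_runs=n,
        fitted=fitted,
        residual=resid,
    )
    fit._coded_extent = np.max(np.abs(design.coded_matrix), axis=0)
    return fit


def predict(fit: QuadraticFit | QuadraticSurface, points):
    """Evaluate a fitted surface at natural-unit point(s).

    Extrapolation outside the design hull is permitted; use
    ``QuadraticFit.in_hull`` to flag it in reports.
    """
    return fit.predict(points)


def residuals(fit: QuadraticFit, responses) -> np.ndarray:
    """Observed minus fitted, per run."""
    y = np.asarray(responses, dtype=float).ravel()
    if y.shape[0] != fit.n_runs:
        raise InvalidParameterError(
            f"got {y.shape[0]} responses for a fit with {fit.n_runs} runs"
        )
    return y - fit.fitted


@dataclass(frozen=True)
class AnovaTable:
    """Corrected-total ANOVA for the whole regression.

    R^2 = SS_model / SS_total, R = sqrt(R^2), and the adjusted R^2 uses the
    usual (n - 1)/(n - p) small-sample correction.
    """

    ss_model: float
    ss_residual: float
    ss_total: float
    df_model: int
    df_residual: int
    ms_model: float
    ms_residual: float
    f_value: float
    p_value: float
    r: float
    r2: float
    r2_adj: float

    @classmethod
    def from_sums(
        cls, ss_model: float, df_model: int, ss_residual: float, df_residual: int
    ) -> "AnovaTable":
        """Build the table from sums of squares and degrees of freedom alone.

        Useful for checking the internal identities (MS = SS/df,
        F = MS_model/MS_residual, R^2 = SS_model/SS_total) of a published
        ANOVA table without access to the underlying data.
        """
        if df_residual < 1:
            raise InvalidParameterError("df_residual must be >= 1 (saturated model)")
        ss_total = ss_model + ss_residual
        ms_m = ss_model / df_model
        ms_r = ss_residual / df_residual
        f = ms_m / ms_r
        p = float(stats.f.sf(f, df_model, df_residual))
        r2 = ss_model / ss_total
        n = df_model + df_residual + 1
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_residual
        return cls(
            ss_model=ss_model,
            ss_residual=ss_residual,
            ss_total=ss_total,
            df_model=df_model,
            df_residual=df_residual,
            ms_model=ms_m,
            ms_residual=ms_r,
            f_value=f,
            p_value=p,
            r=float(np.sqrt(r2)),
            r2=r2,
            r2_adj=r2_adj,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SS": [self.ss_model, self.ss_residual, self.ss_total],
                "df": [self.df_model, self.df_residual, self.df_model + self.df_residual],
                "MS": [self.ms_model, self.ms_residual, np.nan],
                "F": [self.f_value, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            },
            index=["model", "residual", "total"],
        )


def anova(fit: QuadraticFit, responses) -> AnovaTable:
    """Whole-model ANOVA of a fit against the corrected total."""
    if fit.df_residual < 1:
        raise InvalidParameterError("saturated model: no residual degrees of freedom")
    y = np.asarray(responses, dtype=float).ravel()
    if y.shape[0] != fit.n_runs:
        raise InvalidParameterError("response length does not match the fit")
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(fit.residual @ fit.residual)
    ss_model = ss_total - ss_res
    return AnovaTable.from_sums(ss_model, len(fit.term_names) - 1, ss_res, fit.df_residual)


def coefficient_stats(fit: QuadraticFit, units: str = "natural") -> pd.DataFrame:
    """Per-term estimate, standard error, t statistic and two-sided p-value.

    SEs come from the covariance diagonal; t uses the residual degrees of
    freedom.
    """
    if fit.df_residual < 1:
        raise InvalidParameterError("saturated model: inference requires df_residual >= 1")
    if units == "natural":
        est, cov = fit.coef_natural, fit.covariance_natural
    elif units == "coded":
        est, cov = fit.coef_coded, fit.covariance_coded
    else:
        raise InvalidParameterError(f"units must be 'coded' or 'natural', got {units!r}")
    se = np.sqrt(np.diag(cov))
    if np.any(se == 0):
        zero = [n for n, s in zip(fit.term_names, se) if s == 0]
        raise InvalidParameterError("zero standard error, t undefined for: " + ", ".join(zero))
    t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_residual)
    return pd.DataFrame(
        {"estimate": est, "se": se, "t": t, "p": p}, index=list(fit.term_names)
    )


@dataclass(frozen=True)
class StationaryPoint:
    """The point where the fitted quadratic's gradient vanishes."""

    location_natural: np.ndarray
    predicted_value: float
    nature: Literal["maximum", "minimum", "saddle"]
    hessian_eigenvalues: np.ndarray


def stationary_point(
    fit: QuadraticFit | QuadraticSurface, cond_limit: float = 1e12
) -> StationaryPoint:
    """Solve grad f = 0 for the fitted quadratic and classify the point.

    The nature is a maximum iff every Hessian eigenvalue is negative, a
    minimum iff every one is positive, otherwise a saddle.

    Raises
    ------
    SingularHessianError
        If the Hessian condition number exceeds ``cond_limit`` (a ridge or
        degenerate surface).
    """
    surf = fit.surface if isinstance(fit, QuadraticFit) else fit
    H = surf.hessian()
    if not np.all(np.isfinite(H)) or np.linalg.cond(H) > cond_limit:
        raise SingularHessianError(
            "Hessian is singular or near-singular: the surface has a ridge or "
            "degenerate stationary set, no isolated stationary point"
        )
    loc = np.linalg.solve(H, -surf._linear())
    eigs = np.linalg.eigvalsh(H)
    if np.all(eigs < 0):
        nature = "maximum"
    elif np.all(eigs > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    return StationaryPoint(
        location_natural=loc,
        predicted_value=float(surf.predict(loc)),
        nature=nature,
        hessian_eigenvalues=eigs,
    )


@dataclass(frozen=True)
class ResponseGrid:
    """A regular 2-factor prediction grid for contour plotting."""

    x1: np.ndarray
    x2: np.ndarray
    values: np.ndarray  # shape (len(x2), len(x1)), rows indexed by x2
    argmax_natural: tuple[float, float]
    max_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.x2, columns=self.x1)


def response_grid(
    fit: QuadraticFit | QuadraticSurface,
    ranges: Sequence[Sequence[float]],
    resolution: int = 201,
) -> ResponseGrid:
    """Evaluate the fitted surface on a regular 2-D grid.

    Parameters
    ----------
    ranges : [[low1, high1], [low2, high2]]
        Natural-unit extent per factor.
    resolution : int
        Grid points per axis.
    """
    surf = fit.surface if isinstance(fit, QuadraticFit) else fit
    if surf.k != 2:
        raise InvalidParameterError(f"grid export is defined for 2 factors, got k={surf.k}")
    (lo1, hi1), (lo2, hi2) = ranges
    x1 = np.linspace(lo1, hi1, resolution)
    x2 = np.linspace(lo2, hi2, resolution)
    G1, G2 = np.meshgrid(x1, x2)
    pts = np.column_stack([G1.ravel(), G2.ravel()])
    vals = np.asarray(surf.predict(pts)).reshape(G1.shape)
    idx = np.unravel_index(np.argmax(vals), vals.shape)
    return ResponseGrid(
        x1=x1,
        x2=x2,
        values=vals,
        argmax_natural=(float(G1[idx]), float(G2[idx])),
        max_value=float(vals[idx]),
    )
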