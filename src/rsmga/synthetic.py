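"""Synthetic data with the statistical structure the analysis assumes.

The generator draws a known quadratic "truth" surface — concave by
construction, with its stationary point inside the declared box — and
produces design responses as the polynomial value plus i.i.d. homoscedastic
Gaussian noise.  That is exactly the model under which the OLS/ANOVA
machinery is calibrated, so recovery tests (coefficient unbiasedness,
confidence-interval coverage, optimizer accuracy versus the known optimum)
have clean expected answers.

Screening tables are drawn with cell dry weight uniform on [5, 25] g/L and
a conversion fraction uniform on [0.4, 0.85], the ranges spanned by typical
waste-substrate PHA screening campaigns; percent conversion is consistent
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rsmga.doe import Design, InvalidParameterError
from rsmga.pipeline import ScreeningRecord
from rsmga.rsm import QuadraticSurface, StationaryPoint, stationary_point

__all__ = ["TruthSurface", "make_truth", "simulate_responses", "make_screening_table"]

#: Default natural-unit box, mirroring the worked example's design space.
DEFAULT_BOX = ((0.0, 8.0), (0.0, 0.4))


@dataclass(frozen=True)
class TruthSurface:
    """A known quadratic data-generating surface."""

    surface: QuadraticSurface
    noise_sd: float
    box: np.ndarray  # (k, 2)
    stationary: StationaryPoint
    seed: int | None

    @property
    def coef(self) -> np.ndarray:
        return self.surface.coef

    @property
    def k(self) -> int:
        return self.surface.k

    def predict(self, points):
        return self.surface.predict(points)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_truth(
    k: int = 2,
    box=DEFAULT_BOX,
    mode: str = "concave",
    noise_sd: float = 2.0,
    seed=None,
    peak_range: tuple[float, float] = (25.0, 40.0),
    margin: float = 0.1,
) -> TruthSurface:
    """Draw a random quadratic truth surface over a box.

    In ``concave`` mode the Hessian is negative definite by construction
    (−L·R·L with R a random correlation matrix and L a positive diagonal
    scaled to the box half-widths), and the stationary point is rejection-
    sampled into the interior of the box (a ``margin`` fraction inside each
    edge).  ``saddle`` mode draws mixed-sign Hessian eigenvalues instead.

    The peak (stationary) value is uniform on ``peak_range`` and the
    curvature along each axis is set so the surface drops by 30-90% of the
    peak from the stationary point to the box edge — a response that varies
    strongly over the explored region, as a well-chosen design space should.
    """
    rng = _rng(seed)
    box = np.atleast_2d(np.asarray(box, dtype=float))
    if box.shape != (k, 2) or np.any(box[:, 0] >= box[:, 1]):
        raise InvalidParameterError("box must be (k, 2) with low < high")
    if mode not in ("concave", "saddle"):
        raise InvalidParameterError(f"mode must be 'concave' or 'saddle', got {mode!r}")

    width = box[:, 1] - box[:, 0]
    # rejection-sample the stationary location into the interior
    lo = box[:, 0] + margin * width
    hi = box[:, 1] - margin * width
    while True:
        x_star = rng.uniform(box[:, 0], box[:, 1])
        if np.all(x_star >= lo) and np.all(x_star <= hi):
            break

    peak = rng.uniform(*peak_range)
    drop = rng.uniform(0.3, 0.9, size=k) * peak
    curv = 2.0 * drop / (width / 2.0) ** 2  # positive curvature magnitudes

    if mode == "concave":
        A = rng.standard_normal((k, k + 2))
        S = A @ A.T
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)  # random correlation matrix, SPD
        L = np.diag(np.sqrt(curv))
        H = -L @ R @ L
    else:
        A = rng.standard_normal((k, k))
        Q, _ = np.linalg.qr(A)
        signs = np.ones(k)
        signs[rng.integers(k)] = -1.0  # at least one sign flipped -> saddle
        H = Q @ np.diag(-signs * curv) @ Q.T

    b_lin = -H @ x_star
    b0 = peak - x_star @ b_lin - 0.5 * x_star @ H @ x_star

    import itertools

    coef = np.concatenate(
        [
            [b0],
            b_lin,
            np.diag(H) / 2.0,
            [H[i, j] for i, j in itertools.combinations(range(k), 2)],
        ]
    )
    surf = QuadraticSurface(coef, k)
    sp = stationary_point(surf)
    return TruthSurface(
        surface=surf,
        noise_sd=float(noise_sd),
        box=box,
        stationary=sp,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_responses(design: Design, truth: TruthSurface, seed=None) -> np.ndarray:
    """Responses at the design's natural points: truth polynomial plus
    i.i.d. Normal(0, noise_sd^2) noise."""
    if design.k != truth.k:
        raise InvalidParameterError(
            f"design has {design.k} factors but truth has {truth.k}"
        )
    rng = _rng(seed)
    clean = np.asarray(truth.predict(design.natural_matrix))
    return clean + rng.normal(0.0, truth.noise_sd, size=clean.shape)


def make_screening_table(n_carbon: int, n_nitrogen: int, seed=None) -> list[ScreeningRecord]:
    """Random screening records for both roles, consistent by construction."""
    if n_carbon < 1 or n_nitrogen < 1:
        raise InvalidParameterError("need at least one source per role")
    rng = _rng(seed)
    records = []
    for role, n in (("carbon", n_carbon), ("nitrogen", n_nitrogen)):
        cdw = rng.uniform(5.0, 25.0, size=n)
        frac = rng.uniform(0.4, 0.85, size=n)
        for i in range(n):
            records.append(
                ScreeningRecord(
                    source=f"{role}-source-{i + 1:02d}",
                    role=role,
                    cdw=float(cdw[i]),
                    pha=float(cdw[i] * frac[i]),
                )
            )
    return records
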