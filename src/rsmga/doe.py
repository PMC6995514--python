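"""Central composite designs and quadratic model matrices.

Factors are defined by a *center* and a *step* (the natural-unit width of one
coded unit), so that ``natural = center + step * coded``.  A k-factor central
composite design (CCD) consists of the 2**k factorial corners at coded +/-1,
2k axial ("star") points at coded +/-alpha on one axis, and ``n_center``
replicated center points.  With alpha not in {0, 1} each factor takes five
distinct coded levels {-alpha, -1, 0, +1, +alpha}, which is what makes the
full second-order polynomial estimable.

The quadratic model matrix column order used throughout the package is:
intercept, linear terms (factor order), pure quadratic terms (factor order),
pairwise interactions (i < j, lexicographic).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignPoint",
    "Design",
    "InvalidParameterError",
    "generate_ccd",
    "coded_to_natural",
    "natural_to_coded",
    "model_matrix",
    "quadratic_regressors",
    "quadratic_term_names",
    "randomize_runs",
    "write_design",
    "read_design",
]


class InvalidParameterError(ValueError):
    """A design parameter violates its precondition (e.g. step <= 0)."""


@dataclass(frozen=True)
class Factor:
    """A continuous experimental factor on a coded scale.

    Parameters
    ----------
    name : str
        Column label, e.g. ``"carbon"``.
    center : float
        Natural level at coded 0.
    step : float
        Natural-unit change per coded unit; must be positive so the
        coded -> natural map is strictly increasing.
    units : str
        Free-text units, e.g. ``"g/100 mL"``.
    """

    name: str
    center: float
    step: float
    units: str = "g/100 mL"

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise InvalidParameterError(f"factor {self.name!r}: center must be finite")
        if not (self.step > 0) or not np.isfinite(self.step):
            raise InvalidParameterError(
                f"factor {self.name!r}: step must be a positive finite number, got {self.step}"
            )

    def to_natural(self, coded):
        """center + step * coded (vectorized)."""
        return self.center + self.step * np.asarray(coded, dtype=float)

    def to_coded(self, natural):
        """(natural - center) / step, the exact inverse of :meth:`to_natural`."""
        return (np.asarray(natural, dtype=float) - self.center) / self.step


def coded_to_natural(factor: Factor, coded):
    """Map coded level(s) to natural units for one factor."""
    return factor.to_natural(coded)


def natural_to_coded(factor: Factor, natural):
    """Map natural level(s) to coded units for one factor."""
    return factor.to_coded(natural)


Block = Literal["factorial", "axial", "center"]


@dataclass(frozen=True)
class DesignPoint:
    """One experimental run: coded and natural coordinates plus its block."""

    run_id: int
    coded: tuple[float, ...]
    natural: tuple[float, ...]
    block: Block


@dataclass
class Design:
    """A designed experiment: an ordered list of runs over shared factors."""

    factors: list[Factor]
    points: list[DesignPoint]
    alpha: float
    n_center: int

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([p.coded for p in self.points], dtype=float)

    @property
    def natural_matrix(self) -> np.ndarray:
        return np.array([p.natural for p in self.points], dtype=float)

    @property
    def blocks(self) -> list[str]:
        return [p.block for p in self.points]

    def natural_box(self) -> np.ndarray:
        """Per-factor [low, high] hull of the design in natural units, (k, 2)."""
        nat = self.natural_matrix
        return np.column_stack([nat.min(axis=0), nat.max(axis=0)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.natural_matrix, columns=self.factor_names)
        df.insert(0, "block", self.blocks)
        df.insert(0, "run", [p.run_id for p in self.points])
        return df

    @classmethod
    def from_natural(
        cls,
        factors: Sequence[Factor],
        natural: np.ndarray,
        blocks: Sequence[str] | None = None,
        alpha: float = np.nan,
        n_center: int = 0,
        run_ids: Sequence[int] | None = None,
    ) -> "Design":
        """Build a Design from an explicit (n, k) natural-unit run matrix.

        Used for externally supplied run orders (e.g. a published table whose
        order differs from the canonical generator order).
        """
        natural = np.atleast_2d(np.asarray(natural, dtype=float))
        factors = list(factors)
        if natural.shape[1] != len(factors):
            raise InvalidParameterError(
                f"run matrix has {natural.shape[1]} columns for {len(factors)} factors"
            )
        if blocks is None:
            blocks = ["factorial"] * len(natural)
        if run_ids is None:
            run_ids = range(1, len(natural) + 1)
        pts = []
        for rid, row, blk in zip(run_ids, natural, blocks):
            coded = tuple(float(f.to_coded(v)) for f, v in zip(factors, row))
            pts.append(DesignPoint(int(rid), coded, tuple(float(v) for v in row), blk))
        return cls(factors, pts, alpha=float(alpha), n_center=int(n_center))


def generate_ccd(factors: Sequence[Factor], alpha: float, n_center: int) -> Design:
    """Construct a central composite design in canonical run order.

    Order: 2**k factorial corners (lexicographic, low level first), then the
    2k axial points (factor order, minus before plus), then ``n_center``
    center replicates.  Run ids are sequential from 1.

    Parameters
    ----------
    factors : sequence of Factor
    alpha : float
        Coded axial distance; must be positive.
    n_center : int
        Number of center-point replicates; at least 1.
    """
    factors = list(factors)
    if len(factors) == 0:
        raise InvalidParameterError("at least one factor is required")
    if not (alpha > 0) or not np.isfinite(alpha):
        raise InvalidParameterError(f"alpha must be positive and finite, got {alpha}")
    if n_center < 1:
        raise InvalidParameterError(f"n_center must be >= 1, got {n_center}")

    k = len(factors)
    rows: list[tuple[tuple[float, ...], Block]] = []
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        rows.append((corner, "factorial"))
    for i in range(k):
        for sign in (-1.0, 1.0):
            coded = [0.0] * k
            coded[i] = sign * alpha
            rows.append((tuple(coded), "axial"))
    for _ in range(n_center):
        rows.append(((0.0,) * k, "center"))

    points = []
    for rid, (coded, blk) in enumerate(rows, start=1):
        natural = tuple(float(f.to_natural(c)) for f, c in zip(factors, coded))
        points.append(DesignPoint(rid, coded, natural, blk))
    return Design(factors, points, alpha=float(alpha), n_center=int(n_center))


def quadratic_term_names(names: Sequence[str]) -> list[str]:
    """Term labels for the full quadratic model, in canonical column order."""
    names = list(names)
    out = ["intercept"]
    out += list(names)
    out += [f"{n}^2" for n in names]
    out += [f"{a}*{b}" for a, b in itertools.combinations(names, 2)]
    return out


def quadratic_regressors(X: np.ndarray) -> np.ndarray:
    """Expand an (n, k) point matrix into full quadratic regressors.

    Columns: 1, x_1..x_k, x_1^2..x_k^2, x_i*x_j (i < j).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, i] for i in range(k))
    cols.extend(X[:, i] ** 2 for i in range(k))
    cols.extend(X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2))
    return np.column_stack(cols)


def model_matrix(design: Design, units: str = "coded") -> tuple[np.ndarray, list[str]]:
    """Quadratic model matrix of a design plus its column labels.

    Parameters
    ----------
    design : Design
    units : {"coded", "natural"}
        Which coordinate system to expand.
    """
    if design.n_runs == 0:
        raise InvalidParameterError("design has no runs")
    if units == "coded":
        X = design.coded_matrix
    elif units == "natural":
        X = design.natural_matrix
    else:
        raise InvalidParameterError(f"units must be 'coded' or 'natural', got {units!r}")
    return quadratic_regressors(X), quadratic_term_names(design.factor_names)


def randomize_runs(design: Design, rng: np.random.Generator) -> Design:
    """Return a copy of the design with run order shuffled (seeded).

    Run ids are renumbered sequentially in the new order; the original order
    is recoverable from the generator seed only.
    """
    perm = rng.permutation(design.n_runs)
    pts = [
        DesignPoint(i + 1, design.points[j].coded, design.points[j].natural, design.points[j].block)
        for i, j in enumerate(perm)
    ]
    return Design(list(design.factors), pts, design.alpha, design.n_center)


def write_design(design: Design, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write run,block,<factors...> CSV (natural units) plus a JSON sidecar.

    The sidecar stores factors/alpha/n_center so coded levels are
    recomputable bit-exactly.
    """
    csv_path = Path(csv_path)
    design.to_frame().to_csv(csv_path, index=False)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = {
        "factors": [
            {"name": f.name, "center": f.center, "step": f.step, "units": f.units}
            for f in design.factors
        ],
        "alpha": design.alpha,
        "n_center": design.n_center,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_design(csv_path: str | Path, meta_path: str | Path | None = None) -> Design:
    """Read a design written by :func:`write_design`."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    factors = [Factor(**fd) for fd in meta["factors"]]
    df = pd.read_csv(csv_path)
    natural = df[[f.name for f in factors]].to_numpy(dtype=float)
    return Design.from_natural(
        factors,
        natural,
        blocks=list(df["block"]),
        alpha=meta["alpha"],
        n_center=meta["n_center"],
        run_ids=list(df["run"]),
    )
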