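"""Bundled worked-example data: a published PHA medium-optimization study.

A *Bacillus subtilis* fermentation campaign screened kitchen-/agro-waste
carbon and nitrogen sources one factor at a time, then ran a two-factor
central composite design over the concentrations of the best carbon source
(watermelon rind) and nitrogen source (pulse peel) and fitted a quadratic
response surface to the PHA content.  The tables below carry the published
numbers verbatim (including the published run order, predicted/residual
columns and the reported ANOVA sums of squares) so the package's golden
tests and worked examples need no external files.

Two published coefficient sets exist for the same fit: the regression table
(which matches an exact OLS solution of the design data) and a separately
printed polynomial equation with different values.  Both are provided;
``published_polynomial`` returns the printed-equation version as a labelled
fixture because the study's optimization step was run on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rsmga.doe import Design, Factor
from rsmga.rsm import QuadraticSurface

__all__ = [
    "CARBON_FACTOR",
    "NITROGEN_FACTOR",
    "load_screening",
    "load_ccd_experiment",
    "published_polynomial",
    "published_regression_table",
    "published_anova_sums",
    "DESIGN_BOX",
]

CARBON_FACTOR = Factor("carbon", center=4.0, step=2.0, units="g/100 mL")
NITROGEN_FACTOR = Factor("nitrogen", center=0.2, step=0.1, units="g/100 mL")

#: Natural-unit design box, the coded +/-2 hull of the CCD.
DESIGN_BOX = np.array([[0.0, 8.0], [0.0, 0.4]])

_SCREENING_ROWS = [
    # source, role, cell dry weight (g/L), PHA (g/L), published % conversion
    ("Mixed fruit peels", "carbon", 8.5, 4.9, 57.64),
    ("Mixed vegetable peels", "carbon", 9.8, 6.2, 63.27),
    ("Green pea shells", "carbon", 11.26, 8.77, 77.89),
    ("Muskmelon peels", "carbon", 9.98, 7.84, 78.56),
    ("Watermelon rind", "carbon", 16.5, 12.97, 78.61),
    ("Papaya peels", "carbon", 15.0, 11.65, 77.67),
    ("Orange peels", "carbon", 19.39, 9.68, 49.93),
    ("Peptone", "nitrogen", 16.5, 12.97, 78.61),
    ("Pulse peel", "nitrogen", 19.51, 13.5, 69.20),
    ("Beef extract", "nitrogen", 18.85, 11.5, 61.01),
    ("Yeast extract", "nitrogen", 12.02, 9.45, 78.62),
]


def load_screening() -> pd.DataFrame:
    """One-factor-at-a-time screening table.

    Columns: source, role (carbon|nitrogen), cdw (g/L), pha (g/L),
    published_percent_conversion.  The published column is carried verbatim;
    two of its rows differ by 0.01 from 100*pha/cdw due to rounding in the
    original table.
    """
    return pd.DataFrame(
        _SCREENING_ROWS,
        columns=["source", "role", "cdw", "pha", "published_percent_conversion"],
    )


# Published CCD, in its original run order: factorial corners (runs 1-4),
# a center point (5), carbon axials (6-7), nitrogen axials (8-9), center (10).
_CCD_ROWS = [
    # run, carbon, nitrogen, observed, published predicted, published residual
    (1, 2.0, 0.1, 27.221, 23.095, 4.125),
    (2, 2.0, 0.3, 27.928, 25.881, 2.046),
    (3, 6.0, 0.1, 37.996, 35.613, 2.382),
    (4, 6.0, 0.3, 36.052, 35.748, 0.303),
    (5, 4.0, 0.2, 33.124, 35.966, -2.842),
    (6, 0.0, 0.2, 2.25, 4.228, -1.978),
    (7, 8.0, 0.2, 26.377, 26.612, -0.235),
    (8, 4.0, 0.0, 29.38, 31.526, -2.146),
    (9, 4.0, 0.4, 34.38, 34.447, -0.067),
    (10, 4.0, 0.2, 34.38, 35.966, -1.586),
]

_CCD_BLOCKS = [
    "factorial", "factorial", "factorial", "factorial", "center",
    "axial", "axial", "axial", "axial", "center",
]


def load_ccd_experiment() -> tuple[Design, pd.DataFrame]:
    """The published 10-run CCD and its response table.

    Returns the design (alpha = 2, two center replicates, published run
    order) and a DataFrame with columns run, carbon, nitrogen, observed,
    published_predicted, published_residual.  The response is PHA content.
    """
    df = pd.DataFrame(
        _CCD_ROWS,
        columns=["run", "carbon", "nitrogen", "observed", "published_predicted", "published_residual"],
    )
    design = Design.from_natural(
        [CARBON_FACTOR, NITROGEN_FACTOR],
        df[["carbon", "nitrogen"]].to_numpy(),
        blocks=_CCD_BLOCKS,
        alpha=2.0,
        n_center=2,
        run_ids=df["run"].tolist(),
    )
    return design, df


def published_polynomial() -> QuadraticSurface:
    """The study's printed optimization polynomial, as a labelled fixture.

    Y = -0.4595 + 13.053*C - 1.320*C^2 + 44.166*N - 104.756*N^2 + 1.546*C*N
    with C, N in g/100 mL.  Note these coefficients differ from the
    published regression table for the same data (see
    :func:`published_regression_table`); the regression table matches the
    exact OLS solution, this equation does not, but it is the surface the
    study's genetic-algorithm step maximized.
    """
    # canonical term order: intercept, C, N, C^2, N^2, C*N
    coef = np.array([-0.4595, 13.053, 44.166, -1.320, -104.756, 1.546])
    return QuadraticSurface(coef, k=2, term_names=(
        "intercept", "carbon", "nitrogen", "carbon^2", "nitrogen^2", "carbon*nitrogen",
    ))


def published_regression_table() -> pd.DataFrame:
    """The published regression-coefficient table (natural units).

    Columns: estimate, se, t, p; index in canonical term order.  These are
    the values an exact OLS fit of the bundled CCD reproduces.
    """
    rows = {
        "intercept": (-2.8622, 8.43462, -0.33934, 0.751425),
        "carbon": (13.7336, 2.43016, 5.65131, 0.004830),
        "nitrogen": (50.3486, 48.60319, 1.03591, 0.358759),
        "carbon^2": (-1.2841, 0.20846, -6.15993, 0.003525),
        "nitrogen^2": (-74.4777, 83.38407, -0.89319, 0.422238),
        "carbon*nitrogen": (-3.3137, 8.49142, -0.39025, 0.716244),
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["estimate", "se", "t", "p"])


def published_anova_sums() -> dict:
    """The published whole-model ANOVA sums of squares and df.

    These entries are internally consistent (their MS/F/R^2 identities
    reproduce the published F = 19.72049 and R^2 = 96.10%) but are *not*
    consistent with the design data or the published residual column, whose
    squared sum is about 46.15; the package reports both routes rather than
    choosing.
    """
    return {"ss_model": 896.0238, "df_model": 5, "ss_residual": 36.34894, "df_residual": 4}
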