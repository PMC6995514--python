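"""End-to-end orchestration: screening accounting, response-surface fit,
and genetic-algorithm optimization of the fitted surface, gathered into a
single reproducible report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from rsmga.doe import Design, InvalidParameterError, read_design
from rsmga.ga import GAConfig, GAResult, run_ga
from rsmga.rsm import (
    AnovaTable,
    QuadraticFit,
    StationaryPoint,
    anova,
    coefficient_stats,
    fit_quadratic,
    stationary_point,
)

__all__ = [
    "ScreeningRecord",
    "ScreeningRanking",
    "ReportBundle",
    "PipelineError",
    "percent_conversion",
    "rank_sources",
    "run_full_analysis",
]


class PipelineError(RuntimeError):
    """A stage of the full analysis failed; the message names the stage."""


def percent_conversion(pha: float, cdw: float) -> float:
    """Screening yield metric: 100 * PHA mass / cell dry weight.

    Rounding to the 2 decimals used in report tables happens only at
    presentation.
    """
    if not cdw > 0:
        raise InvalidParameterError(f"cell dry weight must be positive, got {cdw}")
    return 100.0 * pha / cdw


Role = Literal["carbon", "nitrogen"]


@dataclass(frozen=True)
class ScreeningRecord:
    """One one-factor-at-a-time screening run for a candidate source."""

    source: str
    role: Role
    cdw: float  # cell dry weight, g/L
    pha: float  # product mass, g/L

    def __post_init__(self) -> None:
        if not self.cdw > 0:
            raise InvalidParameterError(
                f"{self.source!r}: cell dry weight must be positive, got {self.cdw}"
            )
        if self.pha < 0:
            raise InvalidParameterError(f"{self.source!r}: PHA mass must be >= 0")
        if self.role not in ("carbon", "nitrogen"):
            raise InvalidParameterError(f"{self.source!r}: role must be carbon or nitrogen")

    @property
    def percent_conversion(self) -> float:
        return percent_conversion(self.pha, self.cdw)


Criterion = Literal["pha_mass", "percent_conversion"]


@dataclass(frozen=True)
class ScreeningRanking:
    """Sources ranked within role, with the best source per role."""

    ordered: tuple[ScreeningRecord, ...]
    best: dict  # role -> ScreeningRecord
    criterion: Criterion

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [r.source for r in self.ordered],
                "role": [r.role for r in self.ordered],
                "cdw": [r.cdw for r in self.ordered],
                "pha": [r.pha for r in self.ordered],
                "percent_conversion": [round(r.percent_conversion, 2) for r in self.ordered],
                "selected": [r is self.best.get(r.role) for r in self.ordered],
            }
        )


def _criterion_value(record: ScreeningRecord, criterion: Criterion) -> float:
    if criterion == "pha_mass":
        return record.pha
    if criterion == "percent_conversion":
        return record.percent_conversion
    raise InvalidParameterError(f"unknown ranking criterion {criterion!r}")


def rank_sources(
    records: Sequence[ScreeningRecord], criterion: Criterion = "pha_mass"
) -> ScreeningRanking:
    """Rank screening records within each role and pick the best per role.

    Descending by the criterion; ties broken alphabetically by source name.
    """
    records = list(records)
    if not records:
        raise InvalidParameterError("at least one screening record is required")
    ordered = sorted(
        records, key=lambda r: (r.role, -_criterion_value(r, criterion), r.source)
    )
    best: dict = {}
    for r in ordered:
        best.setdefault(r.role, r)
    return ScreeningRanking(tuple(ordered), best, criterion)


@dataclass
class ReportBundle:
    """Every result of the full analysis, traceable to an operation output."""

    screening: ScreeningRanking
    fit: QuadraticFit
    anova_table: AnovaTable
    coefficients: pd.DataFrame
    stationary: StationaryPoint
    ga: GAResult
    provenance: dict

    def to_dict(self) -> dict:
        sp = self.stationary
        return {
            "provenance": self.provenance,
            "screening": {
                "criterion": self.screening.criterion,
                "best": {
                    role: {
                        "source": rec.source,
                        "pha": rec.pha,
                        "cdw": rec.cdw,
                        "percent_conversion": round(rec.percent_conversion, 2),
                    }
                    for role, rec in sorted(self.screening.best.items())
                },
                "table": self.screening.to_frame().to_dict(orient="records"),
            },
            "fit": {
                "term_names": list(self.fit.term_names),
                "coef_natural": [float(v) for v in self.fit.coef_natural],
                "coef_coded": [float(v) for v in self.fit.coef_coded],
                "mse": float(self.fit.mse),
                "df_residual": int(self.fit.df_residual),
                "n_runs": int(self.fit.n_runs),
            },
            "coefficients": {
                term: {k: float(v) for k, v in row.items()}
                for term, row in self.coefficients.iterrows()
            },
            "anova": {
                "ss_model": self.anova_table.ss_model,
                "ss_residual": self.anova_table.ss_residual,
                "ss_total": self.anova_table.ss_total,
                "df_model": self.anova_table.df_model,
                "df_residual": self.anova_table.df_residual,
                "f_value": self.anova_table.f_value,
                "p_value": self.anova_table.p_value,
                "r": self.anova_table.r,
                "r2": self.anova_table.r2,
                "r2_adj": self.anova_table.r2_adj,
            },
            "stationary_point": {
                "location_natural": [float(v) for v in sp.location_natural],
                "predicted_value": sp.predicted_value,
                "nature": sp.nature,
                "hessian_eigenvalues": [float(v) for v in sp.hessian_eigenvalues],
                "inside_design_hull": bool(self.fit.in_hull(sp.location_natural)),
            },
            "ga": {
                "best_genes": [float(v) for v in self.ga.best_genes],
                "best_fitness": self.ga.best_fitness,
                "generations_run": self.ga.generations_run,
                "termination_reason": self.ga.termination_reason,
            },
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_screening(screening) -> list[ScreeningRecord]:
    if isinstance(screening, (str, Path)):
        screening = pd.read_csv(screening)
    if isinstance(screening, pd.DataFrame):
        return [
            ScreeningRecord(
                source=str(row["source"]),
                role=str(row["role"]),
                cdw=float(row["cdw"]),
                pha=float(row["pha"]),
            )
            for _, row in screening.iterrows()
        ]
    return list(screening)


def _load_responses(responses, design: Design) -> np.ndarray:
    if isinstance(responses, (str, Path)):
        responses = pd.read_csv(responses)
    if isinstance(responses, pd.DataFrame):
        df = responses
        col = "response" if "response" in df.columns else df.columns[-1]
        if "run" in df.columns:
            order = {p.run_id: i for i, p in enumerate(design.points)}
            df = df.sort_values("run", key=lambda s: s.map(order))
        return df[col].to_numpy(dtype=float)
    return np.asarray(responses, dtype=float)


def run_full_analysis(
    screening,
    design,
    responses,
    ga_config: GAConfig | None = None,
    seed: int | None = 0,
    criterion: Criterion = "pha_mass",
    response_label: str = "response",
) -> ReportBundle:
    """Run screening ranking, quadratic fit, inference, stationary-point
    analysis and GA maximization of the fitted surface.

    Parameters
    ----------
    screening : CSV path, DataFrame (source, role, cdw, pha) or records
    design : Design or CSV path (with its JSON sidecar next to it)
    responses : CSV path, DataFrame or vector; joined to the design by run
        id when a ``run`` column is present
    ga_config : GAConfig, optional
        Defaults to the replication configuration over the design's natural
        box.
    seed : int
        Drives the GA; the rest of the pipeline is deterministic.
    criterion : {"pha_mass", "percent_conversion"}
        Screening ranking criterion.
    response_label : str
        Free-text name of the response column for the report.

    Returns
    -------
    ReportBundle
        Deterministic given identical inputs and seed.
    """
    stage = "screening"
    try:
        records = _load_screening(screening)
        ranking = rank_sources(records, criterion)

        stage = "design"
        if isinstance(design, (str, Path)):
            design = read_design(design)

        stage = "responses"
        y = _load_responses(responses, design)

        stage = "fit"
        fit = fit_quadratic(design, y)

        stage = "anova"
        an = anova(fit, y)

        stage = "coefficient_stats"
        coefs = coefficient_stats(fit)

        stage = "stationary_point"
        sp = stationary_point(fit)

        stage = "ga"
        if ga_config is None:
            ga_config = GAConfig(bounds=design.natural_box())
        ga_res = run_ga(fit.predict, ga_config, rng=seed, vectorized=True)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    from rsmga import __version__

    provenance = {
        "package": "rsmga",
        "version": __version__,
        "seed": seed,
        "criterion": criterion,
        "response_label": response_label,
        "n_runs": int(design.n_runs),
        "factors": [f.name for f in design.factors],
    }
    return ReportBundle(
        screening=ranking,
        fit=fit,
        anova_table=an,
        coefficients=coefs,
        stationary=sp,
        ga=ga_res,
        provenance=provenance,
    )
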