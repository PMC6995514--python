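"""Rank the screened carbon and nitrogen sources.

Loads the bundled one-factor-at-a-time screening table (cell dry weight and
PHA mass per candidate source), computes percent conversion, ranks the
sources within each role by PHA mass, and writes the ranked table.

Finding: watermelon rind is the best carbon source (12.97 g/L PHA, 78.61%
conversion) and pulse peel the best nitrogen source (13.5 g/L, 69.20%) by
PHA mass — note the percent-conversion criterion would instead favour
yeast extract among nitrogen sources (78.62%), so the criterion matters.
"""

from pathlib import Path

from rsmga import datasets
from rsmga.pipeline import ScreeningRecord, rank_sources

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = datasets.load_screening()
    records = [ScreeningRecord(r.source, r.role, r.cdw, r.pha) for r in df.itertuples()]

    for criterion in ("pha_mass", "percent_conversion"):
        ranking = rank_sources(records, criterion=criterion)
        table = ranking.to_frame()
        OUT.mkdir(exist_ok=True)
        path = OUT / f"screening_ranking_{criterion}.csv"
        table.to_csv(path, index=False)
        print(f"criterion = {criterion}:")
        for role in ("carbon", "nitrogen"):
            best = ranking.best[role]
            print(
                f"  best {role} source: {best.source} "
                f"(PHA {best.pha} g/L, conversion {best.percent_conversion:.2f}%)"
            )
        print(f"  wrote {path}")


if __name__ == "__main__":
    main()
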