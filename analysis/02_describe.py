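#!/usr/bin/env python
"""Descriptive stage: outcome distribution and category-wise death tables.

Two parts: (1) the published category counts packaged with this project,
whose percent columns are exact; (2) the same tables computed from the
synthetic dataset written by 01_simulate.py, with Pearson chi-square
association tests.
"""

from pathlib import Path

import pandas as pd

from mlcount.descriptives import (
    association_test,
    crosstab_from_data,
    percent_table,
    summarize_outcome,
)
from mlcount.simulate import fixture_tables

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    frames = [percent_table(t) for t in fixture_tables()]
    published = pd.concat(frames, ignore_index=True)
    published.to_csv(OUT / "published_percent_table.tsv", sep="\t",
                     index=False)
    print(f"published tables: {len(frames)} variables, "
          f"{len(published)} category rows -> published_percent_table.tsv")

    data_path = OUT / "synthetic_edhs.csv"
    if not data_path.exists():
        print("run 01_simulate.py first for the synthetic tables")
        return
    df = pd.read_csv(data_path)
    s = summarize_outcome(df["y"].to_numpy())
    print(f"synthetic outcome: {s.percent_zero:.1f}% zero, mean {s.mean:.3f},"
          f" variance {s.variance:.3f}")
    rows = []
    for var in ("vaccination", "birth_interval", "antenatal_visits",
                "child_twin", "contraceptive_use"):
        t = association_test(crosstab_from_data(df, var))
        f = percent_table(t)
        f["chi2"], f["df"], f["p"] = t.chi2, t.df, t.p_value
        rows.append(f)
        print(f"  {var}: X2={t.chi2:.1f} (df={t.df}, p={t.p_value:.2g})")
    pd.concat(rows, ignore_index=True).to_csv(
        OUT / "synthetic_percent_table.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
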