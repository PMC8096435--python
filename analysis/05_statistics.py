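"""Statistical comparisons of every mutant genotype against the wild type.

Welch's t on growth rates, Mann-Whitney U on 8-cell-stage durations and
N/C ratios, and the overall summary table with the p < 10⁻² significance
convention.
"""
from pathlib import Path

import pandas as pd

from embryopulse import stats

ROOT = Path(__file__).resolve().parents[1] / "results"


def _compare(df, value_col, test, label, rows):
    wt = df[df.genotype == "WT"][value_col].dropna()
    for genotype, sub in df.groupby("genotype"):
        if genotype == "WT":
            continue
        vals = sub[value_col].dropna()
        if len(vals) < 2 or len(wt) < 2:
            continue
        res = test(wt, vals)
        rows.append({"metric": label, "genotype": genotype,
                     "vs": "WT", "test": res.name,
                     "statistic": res.statistic, "p": res.p_value,
                     "significant": res.significant,
                     "n_wt": len(wt), "n": len(vals)})


def main() -> None:
    rows = []
    growth = pd.read_csv(ROOT / "growth_rates.csv")
    growth = growth[growth.passes_filter]
    _compare(growth, "rate_um2_min", stats.welch_t, "growth_rate", rows)

    timeline = pd.read_csv(ROOT / "timeline_summary.csv")
    _compare(timeline, "stage8_duration_h", stats.mann_whitney,
             "stage8_duration", rows)
    _compare(timeline, "final_cell_count", stats.mann_whitney,
             "final_cell_count", rows)

    cells = pd.read_csv(ROOT / "nc_ratios_per_cell.csv")
    outer = cells[cells.position_class == "outer"]
    _compare(outer, "nc_ratio", stats.mann_whitney, "nc_ratio_outer", rows)

    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "statistics.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
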