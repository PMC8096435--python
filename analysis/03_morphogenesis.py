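"""Long-timescale analysis: compaction, cleavage timing, lumen growth.

Consumes the cohort tables from 01_simulate_cohorts.py and writes the
per-genotype summaries: contact angles per stage, 8-cell-stage durations,
growth-rate fits with the 35 % control filter, and synchronised mean
growth curves.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from embryopulse import events, morphometrics, stats, synthetic

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORTS = ROOT / "cohorts"


def main() -> None:
    angles = pd.read_csv(COHORTS / "contact_angles.csv")
    summary = []
    for (genotype, tag), sub in angles.groupby(["genotype", "stage_tag"]):
        s = stats.group_summary(sub.angle_deg).iloc[0]
        summary.append({"genotype": genotype, "stage_tag": tag,
                        "n": int(s["n"]), "mean_deg": s["mean"],
                        "sem_deg": s["sem"]})
    pd.DataFrame(summary).to_csv(ROOT / "contact_angle_summary.csv",
                                 index=False)

    ev = pd.read_csv(COHORTS / "cleavage_events.csv")
    rows = []
    for (genotype, eid), sub in ev.groupby(["genotype", "embryo_id"]):
        tl = events.EmbryoTimeline(
            embryo_id=str(eid),
            events=[events.Event(r.time_h, r.type, int(r.cell_id))
                    for r in sub.itertuples()])
        rows.append({"genotype": genotype, "embryo_id": eid,
                     "stage8_duration_h": events.stage_duration(tl, 3, 4),
                     "lumen_time_h": events.lumen_time(tl),
                     "final_cell_count": events.final_cell_count(tl)})
    timeline = pd.DataFrame(rows)
    timeline.to_csv(ROOT / "timeline_summary.csv", index=False)

    areas = pd.read_csv(COHORTS / "projected_areas.csv")
    fits, curves = [], []
    for (genotype, eid), sub in areas.groupby(["genotype", "embryo_id"]):
        series = synthetic.AreaSeries(str(eid), sub.time_h.to_numpy(),
                                      sub.area_um2.to_numpy())
        fit = morphometrics.growth_rate(series, is_control=(genotype == "WT"))
        fits.append({"genotype": genotype, "embryo_id": eid,
                     "rate_um2_min": fit.rate_um2_min,
                     "fractional_increase": fit.fractional_increase,
                     "passes_filter": fit.passes_filter})
    fits = pd.DataFrame(fits)
    fits.to_csv(ROOT / "growth_rates.csv", index=False)
    for genotype, sub in areas.groupby("genotype"):
        series = [
            synthetic.AreaSeries(str(eid), g.time_h.to_numpy(),
                                 g.area_um2.to_numpy())
            for eid, g in sub.groupby("embryo_id")]
        curve = morphometrics.sync_and_average(series)
        curve.insert(0, "genotype", genotype)
        curves.append(curve)
    pd.concat(curves).to_csv(ROOT / "growth_curves.csv", index=False)

    for genotype, sub in timeline.groupby("genotype"):
        d = sub.stage8_duration_h.dropna()
        print(f"{genotype:>16}: 8-cell stage {d.mean():.1f} h, "
              f"cells {sub.final_cell_count.mean():.1f}, "
              f"growth {fits[fits.genotype == genotype].rate_um2_min.mean():.1f} um2/min")


if __name__ == "__main__":
    main()
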