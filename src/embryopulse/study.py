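"""End-to-end parameter-recovery workflows on synthetic cohorts.

Each function generates a seeded synthetic cohort at the published sample
size for a genotype, runs the corresponding pipeline stage on it, and
returns the recovered cohort statistic. These are the workhorses of the
reproduction study driven by ``analysis/`` and ``scripts/acceptance.py``.
"""
from __future__ import annotations

import numpy as np

from . import events, synthetic

#: published cohort means and SEMs the recovery workflows aim at
PUBLISHED = {
    "wt_pre4th_angle_deg": (147.0, 2.0, 23),
    "wt_stage8_duration_h": (7.0, 0.3, 23),
    "myh9_stage8_duration_h": (9.8, 0.5, 15),
    "myh9_pre4th_angle_deg": (125.0, 4.0, 15),
    "double_plateau_angle_deg": (117.0, 4.0, 3),
    "double_final_cell_count": (2.9, 0.5, 8),
}


def _subseed(seed: int, index: int) -> int:
    """Independent child seed, kept below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]
               % (2 ** 31))


def mean_pre_fourth_angle(preset_name: str, n: int, seed: int) -> float:
    """Cohort mean of the contact angle just before the fourth cleavage."""
    preset = synthetic.get_preset(preset_name)
    series = synthetic.make_angle_series(preset, n, seed=seed)
    idx = series[0].stage_tags.index("pre-4th")
    return float(np.mean([s.angles_deg[idx] for s in series]))


def mean_plateau_angle(preset_name: str, n: int, seed: int) -> float:
    """Cohort mean of each embryo's maximal (plateau) contact angle."""
    preset = synthetic.get_preset(preset_name)
    series = synthetic.make_angle_series(preset, n, seed=seed)
    return float(np.mean([s.angles_deg.max() for s in series]))


def mean_stage8_duration(preset_name: str, n: int, seed: int) -> float:
    """Cohort mean 8-cell-stage duration (last 3rd-wave to first 4th-wave
    cleavage) from synthetic timelines; embryos whose fourth wave was never
    observed are excluded, as in the annotation protocol."""
    preset = synthetic.get_preset(preset_name)
    timelines = synthetic.make_timeline(preset, n, seed=seed)
    durations = [events.stage_duration(tl, 3, 4) for tl in timelines]
    durations = [d for d in durations if np.isfinite(d)]
    if not durations:
        raise ValueError("no embryo completed both waves")
    return float(np.mean(durations))


def mean_final_cell_count(preset_name: str, n: int, seed: int) -> float:
    """Cohort mean blastocyst-stage cell count under the division-failure
    model (five cleavage waves)."""
    preset = synthetic.get_preset(preset_name)
    timelines = synthetic.make_timeline(preset, n, seed=seed)
    return float(np.mean([events.final_cell_count(tl) for tl in timelines]))


def recover_targets(seed: int) -> dict[str, dict[str, float]]:
    """Recompute every published target from freshly generated cohorts."""
    s = [_subseed(seed, i) for i in range(6)]
    return {
        "t2": {"value": mean_pre_fourth_angle("WT", 23, s[0]), "n": 23},
        "t3": {"value": mean_stage8_duration("WT", 23, s[1]), "n": 23},
        "t4": {"value": mean_stage8_duration("mzMyh9", 15, s[2]), "n": 15},
        "t5": {"value": mean_pre_fourth_angle("mzMyh9", 15, s[3]), "n": 15},
        "t6": {"value": mean_plateau_angle("mzMyh9;mzMyh10", 3, s[4]),
               "n": 3},
        "t8": {"value": mean_final_cell_count("mzMyh9;mzMyh10", 8, s[5]),
               "n": 8},
    }
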