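"""Pipeline orchestration: generate → piv → spectral → morpho → events → stats.

``run_pipeline`` executes the synthetic study for the configured genotype
presets and writes per-stage tidy CSVs plus a JSON manifest (seed, config
hash) to the output directory. Deterministic given the seed.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import events, morphometrics, piv, spectral, synthetic
from .config import RunConfig
from .stats import group_summary


def _subseed(seed: int, *idx: int) -> int:
    return int(np.random.SeedSequence([seed, *idx]).generate_state(1)[0]
               % (2 ** 31))


def analyze_movie(movie, config: RunConfig, embryo_id: str = ""):
    """PIV + spectrum + oscillation call for one movie."""
    field = piv.piv_two_pass(movie, config.window_pass1_um,
                             config.window_pass2_um, config.overlap)
    masks = piv.mask_embryo(movie)
    keep = piv.vectors_in_mask(field, masks)
    spec = spectral.embryo_spectrum(field, keep=keep, embryo_id=embryo_id)
    call = spectral.call_oscillation(
        spec, band=(config.band_low_s, config.band_high_s),
        threshold=config.oscillation_threshold)
    return field, spec, call


def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] = ("movies", "angles", "timelines",
                                            "areas")) -> dict:
    """Run the synthetic study and write per-stage CSVs and a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = {name: synthetic.get_preset(name) for name in config.presets}
    manifest: dict = {"seed": config.seed, "config_hash": config.digest(),
                      "stages": list(stages), "outputs": []}

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    if "movies" in stages:
        calls = []
        for g, preset in presets.items():
            for i in range(config.n_movies):
                rng = np.random.default_rng(_subseed(config.seed, 0, i))
                oscillates = rng.uniform() < preset.oscillating_fraction
                spec = synthetic.SyntheticMovieSpec(
                    pixel_size=config.pixel_size_um,
                    frame_interval=config.frame_interval_s,
                    n_frames=config.movie_n_frames,
                    oscillation_period=80.0 if oscillates else 0.0,
                    seed=_subseed(config.seed, 1, i),
                )
                movie, _ = synthetic.make_movie(spec)
                _, _, call = analyze_movie(movie, config,
                                           embryo_id=f"{g}_{i:03d}")
                calls.append(call)
        save(spectral.calls_to_frame(calls), "oscillation_calls.csv")

    if "angles" in stages:
        frames = []
        for gi, (g, preset) in enumerate(presets.items()):
            series = synthetic.make_angle_series(
                preset, config.n_angle, seed=_subseed(config.seed, 2, gi))
            df = synthetic.angle_series_to_frame(series)
            df.insert(0, "genotype", g)
            frames.append(df)
        angles = pd.concat(frames, ignore_index=True)
        save(angles, "contact_angles.csv")
        pre4 = angles[angles.stage_tag == "pre-4th"]
        save(group_summary(pre4.angle_deg, pre4.genotype),
             "contact_angle_summary.csv")

    if "timelines" in stages:
        frames, summaries = [], []
        for gi, (g, preset) in enumerate(presets.items()):
            tls = synthetic.make_timeline(
                preset, config.n_timeline, seed=_subseed(config.seed, 3, gi))
            ev = pd.concat([tl.to_frame() for tl in tls], ignore_index=True)
            ev.insert(0, "genotype", g)
            frames.append(ev)
            summ = events.summarize_timelines(tls)
            summ.insert(0, "genotype", g)
            summaries.append(summ)
        save(pd.concat(frames, ignore_index=True), "cleavage_events.csv")
        save(pd.concat(summaries, ignore_index=True), "timeline_summary.csv")

    if "areas" in stages:
        rows = []
        for gi, (g, preset) in enumerate(presets.items()):
            series = synthetic.make_area_series(
                preset, config.n_area, seed=_subseed(config.seed, 4, gi))
            for s in series:
                fit = morphometrics.growth_rate(
                    s, config.growth_window_h, config.min_growth_fraction,
                    is_control=(g == "WT"))
                rows.append({"genotype": g, "embryo_id": s.embryo_id,
                             "rate_um2_min": fit.rate_um2_min,
                             "fractional_increase": fit.fractional_increase,
                             "passes_filter": fit.passes_filter})
        save(pd.DataFrame(rows), "growth_rates.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
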