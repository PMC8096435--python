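"""Immunostain and reporter quantification.

Fate-marker levels are read out as nuclear-to-cytoplasmic (N/C) intensity
ratios from small circular ROIs (3.7 µm², the equatorial nuclear plane and
an adjacent cytoplasmic spot). Cells are classified inner/outer by contact
with the outside medium, sampled 5+5+5 across ICM / polar TE / mural TE,
apico-basal polarity is profiled along a 15 µm line from the cell-medium
interface, reporter intensity is a background-subtracted 50-µm-circle mean,
and qPCR CT tables are reduced with the 2^(−ΔCT) method.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import profile_line

NC_ROI_AREA_UM2 = 3.7
LINE_LENGTH_UM = 15.0
LINE_THICKNESS_UM = 0.4


@dataclass
class CellRecord:
    embryo_id: str
    cell_id: int
    position_class: str          # inner | outer
    lineage_class: str           # ICM | polar-TE | mural-TE
    nuclear_intensity: float
    cytoplasm_intensity: float
    excluded: bool = False       # mitotic/apoptotic cells leave summaries

    @property
    def nc_ratio(self) -> float:
        if self.cytoplasm_intensity <= 0:
            raise ValueError("N/C ratio undefined for non-positive cytoplasm")
        return self.nuclear_intensity / self.cytoplasm_intensity


def _circle_mean(image: np.ndarray, center: tuple[float, float],
                 radius_px: float) -> float:
    h, w = image.shape
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("ROI center outside the image")
    if cy - radius_px < -0.5 or cy + radius_px > h - 0.5 or \
            cx - radius_px < -0.5 or cx + radius_px > w - 0.5:
        raise ValueError("ROI extends beyond the image")
    yy, xx = np.ogrid[:h, :w]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    if not mask.any():
        raise ValueError("ROI covers no pixel")
    return float(image[mask].mean())


def nc_ratio(image: np.ndarray, nucleus_center: tuple[float, float],
             cytoplasm_center: tuple[float, float], pixel_size: float,
             roi_area_um2: float = NC_ROI_AREA_UM2) -> float:
    """Nuclear / cytoplasmic mean intensity in circular ROIs of equal area.

    The ROI radius follows from the area (3.7 µm² → ≈1.085 µm). Centers are
    (row, col) pixel coordinates. Scaling the image by a positive constant
    leaves the ratio unchanged; additive offsets do not.
    """
    radius_px = np.sqrt(roi_area_um2 / np.pi) / pixel_size
    nuc = _circle_mean(image, nucleus_center, radius_px)
    cyt = _circle_mean(image, cytoplasm_center, radius_px)
    if cyt <= 0:
        raise ValueError("zero cytoplasmic signal: N/C ratio undefined")
    return nuc / cyt


def measure_cells(image: np.ndarray, rois: pd.DataFrame, pixel_size: float,
                  embryo_id: str = "") -> list[CellRecord]:
    """Apply :func:`nc_ratio` ROIs from a generator/annotation table."""
    records = []
    for row in rois.itertuples():
        nuc_c = (row.nucleus_y, row.nucleus_x)
        cyt_c = (row.cytoplasm_y, row.cytoplasm_x)
        radius_px = np.sqrt(NC_ROI_AREA_UM2 / np.pi) / pixel_size
        records.append(
            CellRecord(
                embryo_id=embryo_id,
                cell_id=int(row.cell_id),
                position_class=getattr(row, "position_true", ""),
                lineage_class=getattr(row, "lineage_true", ""),
                nuclear_intensity=_circle_mean(image, nuc_c, radius_px),
                cytoplasm_intensity=_circle_mean(image, cyt_c, radius_px),
            )
        )
    return records


def sample_cells(cells: pd.DataFrame, per_class: int = 5,
                 seed: int = 0) -> pd.DataFrame:
    """Select 5 ICM + 5 polar TE + 5 mural TE cells per embryo.

    An ICM shortfall is topped up with additional TE cells; embryos with
    fewer than 15 cells are measured in full. ``cells`` needs a
    ``lineage_class`` column.
    """
    total = 3 * per_class
    if len(cells) <= total:
        return cells.copy()
    rng = np.random.default_rng(seed)

    def pick(frame: pd.DataFrame, k: int) -> pd.DataFrame:
        if len(frame) <= k:
            return frame
        idx = rng.choice(len(frame), size=k, replace=False)
        return frame.iloc[np.sort(idx)]

    icm = cells[cells.lineage_class == "ICM"]
    polar = cells[cells.lineage_class == "polar-TE"]
    mural = cells[cells.lineage_class == "mural-TE"]
    chosen = [pick(icm, per_class)]
    shortfall = per_class - len(chosen[0])
    te_quota = 2 * per_class + shortfall
    te_pool = pd.concat([polar, mural])
    # draw polar and mural evenly, then fill the remainder from either
    chosen.append(pick(polar, min(per_class, len(polar))))
    chosen.append(pick(mural, min(per_class, len(mural))))
    selected = pd.concat(chosen)
    remainder = te_quota - (len(selected) - len(chosen[0]))
    if remainder > 0:
        rest = te_pool.loc[~te_pool.index.isin(selected.index)]
        selected = pd.concat([selected, pick(rest, remainder)])
    return selected.sort_index()


def classify_inner_outer(cell_labels: np.ndarray,
                         embryo_mask: np.ndarray) -> pd.DataFrame:
    """Outer cells touch the outside medium; inner cells do not.

    ``cell_labels`` is a label image (0 = medium) consistent with
    ``embryo_mask``. A cell is outer iff it owns pixels on the embryo's
    exterior boundary (the outermost in-mask pixel layer).
    """
    from scipy.ndimage import binary_erosion

    if cell_labels.shape != embryo_mask.shape:
        raise ValueError("label image and mask must have the same shape")
    if not embryo_mask.any():
        raise ValueError("empty embryo mask")
    boundary = embryo_mask & ~binary_erosion(embryo_mask)
    outer_ids = np.unique(cell_labels[boundary])
    outer_ids = set(int(i) for i in outer_ids if i != 0)
    ids = [int(i) for i in np.unique(cell_labels) if i != 0]
    return pd.DataFrame(
        {
            "cell_id": ids,
            "position_class": ["outer" if i in outer_ids else "inner"
                               for i in ids],
        }
    )


def proportion_inner(classes: pd.DataFrame) -> float:
    return float((classes.position_class == "inner").mean())


def line_profile(image: np.ndarray, start: tuple[float, float],
                 direction: tuple[float, float], pixel_size: float,
                 length_um: float = LINE_LENGTH_UM,
                 thickness_um: float = LINE_THICKNESS_UM) -> pd.DataFrame:
    """Min-max-normalised intensity profile along a line from the surface.

    Intensity is averaged across the line thickness and sampled per pixel
    along the length. A constant image has no dynamic range; the profile is
    then returned as all zeros (flagged via the ``degenerate`` attribute).
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    end = np.asarray(start, dtype=float) + d * (length_um / pixel_size)
    h, w = image.shape
    if not (0 <= end[0] <= h - 1 and 0 <= end[1] <= w - 1):
        raise ValueError("profile line leaves the image")
    linewidth = max(int(round(thickness_um / pixel_size)), 1)
    prof = profile_line(image, start, tuple(end), linewidth=linewidth,
                        mode="reflect", reduce_func=np.mean)
    distances = np.linspace(0.0, length_um, prof.size)
    lo, hi = prof.min(), prof.max()
    degenerate = hi - lo < 1e-12
    normed = np.zeros_like(prof) if degenerate else (prof - lo) / (hi - lo)
    out = pd.DataFrame({"distance_um": distances,
                        "normalized_intensity": normed})
    out.attrs["degenerate"] = bool(degenerate)
    return out


def reporter_intensity(sum_projection: np.ndarray,
                       embryo_center: tuple[float, float],
                       bg_center: tuple[float, float], pixel_size: float,
                       radius_um: float = 50.0,
                       bg_radius_um: float = 5.0) -> float:
    """Background-subtracted mean reporter intensity of one embryo.

    Mean gray value in a 50-µm circle over the sum projection, minus the
    mean in a 5-µm background circle.
    """
    emb = _circle_mean(sum_projection, embryo_center, radius_um / pixel_size)
    bg = _circle_mean(sum_projection, bg_center, bg_radius_um / pixel_size)
    return emb - bg


def normalize_to_stage(values: pd.Series, stages: pd.Series,
                       reference_stage: str = "zygote") -> pd.Series:
    """Normalise corrected intensities so the reference-stage mean is 1."""
    ref = values[stages == reference_stage]
    if len(ref) == 0:
        raise ValueError(f"no embryos at reference stage {reference_stage!r}")
    return values / ref.mean()


def relative_expression(ct_target, ct_housekeeping,
                        reference: float = 1.0) -> float:
    """2^(−ΔCT) relative expression, scaled to a reference condition.

    Replicate wells are averaged on the CT scale before the exponential
    transform; ``reference`` is the normalised value of the calibrator
    condition (e.g. the reference gene at the zygote stage).
    """
    ct_t = float(np.mean(np.asarray(ct_target, dtype=float)))
    ct_h = float(np.mean(np.asarray(ct_housekeeping, dtype=float)))
    if not (np.isfinite(ct_t) and np.isfinite(ct_h)):
        raise ValueError("CT values must be finite")
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 2.0 ** (-(ct_t - ct_h)) / reference


def expression_table(ct: pd.DataFrame, housekeeping: str = "Gapdh",
                     calibrator: tuple[str, str] | None = None
                     ) -> pd.DataFrame:
    """Fold changes from a tidy CT table (sample, gene, ct, replicate).

    Replicate wells are averaged on the CT scale per (sample, gene), each
    gene is normalised to the housekeeping gene of its sample, and all
    values are scaled so the ``calibrator`` (sample, gene) pair maps to 1.
    """
    mean_ct = ct.groupby(["sample", "gene"], sort=False).ct.mean()
    rows = []
    for (sample, gene), ct_t in mean_ct.items():
        if gene == housekeeping:
            continue
        try:
            ct_h = mean_ct[(sample, housekeeping)]
        except KeyError:
            raise ValueError(
                f"sample {sample!r} lacks the housekeeping gene") from None
        rows.append({"sample": sample, "gene": gene,
                     "fold_change": relative_expression(ct_t, ct_h)})
    out = pd.DataFrame(rows)
    if calibrator is not None:
        sample, gene = calibrator
        ref = out.loc[(out["sample"] == sample) & (out.gene == gene),
                      "fold_change"]
        if ref.empty or ref.iloc[0] <= 0:
            raise ValueError("calibrator condition missing from the table")
        out["fold_change"] = out.fold_change / ref.iloc[0]
    return out
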