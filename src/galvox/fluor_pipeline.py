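"""Quantification of hypoxia-dye time-lapse stacks and group statistics.

The measurement chain mirrors the standard confocal workflow for an
irreversible, intensity-integrating hypoxia reporter:

1. each time point is a z-stack; it is collapsed by pixelwise
   summation over z,
2. cells are defined by a labelled mask image (masks are an input;
   segmentation is out of scope),
3. the mean masked intensity per cell is normalised by its value at
   the challenge-onset frame,
4. the rate of fluorescence change is the ordinary least-squares slope
   of normalised intensity against time in minutes,
5. groups of per-cell rates are compared with a paired t-test (same
   cells, pre-challenge window vs challenge window) and an F-test on
   the variance ratio.

Intensities are arbitrary units throughout; normalisation makes every
downstream statistic invariant to a global intensity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: labelled regions smaller than this are excluded as degenerate
MIN_MASK_PIXELS = 20


@dataclass
class TimelapseStack:
    """Time-lapse of z-stacks: ``frames[t]`` has shape (nz, ny, nx)."""

    frames: np.ndarray  # (nt, nz, ny, nx)
    frame_times: np.ndarray  # s, strictly increasing
    pixel_size: float = 0.76e-6  # m
    z_step: float = 0.84e-6  # m

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be (time, z, y, x)")
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValueError("frame_times length must match the frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")


@dataclass
class CellMaskSet:
    """Integer label image: 0 = background, 1..n = cells."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D image")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def areas(self) -> dict[int, int]:
        return {
            int(lbl): int(np.sum(self.labels == lbl)) for lbl in self.label_ids
        }


@dataclass
class FluorescenceTrack:
    """Mean intensity of one cell over time, raw and onset-normalised."""

    cell_id: int
    times: np.ndarray  # s, measured from challenge onset
    mean_intensity: np.ndarray  # a.u.
    normalized: np.ndarray  # dimensionless, 1.0 at onset
    area: int  # pixels

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.mean_intensity) == len(self.normalized)):
            raise ValueError("track arrays must have equal length")


@dataclass
class RateSummary:
    """Group summary of per-cell fluorescence rates (min^-1)."""

    label: str
    rates: np.ndarray
    mean: float
    sd: float
    variance: float
    n: int


def sum_project(stack: np.ndarray) -> np.ndarray:
    """Collapse a z-stack (nz, ny, nx) to one image by pixelwise summation."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    if stack.shape[0] == 0:
        raise ValueError("empty stack")
    return stack.sum(axis=0)


def mean_masked_intensity(image: np.ndarray, masks: CellMaskSet, label: int) -> float:
    """Arithmetic mean of the image over the pixels carrying ``label``."""
    image = np.asarray(image)
    if image.shape != masks.labels.shape:
        raise ValueError("image and mask shapes differ")
    region = masks.labels == label
    if not region.any():
        raise ValueError(f"label {label} has no pixels")
    return float(image[region].mean())


def extract_tracks(
    timelapse: TimelapseStack,
    masks: CellMaskSet,
    onset_index: int = 0,
    min_pixels: int = MIN_MASK_PIXELS,
) -> list[FluorescenceTrack]:
    """Per-cell normalised intensity tracks from an image time-lapse.

    The whole track is divided by the mean intensity at the
    challenge-onset frame, so ``normalized[onset_index] == 1``.  Cells
    whose onset intensity is not positive, or whose mask is smaller
    than ``min_pixels``, are excluded with a logged warning.
    """
    nt = timelapse.frames.shape[0]
    if not 0 <= onset_index < nt:
        raise ValueError("onset_index out of range")
    projected = np.stack([sum_project(f) for f in timelapse.frames])
    if projected.shape[1:] != masks.labels.shape:
        raise ValueError("mask shape does not match the images")
    tracks = []
    areas = masks.areas
    for lbl in masks.label_ids:
        area = areas[int(lbl)]
        if area < min_pixels:
            logger.warning("cell %d excluded: mask has %d px (< %d)",
                           lbl, area, min_pixels)
            continue
        region = masks.labels == lbl
        means = projected[:, region].mean(axis=1)
        onset = means[onset_index]
        if onset <= 0:
            logger.warning("cell %d excluded: onset-frame intensity %g <= 0",
                           lbl, onset)
            continue
        tracks.append(FluorescenceTrack(
            cell_id=int(lbl),
            times=timelapse.frame_times - timelapse.frame_times[onset_index],
            mean_intensity=means,
            normalized=means / onset,
            area=area,
        ))
    return tracks


def fluorescence_rate(
    track: FluorescenceTrack,
    window: tuple[float, float] | None = None,
) -> float:
    """OLS slope of normalised intensity vs time in minutes (min^-1).

    ``window`` restricts the fit to ``window[0] <= t_s <= window[1]``
    (seconds, onset-relative); at least three points are required.
    """
    t = track.times
    y = track.normalized
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 points for a rate fit")
    res = stats.linregress(t / 60.0, y)
    return float(res.slope)


def paired_t_test(control: np.ndarray, challenged: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on per-cell rate differences (two-sided).

    Both groups are the same cells, so the test acts on the n
    differences with n-1 degrees of freedom.
    """
    control = np.asarray(control, dtype=float)
    challenged = np.asarray(challenged, dtype=float)
    if control.shape != challenged.shape or control.ndim != 1:
        raise ValueError("groups must be equal-length 1D arrays")
    if len(control) < 2:
        raise ValueError("need at least two pairs")
    diff = challenged - control
    if diff.std(ddof=1) == 0.0:
        if np.all(diff == 0.0):
            return 0.0, 1.0  # identical pairs: no effect, by convention
        raise ValueError("zero variance of the paired differences")
    t, p = stats.ttest_rel(challenged, control)
    return float(t), float(p)


def variance_ratio_test(
    control: np.ndarray, challenged: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """F-test on the two group variances (larger over smaller, upper tail).

    Returns ``(F, F_critical, reject)`` with the critical value at
    ``alpha`` and (n_num - 1, n_den - 1) degrees of freedom; the null
    of equal variances is rejected iff F > F_critical.
    """
    control = np.asarray(control, dtype=float)
    challenged = np.asarray(challenged, dtype=float)
    if len(control) < 2 or len(challenged) < 2:
        raise ValueError("both groups need n >= 2")
    v_c = control.var(ddof=1)
    v_x = challenged.var(ddof=1)
    if v_x >= v_c:
        num_v, num_n, den_v, den_n = v_x, len(challenged), v_c, len(control)
    else:
        num_v, num_n, den_v, den_n = v_c, len(control), v_x, len(challenged)
    if den_v == 0:
        raise ValueError("zero variance in the denominator group")
    F = num_v / den_v
    F_crit = float(stats.f.ppf(1.0 - alpha, num_n - 1, den_n - 1))
    return float(F), F_crit, bool(F > F_crit)


def area_rate_correlation(
    areas: np.ndarray, rates: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between cell area and fluorescence rate.

    Cell area is a proxy for intracellular dye amount; absence of
    correlation indicates the rate spread is not a dye-loading
    artefact.
    """
    areas = np.asarray(areas, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if areas.shape != rates.shape or len(areas) < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    if np.allclose(areas.std(), 0) or np.allclose(rates.std(), 0):
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(areas, rates)
    return float(r), float(p)


def summarize_rates(rates: np.ndarray, label: str = "") -> RateSummary:
    """Mean, sample SD (n-1 denominator), variance and n of a rate group."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("need n >= 2 rates")
    sd = float(rates.std(ddof=1))
    return RateSummary(
        label=label,
        rates=rates,
        mean=float(rates.mean()),
        sd=sd,
        variance=sd**2,
        n=len(rates),
    )


# ---------------------------------------------------------------------------
# tabular I/O


def tracks_from_table(table: pd.DataFrame, onset_time: float = 0.0) -> list[FluorescenceTrack]:
    """Build tracks from a tidy table (cell_id, time_s, mean_intensity, area_px).

    Normalisation uses the frame at ``onset_time`` (which must exist
    for every cell).
    """
    required = {"cell_id", "time_s", "mean_intensity"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    tracks = []
    for cell_id, grp in table.groupby("cell_id"):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        y = grp["mean_intensity"].to_numpy(dtype=float)
        at_onset = np.isclose(t, onset_time)
        if not at_onset.any():
            raise ValueError(f"cell {cell_id} has no frame at onset {onset_time}")
        onset = float(y[at_onset][0])
        if onset <= 0:
            logger.warning("cell %s excluded: onset intensity %g <= 0", cell_id, onset)
            continue
        area = int(grp["area_px"].iloc[0]) if "area_px" in grp.columns else 0
        tracks.append(FluorescenceTrack(
            cell_id=int(cell_id), times=t - onset_time,
            mean_intensity=y, normalized=y / onset, area=area,
        ))
    return tracks


def tracks_to_table(tracks: list[FluorescenceTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for t, raw, norm in zip(tr.times, tr.mean_intensity, tr.normalized):
            rows.append({
                "cell_id": tr.cell_id, "time_s": t,
                "mean_intensity": raw, "normalized": norm, "area_px": tr.area,
            })
    return pd.DataFrame(rows)


def analyze_experiment(
    control_tracks: list[FluorescenceTrack],
    challenged_tracks: list[FluorescenceTrack],
    alpha: float = 0.05,
) -> dict:
    """Full statistical report for a paired control/challenge experiment."""
    ctrl_ids = {t.cell_id for t in control_tracks}
    chal_ids = {t.cell_id for t in challenged_tracks}
    common = sorted(ctrl_ids & chal_ids)
    ctrl = {t.cell_id: t for t in control_tracks}
    chal = {t.cell_id: t for t in challenged_tracks}
    control_rates = np.array([fluorescence_rate(ctrl[i]) for i in common])
    challenged_rates = np.array([fluorescence_rate(chal[i]) for i in common])
    t_stat, p = paired_t_test(control_rates, challenged_rates)
    F, F_crit, reject = variance_ratio_test(control_rates, challenged_rates, alpha)
    report = {
        "n": len(common),
        "control": summarize_rates(control_rates, "control"),
        "challenged": summarize_rates(challenged_rates, "challenged"),
        "paired_t": {"t": t_stat, "p": p},
        "f_test": {"F": F, "F_critical": F_crit, "reject": reject},
    }
    areas = np.array([chal[i].area for i in common], dtype=float)
    if len(common) >= 3 and areas.std() > 0 and challenged_rates.std() > 0:
        r, pr = area_rate_correlation(areas, challenged_rates)
        report["area_correlation"] = {"r": r, "p": pr}
    return report
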