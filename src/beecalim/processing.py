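"""Movie-to-map signal processing.

The pipeline order is fixed: dF/F against a pre-stimulus baseline, then
illumination/bleaching correction by per-frame median subtraction, then
spatial Gaussian filtering, then biphasic amplitude extraction.  All
dF/F values are in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import Cohort
from .types import (
    AmplitudeTable,
    DffMovie,
    Mask,
    Movie,
    ResponseMap,
    TimeCourse,
    ValidationError,
    frames_to_slice,
    replace,
)


def compute_dff(
    movie: Movie, baseline_frames: tuple[int, int] = (9, 11)
) -> DffMovie:
    """Relative fluorescence change, 100 * (F - F0) / F0, per pixel.

    F0 is each pixel's mean over the baseline frames (1-based inclusive,
    default 9-11: the 3 frames just before stimulus onset at frame 15).
    """
    lo, hi = baseline_frames
    if hi >= movie.stimulus_onset_frame:
        raise ValidationError(
            f"baseline {lo}..{hi} must end before stimulus onset "
            f"(frame {movie.stimulus_onset_frame})"
        )
    pixels = movie.pixels.astype(float)
    f0 = pixels[:, :, frames_to_slice(lo, hi)].mean(axis=2)
    n_bad = int((f0 <= 0).sum())
    if n_bad:
        raise ValidationError(
            f"{n_bad} pixels have nonpositive baseline F0; dF/F is undefined"
        )
    values = 100.0 * (pixels - f0[:, :, None]) / f0[:, :, None]
    return DffMovie(
        values,
        baseline_frames=baseline_frames,
        frame_rate=movie.frame_rate,
        stimulus_onset_frame=movie.stimulus_onset_frame,
        structure_label=movie.structure_label,
        bee_id=movie.bee_id,
        stimulus_id=movie.stimulus_id,
        presentation_index=movie.presentation_index,
    )


def correct_illumination(dff: DffMovie) -> DffMovie:
    """Remove frame-wide offsets (lamp irregularities, bleaching trend).

    Subtracts the median pixel value of each frame from every pixel of
    that frame; the correction uses the full frame, not the mask.
    """
    if "illumination_corrected" in dff.processing_flags:
        warnings.warn(
            "illumination correction applied twice; the second pass is a no-op "
            "by construction but usually indicates pipeline misuse",
            stacklevel=2,
        )
    medians = np.median(dff.values.reshape(-1, dff.n_frames), axis=0)
    out = replace(dff, values=dff.values - medians)
    out.processing_flags = set(dff.processing_flags) | {"illumination_corrected"}
    return out


def default_filter_window(structure: str) -> int:
    """Structure-specific Gaussian window: 7 px for AL (and whole-brain
    overviews), 3 px for the smaller LH/MB fields of view."""
    return 3 if structure in ("LH", "MB") else 7


def spatial_filter_frame(frame: np.ndarray, window: int) -> np.ndarray:
    """Filter one frame with a normalized truncated Gaussian.

    sigma = (window - 1) / 4 so the window spans +/-2 sigma; reflecting
    boundaries avoid edge darkening inside masks near image borders.
    """
    if window % 2 == 0 or window < 1:
        raise ValidationError(f"filter window must be odd and >= 1, got {window}")
    if window == 1:
        return frame.copy()
    sigma = (window - 1) / 4.0
    radius = (window - 1) // 2
    return ndimage.gaussian_filter(
        frame, sigma=sigma, mode="reflect", radius=radius
    )


def spatial_filter(dff: DffMovie, window: int | None = None) -> DffMovie:
    """Gaussian-filter the two spatial dimensions of every frame."""
    if window is None:
        window = default_filter_window(dff.structure_label)
    if window % 2 == 0 or window < 1:
        raise ValidationError(f"filter window must be odd and >= 1, got {window}")
    if window == 1:
        out = replace(dff, values=dff.values.copy())
    else:
        sigma = (window - 1) / 4.0
        radius = (window - 1) // 2
        out = replace(
            dff,
            values=ndimage.gaussian_filter(
                dff.values,
                sigma=(sigma, sigma, 0.0),
                mode="reflect",
                radius=(radius, radius, 0),
            ),
        )
    out.processing_flags = set(dff.processing_flags) | {"filtered"}
    return out


def amplitude_map(
    dff: DffMovie,
    mask: Mask,
    positive_frames: tuple[int, int] = (19, 21),
    negative_frames: tuple[int, int] = (49, 51),
) -> ResponseMap:
    """Biphasic response amplitude per pixel.

    Mean dF/F over the positive window (end of odor presentation) minus
    mean over the negative window (the undershoot), giving a
    high-contrast measure that uses both lobes of the biphasic signal.
    """
    if mask.shape != dff.spatial_shape:
        raise ValidationError("mask shape does not match the movie")
    p_lo, p_hi = positive_frames
    n_lo, n_hi = negative_frames
    for lo, hi in (positive_frames, negative_frames):
        if hi > dff.n_frames:
            raise ValidationError(f"frame window {lo}..{hi} exceeds the movie")
    if p_hi >= n_lo and n_hi >= p_lo:
        raise ValidationError("positive and negative windows overlap")
    if p_lo <= dff.stimulus_onset_frame:
        raise ValidationError("positive window must start after stimulus onset")
    pos = dff.values[:, :, frames_to_slice(p_lo, p_hi)].mean(axis=2)
    neg = dff.values[:, :, frames_to_slice(n_lo, n_hi)].mean(axis=2)
    return ResponseMap(
        pos - neg,
        mask=mask,
        bee_id=dff.bee_id,
        stimulus_id=dff.stimulus_id,
        presentation_index=dff.presentation_index,
    )


def response_intensity(response: ResponseMap) -> float:
    """Mean amplitude over all in-mask pixels (dF/F %)."""
    return float(response.valid_values.mean())


def region_time_course(dff: DffMovie, region) -> TimeCourse:
    """Per-frame mean dF/F over a region (a Mask or a 0-based
    ``(top, left, height, width)`` rectangle)."""
    if isinstance(region, Mask):
        if region.shape != dff.spatial_shape:
            raise ValidationError("region mask shape does not match the movie")
        sel = dff.values[region.include]
        label = region.label or "mask"
    else:
        top, left, height, width = region
        h, w = dff.spatial_shape
        if (
            top < 0
            or left < 0
            or height < 1
            or width < 1
            or top + height > h
            or left + width > w
        ):
            raise ValidationError(f"rectangle {region} outside the {h}x{w} image")
        sel = dff.values[top : top + height, left : left + width].reshape(
            -1, dff.n_frames
        )
        label = f"rect({top},{left},{height},{width})"
    return TimeCourse(
        sel.mean(axis=0),
        frame_rate=dff.frame_rate,
        region=label,
        bee_id=dff.bee_id,
        stimulus_id=dff.stimulus_id,
    )


def average_presentations(maps: list[ResponseMap]) -> ResponseMap:
    """Pixel-wise mean map over the presentations of one stimulus."""
    if not maps:
        raise ValidationError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.amplitude.shape != first.amplitude.shape or not np.array_equal(
            m.mask.include, first.mask.include
        ):
            raise ValidationError("maps to average have mismatched shapes/masks")
        if (m.bee_id, m.stimulus_id) != (first.bee_id, first.stimulus_id):
            raise ValidationError("maps to average belong to different recordings")
    mean = np.mean([m.amplitude for m in maps], axis=0)
    return ResponseMap(
        mean,
        mask=first.mask,
        bee_id=first.bee_id,
        stimulus_id=first.stimulus_id,
        presentation_index=None,
    )


@dataclass(frozen=True)
class ProcessingConfig:
    baseline_frames: tuple[int, int] = (9, 11)
    positive_frames: tuple[int, int] = (19, 21)
    negative_frames: tuple[int, int] = (49, 51)
    filter_window: int | None = None  # None: choose from the structure label
    apply_filter: bool = True


def process_recording(
    movie: Movie, mask: Mask, config: ProcessingConfig = ProcessingConfig()
) -> tuple[ResponseMap, TimeCourse]:
    """Full single-recording pipeline, in the canonical order:
    dF/F -> illumination correction -> spatial filter -> amplitude map.

    Returns the response map and the whole-mask time course.
    """
    try:
        dff = compute_dff(movie, config.baseline_frames)
    except ValidationError as exc:
        raise ValidationError(f"compute_dff: {exc}") from exc
    dff = correct_illumination(dff)
    if config.apply_filter:
        dff = spatial_filter(dff, config.filter_window)
    try:
        rmap = amplitude_map(
            dff, mask, config.positive_frames, config.negative_frames
        )
    except ValidationError as exc:
        raise ValidationError(f"amplitude_map: {exc}") from exc
    return rmap, region_time_course(dff, mask)


def process_cohort(
    cohort: Cohort, config: ProcessingConfig = ProcessingConfig()
) -> "CohortMaps":
    """Process every recording of a (simulated or loaded) cohort."""
    per_presentation: dict = {}
    for bee_idx in range(cohort.n_bees):
        bee_id = cohort.bee_ids[bee_idx]
        for stimulus in cohort.panel.names:
            for presentation in (1, 2):
                movie = cohort.movie(bee_idx, stimulus, presentation)
                rmap, _ = process_recording(movie, cohort.mask, config)
                per_presentation[(bee_id, stimulus, presentation)] = rmap
    return CohortMaps(cohort, per_presentation)


@dataclass
class CohortMaps:
    """Response maps of a processed cohort, per presentation."""

    cohort: Cohort
    per_presentation: dict  # (bee_id, stimulus, presentation) -> ResponseMap

    def averaged(self, bee_id: str, stimulus: str) -> ResponseMap:
        return average_presentations(
            [
                self.per_presentation[(bee_id, stimulus, p)]
                for p in (1, 2)
            ]
        )

    def amplitude_table(self) -> AmplitudeTable:
        """Bee x stimulus mean response intensities (over 2 presentations)."""
        rows = [
            {
                "bee_id": bee_id,
                "structure": self.cohort.structure,
                "stimulus": stimulus,
                "amplitude": response_intensity(self.averaged(bee_id, stimulus)),
            }
            for bee_id in self.cohort.bee_ids
            for stimulus in self.cohort.panel.names
        ]
        return AmplitudeTable(pd.DataFrame(rows))
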