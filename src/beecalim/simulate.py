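"""Synthetic calcium-imaging movies with known ground truth.

The generator emulates the signal structure the analysis pipeline assumes:

* odor-specific spatial activity patterns ("glomerular" Gaussian blobs in
  AL mode, a smoother low-spatial-frequency field in LH/MB mode) whose
  similarity structure mirrors chemical similarity (carbon chain length
  and functional group);
* response amplitudes coupled to the logarithm of odorant vapor pressure;
* a biphasic temporal kernel — rise during the stimulus, plateau at its
  end, then a long-lasting undershoot with slow recovery;
* multiplicative photobleaching, frame-level illumination jitter,
  additive pixel noise, and 12-bit quantization.

The forward model for a pixel at frame ``f`` (1-based) is

    F = B(x,y) * (1-bleach)^(f-1) * (1 + A/100 * P(x,y) * k(f))
        * (1 + j_f) + noise

with ``B`` a smooth baseline map, ``P`` the unit-norm spatial pattern,
``k`` the kernel and ``j_f`` the per-frame illumination jitter; the
result is clipped to [0, 4095] and rounded to integer counts.  The model
is multiplicative so that dF/F recovers ``A * P * k`` exactly in the
noiseless, bleach-free limit — the basis of the package's
forward/inverse consistency checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_mask, write_movie
from .types import (
    DistanceMatrix,
    Mask,
    Movie,
    OdorPanel,
    OdorStimulus,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Temporal kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiphasicKernel:
    """Biphasic response kernel, peak-normalized to +1.

    Piecewise form (1-based frames): zero before ``onset_frame``, linear
    rise over ``rise_frames`` to a plateau of ``peak_plateau_frames``,
    linear decline to ``undershoot_depth`` (negative) at
    ``undershoot_onset_frame``, then exponential recovery with time
    constant ``recovery_tau`` frames.
    """

    onset_frame: int = 15
    rise_frames: int = 5
    peak_plateau_frames: int = 3
    undershoot_onset_frame: int = 50
    undershoot_depth: float = -0.3
    recovery_tau: float = 30.0
    n_frames: int = 100
    values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.undershoot_depth > 0:
            raise ValidationError("undershoot depth must be <= 0")
        vals = np.array(
            [self.value_at(f) for f in range(1, self.n_frames + 1)], dtype=float
        )
        object.__setattr__(self, "values", vals)
        peak_frame = int(np.argmax(vals)) + 1
        if not self.onset_frame <= peak_frame <= self.onset_frame + 10:
            raise ValidationError(
                f"positive lobe peaks at frame {peak_frame}, outside "
                f"{self.onset_frame}..{self.onset_frame + 10}"
            )

    def value_at(self, f: int) -> float:
        """Scalar closed form at a 1-based frame index."""
        onset = self.onset_frame
        peak_start = onset + self.rise_frames - 1
        peak_end = peak_start + self.peak_plateau_frames - 1
        trough = self.undershoot_onset_frame
        depth = self.undershoot_depth
        if f < onset:
            return 0.0
        if f < peak_start:
            return (f - onset + 1) / self.rise_frames
        if f <= peak_end:
            return 1.0
        if f < trough:
            return 1.0 + (depth - 1.0) * (f - peak_end) / (trough - peak_end)
        return depth * math.exp(-(f - trough) / self.recovery_tau)

    def contrast(
        self,
        positive_frames: tuple[int, int] = (19, 21),
        negative_frames: tuple[int, int] = (49, 51),
    ) -> float:
        """Mean over the positive window minus mean over the negative one.

        This is the factor linking the injected amplitude ``A`` to the
        biphasic amplitude the processing pipeline measures.
        """
        p = self.values[positive_frames[0] - 1 : positive_frames[1]]
        n = self.values[negative_frames[0] - 1 : negative_frames[1]]
        return float(p.mean() - n.mean())


def biphasic_kernel(**params) -> BiphasicKernel:
    """Build a :class:`BiphasicKernel` from keyword parameters."""
    return BiphasicKernel(**params)


# ---------------------------------------------------------------------------
# Latent odor coordinates and spatial patterns
# ---------------------------------------------------------------------------

#: Axis scales of the latent chemical space: carbon chain length is the
#: dominant axis; the oxygen moiety (alcohol vs carbonyl) comes second,
#: the subtype within a moiety (primary/secondary, aldehyde/ketone) third.
CHAIN_SCALE = 1.2
MOIETY_SCALE = 0.6
SUBTYPE_SCALE = 0.35

_GROUP_AXES = {
    "primary_alcohol": (+1.0, +1.0),
    "secondary_alcohol": (+1.0, -1.0),
    "aldehyde": (-1.0, +1.0),
    "ketone": (-1.0, -1.0),
    "pheromone": (0.0, 0.0),
    "control": (0.0, 0.0),
}


def latent_coordinates(odor: OdorStimulus) -> np.ndarray:
    """3-D latent chemical coordinates of a stimulus.

    Axis 0: centered chain length; axis 1: C-OH vs C=O moiety; axis 2:
    subtype within a moiety.  Controls and pheromones sit at the origin
    of the chain axis.
    """
    chain = odor.chain_length if odor.chain_length is not None else 7.5
    moiety, subtype = _GROUP_AXES[odor.functional_group]
    return np.array(
        [
            CHAIN_SCALE * (chain - 7.5),
            MOIETY_SCALE * moiety,
            SUBTYPE_SCALE * subtype,
        ]
    )


@dataclass(frozen=True)
class BlobGeometry:
    """Layout of response hot-spots within an elliptical structure mask.

    In AL mode the hot-spots stand for glomeruli: the default of 23 blobs
    on a hexagonal layout is an arbitrary but plausible count at this
    magnification.  LH/MB mode uses fewer, wider blobs, giving a smooth
    low-spatial-frequency field.
    """

    # The elliptical mask covers < 50% of the frame so that the frame-wide
    # median used for illumination correction sits in the silent surround.
    shape: tuple[int, int] = (120, 160)
    structure: str = "AL"
    n_blobs: int = 23
    mask_margin: float = 0.78
    blob_margin: float = 0.60
    sigma_scale: float = 0.45
    tuning_width: float = 0.9
    tuning_spread: tuple[float, float, float] = (2.0, 0.8, 0.5)
    layout_seed: int = 0

    def __post_init__(self) -> None:
        if self.structure == "AL" and self.n_blobs < 2:
            raise ValidationError("AL geometry requires at least 2 blobs")

    def mask(self) -> Mask:
        h, w = self.shape
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        a, b = self.mask_margin * h / 2.0, self.mask_margin * w / 2.0
        inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        return Mask(inside, label=self.structure)

    def blob_layout(self) -> tuple[np.ndarray, float]:
        """Hexagonal blob centers (n, 2) inside the ellipse, and sigma."""
        h, w = self.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        a, b = self.blob_margin * h / 2.0, self.blob_margin * w / 2.0
        area = math.pi * a * b
        spacing = math.sqrt(area / (self.n_blobs * math.sqrt(3) / 2.0))
        for _ in range(40):
            pts = []
            ny = int(2 * a / (spacing * math.sqrt(3) / 2)) + 3
            nx = int(2 * b / spacing) + 3
            for i in range(-ny, ny + 1):
                y = cy + i * spacing * math.sqrt(3) / 2
                off = (i % 2) * spacing / 2
                for j in range(-nx, nx + 1):
                    x = cx + j * spacing + off
                    if ((y - cy) / a) ** 2 + ((x - cx) / b) ** 2 <= 1.0:
                        pts.append((y, x))
            if len(pts) >= self.n_blobs:
                break
            spacing *= 0.92
        pts_arr = np.array(pts)
        r = ((pts_arr[:, 0] - cy) / a) ** 2 + ((pts_arr[:, 1] - cx) / b) ** 2
        pts_arr = pts_arr[np.argsort(r)][: self.n_blobs]
        sigma = self.sigma_scale * spacing
        if self.structure in ("LH", "MB"):
            sigma *= 2.2
        return pts_arr, sigma

    def blob_tunings(self) -> np.ndarray:
        """Latent tuning vector of each blob, fixed by the layout seed.

        Tunings are drawn uniformly over a box spanning the latent space
        so every chain length and functional group is covered by some
        blobs.
        """
        rng = np.random.default_rng(
            np.random.SeedSequence((self.layout_seed, 17))
        )
        spread = np.asarray(self.tuning_spread, dtype=float)
        return spread * rng.uniform(-1.0, 1.0, size=(self.n_blobs, 3))


def default_geometry(
    structure: str = "AL", shape: tuple[int, int] = (120, 160)
) -> BlobGeometry:
    if structure in ("LH", "MB"):
        return BlobGeometry(shape=shape, structure=structure, n_blobs=8)
    return BlobGeometry(shape=shape, structure=structure)


def spatial_pattern(
    odor: OdorStimulus,
    structure: str = "AL",
    geometry: BlobGeometry | None = None,
    seed: int = 0,
    jitter_terms: tuple = (),
) -> np.ndarray:
    """Unit-norm nonnegative response pattern for one odorant.

    Blob weights are a smooth Gaussian function of the distance between
    the odorant's latent chemical coordinates and each blob's tuning
    vector, so that pattern distances mirror chemical distances.
    ``jitter_terms`` is a sequence of ``(sigma, key)`` pairs, each adding
    an independent seeded multiplicative log-normal perturbation; keying
    a term by bee only makes it shared across presentations, keying by
    bee and presentation makes it trial-specific.
    """
    geometry = geometry or default_geometry(structure)
    centers, sigma = geometry.blob_layout()
    tunings = geometry.blob_tunings()
    coords = latent_coordinates(odor)
    d2 = ((tunings - coords) ** 2).sum(axis=1)
    weights = np.exp(-d2 / (2.0 * geometry.tuning_width**2)) + 0.05
    for jitter, key in jitter_terms:
        if jitter <= 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence((seed, *key)))
        weights = weights * np.exp(jitter * rng.standard_normal(len(weights)))
    h, w = geometry.shape
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.zeros((h, w))
    for (cy, cx), wgt in zip(centers, weights):
        grid += wgt * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    include = geometry.mask().include
    grid[~include] = 0.0
    norm = math.sqrt(float((grid[include] ** 2).sum()))
    if norm == 0:
        raise ValidationError("degenerate pattern: zero norm inside the mask")
    return grid / norm


# ---------------------------------------------------------------------------
# Movie synthesis
# ---------------------------------------------------------------------------


def baseline_map(shape: tuple[int, int], level: float = 3000.0) -> np.ndarray:
    """Smooth non-uniform resting-fluorescence map (camera counts)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    s = 0.55 * min(h, w)
    vignette = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s**2))
    return level * (0.70 + 0.30 * vignette)


def simulate_movie(
    pattern: np.ndarray,
    amplitude: float,
    kernel: BiphasicKernel,
    baseline: float | np.ndarray = 3000.0,
    bleach_rate: float = 0.0,
    illumination_sigma: float = 0.0,
    pixel_noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    quantize: bool = True,
    **movie_meta,
) -> Movie:
    """Render one movie from the multiplicative forward model."""
    pattern = np.asarray(pattern, dtype=float)
    base = baseline if isinstance(baseline, np.ndarray) else baseline_map(
        pattern.shape, baseline
    )
    if base.shape != pattern.shape:
        raise ValidationError("baseline map and pattern shapes differ")
    n = kernel.n_frames
    response = 1.0 + (amplitude / 100.0) * pattern[:, :, None] * kernel.values
    if response.min() < 0:
        raise ValidationError(
            "amplitude drives the forward model negative before clipping"
        )
    frames = np.arange(n, dtype=float)
    bleach = (1.0 - bleach_rate) ** frames
    rng = np.random.default_rng(seed)
    jitter = (
        1.0 + illumination_sigma * rng.standard_normal(n)
        if illumination_sigma > 0
        else np.ones(n)
    )
    movie = base[:, :, None] * bleach * response * jitter
    if pixel_noise_sd > 0:
        movie = movie + pixel_noise_sd * rng.standard_normal(movie.shape)
    movie = np.clip(movie, 0.0, 4095.0)
    if quantize:
        movie = np.rint(movie).astype(np.uint16)
    meta = {
        "stimulus_onset_frame": kernel.onset_frame,
        "stimulus_duration_frames": kernel.rise_frames,
    }
    meta.update(movie_meta)
    return Movie(movie, **meta)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Simulation bookkeeping for a cohort.

    ``amplitudes`` has one row per bee x stimulus with the injected
    amplitude, the per-presentation response gains (kernel contrast x
    in-mask mean of the filtered, median-corrected pattern) and the
    expected pipeline intensity.  ``latent`` stores each stimulus's
    latent chemical coordinates.
    """

    amplitudes: pd.DataFrame
    latent: pd.DataFrame
    params: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.amplitudes.to_csv(outdir / "ground_truth.csv", index=False)
        self.latent.to_csv(outdir / "latent_coordinates.csv", index=False)
        (outdir / "simulation_params.json").write_text(
            json.dumps(self.params, indent=1, sort_keys=True)
        )

    def latent_distance_matrix(self) -> DistanceMatrix:
        """Euclidean distances between odorant latent coordinates."""
        lat = self.latent[~self.latent["is_control"]]
        coords = lat[["lat0", "lat1", "lat2"]].to_numpy()
        diff = coords[:, None, :] - coords[None, :, :]
        values = np.sqrt((diff**2).sum(axis=2))
        return DistanceMatrix(values, list(lat["stimulus"]), "latent")


@dataclass
class Cohort:
    """A simulated experiment: n bees x panel x 2 presentations.

    Movies are rendered lazily and deterministically from the cohort
    seed, so a cohort of realistic size never has to sit in memory.
    """

    panel: OdorPanel
    structure: str
    geometry: BlobGeometry
    kernel: BiphasicKernel
    mask: Mask
    patterns: dict  # (bee_idx, stimulus, presentation) -> pattern grid
    ground_truth: GroundTruth
    params: dict

    @property
    def n_bees(self) -> int:
        return self.params["n_bees"]

    @property
    def bee_ids(self) -> list[str]:
        return [f"bee{i + 1:02d}" for i in range(self.n_bees)]

    def true_amplitude(self, bee_idx: int, stimulus: str) -> float:
        gt = self.ground_truth.amplitudes
        row = gt[(gt["bee_id"] == self.bee_ids[bee_idx]) & (gt["stimulus"] == stimulus)]
        return float(row["true_amplitude"].iloc[0])

    def movie(self, bee_idx: int, stimulus: str, presentation: int) -> Movie:
        stim_idx = self.panel.names.index(stimulus)
        seed_seq = np.random.SeedSequence(
            (self.params["seed"], 1000 + bee_idx, stim_idx, presentation)
        )
        return simulate_movie(
            self.patterns[(bee_idx, stimulus, presentation)],
            self.true_amplitude(bee_idx, stimulus),
            self.kernel,
            baseline=self.params["baseline"],
            bleach_rate=self.params["bleach_rate"],
            illumination_sigma=self.params["illumination_sigma"],
            pixel_noise_sd=self.params["pixel_noise_sd"],
            seed=seed_seq,
            structure_label=self.structure,
            bee_id=self.bee_ids[bee_idx],
            stimulus_id=stimulus,
            presentation_index=presentation,
        )

    def iter_movies(self):
        for bee_idx in range(self.n_bees):
            for stimulus in self.panel.names:
                for presentation in (1, 2):
                    yield self.movie(bee_idx, stimulus, presentation)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ground_truth.write(outdir)
        write_mask(self.mask, outdir / "mask.png")
        for movie in self.iter_movies():
            safe = movie.stimulus_id.replace(" ", "_")
            name = f"{movie.bee_id}_{safe}_p{movie.presentation_index}.tif"
            write_movie(movie, outdir / name)


def generate_cohort(
    panel: OdorPanel,
    n_bees: int = 10,
    structure: str = "AL",
    amplitude_model: tuple[float, float] = (30.0, 12.0),
    geometry: BlobGeometry | None = None,
    kernel: BiphasicKernel | None = None,
    baseline: float = 3000.0,
    bleach_rate: float = 5e-4,
    illumination_sigma: float = 0.002,
    pixel_noise_sd: float = 8.0,
    bee_gain_sd: float = 0.15,
    bee_pattern_jitter: float = 0.15,
    presentation_jitter: float = 0.05,
    seed: int = 0,
) -> Cohort:
    """Simulate a cohort with 2 presentations of every panel stimulus.

    True amplitudes follow ``a + b * log10(vapor_pressure)`` scaled by a
    per-bee log-normal gain; control stimuli get amplitude 0.  Patterns
    carry seeded bee-level jitter (individual glomerular variability) and
    smaller presentation-level jitter (trial-to-trial variability).
    """
    if n_bees < 2:
        raise ValidationError("a cohort needs at least 2 bees")
    geometry = geometry or default_geometry(structure)
    kernel = kernel or BiphasicKernel()
    mask = geometry.mask()
    a, b = amplitude_model
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    bee_gains = np.exp(bee_gain_sd * rng.standard_normal(n_bees))

    # pipeline settings implied by the structure, used for expected gains
    from .processing import default_filter_window, spatial_filter_frame

    window = default_filter_window(structure)
    kc = kernel.contrast()
    include = mask.include

    bee_ids = [f"bee{i + 1:02d}" for i in range(n_bees)]
    patterns: dict = {}
    rows = []
    for stim_idx, stim in enumerate(panel):
        base_amp = 0.0 if stim.is_control else _model_amplitude(stim, a, b)
        for bee_idx in range(n_bees):
            gains = []
            for presentation in (1, 2):
                # namespace 2: bee-level jitter (shared across presentations);
                # namespace 3: presentation-level jitter (trial-specific)
                pat = spatial_pattern(
                    stim,
                    structure,
                    geometry,
                    seed=seed,
                    jitter_terms=(
                        (bee_pattern_jitter, (2, bee_idx, stim_idx)),
                        (presentation_jitter, (3, bee_idx, stim_idx, presentation)),
                    ),
                )
                patterns[(bee_idx, stim.name, presentation)] = pat
                corrected = pat - np.median(pat)
                filtered = spatial_filter_frame(corrected, window)
                gains.append(kc * float(filtered[include].mean()))
            amp = base_amp * bee_gains[bee_idx]
            rows.append(
                {
                    "bee_id": bee_ids[bee_idx],
                    "structure": structure,
                    "stimulus": stim.name,
                    "true_amplitude": amp,
                    "gain_p1": gains[0],
                    "gain_p2": gains[1],
                    "expected_intensity": amp * (gains[0] + gains[1]) / 2.0,
                }
            )

    latent_rows = [
        {
            "stimulus": s.name,
            "functional_group": s.functional_group,
            "chain_length": s.chain_length,
            "vapor_pressure": s.vapor_pressure,
            "is_control": s.is_control,
            **{f"lat{i}": v for i, v in enumerate(latent_coordinates(s))},
        }
        for s in panel
    ]
    params = {
        "seed": seed,
        "n_bees": n_bees,
        "structure": structure,
        "amplitude_model": list(amplitude_model),
        "baseline": baseline,
        "bleach_rate": bleach_rate,
        "illumination_sigma": illumination_sigma,
        "pixel_noise_sd": pixel_noise_sd,
        "bee_gain_sd": bee_gain_sd,
        "bee_pattern_jitter": bee_pattern_jitter,
        "presentation_jitter": presentation_jitter,
        "filter_window": window,
        "kernel_contrast": kc,
        "shape": list(geometry.shape),
    }
    ground_truth = GroundTruth(
        pd.DataFrame(rows), pd.DataFrame(latent_rows), params
    )
    return Cohort(
        panel, structure, geometry, kernel, mask, patterns, ground_truth, params
    )


def _model_amplitude(stim: OdorStimulus, a: float, b: float) -> float:
    if stim.vapor_pressure is None or stim.vapor_pressure <= 0:
        return a
    return a + b * math.log10(stim.vapor_pressure)


# ---------------------------------------------------------------------------
# Behavioral distance matrix
# ---------------------------------------------------------------------------


def generate_behavior_matrix(
    ground_truth: GroundTruth,
    distortion: float = 0.5,
    seed: int = 0,
) -> DistanceMatrix:
    """Behavior-like odor distance matrix from latent coordinates.

    At ``distortion`` 0 this is exactly the latent distance matrix; the
    distortion level adds seeded symmetric positive perturbations scaled
    by the median latent distance, monotonically degrading the expected
    correlation with the neural matrices.
    """
    latent = ground_truth.latent_distance_matrix()
    if distortion == 0:
        return DistanceMatrix(latent.values, latent.labels, "behavioral")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    n = latent.n
    noise = np.abs(rng.standard_normal((n, n)))
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    scale = distortion * np.median(latent.condensed())
    values = latent.values + scale * noise
    return DistanceMatrix(values, latent.labels, "behavioral")
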