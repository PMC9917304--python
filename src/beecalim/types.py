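"""Core domain types for multisite calcium-imaging analysis.

The central object is a :class:`Movie`, a raw fluorescence stack of shape
(height, width, n_frames) in camera counts (12-bit).  The processing
pipeline turns it into a :class:`DffMovie` (relative fluorescence change,
in percent) and then a :class:`ResponseMap` (per-pixel biphasic response
amplitude).  Odor-coding analyses operate on :class:`ResponseMap`,
:class:`DistanceMatrix` and :class:`AmplitudeTable` objects.

Frame indices in user-facing fields (stimulus onset, baseline windows) are
1-based and inclusive, matching the conventions of the imaging literature;
conversion to 0-based array indexing happens in :func:`frames_to_slice`
and nowhere else.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MAX_INTENSITY = 4095  # 12-bit camera
STRUCTURES = ("AL", "LH", "MB", "whole_brain")
FUNCTIONAL_GROUPS = (
    "primary_alcohol",
    "secondary_alcohol",
    "aldehyde",
    "ketone",
    "pheromone",
    "control",
)


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class CompletenessError(ValidationError):
    """Raised when a block design is missing bee x stimulus cells."""


def frames_to_slice(first: int, last: int) -> slice:
    """Convert a 1-based inclusive frame range to a python slice.

    This is the single place where 1-based frame conventions meet 0-based
    array indexing.
    """
    if first < 1 or last < first:
        raise ValidationError(f"invalid frame range {first}..{last}")
    return slice(first - 1, last)


@dataclass
class Movie:
    """Raw fluorescence stack, (height, width, n_frames), camera counts."""

    pixels: np.ndarray
    frame_rate: float = 5.0
    stimulus_onset_frame: int = 15  # 1-based
    stimulus_duration_frames: int = 5
    structure_label: str = "AL"
    bee_id: str = ""
    stimulus_id: str = ""
    presentation_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValidationError(
                f"movie must be (height, width, n_frames); got ndim={self.pixels.ndim}"
            )
        if np.any(self.pixels < 0):
            raise ValidationError("raw movie contains negative intensities")
        if np.issubdtype(self.pixels.dtype, np.integer) and np.any(
            self.pixels > MAX_INTENSITY
        ):
            raise ValidationError("raw movie exceeds the 12-bit range")
        if self.structure_label not in STRUCTURES:
            raise ValidationError(f"unknown structure {self.structure_label!r}")
        if self.stimulus_onset_frame + self.stimulus_duration_frames > self.n_frames:
            raise ValidationError("stimulus window extends past the last frame")
        if self.n_frames != 100:
            warnings.warn(
                f"movie has {self.n_frames} frames; the standard acquisition is 100",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[2]

    def metadata(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "stimulus_onset_frame": self.stimulus_onset_frame,
            "stimulus_duration_frames": self.stimulus_duration_frames,
            "structure_label": self.structure_label,
            "bee_id": self.bee_id,
            "stimulus_id": self.stimulus_id,
            "presentation_index": self.presentation_index,
        }


@dataclass
class DffMovie:
    """Relative fluorescence change, percent, (height, width, n_frames)."""

    values: np.ndarray
    baseline_frames: tuple[int, int]  # 1-based inclusive
    frame_rate: float = 5.0
    stimulus_onset_frame: int = 15
    structure_label: str = "AL"
    bee_id: str = ""
    stimulus_id: str = ""
    presentation_index: int = 1
    processing_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("dF/F stack must be 3-dimensional")
        lo, hi = self.baseline_frames
        if hi >= self.stimulus_onset_frame:
            raise ValidationError(
                "baseline frames must end strictly before stimulus onset"
            )
        frames_to_slice(lo, hi)  # validates ordering

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


@dataclass
class Mask:
    """Boolean inclusion grid delimiting the imaged structure."""

    include: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 2:
            raise ValidationError("mask must be 2-dimensional")
        if not self.include.any():
            raise ValidationError("mask excludes every pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.include.shape

    @property
    def n_pixels(self) -> int:
        return int(self.include.sum())


@dataclass(frozen=True)
class OdorStimulus:
    """One stimulus of a panel: an odorant, a pheromone or a control."""

    name: str
    functional_group: str = "control"
    chain_length: int | None = None
    vapor_pressure: float | None = None  # mmHg
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValidationError(
                f"unknown functional group {self.functional_group!r}"
            )
        if self.functional_group == "control" and not self.is_control:
            raise ValidationError("control functional group requires is_control")
        if self.chain_length is not None and not 6 <= self.chain_length <= 9:
            raise ValidationError("chain length must lie in 6..9")


@dataclass
class OdorPanel:
    """Ordered stimulus panel presented to every bee of a cohort."""

    stimuli: list[OdorStimulus]
    panel_name: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.stimuli]
        if len(set(names)) != len(names):
            raise ValidationError("stimulus names must be unique")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stimuli]

    @property
    def odorants(self) -> list[OdorStimulus]:
        return [s for s in self.stimuli if not s.is_control]

    @property
    def controls(self) -> list[OdorStimulus]:
        return [s for s in self.stimuli if s.is_control]

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def get(self, name: str) -> OdorStimulus:
        for s in self.stimuli:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class ResponseMap:
    """Per-pixel biphasic response amplitude (dF/F %), with mask."""

    amplitude: np.ndarray
    mask: Mask
    bee_id: str = ""
    stimulus_id: str = ""
    presentation_index: int | None = 1  # None once presentations are averaged

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != self.mask.shape:
            raise ValidationError("map and mask shapes differ")

    @property
    def valid_values(self) -> np.ndarray:
        """Amplitudes of in-mask pixels, 1-D."""
        return self.amplitude[self.mask.include]


@dataclass
class TimeCourse:
    """Region-averaged dF/F trace (percent per frame)."""

    dff: np.ndarray
    frame_rate: float = 5.0
    region: str = ""
    bee_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float).ravel()

    @property
    def n_frames(self) -> int:
        return self.dff.size

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 1 at t=0)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class AmplitudeTable:
    """Long-format bee x stimulus mean response intensities (dF/F %).

    The design must be a complete block: every bee has a value for every
    stimulus of the panel (animals with missing presentations are excluded
    upstream).
    """

    data: pd.DataFrame  # columns: bee_id, structure, stimulus, amplitude

    REQUIRED = ("bee_id", "structure", "stimulus", "amplitude")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"amplitude table lacks columns {missing}")
        self.data = self.data.reset_index(drop=True)
        self.validate_complete()

    def validate_complete(self) -> None:
        stimuli = set(self.data["stimulus"])
        missing_pairs = []
        for bee, sub in self.data.groupby("bee_id"):
            absent = stimuli - set(sub["stimulus"])
            missing_pairs.extend((bee, s) for s in sorted(absent))
            dup = sub["stimulus"].duplicated()
            if dup.any():
                raise ValidationError(
                    f"bee {bee!r} has duplicated stimuli: "
                    f"{sorted(sub['stimulus'][dup])}"
                )
        if missing_pairs:
            raise CompletenessError(
                f"incomplete block design; missing (bee, stimulus) pairs: "
                f"{missing_pairs}"
            )

    @property
    def bees(self) -> list:
        return sorted(self.data["bee_id"].unique())

    @property
    def stimuli(self) -> list:
        return sorted(self.data["stimulus"].unique())

    def wide(self) -> pd.DataFrame:
        """Pivot to bees x stimuli, preserving first-seen stimulus order."""
        order = list(dict.fromkeys(self.data["stimulus"]))
        return self.data.pivot(
            index="bee_id", columns="stimulus", values="amplitude"
        )[order]

    def mean_per_stimulus(self) -> pd.Series:
        return self.data.groupby("stimulus")["amplitude"].mean()


@dataclass
class DistanceMatrix:
    """Symmetric labeled matrix of Euclidean distances between odors."""

    values: np.ndarray
    labels: list[str]
    provenance: str = "per-bee"  # per-bee | cross-bee-mean | behavioral | latent

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("distance matrix labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-8):
            raise ValidationError("distances must be nonnegative")
        # enforce exact symmetry / zero diagonal after tolerance checks
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            self.values[np.ix_(idx, idx)], list(labels), self.provenance
        )


@dataclass
class Dendrogram:
    """Agglomerative merge tree (Ward), wrapping a scipy linkage matrix."""

    linkage: np.ndarray  # (n-1, 4): cluster_a, cluster_b, height, size
    leaf_labels: list[str]

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.leaf_labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValidationError(
                f"linkage shape {self.linkage.shape} does not match {n} leaves"
            )

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def first_bipartition(self) -> tuple[set[str], set[str]]:
        """Leaf labels on each side of the root (the last merge)."""
        n = len(self.leaf_labels)

        def members(node: int) -> set[str]:
            if node < n:
                return {self.leaf_labels[node]}
            a, b = self.linkage[node - n, 0], self.linkage[node - n, 1]
            return members(int(a)) | members(int(b))

        last = self.linkage[-1]
        return members(int(last[0])), members(int(last[1]))

    def to_newick(self) -> str:
        """Nested-parenthesis text form with merge heights as branch labels."""
        n = len(self.leaf_labels)

        def rec(node: int) -> str:
            if node < n:
                return self.leaf_labels[node].replace(" ", "_")
            a, b, h, _ = self.linkage[node - n]
            return f"({rec(int(a))},{rec(int(b))}):{h:.6g}"

        return rec(2 * n - 2) + ";"


def replace(obj, **changes):
    """dataclasses.replace that is re-exported for pipeline convenience."""
    return dataclasses.replace(obj, **changes)
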